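"""End-to-end synthetic modeling-control scenario.

Reproduces, on virtual plants, the full experimental protocol the package
implements:

1. FARIT stimulation of the upstream pathway; the upstream ground truth
   turns it into varying population-spike amplitudes (DG), and the
   trajectory ground truth turns those into reference downstream responses
   (the "trisynaptic" outputs).  A trajectory model is fitted on this data.
2. RARIT stimulation of the downstream pathway through the plant ground
   truth; a plant model is fitted on this data.
3. The fitted trajectory model predicts desired downstream outputs from
   the DG trains; the fitted inverse plant model converts them into DARIT
   stimulation amplitudes; the DARITs are "delivered" to the plant ground
   truth and the evoked responses compared with the reference outputs.
4. A non-optimal comparison arm stimulates with a fixed amplitude equal to
   the mean DARIT amplitude.

The headline readouts are the NMSE of the controlled responses against the
reference outputs, and the same NMSE for the fixed-amplitude arm; model-
based control should track the reference dynamics, the fixed arm cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .control import ControlResult, run_control_pipeline
from .estimation import FitReport, fit_trains
from .events import EventTrain
from .laguerre import LaguerreBasis, build_basis
from .metrics import nmse
from .synthetic import (TrainSpec, generate_farit, generate_rarit,
                        make_ground_truth_model, simulate_plant)

__all__ = ["EndToEndResult", "run_endtoend"]


@dataclass
class EndToEndResult:
    """Everything the end-to-end scenario produced."""

    trajectory_report: FitReport
    plant_report: FitReport
    controls: list[ControlResult]
    dg_trains: list[EventTrain]
    reference_outputs: np.ndarray      # trisynaptic (desired-path) responses
    controlled_outputs: np.ndarray     # plant responses to the DARITs
    fixed_outputs: np.ndarray          # plant responses to fixed-amplitude arm
    controlled_nmse: float
    fixed_nmse: float
    mean_darit_amplitude: float
    flag_counts: dict = field(default_factory=dict)
    seed: int = 0
    noise_sd: float = 0.0
    preset: str = "mixed"

    def summary(self) -> dict:
        return {
            "preset": self.preset, "seed": self.seed, "noise_sd": self.noise_sd,
            "controlled_nmse_pct": 100.0 * self.controlled_nmse,
            "fixed_nmse_pct": 100.0 * self.fixed_nmse,
            "mean_darit_amplitude": self.mean_darit_amplitude,
            "trajectory_mean_train_vaf": float(
                np.mean(self.trajectory_report.per_train_vaf)),
            "plant_mean_train_vaf": float(
                np.mean(self.plant_report.per_train_vaf)),
            "flag_counts": self.flag_counts,
            "n_events": int(self.reference_outputs.size),
        }


def run_endtoend(preset: str = "mixed", noise_sd: float = 0.05,
                 seed: int = 0, n_trains: int = 4, n_pulses: int = 300,
                 farit_amplitude: float = 200.0,
                 rarit_mean: float = 150.0, rarit_sd: float = 45.0,
                 basis: LaguerreBasis | None = None) -> EndToEndResult:
    """Run the full synthetic modeling-control protocol.

    Parameters
    ----------
    preset : str
        Ground-truth plant preset for the stimulated (downstream) system.
    noise_sd : float
        Gaussian output noise (mV) applied to every simulated response.
    seed : int
        Seed of the single random stream driving the whole scenario.

    Returns
    -------
    EndToEndResult
    """
    rng = np.random.default_rng(seed)
    if basis is None:
        basis = build_basis()
    upstream = make_ground_truth_model("dg_upstream", basis, noise_sd)
    trajectory_true = make_ground_truth_model("trajectory", basis, noise_sd)
    plant_true = make_ground_truth_model(preset, basis, noise_sd)

    # Step 1: FARIT -> upstream responses -> reference downstream responses.
    farit_spec = TrainSpec(n_trains=n_trains, n_pulses=n_pulses,
                           amplitude_mode="fixed",
                           amplitude_params=(farit_amplitude,), seed=seed)
    farits = generate_farit(farit_spec, rng)
    dg_trains, tri_trains = [], []
    for train in farits:
        dg_amps = simulate_plant(upstream, train, rng).outputs
        dg = EventTrain(train.times, np.maximum(dg_amps, 0.0),
                        train_id=train.train_id.replace("farit", "dg"),
                        amplitude_unit="mV")
        tri = simulate_plant(trajectory_true, dg, rng)
        dg_trains.append(dg)
        tri_trains.append(tri)
    trajectory_report = fit_trains(basis, tri_trains)

    # Step 2: RARIT -> plant responses -> plant model.
    rarit_spec = TrainSpec(n_trains=n_trains, n_pulses=n_pulses,
                           amplitude_mode="gaussian",
                           amplitude_params=(rarit_mean, rarit_sd), seed=seed)
    rarits = generate_rarit(rarit_spec, rng)
    mono_trains = [simulate_plant(plant_true, t, rng) for t in rarits]
    plant_report = fit_trains(basis, mono_trains)

    # Step 3: trajectory prediction -> inverse plant -> DARIT -> delivery.
    controls, controlled, flag_counts = [], [], {}
    for dg in dg_trains:
        res = run_control_pipeline(trajectory_report.coefficients, basis,
                                   plant_report.coefficients, basis, dg)
        controls.append(res)
        darit = res.to_train(dg.train_id.replace("dg", "darit"))
        controlled.append(simulate_plant(plant_true, darit, rng).outputs)
        for k, n in res.flag_counts().items():
            flag_counts[k] = flag_counts.get(k, 0) + n
    reference = np.concatenate([t.outputs for t in tri_trains])
    controlled = np.concatenate(controlled)
    mean_amp = float(np.mean(np.concatenate([r.amplitudes for r in controls])))

    # Step 4: non-optimal fixed-amplitude arm at matched mean intensity.
    fixed = []
    for dg in dg_trains:
        const = EventTrain(dg.times, np.full(dg.n_events, mean_amp),
                           train_id=dg.train_id.replace("dg", "fixed"))
        fixed.append(simulate_plant(plant_true, const, rng).outputs)
    fixed = np.concatenate(fixed)

    return EndToEndResult(
        trajectory_report=trajectory_report, plant_report=plant_report,
        controls=controls, dg_trains=dg_trains,
        reference_outputs=reference, controlled_outputs=controlled,
        fixed_outputs=fixed,
        controlled_nmse=nmse(reference, controlled),
        fixed_nmse=nmse(reference, fixed),
        mean_darit_amplitude=mean_amp, flag_counts=flag_counts,
        seed=seed, noise_sd=noise_sd, preset=preset)
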