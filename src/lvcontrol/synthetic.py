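"""Synthetic stimulation protocols and ground-truth virtual plants.

Emulates the experimental protocols the models were designed for, so every
other module is testable without laboratory data:

* FARIT - fixed-amplitude random-interval trains: 4 trains x 300 pulses,
  Poisson (exponential-interval) timing truncated to [2 ms, 5 s] at a mean
  rate of 2 Hz, constant intensity (default 200 uA within the 150-300 uA
  fixed-intensity range).
* RARIT - random-amplitude random-interval trains: same timing, Gaussian
  amplitudes with mean 150 uA (sd default 45 uA, truncated at > 0).
* Ground-truth second-order LV plants with preset kernel signatures
  (facilitating / depressing / mixed paired-pulse dynamics), plus an
  upstream stimulation->population-spike preset and a trajectory
  (upstream->downstream) preset used by the end-to-end scenario.

Interval truncation is by resampling, not clipping, so no probability mass
accumulates at the bounds.  All randomness flows through an explicit
numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .events import EventTrain
from .laguerre import LaguerreBasis, build_basis
from .model import LVCoefficients, predict_output

__all__ = ["TrainSpec", "GroundTruthPlant", "generate_intervals",
           "generate_farit", "generate_rarit", "make_ground_truth_model",
           "simulate_plant", "PRESET_NAMES"]


@dataclass
class TrainSpec:
    """Protocol parameters of a random-interval train battery."""

    n_trains: int = 4
    n_pulses: int = 300
    mean_rate: float = 2.0                       # Hz
    interval_bounds: tuple = (0.002, 5.0)        # seconds
    amplitude_mode: str = "fixed"                # fixed | gaussian | supplied
    amplitude_params: tuple = (200.0,)           # (value) or (mean, sd)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.interval_bounds
        if not (0 <= lo < hi):
            raise ParameterError(f"interval bounds must be ordered; got {lo}, {hi}")
        if self.mean_rate <= 0:
            raise ParameterError("mean_rate must be positive")
        if self.n_trains < 1 or self.n_pulses < 1:
            raise ParameterError("n_trains and n_pulses must be >= 1")
        mean_interval = 1.0 / self.mean_rate
        # A truncated exponential on [lo, hi] has mean in (lo, (lo+hi)/2).
        if not (lo < mean_interval < 0.5 * (lo + hi)):
            raise ParameterError(
                f"mean interval {mean_interval}s unachievable within "
                f"truncation bounds {self.interval_bounds}")
        if self.amplitude_mode == "gaussian" and len(self.amplitude_params) < 2:
            raise ParameterError("gaussian amplitudes need (mean, sd)")
        if self.amplitude_mode == "gaussian" and self.amplitude_params[1] < 0:
            raise ParameterError("amplitude sd must be >= 0")


def generate_intervals(spec: TrainSpec, rng: np.random.Generator) -> np.ndarray:
    """Cumulative event times of one train: truncated-exponential intervals.

    Intervals are drawn from Exp(mean = 1/mean_rate) and redrawn until they
    fall inside ``interval_bounds`` (resampling, not clipping).
    """
    lo, hi = spec.interval_bounds
    mean = 1.0 / spec.mean_rate
    intervals = np.empty(spec.n_pulses)
    filled = 0
    while filled < spec.n_pulses:
        draw = rng.exponential(mean, size=2 * (spec.n_pulses - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, spec.n_pulses - filled)
        intervals[filled:filled + take] = ok[:take]
        filled += take
    return np.cumsum(intervals)


def _amplitudes(spec: TrainSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.amplitude_mode == "fixed":
        return np.full(spec.n_pulses, float(spec.amplitude_params[0]))
    if spec.amplitude_mode == "gaussian":
        mean, sd = spec.amplitude_params[:2]
        amps = rng.normal(mean, sd, size=spec.n_pulses)
        # truncate at > 0 by redrawing the (rare) non-positive values
        while np.any(amps <= 0):
            n_bad = int(np.sum(amps <= 0))
            amps[amps <= 0] = rng.normal(mean, sd, size=n_bad)
        return amps
    raise ParameterError(f"unknown amplitude mode {spec.amplitude_mode!r}")


def _generate(spec: TrainSpec, rng, prefix: str) -> list[EventTrain]:
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return [EventTrain(generate_intervals(spec, rng), _amplitudes(spec, rng),
                       train_id=f"{prefix}{k}")
            for k in range(spec.n_trains)]


def generate_farit(spec: TrainSpec | None = None,
                   rng: np.random.Generator | None = None) -> list[EventTrain]:
    """Fixed-amplitude random-interval trains (default 4 x 300 pulses)."""
    if spec is None:
        spec = TrainSpec()
    if spec.amplitude_mode != "fixed":
        raise ParameterError("FARIT requires amplitude_mode='fixed'")
    return _generate(spec, rng, "farit")


def generate_rarit(spec: TrainSpec | None = None,
                   rng: np.random.Generator | None = None) -> list[EventTrain]:
    """Random-amplitude (Gaussian, mean 150 uA) random-interval trains."""
    if spec is None:
        spec = TrainSpec(amplitude_mode="gaussian", amplitude_params=(150.0, 45.0))
    if spec.amplitude_mode != "gaussian":
        raise ParameterError("RARIT requires amplitude_mode='gaussian'")
    return _generate(spec, rng, "rarit")


# Ground-truth coefficient tables (all entries nonzero so that relative
# parameter-recovery checks are well defined).  Units: CA1 plant presets map
# stimulation uA -> fEPSP mV; "dg_upstream" maps stimulation uA -> population
# spike mV; "trajectory" maps population spike mV -> fEPSP mV.  Static curves
# are saturating (c2_present < 0) and monotone increasing over the operating
# amplitude range; first-order history terms carry the preset's paired-pulse
# signature.
_PRESETS: dict[str, dict] = {
    "facilitating": dict(
        c0=0.10, c1_present=4.0e-3, c2_present=-5.0e-6,
        c1=[2.0e-2, 6.0e-3, 2.0e-3],
        c2=[[-6.0e-5, 8.0e-6, 2.0e-6],
            [8.0e-6, -2.0e-5, 1.0e-6],
            [2.0e-6, 1.0e-6, -8.0e-6]],
        c2_cross=[-1.5e-5, -4.0e-6, -1.0e-6]),
    "depressing": dict(
        c0=0.10, c1_present=4.0e-3, c2_present=-5.0e-6,
        c1=[-1.6e-2, -5.0e-3, -1.5e-3],
        c2=[[-4.0e-5, 6.0e-6, 1.5e-6],
            [6.0e-6, -1.5e-5, 1.0e-6],
            [1.5e-6, 1.0e-6, -6.0e-6]],
        c2_cross=[6.0e-6, 2.0e-6, 5.0e-7]),
    "mixed": dict(
        c0=0.10, c1_present=4.0e-3, c2_present=-5.0e-6,
        c1=[1.8e-2, -8.0e-3, 3.0e-3],
        c2=[[-5.0e-5, 6.0e-6, 2.0e-6],
            [6.0e-6, -1.5e-5, 1.0e-6],
            [2.0e-6, 1.0e-6, -6.0e-6]],
        c2_cross=[-1.2e-5, 3.0e-6, -1.0e-6]),
    "dg_upstream": dict(
        c0=0.20, c1_present=6.0e-3, c2_present=-8.0e-6,
        c1=[3.0e-2, 1.0e-2, 4.0e-3],
        c2=[[-8.0e-5, 1.0e-5, 3.0e-6],
            [1.0e-5, -3.0e-5, 2.0e-6],
            [3.0e-6, 2.0e-6, -1.0e-5]],
        c2_cross=[-2.0e-5, -6.0e-6, -2.0e-6]),
    "trajectory": dict(
        c0=0.05, c1_present=0.5, c2_present=-0.08,
        c1=[0.8, 0.3, 0.1],
        c2=[[-0.5, 0.06, 0.02],
            [0.06, -0.15, 0.01],
            [0.02, 0.01, -0.06]],
        c2_cross=[-0.05, 0.012, -0.004]),
}

PRESET_NAMES = tuple(_PRESETS)


@dataclass
class GroundTruthPlant:
    """A known second-order LV system plus output-noise level."""

    coefficients: LVCoefficients
    basis: LaguerreBasis
    noise_sd: float
    preset_name: str


def make_ground_truth_model(preset: str,
                            basis: LaguerreBasis | None = None,
                            noise_sd: float = 0.05) -> GroundTruthPlant:
    """Instantiate a preset ground-truth plant on the given basis.

    Presets require a three-function basis (the coefficient tables are
    defined for L=3).  ``noise_sd`` is the Gaussian output noise (mV)
    added by :func:`simulate_plant`.
    """
    if preset not in _PRESETS:
        raise ParameterError(
            f"unknown preset {preset!r}; available: {sorted(_PRESETS)}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if basis is None:
        basis = build_basis()
    if basis.n_basis != 3:
        raise ParameterError("ground-truth presets are defined for n_basis=3")
    table = _PRESETS[preset]
    coeffs = LVCoefficients(basis_spec=basis.to_spec(), **table)
    return GroundTruthPlant(coefficients=coeffs, basis=basis,
                            noise_sd=float(noise_sd), preset_name=preset)


def simulate_plant(plant: GroundTruthPlant, train: EventTrain,
                   rng: np.random.Generator | None = None) -> EventTrain:
    """Simulate responses: model prediction plus Gaussian output noise."""
    y = predict_output(plant.coefficients, plant.basis, train)
    if plant.noise_sd > 0:
        if rng is None:
            raise ParameterError("rng required when noise_sd > 0")
        y = y + rng.normal(0.0, plant.noise_sd, size=y.shape)
    return train.with_outputs(y)
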