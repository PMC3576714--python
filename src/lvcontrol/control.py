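"""Inverse plant model: per-event quadratic solve for stimulation amplitude.

Because the LV model isolates the present-impulse terms, the predicted
output at an event is a quadratic in the present amplitude A:

    a A^2 + b A + c = 0, with
    a = c2(0,0)
    b = c1(0) + 2 sum_l c2(l) v_l
    c = c0 + sum_l c1(l) v_l + sum_{l1,l2} c2(l1,l2) v_l1 v_l2 - y_desired

where the convolutions v_l are built from *previously solved* amplitudes,
so the inversion proceeds recursively through the train: nothing is known
before the first stimulation, hence v = 0 there; each solved amplitude is
then convolved into the history for the next event.  The default root is

    A = (-b + sqrt(b^2 - 4ac)) / (2a)

which, for a saturating plant (a < 0, b > 0), selects the physically
meaningful root on the ascending limb of the static curve.  Degenerate and
infeasible events are flagged rather than fatal: a ~ 0 falls back to the
linear solve -c/b, a negative discriminant (target above the reachable
maximum) emits the vertex amplitude -b/(2a), and negative amplitudes are
clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, UnsolvableEventError
from .events import EventTrain
from .laguerre import LaguerreBasis, _convolution_at, check_basis_compatible
from .model import LVCoefficients, predict_output

__all__ = ["QuadraticTerms", "ControlResult", "quadratic_terms",
           "solve_amplitude", "invert_sequence", "run_control_pipeline",
           "FLAG_OK", "FLAG_CLAMPED", "FLAG_VERTEX", "FLAG_LINEAR"]

FLAG_OK = "ok"
FLAG_CLAMPED = "clamped_negative"
FLAG_VERTEX = "no_real_root_vertex"
FLAG_LINEAR = "linear_fallback"

#: |a| below this is treated as a linear (first-order) event equation.
A_TOL = 1e-15


@dataclass(frozen=True)
class QuadraticTerms:
    """Coefficients of the per-event quadratic a A^2 + b A + c = 0."""

    a: float
    b: float
    c: float
    discriminant: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "discriminant",
                           self.b * self.b - 4.0 * self.a * self.c)


def quadratic_terms(plant: LVCoefficients, v: np.ndarray,
                    y_desired: float) -> QuadraticTerms:
    """Quadratic coefficients at one event given history convolutions v."""
    v = np.asarray(v, dtype=float)
    a = plant.c2_present
    b = plant.c1_present + 2.0 * float(plant.c2_cross @ v)
    c = (plant.c0 + float(plant.c1 @ v) + float(v @ plant.c2 @ v)
         - float(y_desired))
    return QuadraticTerms(a=a, b=b, c=c)


def solve_amplitude(q: QuadraticTerms, policy: str = "plus",
                    prev_amplitude: float = 0.0,
                    a_tol: float = A_TOL) -> tuple[float, str]:
    """Solve one event's quadratic for the stimulation amplitude.

    Parameters
    ----------
    q : QuadraticTerms
    policy : {"plus", "minus", "nearest"}
        Root branch: the printed "+" branch (default), the "-" branch, or
        the real root nearest ``prev_amplitude``.
    prev_amplitude : float
        Reference amplitude for the "nearest" policy.

    Returns
    -------
    (amplitude, flag)
        Amplitude in input units (>= 0) and a status flag.
    """
    a, b, c = q.a, q.b, q.c
    if abs(a) <= a_tol:
        if abs(b) <= a_tol:
            raise UnsolvableEventError(
                "degenerate event equation: a ~ 0 and b ~ 0")
        A, flag = -c / b, FLAG_LINEAR
    elif q.discriminant < 0:
        # Target beyond the quadratic's reachable extremum: emit the vertex.
        A, flag = -b / (2.0 * a), FLAG_VERTEX
    else:
        root = np.sqrt(q.discriminant)
        if policy == "plus":
            A = (-b + root) / (2.0 * a)
        elif policy == "minus":
            A = (-b - root) / (2.0 * a)
        elif policy == "nearest":
            r1 = (-b + root) / (2.0 * a)
            r2 = (-b - root) / (2.0 * a)
            A = r1 if abs(r1 - prev_amplitude) <= abs(r2 - prev_amplitude) else r2
        else:
            raise ValueError(f"unknown root policy {policy!r}")
        flag = FLAG_OK
    if A < 0:
        A, flag = 0.0, FLAG_CLAMPED
    return float(A), flag


@dataclass
class ControlResult:
    """A derived stimulation sequence (DARIT) with solver diagnostics."""

    times: np.ndarray
    desired_outputs: np.ndarray
    amplitudes: np.ndarray
    flags: list[str]
    achieved_outputs: np.ndarray

    @property
    def ok_fraction(self) -> float:
        return sum(f == FLAG_OK for f in self.flags) / max(len(self.flags), 1)

    def flag_counts(self) -> dict:
        counts: dict[str, int] = {}
        for f in self.flags:
            counts[f] = counts.get(f, 0) + 1
        return counts

    def to_train(self, train_id: str = "darit") -> EventTrain:
        return EventTrain(self.times, self.amplitudes, train_id=train_id)

    def to_frame(self, train_id: str = "darit") -> pd.DataFrame:
        return pd.DataFrame({
            "train_id": train_id, "time_s": self.times,
            "amplitude": self.amplitudes,
            "desired_output": self.desired_outputs, "flag": self.flags})


def invert_sequence(plant: LVCoefficients, basis: LaguerreBasis,
                    times, desired_outputs,
                    policy: str = "plus") -> ControlResult:
    """Recursively invert a desired output sequence into amplitudes.

    Iterates events in time order; at each event the history convolutions
    are computed from the amplitudes *already solved* (never from any
    reference input), the quadratic is solved, and the amplitude is
    appended.  Finally the solved train is forward-simulated through the
    plant for the ``achieved_outputs`` diagnostic.
    """
    check_basis_compatible(basis, plant.basis_spec)
    times = np.asarray(times, dtype=float)
    desired = np.asarray(desired_outputs, dtype=float)
    if times.shape != desired.shape:
        raise DataError("times and desired_outputs differ in length")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise DataError("times must be strictly increasing")
    if not np.all(np.isfinite(desired)):
        raise DataError("desired outputs must be finite")
    solved = np.zeros_like(times)
    flags: list[str] = []
    for i in range(times.size):
        v = _convolution_at(basis, times, solved, i)
        q = quadratic_terms(plant, v, desired[i])
        prev = solved[i - 1] if i else 0.0
        try:
            A, flag = solve_amplitude(q, policy=policy, prev_amplitude=prev)
        except UnsolvableEventError as err:
            raise UnsolvableEventError(
                f"event {i} at t={times[i]:.6f}s: {err}", index=i) from err
        solved[i] = A
        flags.append(flag)
    achieved = predict_output(
        plant, basis, EventTrain(times, solved, train_id="darit"))
    return ControlResult(times=times, desired_outputs=desired,
                         amplitudes=solved, flags=flags,
                         achieved_outputs=achieved)


def run_control_pipeline(trajectory: LVCoefficients,
                         trajectory_basis: LaguerreBasis,
                         plant: LVCoefficients,
                         plant_basis: LaguerreBasis,
                         dg_train: EventTrain,
                         policy: str = "plus") -> ControlResult:
    """Full trajectory -> inverse-plant control step.

    The trajectory model predicts the desired downstream outputs from the
    upstream (DG) event train; the inverse plant model then converts those
    desired outputs into the stimulation amplitudes of a DARIT sharing the
    upstream event times.
    """
    desired = predict_output(trajectory, trajectory_basis, dg_train)
    return invert_sequence(plant, plant_basis, dg_train.times, desired,
                           policy=policy)
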