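"""Second-order Laguerre-Volterra (LV) model of graded event-driven responses.

The response amplitude at event i with present input amplitude A_i and
past-input Laguerre convolutions v_l(t_i) is

    y(t_i) = c0 + c1(0) A_i + c2(0,0) A_i^2
             + sum_l c1(l) v_l
             + sum_{l1,l2} c2(l1,l2) v_l1 v_l2
             + 2 A_i sum_l c2(l) v_l

i.e. a static quadratic input-output curve (first three terms) plus the
nonlinear dynamical effect of past inputs (last three).  The zero-lag
(present-input) terms are isolated from the history terms so that, with
history fixed, the output is a quadratic in A_i — the property exploited
by the inverse model in :mod:`lvcontrol.control`.

The equivalent direct Volterra form, with kernels on the lag grid,

    y(n) = k0 + k1(0) x(n) + k2(0,0) x(n)^2
           + sum_m k1(m) x(n-m) + sum_{m1,m2} k2(m1,m2) x(n-m1) x(n-m2)
           + 2 x(n) sum_m k2(m,0) x(n-m)

is provided by :func:`predict_from_kernels` as a brute-force oracle, and
:func:`reconstruct_kernels` maps coefficients to kernels via
k1(m) = sum_l c1(l) L_l(m), k2(m1,m2) = sum_{l1,l2} c2(l1,l2) L_l1(m1) L_l2(m2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .events import EventTrain
from .laguerre import LaguerreBasis, check_basis_compatible, event_convolutions

__all__ = ["LVCoefficients", "VolterraKernels", "predict_output",
           "reconstruct_kernels", "predict_from_kernels"]


@dataclass
class LVCoefficients:
    """Laguerre expansion coefficients of a second-order LV model.

    Attributes
    ----------
    c0 : float
        Output when input is absent (zeroth-order kernel).
    c1_present, c2_present : float
        Coefficients of the present amplitude A_i and A_i^2 (the paper-style
        zero-lag entries c1(0) and c2(0,0)).
    c1 : ndarray, shape (L,)
        First-order history coefficients c1(l).
    c2 : ndarray, shape (L, L)
        Symmetric second-order history coefficients c2(l1, l2).
    c2_cross : ndarray, shape (L,)
        Present-by-past cross coefficients c2(l).
    basis_spec : dict or None
        Parameters of the LaguerreBasis the model refers to.
    """

    c0: float
    c1_present: float
    c2_present: float
    c1: np.ndarray
    c2: np.ndarray
    c2_cross: np.ndarray
    basis_spec: dict | None = field(default=None)

    def __post_init__(self):
        self.c0 = float(self.c0)
        self.c1_present = float(self.c1_present)
        self.c2_present = float(self.c2_present)
        self.c1 = np.atleast_1d(np.asarray(self.c1, dtype=float))
        self.c2 = np.atleast_2d(np.asarray(self.c2, dtype=float))
        self.c2_cross = np.atleast_1d(np.asarray(self.c2_cross, dtype=float))
        L = self.c1.shape[0]
        if self.c2.shape != (L, L) or self.c2_cross.shape != (L,):
            raise ParameterError(
                f"inconsistent coefficient shapes: c1 {self.c1.shape}, "
                f"c2 {self.c2.shape}, c2_cross {self.c2_cross.shape}")
        for arr in (self.c1, self.c2, self.c2_cross):
            if not np.all(np.isfinite(arr)):
                raise ParameterError("non-finite coefficients")
        if not np.all(np.isfinite([self.c0, self.c1_present, self.c2_present])):
            raise ParameterError("non-finite coefficients")
        if np.max(np.abs(self.c2 - self.c2.T), initial=0.0) > 1e-12:
            raise ParameterError("c2 must be symmetric")
        # enforce exact symmetry for downstream algebra
        self.c2 = 0.5 * (self.c2 + self.c2.T)

    @property
    def n_basis(self) -> int:
        return self.c1.shape[0]

    @property
    def n_params(self) -> int:
        L = self.n_basis
        return 3 + 2 * L + L * (L + 1) // 2

    def to_dict(self) -> dict:
        return {"c0": self.c0, "c1_present": self.c1_present,
                "c2_present": self.c2_present, "c1": self.c1.tolist(),
                "c2": self.c2.tolist(), "c2_cross": self.c2_cross.tolist(),
                "basis_spec": self.basis_spec}

    @classmethod
    def from_dict(cls, d: dict) -> "LVCoefficients":
        return cls(c0=d["c0"], c1_present=d["c1_present"],
                   c2_present=d["c2_present"], c1=d["c1"], c2=d["c2"],
                   c2_cross=d["c2_cross"], basis_spec=d.get("basis_spec"))


@dataclass
class VolterraKernels:
    """Volterra kernels materialized on the basis lag grid.

    ``k1[m]``, ``k2_cross[m]`` and ``k2[m1, m2]`` are indexed by lag *bin*
    (0..M-1) of strictly-past events; the present-impulse entries
    ``k1_present`` (k1 at zero lag) and ``k2_present`` (k2 at zero lag pair)
    are held separately, mirroring the zero-lag isolation of the model.
    """

    k0: float
    k1_present: float
    k2_present: float
    k1: np.ndarray
    k2_cross: np.ndarray
    k2: np.ndarray

    def __post_init__(self):
        self.k1 = np.asarray(self.k1, dtype=float)
        self.k2_cross = np.asarray(self.k2_cross, dtype=float)
        self.k2 = np.asarray(self.k2, dtype=float)
        if np.max(np.abs(self.k2 - self.k2.T), initial=0.0) > 1e-10:
            raise ParameterError("k2 must be symmetric")


def predict_output(coeffs: LVCoefficients, basis: LaguerreBasis,
                   train: EventTrain) -> np.ndarray:
    """Forward-predict the response amplitude at every event of a train.

    Histories start empty at the first event of the train (trains are
    independent).  Returns an array of predicted outputs, one per event.
    """
    check_basis_compatible(basis, coeffs.basis_spec)
    if coeffs.n_basis != basis.n_basis:
        raise ParameterError(
            f"model has {coeffs.n_basis} basis coefficients but basis has "
            f"{basis.n_basis} functions")
    A = train.amplitudes
    v = event_convolutions(basis, train)          # (I, L)
    y = (coeffs.c0
         + A * coeffs.c1_present
         + A ** 2 * coeffs.c2_present
         + v @ coeffs.c1
         + np.einsum("il,lk,ik->i", v, coeffs.c2, v)
         + 2.0 * A * (v @ coeffs.c2_cross))
    return y


def reconstruct_kernels(coeffs: LVCoefficients,
                        basis: LaguerreBasis) -> VolterraKernels:
    """Map Laguerre expansion coefficients to Volterra kernels.

    k0 = c0;  k1(m) = sum_l c1(l) L_l(m);
    k2(m1,m2) = sum_{l1,l2} c2(l1,l2) L_l1(m1) L_l2(m2);
    cross terms k2(m,0) = sum_l c2(l) L_l(m); present entries pass through.
    """
    check_basis_compatible(basis, coeffs.basis_spec)
    Lmat = basis.values                            # (L, M)
    return VolterraKernels(
        k0=coeffs.c0,
        k1_present=coeffs.c1_present,
        k2_present=coeffs.c2_present,
        k1=coeffs.c1 @ Lmat,
        k2_cross=coeffs.c2_cross @ Lmat,
        k2=Lmat.T @ coeffs.c2 @ Lmat,
    )


def predict_from_kernels(kernels: VolterraKernels, train: EventTrain,
                         dt: float) -> np.ndarray:
    """Direct Volterra prediction by explicit double sums over past events.

    The brute-force counterpart of :func:`predict_output`: O(I * w^2) in the
    number of in-window past events w.  Used as an independent route to the
    same prediction; the two agree to numerical precision.
    """
    M = kernels.k1.shape[0]
    times, A = train.times, train.amplitudes
    y = np.empty(train.n_events)
    for i in range(train.n_events):
        bins = np.rint((times[i] - times[:i]) / dt).astype(int)
        keep = bins <= M - 1
        b = np.clip(bins[keep], 0, M - 1)
        a = A[:i][keep]
        first = kernels.k1[b] @ a
        second = a @ kernels.k2[np.ix_(b, b)] @ a
        cross = 2.0 * A[i] * (kernels.k2_cross[b] @ a)
        y[i] = (kernels.k0 + kernels.k1_present * A[i]
                + kernels.k2_present * A[i] ** 2 + first + second + cross)
    return y
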