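"""Least-squares estimation of LV model coefficients from event trains.

Each event with an observed output contributes one regression row; the
model is linear in its coefficients, so the fit is ordinary (optionally
ridge-penalized) least squares.  Column order of the design matrix:

    [ 1, A, A^2,
      v_0 .. v_{L-1},
      v_i*v_j for i <= j (off-diagonal columns doubled: 2*v_i*v_j),
      2*A*v_0 .. 2*A*v_{L-1} ]

The doubling conventions make the estimated vector map one-to-one onto the
symmetric-c2 parameterization: an off-diagonal pair (l1, l2)/(l2, l1) of
the second-order double sum shares one coefficient estimated on the folded
column 2*v_l1*v_l2, and the cross term 2 A sum_l c2(l) v_l is estimated on
the column 2*A*v_l.  Trains are treated as independent: histories reset at
each train start.

The solver is SVD-based (scipy.linalg.lstsq) on a column-equilibrated copy
of the design; coefficients are returned on the raw amplitude scale and the
condition number reported is that of the raw design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import scipy.linalg

from .errors import DataError, EstimationError, SingularDesignError, UndefinedMetricError
from .events import EventTrain
from .laguerre import LaguerreBasis, build_basis, event_convolutions
from .metrics import nmse, vaf
from .model import LVCoefficients, predict_output

__all__ = ["DesignMatrix", "FitReport", "CVResult", "build_design_matrix",
           "fit_least_squares", "fit_trains", "cross_validate",
           "coefficients_from_vector", "vector_from_coefficients",
           "design_column_names"]


def design_column_names(n_basis: int) -> list[str]:
    """Stable, documented column order of the design matrix."""
    L = n_basis
    names = ["const", "A", "A^2"]
    names += [f"v{l}" for l in range(L)]
    names += [f"v{i}*v{j}" for i, j in combinations_with_replacement(range(L), 2)]
    names += [f"A*v{l}" for l in range(L)]
    return names


@dataclass
class DesignMatrix:
    """Regression design assembled from one or more event trains."""

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    train_slices: list[slice]
    train_ids: list[str]
    n_basis: int
    basis_spec: dict


def build_design_matrix(basis: LaguerreBasis,
                        trains: list[EventTrain]) -> DesignMatrix:
    """Assemble the regression design from trains with observed outputs."""
    if isinstance(trains, EventTrain):
        trains = [trains]
    if not trains:
        raise DataError("no trains given")
    L = basis.n_basis
    pairs = list(combinations_with_replacement(range(L), 2))
    blocks, outputs, slices, ids = [], [], [], []
    row0 = 0
    for train in trains:
        if not train.has_outputs:
            raise DataError(f"train {train.train_id!r} has no outputs; "
                            "cannot be used for estimation")
        A = train.amplitudes
        v = event_convolutions(basis, train)
        cols = [np.ones_like(A), A, A ** 2]
        cols += [v[:, l] for l in range(L)]
        cols += [(v[:, i] * v[:, j] if i == j else 2.0 * v[:, i] * v[:, j])
                 for i, j in pairs]
        cols += [2.0 * A * v[:, l] for l in range(L)]
        blocks.append(np.column_stack(cols))
        outputs.append(train.outputs)
        slices.append(slice(row0, row0 + train.n_events))
        ids.append(train.train_id)
        row0 += train.n_events
    return DesignMatrix(X=np.vstack(blocks), y=np.concatenate(outputs),
                        column_names=design_column_names(L),
                        train_slices=slices, train_ids=ids,
                        n_basis=L, basis_spec=basis.to_spec())


def coefficients_from_vector(beta: np.ndarray, n_basis: int,
                             basis_spec: dict | None = None) -> LVCoefficients:
    """Unpack a design-ordered coefficient vector into LVCoefficients."""
    L = n_basis
    beta = np.asarray(beta, dtype=float)
    c0, c1p, c2p = beta[0], beta[1], beta[2]
    c1 = beta[3:3 + L]
    c2 = np.zeros((L, L))
    k = 3 + L
    for i, j in combinations_with_replacement(range(L), 2):
        c2[i, j] = c2[j, i] = beta[k]
        k += 1
    c2_cross = beta[k:k + L]
    return LVCoefficients(c0=c0, c1_present=c1p, c2_present=c2p, c1=c1,
                          c2=c2, c2_cross=c2_cross, basis_spec=basis_spec)


def vector_from_coefficients(coeffs: LVCoefficients) -> np.ndarray:
    """Inverse of :func:`coefficients_from_vector` (round-trip helper)."""
    L = coeffs.n_basis
    parts = [np.array([coeffs.c0, coeffs.c1_present, coeffs.c2_present]),
             coeffs.c1,
             np.array([coeffs.c2[i, j]
                       for i, j in combinations_with_replacement(range(L), 2)]),
             coeffs.c2_cross]
    return np.concatenate(parts)


@dataclass
class FitReport:
    """Result of a least-squares fit."""

    coefficients: LVCoefficients
    n_events: int
    n_params: int
    condition_number: float
    per_train_vaf: list[float] = field(default_factory=list)
    per_train_nmse: list[float] = field(default_factory=list)
    residuals: np.ndarray = field(default=None, repr=False)


def fit_least_squares(design: DesignMatrix, ridge: float = 0.0) -> FitReport:
    """Estimate coefficients by SVD least squares, optionally ridge-penalized.

    Minimizes ||y - X b||^2 + ridge * ||b_noint||^2 (intercept excluded from
    the penalty).  Raises :class:`SingularDesignError` on rank deficiency
    when ridge is 0, naming the columns involved in the null space.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if ridge < 0:
        raise EstimationError(f"ridge must be >= 0; got {ridge}")
    if n < p and ridge == 0:
        raise EstimationError(
            f"underdetermined fit: {n} events for {p} parameters (use ridge)")
    # Column equilibration: purely numerical, coefficients unscaled below.
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    ys = y
    if ridge > 0:
        pen = np.sqrt(ridge) * np.eye(p)
        pen[0, 0] = 0.0  # no penalty on the intercept, raw scale
        Xs = np.vstack([Xs, pen / scale])
        ys = np.concatenate([y, np.zeros(p)])
    beta_s, _, rank, sv = scipy.linalg.lstsq(Xs, ys)
    if ridge == 0 and rank < p:
        _, _, Vt = np.linalg.svd(Xs, full_matrices=True)
        null = Vt[rank:]
        bad = np.where(np.max(np.abs(null), axis=0) > 1e-8)[0]
        names = [design.column_names[j] for j in bad]
        raise SingularDesignError(
            f"rank-deficient design (rank {rank} < {p} parameters); "
            f"linearly dependent columns involve: {names}", columns=names)
    beta = beta_s / scale
    coeffs = coefficients_from_vector(beta, design.n_basis, design.basis_spec)
    yhat = X @ beta
    residuals = y - yhat
    per_vaf, per_nmse = [], []
    for sl in design.train_slices:
        try:
            per_vaf.append(vaf(y[sl], yhat[sl]))
        except UndefinedMetricError:
            per_vaf.append(float("nan"))
        try:
            per_nmse.append(nmse(y[sl], yhat[sl]))
        except UndefinedMetricError:
            per_nmse.append(float("nan"))
    with np.errstate(divide="ignore"):
        cond = float(np.linalg.cond(X))
    return FitReport(coefficients=coeffs, n_events=n, n_params=p,
                     condition_number=cond, per_train_vaf=per_vaf,
                     per_train_nmse=per_nmse, residuals=residuals)


def fit_trains(basis: LaguerreBasis, trains: list[EventTrain],
               ridge: float = 0.0) -> FitReport:
    """Convenience: build the design from trains and fit in one call."""
    return fit_least_squares(build_design_matrix(basis, trains), ridge=ridge)


@dataclass
class CVResult:
    """Leave-one-train-out cross-validation over a basis-parameter grid."""

    records: list[dict]          # one per configuration
    best_index: int

    @property
    def best(self) -> dict:
        return self.records[self.best_index]

    @property
    def best_config(self) -> tuple:
        b = self.best
        return (b["alpha"], b["n_basis"], b["memory_s"])


def cross_validate(trains: list[EventTrain],
                   basis_grid: list[tuple],
                   dt: float = None,
                   ridge: float = 0.0) -> CVResult:
    """Leave-one-train-out CV of basis configurations.

    Parameters
    ----------
    trains : list of EventTrain
        At least two trains with outputs; each in turn is held out while the
        model is fitted on the rest.
    basis_grid : list of (alpha, n_basis, memory_s)
        Candidate basis configurations.
    dt : float, optional
        Lag-bin width; defaults to the package default (1 ms).

    Returns
    -------
    CVResult
        Per-configuration fold VAF/NMSE; ``best`` maximizes mean held-out VAF.
    """
    from .laguerre import DEFAULT_DT
    if dt is None:
        dt = DEFAULT_DT
    if len(trains) < 2:
        raise DataError("cross-validation needs at least 2 trains")
    records = []
    for alpha, n_basis, memory_s in basis_grid:
        basis = build_basis(alpha, n_basis, int(round(memory_s / dt)), dt)
        fold_vaf, fold_nmse = [], []
        for k, held_out in enumerate(trains):
            fit_set = [t for j, t in enumerate(trains) if j != k]
            report = fit_trains(basis, fit_set, ridge=ridge)
            pred = predict_output(report.coefficients, basis, held_out)
            fold_vaf.append(vaf(held_out.outputs, pred))
            fold_nmse.append(nmse(held_out.outputs, pred))
        records.append({
            "alpha": alpha, "n_basis": n_basis, "memory_s": memory_s,
            "fold_vaf": fold_vaf, "fold_nmse": fold_nmse,
            "mean_vaf": float(np.mean(fold_vaf)),
            "mean_nmse": float(np.mean(fold_nmse)),
            "n_folds": len(trains),
        })
    best_index = int(np.argmax([r["mean_vaf"] for r in records]))
    return CVResult(records=records, best_index=best_index)
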