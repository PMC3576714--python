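"""Goodness-of-fit statistics: VAF, NMSE, and Q-Q comparison data.

VAF  = 1 - var(Y - X) / var(Y)        (variance accounted for)
NMSE = sum (Y - X)^2 / sum Y^2        (normalized mean square error)

with Y the observed and X the predicted amplitudes.  The VAF variance is
the sample variance (ddof=1); the convention cancels between numerator and
denominator, so the value is identical with ddof=0.  Note VAF is blind to a
constant offset (the residual of X = Y + const has zero variance), and the
NMSE denominator is the *uncentered* sum of squares of Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError

__all__ = ["vaf", "nmse", "qq_points", "MetricsReport", "QQPoints"]


def _paired(Y, X):
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.shape != X.shape or Y.ndim != 1:
        raise UndefinedMetricError(
            f"Y and X must be equal-length 1-D arrays; got {Y.shape} vs {X.shape}")
    return Y, X


def vaf(Y, X) -> float:
    """Variance accounted for, as a fraction (1.0 = 100%)."""
    Y, X = _paired(Y, X)
    if Y.size < 2:
        raise UndefinedMetricError("VAF needs at least 2 observations")
    vy = np.var(Y, ddof=1)
    if vy == 0:
        raise UndefinedMetricError("VAF undefined: var(Y) = 0")
    return float(1.0 - np.var(Y - X, ddof=1) / vy)


def nmse(Y, X) -> float:
    """Normalized mean square error, as a fraction (0.0 = perfect)."""
    Y, X = _paired(Y, X)
    denom = float(np.sum(Y ** 2))
    if denom == 0:
        raise UndefinedMetricError("NMSE undefined: sum(Y^2) = 0")
    return float(np.sum((Y - X) ** 2) / denom)


@dataclass
class QQPoints:
    """Rank-paired sorted quantiles of observed vs predicted amplitudes."""

    y_sorted: np.ndarray
    x_sorted: np.ndarray
    max_abs_deviation: float  # max |y_q - x_q| from the identity line


def qq_points(Y, X) -> QQPoints:
    """Quantile-quantile pairing: ascending sort of each series by rank."""
    Y, X = _paired(Y, X)
    ys = np.sort(Y)
    xs = np.sort(X)
    dev = float(np.max(np.abs(ys - xs))) if Y.size else 0.0
    return QQPoints(y_sorted=ys, x_sorted=xs, max_abs_deviation=dev)


@dataclass
class MetricsReport:
    """VAF/NMSE summary of one observed-vs-predicted comparison."""

    vaf: float
    nmse: float
    n: int
    qq: QQPoints

    @property
    def vaf_pct(self) -> float:
        return 100.0 * self.vaf

    @property
    def nmse_pct(self) -> float:
        return 100.0 * self.nmse

    @classmethod
    def from_pairs(cls, Y, X) -> "MetricsReport":
        Y = np.asarray(Y, dtype=float)
        return cls(vaf=vaf(Y, X), nmse=nmse(Y, X), n=Y.size,
                   qq=qq_points(Y, X))

    def to_dict(self) -> dict:
        return {"vaf": self.vaf, "vaf_pct": self.vaf_pct,
                "nmse": self.nmse, "nmse_pct": self.nmse_pct,
                "n": self.n, "qq_max_abs_deviation": self.qq.max_abs_deviation}
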