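"""Discrete orthonormal Laguerre basis and event-driven convolutions.

The Volterra kernels of the input-output models in this package are
compressed on the discrete orthonormal Laguerre functions

    L_l(m) = alpha^((m-l)/2) (1-alpha)^(1/2)
             * sum_{k=0..l} (-1)^k C(m,k) C(l,k) alpha^(l-k) (1-alpha)^k

where ``alpha`` in (0, 1) sets the geometric decay (and hence the time
extent) of the basis and ``m`` is the discrete lag in bins of width ``dt``.
Basis order is 0-based here: orders ``0 .. n_basis-1``.

Numerical evaluation uses the standard two-term recurrence

    L_0(m) = sqrt(alpha) * L_0(m-1),             L_0(0) = sqrt(1-alpha)
    L_l(m) = sqrt(alpha) * (L_l(m-1) + L_{l-1}(m)) - L_{l-1}(m-1)

(realized as an IIR filter), which is stable for arbitrarily large lag,
rather than the alternating binomial sum above; the two agree to machine
precision and the direct sum is kept as a test oracle.

For an impulse train x(t) = sum_j A_j delta(t - t_j) the model regressors
are the event-driven convolutions

    v_l(t_i) = sum_{t_i - mu < t_j < t_i} A_j * L_l(round((t_i - t_j)/dt))

over strictly *past* events within the memory window mu = n_lags * dt.
The present impulse (t_j = t_i) is excluded: its effect enters the model
through separately isolated zero-lag terms, which is what makes the model
a quadratic in the present amplitude and hence analytically invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError, ParameterError
from .events import EventTrain

__all__ = [
    "DEFAULT_ALPHA", "DEFAULT_N_BASIS", "DEFAULT_N_LAGS", "DEFAULT_DT",
    "LaguerreBasis", "evaluate_laguerre", "build_basis",
    "convolve_events", "event_convolutions",
]

#: Default decay parameter; with 1 ms bins the basis has appreciable support
#: over the first few hundred milliseconds, the timescale of paired-pulse
#: facilitation/depression in hippocampal pathways.
DEFAULT_ALPHA = 0.95
DEFAULT_N_BASIS = 3
#: Default memory window: 1000 bins of 1 ms = 1.0 s.
DEFAULT_N_LAGS = 1000
DEFAULT_DT = 0.001


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1); got {alpha}")
    return alpha


def _laguerre_rows(alpha: float, n_basis: int, n_lags: int) -> np.ndarray:
    """Tabulate L_l(m) for l in 0..n_basis-1, m in 0..n_lags-1 via recurrence."""
    sa = np.sqrt(alpha)
    values = np.empty((n_basis, n_lags))
    # L_0(m) = alpha^(m/2) sqrt(1-alpha), computed in log space to avoid
    # spurious under/overflow at very large m.
    m = np.arange(n_lags)
    values[0] = np.exp(0.5 * m * np.log(alpha)) * np.sqrt(1.0 - alpha)
    # Order recursion L_l = IIR filter of L_{l-1}:
    #   L_l(m) = sa*L_l(m-1) + sa*L_{l-1}(m) - L_{l-1}(m-1)
    for l in range(1, n_basis):
        values[l] = lfilter([sa, -1.0], [1.0, -sa], values[l - 1])
    return values


def evaluate_laguerre(alpha: float, order: int, lag) -> float | np.ndarray:
    """Evaluate the discrete orthonormal Laguerre function L_order(lag).

    Parameters
    ----------
    alpha : float
        Decay parameter in (0, 1).
    order : int
        Basis order ``l >= 0`` (0-based).
    lag : int or array of int
        Discrete lag ``m >= 0``.

    Returns
    -------
    float or ndarray
        L_order(lag); an array if ``lag`` is an array.
    """
    alpha = _check_alpha(alpha)
    order = int(order)
    if order < 0:
        raise ParameterError(f"order must be >= 0; got {order}")
    lag_arr = np.asarray(lag)
    if np.any(lag_arr < 0):
        raise ParameterError("lag must be >= 0")
    rows = _laguerre_rows(alpha, order + 1, int(np.max(lag_arr)) + 1)
    result = rows[order, lag_arr]
    return float(result) if np.isscalar(lag) or lag_arr.ndim == 0 else result


@dataclass(frozen=True)
class LaguerreBasis:
    """A tabulated discrete Laguerre basis on a uniform lag grid.

    ``values[l, m]`` holds L_l(m) for orders ``0..n_basis-1`` and lag bins
    ``0..n_lags-1`` of width ``dt`` seconds; the memory window is
    ``memory_s = n_lags * dt``.
    """

    alpha: float
    n_basis: int
    n_lags: int
    dt: float
    values: np.ndarray = field(repr=False, compare=False)

    @property
    def memory_s(self) -> float:
        return self.n_lags * self.dt

    def gram(self) -> np.ndarray:
        """Gram matrix of the basis rows; near-identity for adequate n_lags."""
        return self.values @ self.values.T

    def to_spec(self) -> dict:
        """JSON-serializable parameters; ``values`` regenerate on load."""
        return {"alpha": self.alpha, "n_basis": self.n_basis,
                "n_lags": self.n_lags, "dt": self.dt}

    @classmethod
    def from_spec(cls, spec: dict) -> "LaguerreBasis":
        return build_basis(spec["alpha"], spec["n_basis"],
                           spec["n_lags"], spec["dt"])

    def matches_spec(self, spec: dict | None) -> bool:
        return spec is None or self.to_spec() == dict(spec)


def build_basis(alpha: float = DEFAULT_ALPHA,
                n_basis: int = DEFAULT_N_BASIS,
                n_lags: int = DEFAULT_N_LAGS,
                dt: float = DEFAULT_DT) -> LaguerreBasis:
    """Tabulate a Laguerre basis.

    Parameters
    ----------
    alpha : float
        Decay parameter in (0, 1).
    n_basis : int
        Number of basis functions L (orders 0..L-1).
    n_lags : int
        Memory length M in lag bins; must exceed ``n_basis``.
    dt : float
        Lag-bin width in seconds.
    """
    alpha = _check_alpha(alpha)
    n_basis, n_lags = int(n_basis), int(n_lags)
    if n_basis < 1:
        raise ParameterError(f"n_basis must be >= 1; got {n_basis}")
    if n_lags <= n_basis:
        raise ParameterError(
            f"n_lags must exceed n_basis; got n_lags={n_lags}, n_basis={n_basis}")
    if not dt > 0:
        raise ParameterError(f"dt must be positive; got {dt}")
    values = _laguerre_rows(alpha, n_basis, n_lags)
    return LaguerreBasis(alpha=alpha, n_basis=n_basis, n_lags=n_lags,
                         dt=float(dt), values=values)


def _convolution_at(basis: LaguerreBasis, times: np.ndarray,
                    amplitudes: np.ndarray, index: int) -> np.ndarray:
    """v_l(t_i) from strictly past events; times assumed sorted."""
    t_i = times[index]
    # Events with round(dt_lag/dt) <= n_lags-1, i.e. dt_lag < (M-0.5)*dt.
    lo = np.searchsorted(times, t_i - (basis.n_lags - 0.5) * basis.dt, side="right")
    past_t = times[lo:index]
    if past_t.size == 0:
        return np.zeros(basis.n_basis)
    bins = np.rint((t_i - past_t) / basis.dt).astype(int)
    keep = bins <= basis.n_lags - 1
    bins = np.clip(bins[keep], 0, basis.n_lags - 1)
    amps = amplitudes[lo:index][keep]
    return basis.values[:, bins] @ amps


def convolve_events(basis: LaguerreBasis, train: EventTrain, index: int) -> np.ndarray:
    """Convolution vector v_l(t_i) of past impulses with the basis.

    Returns the length-``n_basis`` vector of
    v_l(t_i) = sum_j A_j L_l(lag_bin(t_i - t_j)) over events strictly before
    event ``index`` and within the memory window.  The first event of a
    train therefore yields the zero vector.
    """
    if not 0 <= index < train.n_events:
        raise ParameterError(f"event index {index} out of range 0..{train.n_events - 1}")
    return _convolution_at(basis, train.times, train.amplitudes, index)


def event_convolutions(basis: LaguerreBasis, train: EventTrain) -> np.ndarray:
    """All convolution vectors of a train, shape (n_events, n_basis)."""
    out = np.zeros((train.n_events, basis.n_basis))
    for i in range(train.n_events):
        out[i] = _convolution_at(basis, train.times, train.amplitudes, i)
    return out


def check_basis_compatible(basis: LaguerreBasis, spec: dict | None) -> None:
    """Raise ConfigurationError if ``basis`` differs from a stored spec."""
    if not basis.matches_spec(spec):
        raise ConfigurationError(
            f"basis {basis.to_spec()} does not match the basis the model "
            f"was fitted with ({spec})")
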