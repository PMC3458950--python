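"""Bivariate VAR fitting and parametric spectral coherence.

The functional-connectivity feature used throughout this package is the
spectral coherence between two region signals, estimated *parametrically*:
a vector autoregression

    z_t = B_1 z_{t-1} + ... + B_p z_{t-p} + e_t,      z_t = (x_t, y_t)'

is fitted by the multivariate Yule-Walker moment equations, the lag order
p is chosen per subject by AIC over candidates 1..10, and the model-implied
spectral density matrix

    S(f) = A(f)^{-1} Sigma A(f)^{-H},
    A(f) = I - sum_k B_k exp(-i 2 pi f dt k)

is evaluated on a fixed grid.  The magnitude-squared coherence

    C(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f))  in [0, 1]

at the grid frequencies is the per-subject feature vector.  Constant
spectral scaling conventions (1/(2 pi), dt) cancel in C(f) and are
omitted from S(f).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "VARModel",
    "CoherenceSpectrum",
    "sample_autocovariances",
    "fit_var_yule_walker",
    "select_order_aic",
    "spectral_matrix",
    "coherence",
    "default_grid",
    "coherence_features",
]

#: Number of grid frequencies used by the default pipeline.
DEFAULT_N_FREQ = 125

#: Candidate lag orders for AIC selection.
DEFAULT_ORDERS = tuple(range(1, 11))


@dataclasses.dataclass
class VARModel:
    """A fitted bivariate VAR(p): coefficients, innovation covariance, dt."""

    order: int
    coefs: np.ndarray  # (p, 2, 2)
    sigma: np.ndarray  # (2, 2) innovation covariance
    dt: float

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float).reshape(self.order, 2, 2)
        self.sigma = np.asarray(self.sigma, dtype=float)

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.dt)

    def companion_spectral_radius(self) -> float:
        """Spectral radius of the companion matrix; < 1 means stable."""
        p = self.order
        comp = np.zeros((2 * p, 2 * p))
        comp[:2, :] = np.concatenate(self.coefs, axis=1)
        if p > 1:
            comp[2:, :-2] = np.eye(2 * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    @property
    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0


@dataclasses.dataclass
class CoherenceSpectrum:
    """Coherence values of one subject on a fixed frequency grid (Hz)."""

    subject_id: str
    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequencies and values must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def _as_bivariate(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    return np.stack([x, y], axis=1)


def sample_autocovariances(x, y, max_lag: int) -> np.ndarray:
    """Sample cross-covariance matrices Gamma(0..max_lag), divisor 1/T.

    Gamma(k) = (1/T) sum_{t=k+1}^{T} (z_t - zbar)(z_{t-k} - zbar)'.

    The biased 1/T divisor keeps the block-Toeplitz Yule-Walker system
    positive semidefinite.  Gamma(-k) = Gamma(k)' by construction.
    """
    z = _as_bivariate(x, y)
    T = z.shape[0]
    if T <= max_lag:
        raise ValueError(f"series length {T} must exceed max_lag {max_lag}")
    z = z - z.mean(axis=0)
    gammas = np.empty((max_lag + 1, 2, 2))
    for k in range(max_lag + 1):
        gammas[k] = z[k:].T @ z[: T - k] / T
    return gammas


def fit_var_yule_walker(x, y, p: int, *, dt: float = 2.0) -> VARModel:
    """Fit a bivariate VAR(p) by solving the multivariate Yule-Walker system.

    The coefficients solve  Gamma(k) = sum_m B_m Gamma(k-m)  for k = 1..p
    via the symmetric block-Toeplitz matrix R with blocks R_ij =
    Gamma(i-j); the innovation covariance is

        Sigma = Gamma(0) - sum_k B_k Gamma(k)',  symmetrized.

    Emits a warning for short series (T <= 10 p) and for unstable fits.
    """
    if p < 1:
        raise ValueError("order p must be >= 1")
    z = _as_bivariate(x, y)
    T = z.shape[0]
    if T <= 10 * p:
        warnings.warn(
            f"series length {T} is short for VAR({p}); estimates may be unstable",
            stacklevel=2,
        )
    g = sample_autocovariances(x, y, p)

    # R is symmetric as a full matrix: block (i, j) = Gamma(i - j).
    R = np.empty((2 * p, 2 * p))
    for i in range(p):
        for j in range(p):
            blk = g[i - j] if i >= j else g[j - i].T
            R[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = blk
    c = np.concatenate([g[k] for k in range(1, p + 1)], axis=1)  # 2 x 2p

    try:
        sol = np.linalg.solve(R, c.T)  # R G' = c'
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular Yule-Walker system at order {p}; try a lower order"
        ) from exc
    B = sol.T.reshape(2, p, 2).transpose(1, 0, 2)  # (p, 2, 2)

    sigma = g[0] - sum(B[k] @ g[k + 1].T for k in range(p))
    sigma = (sigma + sigma.T) / 2.0
    model = VARModel(order=p, coefs=B, sigma=sigma, dt=dt)
    if not model.is_stable:
        warnings.warn(
            f"fitted VAR({p}) is unstable (companion spectral radius "
            f"{model.companion_spectral_radius():.3f})",
            stacklevel=2,
        )
    return model


def aic(model: VARModel, T: int) -> float:
    """AIC in the ranking-equivalent form T log det Sigma + 2 p d^2 (d = 2)."""
    sign, logdet = np.linalg.slogdet(model.sigma)
    if sign <= 0:
        return np.inf
    return float(T * logdet + 2 * model.order * 4)


def select_order_aic(x, y, candidate_orders=DEFAULT_ORDERS, *, dt: float = 2.0) -> int:
    """Smallest candidate order minimizing AIC (ties go to the lower order)."""
    candidates = sorted(set(int(p) for p in candidate_orders))
    if not candidates:
        raise ValueError("candidate_orders must be nonempty")
    T = np.asarray(x).size
    best_p, best_aic = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-series warnings handled by caller
        for p in candidates:
            value = aic(fit_var_yule_walker(x, y, p, dt=dt), T)
            if value < best_aic:  # strict: ties keep the smaller order
                best_p, best_aic = p, value
    if best_p is None:
        raise ValueError("no candidate order produced a finite AIC")
    return best_p


def spectral_matrix(model: VARModel, f_hz: float) -> np.ndarray:
    """Model-implied 2x2 spectral density matrix at frequency ``f_hz``.

    S(f) = A(f)^{-1} Sigma A(f)^{-H} with A(f) = I - sum B_k e^{-i2pi f dt k};
    Hermitian with real positive diagonal for positive-definite Sigma.
    The 1/(2 pi) density convention factor is omitted (cancels in coherence).
    """
    if not (0.0 <= f_hz <= model.nyquist + 1e-12):
        raise ValueError(f"frequency {f_hz} Hz outside [0, Nyquist={model.nyquist}]")
    k = np.arange(1, model.order + 1)
    phases = np.exp(-2j * np.pi * f_hz * model.dt * k)
    A = np.eye(2, dtype=complex) - np.tensordot(phases, model.coefs, axes=(0, 0))
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError(
            f"A(f) numerically singular at f={f_hz} Hz (model near unit root)"
        )
    Ainv = np.linalg.inv(A)
    S = Ainv @ model.sigma @ Ainv.conj().T
    return (S + S.conj().T) / 2.0


def default_grid(dt: float, n: int = DEFAULT_N_FREQ) -> np.ndarray:
    """n equally spaced frequencies f_j = j * Nyquist / n, j = 1..n.

    Excludes 0 Hz (uninformative after normalization and high-pass
    preprocessing) and includes the Nyquist frequency 1/(2 dt).  For
    dt = 2 s, n = 125 this is 0.002, 0.004, ..., 0.250 Hz.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    nyq = 1.0 / (2.0 * dt)
    return np.arange(1, n + 1) * (nyq / n)


def coherence(
    model: VARModel,
    grid: np.ndarray,
    *,
    subject_id: str = "",
    squared: bool = True,
) -> CoherenceSpectrum:
    """Parametric coherence of the fitted VAR on a frequency grid.

    ``squared=True`` (default) gives magnitude-squared coherence
    |S_xy|^2 / (S_xx S_yy); ``squared=False`` its square root.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0 or grid.max() > model.nyquist + 1e-12:
        raise ValueError("grid frequencies must lie within [0, Nyquist]")
    vals = np.empty(grid.size)
    for i, f in enumerate(grid):
        S = spectral_matrix(model, f)
        sxx, syy = S[0, 0].real, S[1, 1].real
        if sxx <= 0 or syy <= 0:
            raise ValueError(f"non-positive diagonal spectrum at f={f} Hz")
        c = abs(S[0, 1]) ** 2 / (sxx * syy)
        vals[i] = min(max(c, 0.0), 1.0)
    if not squared:
        vals = np.sqrt(vals)
    return CoherenceSpectrum(subject_id=subject_id, frequencies=grid, values=vals)


def coherence_features(
    x,
    y,
    *,
    dt: float = 2.0,
    n_freq: int = DEFAULT_N_FREQ,
    candidate_orders=DEFAULT_ORDERS,
    subject_id: str = "",
    squared: bool = True,
) -> tuple[CoherenceSpectrum, VARModel]:
    """Full per-subject feature extraction: AIC order, YW fit, coherence grid."""
    p = select_order_aic(x, y, candidate_orders, dt=dt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_var_yule_walker(x, y, p, dt=dt)
    spec = coherence(model, default_grid(dt, n_freq), subject_id=subject_id, squared=squared)
    return spec, model
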