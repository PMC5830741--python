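"""Directional influence between two region time series (Granger causality).

The question: do past samples of one region's virtual-sensor trace reduce
the prediction error of the other region beyond that region's own past?
The causal density is the log ratio of restricted to full residual
variances from bivariate vector-autoregressive (VAR) fits; its
frequency-domain decomposition (Geweke) is averaged across a band for
spectral analyses, with a permutation null built by shuffling the trial
pairing between the two sensors.

Preprocessing enforces the VAR stationarity assumptions: linear
detrending, z-normalization and repeated first-differencing until the
augmented Dickey–Fuller test no longer signals a unit root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "GrangerResult",
    "enforce_stationarity",
    "select_order_bic",
    "granger_pair",
    "spectral_granger",
    "group_direction_test",
    "StationarityError",
]


class StationarityError(RuntimeError):
    """Differencing failed to produce a covariance-stationary series."""


@dataclass
class GrangerResult:
    """Causal densities in both directions for one subject/band.

    gc_xy is the density of x driving y (log variance-ratio units);
    perm_p, when present, is the (p_xy, p_yx) pair of permutation
    p-values for the band statistic.
    """

    gc_xy: float
    gc_yx: float
    order: int
    n_diffs: int = 0
    band: tuple[float, float] | None = None
    perm_p: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# stationarity
# ---------------------------------------------------------------------------

def _normalize(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    t = np.arange(x.size)
    slope, intercept = np.polyfit(t, x, 1)
    x = x - (slope * t + intercept)
    sd = x.std()
    if sd == 0:
        return x
    return (x - x.mean()) / sd


def enforce_stationarity(series, alpha: float = 0.05,
                         max_iters: int = 10) -> tuple[np.ndarray, int]:
    """Detrend, z-normalize, then difference until the ADF test passes.

    The ADF regression includes a constant, no trend (the trend is removed
    beforehand), with the Schwert-rule maximum lag.  Raises
    StationarityError if ``max_iters`` differencing passes cannot remove
    the unit root — such a series is excluded from the analysis.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= 20:
        raise ValueError("series too short for a stationarity test")
    if np.ptp(x) == 0:
        raise StationarityError("constant series cannot be made stationary")
    x = _normalize(x)
    for n_diffs in range(max_iters + 1):
        if np.ptp(x) == 0:
            raise StationarityError("differencing produced a constant series")
        maxlag = int(np.floor(12 * (x.size / 100.0) ** 0.25))
        maxlag = min(maxlag, x.size // 2 - 2)
        pval = adfuller(x, maxlag=maxlag, regression="c", autolag=None)[1]
        if pval < alpha:
            return x, n_diffs
        x = np.diff(x)
    raise StationarityError(f"still non-stationary after {max_iters} differences")


# ---------------------------------------------------------------------------
# VAR machinery (ordinary least squares, per-trial lag construction)
# ---------------------------------------------------------------------------

def _as_trials(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def _lag_design(x: np.ndarray, y: np.ndarray, order: int,
                use_x: bool, use_y: bool):
    """Stacked lagged design + targets across trials (no cross-trial lags)."""
    rows_d, rows_x, rows_y = [], [], []
    for xi, yi in zip(x, y):
        T = xi.size
        if T <= order:
            raise ValueError("trial shorter than the VAR order")
        cols = [np.ones(T - order)]
        for k in range(1, order + 1):
            if use_x:
                cols.append(xi[order - k:T - k])
            if use_y:
                cols.append(yi[order - k:T - k])
        rows_d.append(np.column_stack(cols))
        rows_x.append(xi[order:])
        rows_y.append(yi[order:])
    return (np.vstack(rows_d), np.concatenate(rows_x), np.concatenate(rows_y))


def _resid_var(design: np.ndarray, target: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("singular regression design")
    resid = target - design @ coef
    return float(resid @ resid / resid.size)


def select_order_bic(x, y, bounds: tuple[int, int] | None = None) -> int:
    """Bivariate VAR order minimizing the BIC over a bounded range.

    The default bounds are [5, L−5] with L the trial sample length,
    keeping the lag structure away from both the filter-induced short-lag
    correlations and the trial edges.
    """
    x, y = _as_trials(x), _as_trials(y)
    L = x.shape[1]
    if bounds is None:
        bounds = (5, L - 5)
    lo, hi = bounds
    if L < 2 * lo:
        raise ValueError("series shorter than twice the lower order bound")
    hi = min(hi, L - 2)
    best_order, best_bic = lo, np.inf
    for p in range(lo, hi + 1):
        design, tx, ty = _lag_design(x, y, p, use_x=True, use_y=True)
        n = tx.size
        k = design.shape[1]  # params per equation
        if n <= k + 2:  # not enough residual dof to estimate the variance
            continue
        try:
            # dof-corrected residual variances: the MLE collapses to zero
            # as k -> n, which would let BIC favour absurdly large orders
            vx = _resid_var(design, tx) * n / (n - k)
            vy = _resid_var(design, ty) * n / (n - k)
        except np.linalg.LinAlgError:
            continue
        # BIC for the bivariate system (diagonal approximation of Sigma)
        bic = np.log(vx * vy) + 2 * k * np.log(n) / n
        if bic < best_bic:
            best_bic, best_order = bic, p
    return best_order


def granger_pair(x, y, order: int) -> GrangerResult:
    """Time-domain causal densities between two (sets of) series.

    gc_xy = ln[ var(y_t | y's past) / var(y_t | both pasts) ]; likewise
    gc_yx.  2-D inputs (trials × samples) are fitted with per-trial lag
    construction (no lags straddle a trial boundary), pooling residuals —
    so swapping arguments swaps the two densities exactly.
    """
    x, y = _as_trials(x), _as_trials(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shapes")
    full_design, tx, ty = _lag_design(x, y, order, use_x=True, use_y=True)
    var_y_full = _resid_var(full_design, ty)
    var_x_full = _resid_var(full_design, tx)
    own_y, _, ty2 = _lag_design(x, y, order, use_x=False, use_y=True)
    own_x, tx2, _ = _lag_design(x, y, order, use_x=True, use_y=False)
    var_y_own = _resid_var(own_y, ty2)
    var_x_own = _resid_var(own_x, tx2)
    return GrangerResult(
        gc_xy=float(np.log(var_y_own / var_y_full)),
        gc_yx=float(np.log(var_x_own / var_x_full)),
        order=order,
    )


# ---------------------------------------------------------------------------
# spectral (Geweke) decomposition
# ---------------------------------------------------------------------------

def _fit_var_full(x: np.ndarray, y: np.ndarray, order: int):
    """Full bivariate VAR coefficients (order, 2, 2) and residual covariance."""
    design, tx, ty = _lag_design(x, y, order, use_x=True, use_y=True)
    coef_x, _, _, _ = np.linalg.lstsq(design, tx, rcond=None)
    coef_y, _, _, _ = np.linalg.lstsq(design, ty, rcond=None)
    rx = tx - design @ coef_x
    ry = ty - design @ coef_y
    sigma = np.cov(np.vstack([rx, ry]), ddof=0)
    # design columns: const, then (x_{t-1}, y_{t-1}, x_{t-2}, y_{t-2}, ...)
    A = np.empty((order, 2, 2))
    for k in range(order):
        A[k, 0, 0] = coef_x[1 + 2 * k]
        A[k, 0, 1] = coef_x[2 + 2 * k]
        A[k, 1, 0] = coef_y[1 + 2 * k]
        A[k, 1, 1] = coef_y[2 + 2 * k]
    return A, sigma


def geweke_spectrum(x, y, order: int, fs: float,
                    freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-resolved causal densities (f_xy, f_yx) at ``freqs`` Hz."""
    x, y = _as_trials(x), _as_trials(y)
    A, sigma = _fit_var_full(x, y, order)
    s_xx, s_xy, s_yy = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    # partialized noise variances
    nx = s_xx - (s_xy ** 2) / s_yy if s_yy > 0 else s_xx
    ny = s_yy - (s_xy ** 2) / s_xx if s_xx > 0 else s_yy
    f_xy = np.empty(freqs.size)
    f_yx = np.empty(freqs.size)
    eye = np.eye(2, dtype=complex)
    ks = np.arange(1, order + 1)
    for i, f in enumerate(freqs):
        phase = np.exp(-2j * np.pi * f * ks / fs)
        Af = eye - np.tensordot(phase, A, axes=(0, 0))
        H = np.linalg.inv(Af)
        S = H @ sigma @ H.conj().T
        syy = S[1, 1].real
        sxx = S[0, 0].real
        f_xy[i] = np.log(syy / max(syy - nx * abs(H[1, 0]) ** 2, 1e-300))
        f_yx[i] = np.log(sxx / max(sxx - ny * abs(H[0, 1]) ** 2, 1e-300))
    return f_xy, f_yx


def spectral_granger(x, y, order: int, fs: float,
                     band: tuple[float, float],
                     n_perm: int = 500, seed: int | None = None,
                     freq_step: float = 1.0) -> GrangerResult:
    """Band-limited spectral causal density with a permutation null.

    The Geweke decomposition of the fitted VAR is averaged over the band
    at ``freq_step`` (1 Hz) resolution.  Surrogates shuffle the trial
    pairing between the two sensors (destroying any consistent cross-
    region lag while preserving each sensor's own statistics); perm_p is
    the fraction of surrogates whose band density reaches the observed.
    With single-trial input the surrogate instead circularly shifts one
    sensor by a random lag.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x, y = _as_trials(x), _as_trials(y)
    freqs = np.arange(band[0], band[1] + freq_step / 2, freq_step)
    if freqs.size == 0 or band[1] > fs / 2:
        raise ValueError("band must lie within the Nyquist range")
    f_xy, f_yx = geweke_spectrum(x, y, order, fs, freqs)
    obs_xy, obs_yx = float(f_xy.mean()), float(f_yx.mean())

    rng = np.random.default_rng(seed)
    count_xy = count_yx = 0
    n_trials = x.shape[0]
    for _ in range(n_perm):
        if n_trials > 1:
            perm = rng.permutation(n_trials)
            ys = y[perm]
        else:
            shift = int(rng.integers(1, x.shape[1]))
            ys = np.roll(y, shift, axis=1)
        s_xy, s_yx = geweke_spectrum(x, ys, order, fs, freqs)
        if s_xy.mean() >= obs_xy:
            count_xy += 1
        if s_yx.mean() >= obs_yx:
            count_yx += 1
    return GrangerResult(gc_xy=obs_xy, gc_yx=obs_yx, order=order, band=band,
                         perm_p=(count_xy / n_perm, count_yx / n_perm))


def group_direction_test(results: list[GrangerResult]):
    """Group-level paired comparison of the two causal directions.

    Tests gc_xy − gc_yx across subjects with a paired t-test and its JZS
    Bayesian equivalent.  Returns (TTestResult, BF10).
    """
    from .bayes_stats import jzs_bf, paired_t

    if len(results) < 2:
        raise ValueError("need at least 2 subjects")
    diffs = np.array([r.gc_xy - r.gc_yx for r in results])
    tt = paired_t(diffs)
    bf = jzs_bf(tt.t, diffs.size)
    return tt, bf
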