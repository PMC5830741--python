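"""Participant-specific frequency band selection within broad α/β/γ ranges.

A broad-band induced spectrogram is collapsed across the tROI into a
spectrum (amplitude change per integer centre frequency).  Every candidate
(low, high) sub-band meeting a family-specific minimum span is scored by
fitting a Gaussian peak model to the sub-spectrum and multiplying the
fit's adjusted R² by the maximum absolute deflection of the data; the
highest-scoring non-slope candidate wins.  Candidates whose spectral peak
sits on a band edge (a slope, not a peak) never beat a genuine peak fit,
and when nothing but slopes is available the full broad band is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BandPair",
    "PeakFit",
    "BROAD_BANDS",
    "MIN_SPANS",
    "fit_peak_model",
    "select_band",
    "restricted_vs_unrestricted",
]

# broad family ranges (Hz, inclusive) and minimum candidate spans (high - low)
BROAD_BANDS: dict[str, tuple[int, int]] = {
    "alpha": (6, 13),
    "beta": (14, 30),
    "gamma": (31, 130),
}
MIN_SPANS: dict[str, int] = {"alpha": 2, "beta": 4, "gamma": 12}


@dataclass(frozen=True)
class BandPair:
    """Inclusive (low, high) Hz band of integer centre frequencies."""

    low: int
    high: int

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")

    @property
    def width(self) -> int:
        """Number of integer centre frequencies included."""
        return self.high - self.low + 1

    @property
    def span(self) -> int:
        return self.high - self.low


@dataclass
class PeakFit:
    """Gaussian peak-model fit y = a·exp(−((x−b)/c)²) plus its score."""

    a: float
    b: float
    c: float
    adj_r2: float
    max_deflection: float
    slope: bool
    converged: bool

    @property
    def score(self) -> float:
        return self.adj_r2 * self.max_deflection


def _gaussian(x, a, b, c):
    return a * np.exp(-(((x - b) / c) ** 2))


def _parabola(x, a, b, c):
    return a - ((x - b) / c) ** 2


def fit_peak_model(freqs, spectrum, model: str = "gaussian") -> PeakFit:
    """Least-squares peak fit to a (sub-)spectrum.

    The score multiplies the fit's adjusted R² (3 parameters) by the
    maximum absolute deflection of the *data* spectrum.  A spectrum whose
    absolute maximum lies on the first or last frequency is flagged as a
    slope rather than a peak.  Non-convergence is reported via
    ``converged=False`` with adj_r2 = 0, not raised.
    """
    x = np.asarray(freqs, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 spectral points to fit a peak")
    fn = {"gaussian": _gaussian, "parabola": _parabola}[model]

    peak_idx = int(np.argmax(np.abs(y)))
    slope = peak_idx in (0, x.size - 1)
    max_defl = float(np.max(np.abs(y)))

    if np.ptp(y) == 0:
        return PeakFit(a=float(y[0]), b=float(x.mean()), c=1.0, adj_r2=0.0,
                       max_deflection=max_defl, slope=slope, converged=False)

    p0 = (y[peak_idx], x[peak_idx], max((x[-1] - x[0]) / 4.0, 0.5))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(fn, x, y, p0=p0, maxfev=5000)
        resid = y - fn(x, *popt)
        ss_res = float(np.sum(resid ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        n, p = x.size, 3
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)
        if not np.isfinite(adj_r2):
            raise RuntimeError("non-finite fit quality")
        return PeakFit(a=float(popt[0]), b=float(popt[1]), c=abs(float(popt[2])),
                       adj_r2=adj_r2, max_deflection=max_defl, slope=slope,
                       converged=True)
    except (RuntimeError, ValueError):
        return PeakFit(a=float(y[peak_idx]), b=float(x[peak_idx]), c=1.0,
                       adj_r2=0.0, max_deflection=max_defl, slope=slope,
                       converged=False)


def enumerate_pairs(family: str) -> list[BandPair]:
    """All candidate (low, high) integer pairs for a family, at or above
    its minimum span, within the broad range."""
    lo, hi = BROAD_BANDS[family]
    min_span = MIN_SPANS[family]
    return [BandPair(a, b)
            for a in range(lo, hi + 1)
            for b in range(a + min_span, hi + 1)]


def select_band(spectrum, freqs, family: str,
                model: str = "gaussian") -> tuple[BandPair, PeakFit | None]:
    """Pick the best sub-band of a tROI-collapsed spectrum.

    ``spectrum`` holds the induced amplitude change at each integer
    frequency in ``freqs``, which must cover the family's broad range.
    Every admissible pair is scored; slope-flagged candidates compete only
    among themselves and lose to any genuine peak.  If every candidate is
    a slope, the full broad band is returned with no fit.
    """
    freqs = np.asarray(freqs)
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = BROAD_BANDS[family]
    if freqs.min() > lo or freqs.max() < hi:
        raise ValueError(f"spectrum does not cover the {family} broad range")

    best: tuple[BandPair, PeakFit] | None = None
    best_slope: tuple[BandPair, PeakFit] | None = None
    for pair in enumerate_pairs(family):
        mask = (freqs >= pair.low) & (freqs <= pair.high)
        if mask.sum() < 4:
            continue
        fit = fit_peak_model(freqs[mask], spectrum[mask], model=model)
        bucket = best_slope if fit.slope else best
        if bucket is None or fit.score > bucket[1].score:
            if fit.slope:
                best_slope = (pair, fit)
            else:
                best = (pair, fit)
    if best is not None:
        return best
    return BandPair(lo, hi), None


def restricted_vs_unrestricted(restricted_results, unrestricted_results):
    """Choose between restricted and unrestricted induced traces.

    ``*_results`` are the per-region CriterionResults of the candidate
    traces.  The mean criterion level across the two regions decides
    (excluded traces contribute level 0); the restricted trace must win
    strictly — an equal mean level keeps the broader, unrestricted band.

    Returns ``(choice, flag)`` with choice in {"restricted",
    "unrestricted"}; flag is "all_excluded" when neither candidate
    produced an includable trace in any region.
    """
    def mean_level(results) -> float:
        levels = [(r.level if r.included and r.level is not None else 0.0)
                  for r in results]
        return float(np.mean(levels)) if levels else 0.0

    r_level = mean_level(restricted_results)
    u_level = mean_level(unrestricted_results)
    flag = None
    if r_level == 0.0 and u_level == 0.0:
        flag = "all_excluded"
    choice = "restricted" if r_level > u_level else "unrestricted"
    return choice, flag
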