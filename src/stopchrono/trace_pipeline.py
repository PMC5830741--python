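"""Contrast traces, baselining, evoked/induced traces and onset latency.

The measurement chain mirrors a source-level MEG analysis of stopping:

1. (Stop − Go) − Fixation contrast, with Go trials randomly down-sampled
   to match the stop-trial count;
2. z-scoring against the final 500 ms of the fixation baseline;
3. either a 30 Hz zero-phase low-pass (evoked trace) or a Hilbert
   amplitude-envelope spectrogram collapsed across a frequency band
   (induced trace);
4. iterative criterion-level determination in 0.5 SD steps and latency
   quantification as the first tROI sample whose |z| reaches the level.

All criterion and latency comparisons use the absolute z-score, so both
polarities of deflection are detected symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthdata import EpochSet
from .task_behavior import TROI

__all__ = [
    "ZTrace",
    "CriterionResult",
    "build_contrast",
    "build_success_fail_contrast",
    "baseline_zscore",
    "evoked_trace",
    "hilbert_envelope",
    "hilbert_spectrogram",
    "collapse_band",
    "criterion_level",
    "latency_quantify",
    "quantify_trace",
    "DegenerateDataError",
]

CRITERION_STEP = 0.5

EXCL_MEAN = "mean<0.5"
EXCL_MAX = "max<1"
EXCL_PEAK_NEAR_MEAN = "peak-within-0.5-of-mean"


class DegenerateDataError(ValueError):
    """Data degenerate for the requested operation (e.g. zero-variance baseline)."""


@dataclass
class ZTrace:
    """Baselined z-scored activity trace with tROI annotation.

    ``values[i]`` is the z-score at ``times[i]`` (ms; 0 = Go-stimulus
    onset), in units of the fixation-baseline SD.
    """

    values: np.ndarray
    times: np.ndarray
    fs: float
    troi: TROI | None = None
    baseline_window: tuple[float, float] = (-500.0, 0.0)

    def troi_mask(self) -> np.ndarray:
        if self.troi is None:
            raise ValueError("ZTrace has no tROI set")
        return (self.times >= self.troi.start) & (self.times <= self.troi.end)

    def with_values(self, values: np.ndarray) -> "ZTrace":
        return ZTrace(values=values, times=self.times, fs=self.fs,
                      troi=self.troi, baseline_window=self.baseline_window)


@dataclass
class CriterionResult:
    """Outcome of the iterative criterion procedure for one trace."""

    level: float | None
    latency_ms: float | None
    excluded_by: set = field(default_factory=set)

    @property
    def included(self) -> bool:
        return not self.excluded_by


# ---------------------------------------------------------------------------
# contrasts and baselining
# ---------------------------------------------------------------------------

def _check_grids(a: EpochSet, b: EpochSet) -> None:
    if a.data.shape[0] != b.data.shape[0] or a.data.shape[2] != b.data.shape[2]:
        raise ValueError("epoch sets are on different grids")
    if not np.allclose(a.times, b.times):
        raise ValueError("epoch sets are on different time grids")


def build_contrast(stop_epochs: EpochSet, go_epochs: EpochSet,
                   downsample: bool = True,
                   seed: int | None = None) -> np.ndarray:
    """Mean (Stop − Go) trace per region, shape (n_regions, n_samples).

    With ``downsample`` the Go trials are randomly subsampled (seeded)
    down to the stop-trial count before averaging, equalizing the noise
    contribution of the two conditions.
    """
    _check_grids(stop_epochs, go_epochs)
    if stop_epochs.n_trials == 0 or go_epochs.n_trials == 0:
        raise ValueError("both epoch sets must be nonempty")
    go_data = go_epochs.data
    if downsample and go_epochs.n_trials > stop_epochs.n_trials:
        rng = np.random.default_rng(seed)
        keep = rng.choice(go_epochs.n_trials, size=stop_epochs.n_trials,
                          replace=False)
        go_data = go_data[:, keep, :]
    return stop_epochs.data.mean(axis=1) - go_data.mean(axis=1)


def build_success_fail_contrast(succ_epochs: EpochSet,
                                fail_epochs: EpochSet) -> np.ndarray:
    """Successful-stop minus failed-stop mean trace; no down-sampling, since
    50% titration already yields roughly equal trial counts."""
    return build_contrast(succ_epochs, fail_epochs, downsample=False)


def baseline_zscore(trace: np.ndarray, times: np.ndarray, fs: float,
                    baseline_window: tuple[float, float] = (-500.0, 0.0),
                    troi: TROI | None = None) -> ZTrace:
    """z-score a single-region trace against its fixation baseline."""
    trace = np.asarray(trace, dtype=float)
    lo, hi = baseline_window
    if lo < times[0] or hi > times[-1]:
        raise ValueError("baseline window falls outside the epoch")
    mask = (times >= lo) & (times < hi)
    mu = trace[mask].mean()
    sd = trace[mask].std(ddof=0)
    if sd == 0:
        raise DegenerateDataError("zero-variance baseline")
    return ZTrace(values=(trace - mu) / sd, times=times, fs=fs, troi=troi,
                  baseline_window=baseline_window)


# ---------------------------------------------------------------------------
# evoked and induced traces
# ---------------------------------------------------------------------------

def _zero_phase_lowpass(x: np.ndarray, fs: float, cutoff: float,
                        order: int = 4) -> np.ndarray:
    b, a = signal.butter(order, cutoff / (fs / 2.0), btype="low")
    return signal.filtfilt(b, a, x, axis=-1)


def _zero_phase_bandpass(x: np.ndarray, fs: float, f_lo: float, f_hi: float,
                         order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    b, a = signal.butter(order, [f_lo / nyq, f_hi / nyq], btype="band")
    return signal.filtfilt(b, a, x, axis=-1)


def evoked_trace(ztrace: ZTrace, cutoff: float = 30.0) -> ZTrace:
    """30 Hz zero-phase (bidirectional Butterworth) low-pass of a z-trace.

    Forward-backward filtering cancels the group delay, so deflection
    timing is preserved — essential for latency measures.
    """
    if ztrace.fs <= 2 * cutoff:
        raise ValueError("sampling rate too low for the requested cutoff")
    return ztrace.with_values(_zero_phase_lowpass(ztrace.values, ztrace.fs, cutoff))


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope as the magnitude of the analytic signal."""
    return np.abs(signal.hilbert(np.asarray(x, dtype=float), axis=-1))


def hilbert_spectrogram(data: np.ndarray, fs: float, f_low: float,
                        f_high: float, step: float = 1.0,
                        bandwidth: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Time-frequency amplitude via band-passed analytic signals.

    For each integer centre frequency f in [f_low, f_high] (1 Hz step) the
    input is band-passed to f ± bandwidth/2 (zero-phase) and the Hilbert
    envelope taken.  2-D input (trials × samples) gives per-trial envelopes
    averaged across trials — the non-phase-locked (induced) amplitude.
    Band edges are clipped into (0, Nyquist) where necessary.

    Returns (spectrogram, centre_freqs); spectrogram rows are frequencies.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nyq = fs / 2.0
    if f_high + bandwidth / 2.0 > nyq and f_high >= nyq:
        raise ValueError("band outside the Nyquist range")
    if f_low > f_high:
        raise ValueError("f_low must be <= f_high")
    centres = np.arange(f_low, f_high + step / 2, step)
    rows = []
    for f in centres:
        lo = max(f - bandwidth / 2.0, 0.1)
        hi = min(f + bandwidth / 2.0, nyq * 0.999)
        filtered = _zero_phase_bandpass(data, fs, lo, hi)
        rows.append(hilbert_envelope(filtered).mean(axis=0))
    return np.vstack(rows), centres


def collapse_band(spectrogram: np.ndarray, centres: np.ndarray,
                  low: float, high: float) -> np.ndarray:
    """Mean across the centre frequencies in [low, high], per time point."""
    mask = (centres >= low) & (centres <= high)
    if not mask.any():
        raise ValueError("band pairing selects no centre frequencies")
    return spectrogram[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# criterion levels and latency
# ---------------------------------------------------------------------------

def criterion_level(ztrace: ZTrace, step: float = CRITERION_STEP,
                    use_absolute: bool = True) -> CriterionResult:
    """Iterative per-trace criterion determination.

    With m = mean|z| and M = max|z| over the tROI, the trace is excluded
    when m < 0.5 (no sustained deflection), M < 1 (no discernible peak) or
    M − m < 0.5 (peak too close to mean — noise-dominated).  Otherwise the
    criterion starts at 0.5 SD and is incremented in 0.5 SD steps while
    both m ≥ level and M ≥ level + 0.5 hold; the last level met is
    returned, which guarantees a crossing exists within the tROI.
    """
    z = ztrace.values if not use_absolute else np.abs(ztrace.values)
    zi = z[ztrace.troi_mask()]
    m = float(zi.mean())
    M = float(zi.max())
    excluded = set()
    if m < step:
        excluded.add(EXCL_MEAN)
    if M < 2 * step:
        excluded.add(EXCL_MAX)
    if M - m < step:
        excluded.add(EXCL_PEAK_NEAR_MEAN)
    if excluded:
        return CriterionResult(level=None, latency_ms=None, excluded_by=excluded)
    level = step
    while m >= level + step and M >= level + 2 * step:
        level += step
    latency = latency_quantify(ztrace, level, use_absolute=use_absolute)
    return CriterionResult(level=level, latency_ms=latency, excluded_by=set())


def latency_quantify(ztrace: ZTrace, level: float,
                     use_absolute: bool = True) -> float:
    """First time point in the tROI where |z| reaches the criterion level."""
    if level is None:
        raise ValueError("cannot quantify latency for an excluded trace")
    z = ztrace.values if not use_absolute else np.abs(ztrace.values)
    mask = ztrace.troi_mask()
    idx = np.flatnonzero(mask & (z >= level))
    if idx.size == 0:
        raise ValueError("trace never reaches the criterion level in the tROI")
    return float(ztrace.times[idx[0]])


def quantify_trace(ztrace: ZTrace) -> CriterionResult:
    """Criterion level plus latency in one call (alias of criterion_level)."""
    return criterion_level(ztrace)
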