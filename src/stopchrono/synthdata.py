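"""Synthetic stop-signal behaviour and source-level MEG epochs.

Generates the two kinds of raw material the analysis pipeline consumes,
with known ground truth:

* behavioural trial tables from an independent horse-race model — an
  ex-Gaussian Go process racing a (truncated-normal) Stop process whose
  finishing line is the stop-signal delay (SSD) plus the stop-signal
  reaction time (SSRT);
* per-trial "virtual sensor" activity epochs for two cortical regions
  (pre-SMA and IFC), built from 1/f background noise plus, on stop trials,
  a phase-locked evoked deflection and a non-phase-locked band-limited
  induced amplitude increase with configurable onsets.

Ground-truth onsets are carried in the epoch metadata so that downstream
latency quantification can be validated against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RaceParams",
    "TraceParams",
    "EpochSet",
    "simulate_race_trials",
    "synth_epochs",
    "save_trial_table",
    "load_trial_table",
    "save_epochs",
    "load_epochs",
    "REGIONS",
]

REGIONS = ("presma", "ifc")

TRIAL_COLUMNS = ["trial_id", "type", "ssd_ms", "responded", "rt_ms", "block"]


class ParameterError(ValueError):
    """Invalid generator parameterization."""


@dataclass
class RaceParams:
    """Horse-race model parameters (all times in ms).

    Defaults emulate healthy-adult group behaviour in a titrated
    stop-signal task: mean Go RT near 430 ms and SSRT near 210 ms.
    The Go finishing time is ex-Gaussian(mu_go, sigma_go, tau_go); the
    stop finishing time is normal(ssrt_mean, ssrt_sd) truncated at 0
    (ssrt_sd = 0 gives the constant-SSRT mode used for analytic checks).
    """

    mu_go: float = 350.0
    sigma_go: float = 50.0
    tau_go: float = 80.0
    ssrt_mean: float = 210.0
    ssrt_sd: float = 30.0
    p_stop_trial: float = 1.0 / 3.0
    omission_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_go", "sigma_go", "tau_go", "ssrt_mean"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.mu_go <= 0:
            raise ParameterError("mu_go must be > 0")
        if self.ssrt_sd < 0:
            raise ParameterError("ssrt_sd must be >= 0")
        if not 0.0 <= self.p_stop_trial <= 1.0:
            raise ParameterError("p_stop_trial must lie in [0, 1]")
        if not 0.0 <= self.omission_rate < 1.0:
            raise ParameterError("omission_rate must lie in [0, 1)")


@dataclass
class TraceParams:
    """Epoch-generator parameters.

    Epochs span ``epoch_window`` ms around Go-stimulus onset at sampling
    rate ``fs``; the default grid (−1300..+1300 ms at 1200 Hz) covers a
    full fixation baseline and response period.  ``evoked_onset`` /
    ``induced_onset`` are the ground-truth onsets (ms post-stimulus) in
    the first region; the second region's onsets are shifted by
    ``region_offset`` (the planted latency difference the pipeline should
    recover).  Amplitudes are expressed relative to the baseline noise SD.
    """

    fs: float = 1200.0
    epoch_window: tuple[float, float] = (-1300.0, 1300.0)
    evoked_onset: float = 260.0
    induced_onset: float = 260.0
    evoked_amp: float = 3.0
    induced_band: tuple[float, float] = (18.0, 26.0)
    induced_amp: float = 1.0
    noise_exponent: float = 1.0
    region_offset: float = 0.0
    regions: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window
        if hi <= lo:
            raise ParameterError("epoch_window must be increasing")
        if lo > -500.0:
            raise ParameterError("epoch must cover >= 500 ms of pre-stimulus baseline")
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        for onset in self.onsets_by_region().values():
            ev, ind = onset
            if not (lo < ev < hi) or not (lo < ind < hi):
                raise ParameterError("onsets must lie inside the epoch window")

    def onsets_by_region(self) -> dict[str, tuple[float, float]]:
        """Ground-truth (evoked, induced) onset per region, ms post-stimulus."""
        out: dict[str, tuple[float, float]] = {}
        for i, region in enumerate(self.regions):
            shift = self.region_offset if i > 0 else 0.0
            out[region] = (self.evoked_onset + shift, self.induced_onset + shift)
        return out


@dataclass
class EpochSet:
    """Per-trial region time series on a fixed epoch grid.

    ``data`` has shape (n_regions, n_trials, n_samples); ``times`` is in
    ms relative to Go-stimulus onset.  ``meta`` records fs, window,
    ground-truth onsets and the generator seed.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    regions: tuple[str, ...]
    trial_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def region(self, name: str) -> np.ndarray:
        """(n_trials, n_samples) array for one region."""
        return self.data[self.regions.index(name)]

    def subset(self, trial_index: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[:, trial_index, :],
            times=self.times,
            fs=self.fs,
            regions=self.regions,
            trial_ids=self.trial_ids[trial_index],
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# behavioural simulation
# ---------------------------------------------------------------------------

def _sample_go_finish(params: RaceParams, rng: np.random.Generator, n: int) -> np.ndarray:
    rt = rng.normal(params.mu_go, params.sigma_go, size=n)
    if params.tau_go > 0:
        rt = rt + rng.exponential(params.tau_go, size=n)
    return np.maximum(rt, 1.0)


def _sample_stop_finish(params: RaceParams, rng: np.random.Generator, n: int) -> np.ndarray:
    if params.ssrt_sd == 0:
        return np.full(n, float(params.ssrt_mean))
    out = rng.normal(params.ssrt_mean, params.ssrt_sd, size=n)
    # truncate at zero by resampling the (rare) negative draws
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(params.ssrt_mean, params.ssrt_sd, size=int(bad.sum()))
        bad = out < 0
    return out


def simulate_race_trials(
    params: RaceParams,
    n_trials: int,
    staircase=None,
    fixed_ssd: float | None = None,
    seed: int | None = None,
    block: int = 0,
) -> pd.DataFrame:
    """Simulate one block of stop-signal trials under the horse-race model.

    Stop trials occur with probability ``params.p_stop_trial``.  On a stop
    trial the response is made ("failed stop") iff the sampled Go finishing
    time beats SSD + sampled stop finishing time, in which case the recorded
    RT is that Go finishing time.  The SSD either follows the supplied
    staircase (one-up/one-down in `staircase.step` ms) or is held at
    ``fixed_ssd``.

    Returns a trial table with columns
    ``trial_id, type, ssd_ms, responded, rt_ms, block``.
    """
    from .task_behavior import StaircaseConfig, staircase_update

    if n_trials <= 0:
        raise ParameterError("n_trials must be > 0")
    if seed is None:
        raise ParameterError("a seed is required for reproducibility")
    if staircase is None and fixed_ssd is None:
        staircase = StaircaseConfig()
    rng = np.random.default_rng(seed)

    is_stop = rng.random(n_trials) < params.p_stop_trial
    go_finish = _sample_go_finish(params, rng, n_trials)
    stop_finish = _sample_stop_finish(params, rng, n_trials)
    omitted = rng.random(n_trials) < params.omission_rate

    ssd = float(staircase.initial_ssd) if staircase is not None else float(fixed_ssd)
    rows = []
    for i in range(n_trials):
        if is_stop[i]:
            failed = go_finish[i] < ssd + stop_finish[i]
            rows.append(
                (i, "stop", ssd, bool(failed), go_finish[i] if failed else np.nan, block)
            )
            if staircase is not None:
                ssd = staircase_update(ssd, "fail" if failed else "success", staircase)
        else:
            responded = not omitted[i]
            rows.append(
                (i, "go", np.nan, responded, go_finish[i] if responded else np.nan, block)
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# epoch synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n_trials: int, n_samples: int,
                      fs: float, exponent: float) -> np.ndarray:
    """1/f^exponent (power) background noise, unit variance per trial."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.ones_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal((n_trials, freqs.size))
                  + 1j * rng.standard_normal((n_trials, freqs.size)))
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _evoked_kernel(times_ms: np.ndarray, onset_ms: float, amp: float) -> np.ndarray:
    """Gamma-like deflection: fast rise, slow decay, peak height = amp."""
    t = (times_ms - onset_ms) / 1000.0  # s
    k = np.zeros_like(t)
    pos = t > 0
    shape, scale = 2.0, 0.04  # mode at (shape-1)*scale = 40 ms after onset
    tp = t[pos]
    k[pos] = (tp / scale) ** (shape - 1) * np.exp(-(tp - (shape - 1) * scale) / scale)
    peak = k.max()
    if peak > 0:
        k = k / peak * amp
    return k


def _induced_component(rng: np.random.Generator, times_ms: np.ndarray, fs: float,
                       band: tuple[float, float], onset_ms: float,
                       amp_increase: float, n_trials: int) -> np.ndarray:
    """Band-limited noise whose amplitude steps up by ``amp_increase`` at onset.

    The step is convolved with a 20 ms ramp so the subsequent band-pass
    filtering stages do not ring; the carrier has random phase per trial,
    so the component averages out of the evoked trace.
    """
    n_samples = times_ms.size
    nyq = fs / 2.0
    b, a = signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="band")
    carrier = rng.standard_normal((n_trials, n_samples))
    carrier = signal.filtfilt(b, a, carrier, axis=-1)
    sd = carrier.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    carrier /= sd

    envelope = 1.0 + amp_increase * (times_ms >= onset_ms).astype(float)
    ramp_len = max(int(round(0.020 * fs)), 1)
    ramp = np.ones(ramp_len) / ramp_len
    envelope = np.convolve(envelope, ramp, mode="same")
    return carrier * envelope - carrier  # only the amplitude *increase* part


def synth_epochs(params: TraceParams, trial_table: pd.DataFrame,
                 seed: int | None = None) -> EpochSet:
    """Generate per-trial virtual-sensor epochs for every trial in the table.

    All trials carry 1/f background noise; stop trials additionally carry a
    phase-locked evoked deflection and a band-limited induced amplitude
    increase at the region-specific ground-truth onsets.
    """
    if len(trial_table) == 0:
        raise ParameterError("trial_table must be nonempty")
    if seed is None:
        raise ParameterError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)

    lo, hi = params.epoch_window
    n_samples = int(round((hi - lo) * params.fs / 1000.0))
    times = lo + np.arange(n_samples) * 1000.0 / params.fs
    n_trials = len(trial_table)
    stop_mask = (trial_table["type"] == "stop").to_numpy()

    onsets = params.onsets_by_region()
    data = np.empty((len(params.regions), n_trials, n_samples))
    for r, region in enumerate(params.regions):
        noise = _one_over_f_noise(rng, n_trials, n_samples, params.fs,
                                  params.noise_exponent)
        sig = noise
        ev_on, ind_on = onsets[region]
        if stop_mask.any():
            if params.evoked_amp != 0:
                sig[stop_mask] += _evoked_kernel(times, ev_on, params.evoked_amp)
            if params.induced_amp != 0:
                sig[stop_mask] += _induced_component(
                    rng, times, params.fs, params.induced_band, ind_on,
                    params.induced_amp, int(stop_mask.sum()))
        data[r] = sig

    meta = {
        "fs": params.fs,
        "epoch_window": list(params.epoch_window),
        "onsets": {k: list(v) for k, v in onsets.items()},
        "induced_band": list(params.induced_band),
        "seed": int(seed),
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(params).items()},
    }
    return EpochSet(data=data, times=times, fs=params.fs,
                    regions=tuple(params.regions),
                    trial_ids=trial_table["trial_id"].to_numpy(), meta=meta)


# ---------------------------------------------------------------------------
# on-disk formats: CSV trial tables, npz + JSON sidecar epochs
# ---------------------------------------------------------------------------

def save_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write the numeric archive (<path>.npz style) plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, data=epochs.data, times=epochs.times,
                        trial_ids=epochs.trial_ids)
    sidecar = dict(epochs.meta)
    sidecar["regions"] = list(epochs.regions)
    sidecar["fs"] = epochs.fs
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    arrays = np.load(npz)
    meta = json.loads(npz.with_suffix(".json").read_text())
    return EpochSet(data=arrays["data"], times=arrays["times"],
                    fs=float(meta["fs"]), regions=tuple(meta["regions"]),
                    trial_ids=arrays["trial_ids"], meta=meta)
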