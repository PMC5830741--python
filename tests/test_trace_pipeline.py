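"""Contrast construction, baselining, filtering, criterion levels, latency."""

import numpy as np
import pytest

from stopchrono.synthdata import EpochSet, RaceParams, TraceParams, simulate_race_trials, synth_epochs
from stopchrono.task_behavior import TROI
from stopchrono.trace_pipeline import (
    DegenerateDataError,
    baseline_zscore,
    build_contrast,
    build_success_fail_contrast,
    collapse_band,
    criterion_level,
    evoked_trace,
    hilbert_spectrogram,
    latency_quantify,
)

from conftest import make_ztrace


def _epochs_from_array(data, fs=500.0, t0=-500.0):
    data = np.asarray(data, dtype=float)
    times = t0 + np.arange(data.shape[-1]) * 1000.0 / fs
    return EpochSet(data=data, times=times, fs=fs, regions=("presma", "ifc"),
                    trial_ids=np.arange(data.shape[1]))


def _troi_trace(values_in_troi, n_troi=200, baseline_sd=1.0, seed=0):
    """ZTrace whose tROI holds the requested values; baseline is N(0,1)."""
    rng = np.random.default_rng(seed)
    pre = rng.normal(0, baseline_sd, 600)
    troi_vals = np.resize(np.asarray(values_in_troi, dtype=float), n_troi)
    z = make_ztrace(np.concatenate([pre, troi_vals]), fs=1000.0,
                    troi=(100.0, 100.0 + n_troi - 1), t0=-500.0)
    return z


class TestContrast:
    def test_identical_sets_cancel(self):
        data = np.random.default_rng(0).standard_normal((2, 10, 300))
        ep = _epochs_from_array(data)
        trace = build_contrast(ep, ep, downsample=False)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)

    def test_downsample_uses_exactly_n_stop_go_trials(self):
        """Each Go trial is a constant equal to its index, so the contrast
        identifies exactly which trials the seeded subsample selected."""
        n_go, n_stop = 120, 60
        go = _epochs_from_array(
            np.tile(np.arange(n_go)[None, :, None], (2, 1, 50)))
        stop = _epochs_from_array(np.zeros((2, n_stop, 50)))
        trace = build_contrast(stop, go, downsample=True, seed=99)
        expected = np.random.default_rng(99).choice(n_go, size=n_stop,
                                                    replace=False)
        np.testing.assert_allclose(trace[0], -expected.mean())
        trace2 = build_contrast(stop, go, downsample=True, seed=99)
        np.testing.assert_array_equal(trace, trace2)

    def test_success_fail_variant_never_downsamples(self):
        data = np.random.default_rng(1).standard_normal((2, 8, 100))
        ep = _epochs_from_array(data)
        np.testing.assert_allclose(build_success_fail_contrast(ep, ep), 0.0,
                                   atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = _epochs_from_array(np.zeros((2, 5, 100)))
        b = _epochs_from_array(np.zeros((2, 5, 80)))
        with pytest.raises(ValueError):
            build_contrast(a, b)


class TestBaselineZScore:
    def test_moments_after_zscoring(self, rng):
        times = -500.0 + np.arange(1200)
        trace = rng.normal(5.0, 2.0, 1200)
        z = baseline_zscore(trace, times, 1000.0)
        mask = (times >= -500) & (times < 0)
        assert abs(z.values[mask].mean()) < 1e-9
        assert z.values[mask].std() == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_baseline_rejected(self):
        times = -500.0 + np.arange(1000)
        with pytest.raises(DegenerateDataError):
            baseline_zscore(np.ones(1000), times, 1000.0)


class TestEvokedFilter:
    def test_dc_unchanged(self):
        z = make_ztrace(np.full(2000, 3.0))
        out = evoked_trace(z)
        np.testing.assert_allclose(out.values, 3.0, atol=1e-6)

    def test_50hz_attenuated(self):
        t = np.arange(4000) / 1000.0
        z = make_ztrace(np.sin(2 * np.pi * 50.0 * t))
        out = evoked_trace(z)
        core = out.values[500:-500]
        assert np.abs(core).max() < 0.1  # > 90% attenuation above cutoff

    def test_zero_phase_preserves_peak(self):
        t = np.arange(3000)
        pulse = np.exp(-((t - 1500.0) / 80.0) ** 2)
        out = evoked_trace(make_ztrace(pulse))
        assert abs(int(np.argmax(out.values)) - 1500) <= 1


class TestHilbertSpectrogram:
    def test_pure_tone_envelope_recovers_amplitude(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        x = 2.5 * np.sin(2 * np.pi * 22.0 * t)
        spec, centres = hilbert_spectrogram(x, fs, 18, 26)
        row = spec[list(centres).index(22.0)]
        core = row[int(fs):-int(fs)]
        np.testing.assert_allclose(core, 2.5, rtol=0.02)

    def test_two_tone_separation(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        x = 1.0 * np.sin(2 * np.pi * 15.0 * t) + 3.0 * np.sin(2 * np.pi * 40.0 * t)
        spec, centres = hilbert_spectrogram(x, fs, 10, 45)
        core = slice(int(fs), -int(fs))
        at15 = spec[list(centres).index(15.0)][core].mean()
        at40 = spec[list(centres).index(40.0)][core].mean()
        assert at15 == pytest.approx(1.0, rel=0.05)
        assert at40 == pytest.approx(3.0, rel=0.05)

    def test_white_noise_envelope_is_trendless(self, rng):
        """Per-trial envelope slopes of stationary noise centre on zero.

        The slope is estimated per trial (trials are independent; time
        points within an envelope are not) and tested across trials.
        """
        from scipy import stats as sps
        fs = 250.0
        x = rng.standard_normal((24, int(8 * fs)))
        slopes = []
        for trial in x:
            spec, _ = hilbert_spectrogram(trial, fs, 20, 20)
            env = spec[0][int(fs):-int(fs)]
            slopes.append(sps.linregress(np.arange(env.size), env).slope)
        assert sps.ttest_1samp(slopes, 0.0).pvalue > 0.01

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            hilbert_spectrogram(np.zeros(100), 100.0, 40, 60)


class TestCollapseBand:
    def test_single_row_identity_and_direct_mean(self, rng):
        spec = rng.standard_normal((10, 50))
        centres = np.arange(10, 20, dtype=float)
        np.testing.assert_array_equal(
            collapse_band(spec, centres, 13, 13), spec[3])
        np.testing.assert_allclose(
            collapse_band(spec, centres, 12, 16), spec[2:7].mean(axis=0))

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            collapse_band(np.zeros((5, 10)), np.arange(5.0), 30, 40)


class TestCriterionLevel:
    def test_low_mean_excluded(self):
        # tROI: mostly 0.4 with one 2.0 peak -> mean < 0.5
        vals = np.full(200, 0.39)
        vals[100] = 2.0
        res = criterion_level(_troi_trace(vals))
        assert "mean<0.5" in res.excluded_by
        assert res.level is None

    def test_increment_loop_lands_between_mean_and_peak(self):
        # m = 1.2, M = 2.1: levels 0.5 and 1.0 qualify, 1.5 does not
        n = 200
        peak = 2.1
        fill = (1.2 * n - peak) / (n - 1)
        vals = np.full(n, fill)
        vals[150] = peak
        res = criterion_level(_troi_trace(vals))
        assert res.level == 1.0
        assert res.included

    def test_peak_near_mean_excluded(self):
        # m = 2.0, M = 2.3: peak within 0.5 SD of the mean -> noise-dominated
        n = 200
        peak = 2.3
        fill = (2.0 * n - peak) / (n - 1)
        vals = np.full(n, fill)
        vals[50] = peak
        res = criterion_level(_troi_trace(vals))
        assert res.excluded_by == {"peak-within-0.5-of-mean"}

    def test_negative_deflections_counted_via_absolute_value(self):
        n = 200
        peak = 2.1
        fill = (1.2 * n - peak) / (n - 1)
        vals = -np.full(n, fill)
        vals[150] = -peak
        res = criterion_level(_troi_trace(vals))
        assert res.level == 1.0


class TestLatency:
    def test_linear_ramp_crossing(self):
        n = 201
        ramp = np.linspace(0, 3, n)
        z = _troi_trace(ramp, n_troi=n)
        lat = latency_quantify(z, 1.5)
        mid = z.troi.start + z.troi.duration / 2
        assert abs(lat - mid) <= 1.0  # one sample at 1 kHz

    def test_level_at_peak_gives_argmax(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.5, 2.0, 200)
        vals[137] = 3.0
        z = _troi_trace(vals)
        assert latency_quantify(z, 2.999) == z.troi.start + 137.0

    def test_monotone_in_level(self):
        rng = np.random.default_rng(4)
        vals = np.abs(rng.standard_normal(200)) + np.linspace(0, 2, 200)
        z = _troi_trace(vals)
        lats = [latency_quantify(z, lv) for lv in (0.5, 1.0, 1.5, 2.0)]
        assert lats == sorted(lats)

    def test_scale_invariance_of_pipeline(self):
        """Scaling the raw trace by k > 0 leaves the z-trace, criterion level
        and latency unchanged."""
        rng = np.random.default_rng(5)
        times = -500.0 + np.arange(1000)
        raw = rng.standard_normal(1000) + 4.0 * (times > 100) * (times < 300)
        troi = TROI(100.0, 300.0)
        z1 = baseline_zscore(raw, times, 1000.0, troi=troi)
        z2 = baseline_zscore(7.3 * raw, times, 1000.0, troi=troi)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)
        r1, r2 = criterion_level(z1), criterion_level(z2)
        assert r1.level == r2.level and r1.latency_ms == r2.latency_ms

    def test_excluded_trace_cannot_be_quantified(self):
        z = _troi_trace(np.full(200, 0.1))
        with pytest.raises(ValueError):
            latency_quantify(z, None)


class TestOnsetRecovery:
    def test_planted_evoked_onset_recovered(self):
        """High-SNR synthetic epochs: the criterion-latency chain recovers the
        planted evoked onset within ±15 ms."""
        params = TraceParams(fs=600.0, epoch_window=(-600.0, 900.0),
                            evoked_onset=300.0, evoked_amp=0.8,
                            induced_amp=0.0)
        trials = simulate_race_trials(RaceParams(p_stop_trial=0.5), 160,
                                      fixed_ssd=200.0, seed=31)
        ep = synth_epochs(params, trials, seed=32)
        stop_idx = np.flatnonzero((trials["type"] == "stop").to_numpy())
        go_idx = np.flatnonzero((trials["type"] == "go").to_numpy())
        contrast = build_contrast(ep.subset(stop_idx), ep.subset(go_idx),
                                  seed=33)
        troi = TROI(250.0, 500.0)
        for r in range(2):
            z = baseline_zscore(contrast[r], ep.times, ep.fs, troi=troi)
            z = evoked_trace(z)
            res = criterion_level(z)
            assert res.included
            assert res.latency_ms == pytest.approx(300.0, abs=15.0)
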