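"""Pupil preprocessing: interpolation, filtering, deconvolution, scalar
extraction, exclusions and binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from pupilbias import preproc
from pupilbias.preproc import PreprocConfig, PupilTrace


def make_trace(x, rate=100.0, mask=None, events=()):
    return PupilTrace(np.asarray(x, float), rate, mask, list(events))


class TestCleanTrace:
    def test_gap_between_equal_values_filled_flat(self, preproc_config):
        x = np.full(1000, 5.0)
        mask = np.zeros(1000, bool)
        mask[400:450] = True
        x[mask] = -99.0
        out = preproc.clean_trace(make_trace(x, mask=mask), preproc_config)
        assert np.allclose(out.samples, 5.0, atol=1e-6)
        assert not out.missing_mask.any()

    def test_gap_interpolated_linearly_between_anchors(self):
        cfg = PreprocConfig(interp_pad_s=0.0, lowpass_cut_hz=49.0, target_rate_hz=100.0)
        x = np.concatenate([np.full(500, 1.0), np.full(500, 2.0)])
        mask = np.zeros(1000, bool)
        mask[495:505] = True
        out = preproc.clean_trace(make_trace(x, rate=100.0, mask=mask), cfg)
        seg = out.samples[494:506]
        assert np.all(np.diff(seg) >= -1e-6)  # monotone ramp across the gap

    def test_edge_gap_held_at_nearest_value(self, preproc_config):
        x = np.full(1000, 3.0)
        mask = np.zeros(1000, bool)
        mask[:50] = True
        x[:50] = -99
        out = preproc.clean_trace(make_trace(x, mask=mask), preproc_config)
        assert np.allclose(out.samples[:30], 3.0, atol=1e-6)

    def test_fully_missing_trace_rejected(self, preproc_config):
        with pytest.raises(ValueError):
            preproc.clean_trace(
                make_trace(np.zeros(100), mask=np.ones(100, bool)), preproc_config
            )

    def test_lowpass_attenuation_matches_transfer_function(self):
        # 10 Hz sinusoid through the 6 Hz zero-phase stage: amplitude ratio
        # equals |H|^2 of the third-order Butterworth at 10 Hz
        rate, f = 500.0, 10.0
        cfg = PreprocConfig()
        t = np.arange(0, 20, 1 / rate)
        x = np.sin(2 * np.pi * f * t)
        out = preproc.clean_trace(make_trace(x, rate=rate), cfg)
        b, a = sps.butter(3, cfg.lowpass_cut_hz / (rate / 2), "low")
        _, h = sps.freqz(b, a, worN=[f], fs=rate)
        expected = np.abs(h[0]) ** 2
        mid = slice(2000, 8000)
        ratio = out.samples[mid].std() / x[mid].std()
        assert ratio == pytest.approx(expected, rel=0.02)

    def test_idempotent_once_gaps_filled(self, preproc_config):
        # band-limited input: the second pass has no gaps left to fill and
        # its filter passes the (sub-cutoff) content unchanged
        t = np.arange(2000) / 100.0
        x = 100 + 2 * np.sin(2 * np.pi * 0.8 * t)
        mask = np.zeros(2000, bool)
        mask[300:340] = True
        once = preproc.clean_trace(make_trace(x, mask=mask), preproc_config)
        twice = preproc.clean_trace(once, preproc_config)
        assert not twice.missing_mask.any()
        # residual kink at the interpolated gap is ~1% of signal amplitude
        assert np.allclose(once.samples[100:-100], twice.samples[100:-100], atol=0.03)


class TestDeconvolution:
    def test_zero_events_identity(self, preproc_config):
        tr = make_trace(np.sin(np.linspace(0, 10, 500)))
        out = preproc.deconvolve_artifacts(tr, preproc_config)
        assert np.array_equal(out.samples, tr.samples)

    def test_construct_and_recover_known_response(self):
        # sample-resolution FIR on a 50 Hz trace recovers the planted kernel
        rate = 50.0
        cfg = PreprocConfig(deconv_epoch_s=2.0, deconv_bin_s=1 / rate)
        rng = np.random.default_rng(1)
        n = 6000
        kernel = np.exp(-np.arange(0, 2, 1 / rate)) * np.hanning(100)
        ev = np.sort(rng.choice(np.arange(100, n - 200), 40, replace=False))
        x = np.full(n, 10.0)
        for e in ev:
            x[e : e + 100] += kernel
        tr = make_trace(x, rate=rate, events=[("blink", e / rate) for e in ev])
        out = preproc.deconvolve_artifacts(tr, cfg)
        assert np.allclose(out.fir_estimates["blink"], kernel, atol=0.02)
        assert out.samples.std() < 0.02  # residual ~ constant

    def test_residual_orthogonal_to_event_regressors(self):
        rate = 50.0
        cfg = PreprocConfig(deconv_epoch_s=1.0, deconv_bin_s=0.1)
        rng = np.random.default_rng(2)
        n = 4000
        x = 10 + rng.standard_normal(n)
        ev = np.sort(rng.choice(np.arange(100, n - 100), 30, replace=False))
        tr = make_trace(x, rate=rate, events=[("blink", e / rate) for e in ev])
        out = preproc.deconvolve_artifacts(tr, cfg)
        # event-locked average of the residual should be flat
        epochs = np.array([out.samples[e : e + 50] for e in ev])
        assert np.abs(epochs.mean(axis=0) - out.samples.mean()).max() < 0.5

    def test_single_event_skipped_with_warning(self, preproc_config):
        tr = make_trace(np.ones(500), events=[("blink", 1.0)])
        with pytest.warns(UserWarning):
            out = preproc.deconvolve_artifacts(tr, preproc_config)
        assert np.array_equal(out.samples, tr.samples)


class TestNormalizeDownsample:
    def test_constant_trace_all_zeros(self, preproc_config):
        out = preproc.normalize_downsample(make_trace(np.full(1000, 7.0)), preproc_config)
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_downsample_1000_to_50(self):
        cfg = PreprocConfig()
        out = preproc.normalize_downsample(
            make_trace(100 + np.random.default_rng(0).standard_normal(10000), rate=1000.0),
            cfg,
        )
        assert out.rate_hz == 50.0
        assert out.samples.size == 10000 // 20

    def test_output_mean_near_zero(self, rng):
        x = 50 + rng.standard_normal(5000)
        out = preproc.normalize_downsample(make_trace(x, rate=100.0), PreprocConfig())
        assert abs(out.samples.mean()) < 0.1

    def test_nonpositive_mean_rejected(self, preproc_config):
        with pytest.raises(ValueError):
            preproc.normalize_downsample(make_trace(np.full(100, -1.0)), preproc_config)


class TestDerivative:
    def test_linear_trace_constant_slope(self):
        cfg = PreprocConfig()
        rate = 50.0
        x = 3.0 * np.arange(500) / rate  # 3 %/s ramp
        out = preproc.compute_derivative(make_trace(x, rate=rate), cfg)
        assert np.allclose(out.samples[50:-50], 3.0, atol=0.01)

    def test_constant_trace_zero(self):
        out = preproc.compute_derivative(make_trace(np.full(300, 2.0)), PreprocConfig())
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_slow_sinusoid_amplitude_scales_with_frequency(self):
        # calculus oracle: d/dt A sin(2 pi f t) has amplitude 2 pi f A
        rate, f, A = 100.0, 0.5, 2.0
        t = np.arange(0, 30, 1 / rate)
        out = preproc.compute_derivative(
            make_trace(A * np.sin(2 * np.pi * f * t), rate=rate), PreprocConfig()
        )
        assert out.samples[200:-200].max() == pytest.approx(2 * np.pi * f * A, rel=0.03)


class TestScalarExtraction:
    def _trials(self, onsets, rts=None):
        df = pd.DataFrame({"onset_t_s": onsets})
        df["rt_s"] = rts if rts is not None else np.nan
        return df

    def test_constant_derivative_returns_constant(self):
        cfg = PreprocConfig(scalar_window=("stimulus", 0.23, 0.50))
        d = make_trace(np.full(1000, 4.2))
        norm = make_trace(np.zeros(1000))
        out = preproc.extract_phasic_scalar(d, norm, self._trials([2.0, 4.0]), cfg)
        assert np.allclose(out["phasic_scalar"], 4.2)

    def test_linear_ramp_gives_95th_percentile(self):
        cfg = PreprocConfig(scalar_window=("stimulus", 0.0, 10.0))
        d = make_trace(np.linspace(0, 1, 1001), rate=100.0)
        norm = make_trace(np.zeros(1001))
        out = preproc.extract_phasic_scalar(d, norm, self._trials([0.0]), cfg)
        assert out["phasic_scalar"].iloc[0] == pytest.approx(0.95, abs=0.01)

    def test_published_window_defaults(self):
        assert preproc.HUMAN_GONOGO_WINDOW == ("stimulus", 0.23, 0.50)
        assert preproc.MOUSE_GONOGO_WINDOW == ("stimulus", 0.04, 0.23)
        assert preproc.MOUSE_RT_CUTOFF == pytest.approx(0.28)
        assert preproc.HUMAN_RT_CUTOFF == pytest.approx(0.55)

    def test_window_outside_trace_flags_trial(self):
        cfg = PreprocConfig(scalar_window=("stimulus", 0.23, 0.50))
        d = make_trace(np.zeros(100))  # 1 s of data at 100 Hz
        norm = make_trace(np.zeros(100))
        out = preproc.extract_phasic_scalar(d, norm, self._trials([5.0]), cfg)
        assert not out["included"].iloc[0]


class TestExclusions:
    def test_fast_go_trials_removed_nogo_kept(self):
        cfg = PreprocConfig(rt_cutoff_s=0.55)
        df = pd.DataFrame({"rt_s": [0.20, 0.30, 0.60, np.nan]})
        out = preproc.exclude_fast_trials(df, cfg)
        assert sorted(out["rt_s"].dropna()) == [0.60]
        assert out["rt_s"].isna().sum() == 1

    def test_all_slow_identity(self):
        cfg = PreprocConfig(rt_cutoff_s=0.55)
        df = pd.DataFrame({"rt_s": [0.7, 0.9, 1.2]})
        assert len(preproc.exclude_fast_trials(df, cfg)) == 3

    def test_cue_trials_removed(self):
        cfg = PreprocConfig(rt_cutoff_s=0.55)
        df = pd.DataFrame({"rt_s": [0.7, 0.9], "is_cue_trial": [True, False]})
        out = preproc.exclude_fast_trials(df, cfg)
        assert len(out) == 1 and not out["is_cue_trial"].iloc[0]


class TestBinning:
    def _table(self, scalars, **cols):
        df = pd.DataFrame({"phasic_scalar": scalars})
        for k, v in cols.items():
            df[k] = v
        df["included"] = True
        return df

    def test_equal_population_no_strata(self, rng):
        cfg = PreprocConfig(n_bins=5)
        out = preproc.assign_pupil_bins(self._table(rng.standard_normal(100)), cfg)
        assert (out["pupil_bin"].value_counts() == 20).all()

    def test_stratified_counts_exact(self, rng):
        cfg = PreprocConfig(n_bins=5)
        df = self._table(
            rng.standard_normal(100), loudness_db=np.repeat([-20.0, -10.0], 50)
        )
        out = preproc.assign_pupil_bins(df, cfg, stratify_by="loudness_db")
        counts = out.groupby(["loudness_db", "pupil_bin"]).size()
        assert (counts == 10).all()

    def test_bins_ordered_by_scalar(self, rng):
        cfg = PreprocConfig(n_bins=4)
        out = preproc.assign_pupil_bins(self._table(rng.standard_normal(80)), cfg)
        means = out.groupby("pupil_bin")["phasic_scalar"].mean()
        assert means.is_monotonic_increasing

    @given(n=st.integers(min_value=6, max_value=97), bins=st.integers(2, 6))
    @settings(max_examples=20, deadline=None)
    def test_bin_populations_differ_by_at_most_one(self, n, bins):
        rng = np.random.default_rng(n)
        cfg = PreprocConfig(n_bins=bins)
        out = preproc.assign_pupil_bins(self._table(rng.standard_normal(n)), cfg)
        counts = out["pupil_bin"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_small_stratum_warns(self):
        cfg = PreprocConfig(n_bins=5)
        with pytest.warns(UserWarning):
            out = preproc.assign_pupil_bins(self._table([0.1, 0.2, 0.3]), cfg)
        assert (out["pupil_bin"] >= 0).all()


class TestPipelineConsistency:
    def test_latent_arousal_recovered_by_scalar(self, small_yesno_dataset):
        from scipy.stats import spearmanr

        # window matched to the generator's impulse-response rising flank
        # (the gamma IRF peaks at 0.93 s)
        cfg = PreprocConfig(scalar_window=("stimulus", 0.3, 0.9), n_bins=3)
        tr = small_yesno_dataset["trace"]
        trials = small_yesno_dataset["trials"]
        sub = trials[trials["subject_id"] == "s00"].reset_index(drop=True)
        aug = preproc.preprocess_session(tr, sub, cfg)
        truth = small_yesno_dataset["truth"]
        m = aug[aug["included"] & aug["phasic_scalar"].notna()]
        rho = spearmanr(truth.arousal[m["trial"].to_numpy()], m["phasic_scalar"])[0]
        assert rho > 0.8
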