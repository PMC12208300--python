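"""Feature extraction, referencing, binning and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocursor.cortex import synthetic_voltage_block
from neurocursor.features import (
    FeatureNormalizer,
    RawVoltageBlock,
    bandpass_filter,
    bin_frames,
    extract_frames,
    linear_regression_reference,
    stack_features,
)

FS = 30_000.0


def _block(samples, arrays=None):
    samples = np.atleast_2d(np.asarray(samples, float))
    if arrays is None:
        arrays = np.array(["a"] * samples.shape[0])
    return RawVoltageBlock(samples, FS, arrays)


class TestExtractFrames:
    def test_zero_signal_yields_zero_features(self):
        crossings, sbp = extract_frames(_block(np.zeros((3, 3000))))
        assert crossings.sum() == 0
        assert np.allclose(sbp, 0)

    def test_injected_spike_registers_one_crossing(self):
        """A biphasic -6xRMS spike crosses threshold exactly where a direct
        scan of the filtered trace says it does."""
        rng = np.random.default_rng(0)
        noise = bandpass_filter(rng.normal(0, 5.0, size=(1, 6000)), FS)
        rms0 = float(np.sqrt(np.mean(noise**2)))
        spf = int(FS * 0.001)
        t = np.arange(spf)
        templ = -np.sin(np.pi * t / spf)  # 1 ms downward lobe
        trace = noise.copy()
        start = 50 * spf + spf // 4
        trace[0, start : start + spf] += 6.0 * rms0 * templ
        crossings, _ = extract_frames(_block(trace), prefiltered=True)
        # independent oracle: scan the same (already filtered) trace directly
        rms = float(np.sqrt(np.mean(trace**2)))
        thresh = -4.5 * rms
        windows = trace[0, : (trace.shape[1] // spf) * spf].reshape(-1, spf)
        manual = (windows.min(axis=1) <= thresh).astype(int)
        assert np.array_equal(crossings[:, 0], manual)
        assert crossings[50, 0] == 1

    def test_sub_band_sinusoid_never_crosses(self):
        t = np.arange(30000) / FS
        sine = 500.0 * np.sin(2 * np.pi * 100.0 * t)  # below the 250 Hz edge
        crossings, _ = extract_frames(_block(sine))
        assert crossings.sum() == 0

    def test_dc_offset_invariance(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(0, 10, size=(2, 9000))
        c0, _ = extract_frames(_block(raw))
        c1, _ = extract_frames(_block(raw + 500.0))
        assert np.array_equal(c0, c1)

    def test_rejects_nonfinite(self):
        bad = np.zeros((2, 3000))
        bad[0, 5] = np.nan
        with pytest.raises(ValueError):
            _block(bad)


class TestLinearRegressionReference:
    def test_common_mode_rejection(self):
        rng = np.random.default_rng(2)
        n_e, n = 8, 20000
        common = rng.normal(0, 20, size=n)
        sig = rng.normal(0, 5, size=(n_e, n)) + common
        out = linear_regression_reference(_block(sig))
        u = np.ones(n_e) / np.sqrt(n_e)
        before = np.var(u @ sig)
        after = np.var(u @ out.samples)
        assert after <= 0.1 * before

    def test_independent_signals_pass_through(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(0, 10, size=(6, 30000))
        out = linear_regression_reference(_block(sig))
        for e in range(6):
            r = np.corrcoef(sig[e], out.samples[e])[0, 1]
            assert r > 0.95

    def test_duplicated_electrode_residual_is_zero(self):
        rng = np.random.default_rng(4)
        sig = rng.normal(0, 10, size=(4, 5000))
        sig[1] = sig[0]
        out = linear_regression_reference(_block(sig))
        assert np.allclose(out.samples[0], 0, atol=1e-8)
        assert np.allclose(out.samples[1], 0, atol=1e-8)

    def test_never_increases_residual_variance(self):
        rng = np.random.default_rng(5)
        sig = rng.normal(0, 10, size=(5, 8000)) + rng.normal(0, 15, size=8000)
        out = linear_regression_reference(_block(sig))
        assert np.var(out.samples, axis=1).sum() <= np.var(sig, axis=1).sum() + 1e-9

    def test_arrays_referenced_independently(self):
        rng = np.random.default_rng(6)
        arrays = np.array(["a", "a", "b", "b"])
        common_a = rng.normal(0, 20, size=4000)
        sig = rng.normal(0, 5, size=(4, 4000))
        sig[:2] += common_a  # only array 'a' sees this
        out = linear_regression_reference(RawVoltageBlock(sig, FS, arrays))
        # array b electrodes barely change
        for e in (2, 3):
            assert np.corrcoef(sig[e], out.samples[e])[0, 1] > 0.95


class TestBinning:
    def test_sum_and_mean_aggregation(self):
        crossings = np.ones((10, 3), dtype=int)
        sbp = np.tile(np.arange(10.0)[:, None], (1, 3))
        b = bin_frames(crossings, sbp)
        assert b.n_bins == 1
        assert np.all(b.crossings == 10)
        assert np.allclose(b.sbp, 4.5)

    def test_partial_bin_dropped(self):
        b = bin_frames(np.ones((25, 2), dtype=int), np.ones((25, 2)))
        assert b.n_bins == 2

    @given(n_bins=st.integers(1, 8), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_binning_conserves_crossings(self, n_bins, seed):
        rng = np.random.default_rng(seed)
        crossings = rng.integers(0, 2, size=(n_bins * 10, 4))
        b = bin_frames(crossings, np.zeros((n_bins * 10, 4)))
        assert b.crossings.sum() == crossings.sum()


class TestFeatureNormalizer:
    def _training(self, rng, n_bins=200, n_e=4):
        counts = rng.poisson(2.0, size=(n_bins, n_e)).astype(float)
        sbp = 50 + 10 * rng.random((n_bins, n_e))
        return stack_features(counts, sbp)

    def test_rate_based_exclusion(self):
        rng = np.random.default_rng(7)
        X = self._training(rng, n_bins=200, n_e=4)
        X[:, 0] = 0.0  # 0 Hz -> excluded
        X[:, 1] = 1.0  # exactly 1 crossing per bin = 100 Hz -> retained
        X[:, 2] = 0.0
        X[::25, 2] = 1.0  # 4 per 100 bins = 4 Hz -> excluded
        norm = FeatureNormalizer().fit(X)
        assert norm.excluded_[0]
        assert not norm.excluded_[1]
        assert norm.excluded_[2]

    def test_all_excluded_is_an_error(self):
        X = np.zeros((150, 4))
        with pytest.raises(ValueError):
            FeatureNormalizer().fit(X)

    def test_zscore_clip_and_mean_identity(self):
        rng = np.random.default_rng(8)
        X = self._training(rng)
        norm = FeatureNormalizer().fit(X)
        e = int(norm.retained_electrodes_[0])
        col = int(np.flatnonzero(norm.retained_features_ == e)[0])
        x = X.mean(axis=0).copy()
        z = norm.transform(x[None, :])[0]
        assert abs(z[col]) < 1e-9  # raw value = mean -> z = 0
        x[e] = norm.mean_[e] + 7 * norm.std_[e]
        z = norm.transform(x[None, :])[0]
        assert z[col] == pytest.approx(5.0)  # clipped at +5

    def test_noise_gate_substitutes_means(self):
        rng = np.random.default_rng(9)
        X = self._training(rng)
        norm = FeatureNormalizer().fit(X)
        n_e = norm.n_electrodes_
        stream = np.tile(X.mean(axis=0), (5, 1))
        stream[:, 0] = 6.0  # 5 consecutive bins of >= 5 crossings (>= 500 Hz)
        Z = norm.transform(stream)
        cols = np.flatnonzero(np.isin(norm.retained_features_, [0, n_e]))
        assert np.allclose(Z[4, cols], 0.0)

    def test_noise_gate_inactive_without_history(self):
        rng = np.random.default_rng(10)
        X = self._training(rng)
        norm = FeatureNormalizer().fit(X)
        one = X.mean(axis=0).copy()
        one[0] = 6.0
        Z = norm.transform(one[None, :])  # < 5 bins of history: gate off
        col = int(np.flatnonzero(norm.retained_features_ == 0)[0])
        assert Z[0, col] > 0

    @given(seed=st.integers(0, 200))
    @settings(max_examples=30, deadline=None)
    def test_output_always_within_clip_bound(self, seed):
        rng = np.random.default_rng(seed)
        X = self._training(rng)
        norm = FeatureNormalizer().fit(X)
        probe = 1e4 * rng.standard_normal((7, X.shape[1])) ** 2
        Z = norm.transform(probe)
        assert np.all(np.abs(Z) <= 5.0)

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = self._training(rng)
        norm = FeatureNormalizer().fit(X)
        norm.save_json(tmp_path / "norm.json")
        back = FeatureNormalizer.load_json(tmp_path / "norm.json")
        assert np.array_equal(back.excluded_, norm.excluded_)
        assert np.allclose(back.transform(X), norm.transform(X))


def test_voltage_to_bins_pipeline_end_to_end():
    """The voltage path produces nonnegative integer counts <= 10 per bin."""
    block = synthetic_voltage_block(n_electrodes=8, duration_s=0.25, seed=3)
    ref = linear_regression_reference(block)
    crossings, sbp = extract_frames(ref)
    b = bin_frames(crossings, sbp)
    assert b.crossings.min() >= 0 and b.crossings.max() <= 10
    assert np.all(b.sbp >= 0)
    assert b.n_bins == 25
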