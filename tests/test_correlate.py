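"""Multi-tau correlator against the brute-force oracle and white noise."""

import numpy as np
import pytest
from conftest import naive_acf

from fcskit import (
    IntensityTrace,
    MultiTauScheme,
    TraceSegmentSet,
    average_segment_acfs,
    compute_acf,
    normalize_amplitude,
    segment_trace,
)


def _white_noise_trace(mean, n_bins, bin_width, seed):
    rng = np.random.default_rng(seed)
    return IntensityTrace(
        rng.poisson(mean, n_bins).astype(float), bin_width=bin_width
    )


class TestComputeAcf:
    def test_constant_trace_gives_unity(self):
        tr = IntensityTrace(np.full(100000, 7.0), bin_width=1e-4)
        curve = compute_acf(tr)
        np.testing.assert_allclose(curve.G, 1.0, atol=1e-12)

    def test_white_noise_is_flat_at_one(self):
        tr = _white_noise_trace(50, 200000, 1e-4, seed=5)
        curve = compute_acf(tr)
        # independent Poisson bins decorrelate at any lag >= 1 bin
        assert np.all(np.abs(curve.G - 1.0) < 5e-3)

    def test_zero_trace_rejected(self):
        tr = IntensityTrace(np.zeros(100000), bin_width=1e-4)
        with pytest.raises(ValueError):
            compute_acf(tr)

    def test_max_lag_requires_10x_duration(self):
        tr = _white_noise_trace(10, 10000, 1e-4, seed=0)  # 1 s
        with pytest.raises(ValueError):
            compute_acf(tr, MultiTauScheme(max_lag=0.5))

    def test_agrees_with_brute_force_on_short_trace(self):
        # correlated signal: sum of smoothed noise so G decays over lags
        rng = np.random.default_rng(11)
        raw = rng.poisson(4, 133334).astype(float)  # 2 s at 15 us
        kernel = np.ones(30) / 30
        sig = np.convolve(raw, kernel, mode="same") * 10
        tr = IntensityTrace(sig, bin_width=15e-6)
        curve = compute_acf(tr, MultiTauScheme(max_lag=0.2))
        lag_bins = np.rint(curve.lags / tr.bin_width).astype(int)
        oracle = naive_acf(tr.counts, lag_bins)
        # level-0 lags are exact; coarsened lags agree within the
        # coarsening bin's averaging error plus the single-lag sampling
        # noise of the brute-force estimate itself
        amp = curve.G[0] - 1.0
        np.testing.assert_allclose(curve.G[:32], oracle[:32], atol=1e-10)
        np.testing.assert_allclose(curve.G, oracle, atol=0.02 * amp + 5e-4)

    def test_invariant_under_intensity_scaling(self):
        tr = _white_noise_trace(20, 100000, 1e-4, seed=3)
        scaled = IntensityTrace(tr.counts * 13.0, bin_width=tr.bin_width)
        np.testing.assert_allclose(
            compute_acf(tr).G, compute_acf(scaled).G, rtol=1e-12
        )

    def test_time_reversal_symmetry_within_noise(self):
        tr = _white_noise_trace(30, 200000, 1e-4, seed=9)
        rev = IntensityTrace(tr.counts[::-1].copy(), bin_width=tr.bin_width)
        g1, g2 = compute_acf(tr).G, compute_acf(rev).G
        assert np.all(np.abs(g1 - g2) < 5e-3)


class TestAverageSegments:
    def test_identical_segments_give_sigma_floor(self):
        seg = IntensityTrace(np.tile([3.0, 5.0, 4.0, 6.0], 25000), bin_width=1e-4)
        segs = TraceSegmentSet(segments=[seg, seg, seg])
        curve = average_segment_acfs(segs)
        assert np.all(curve.sigma == pytest.approx(1e-6))
        assert curve.n_segments == 3

    def test_averaging_reduces_white_noise_scatter(self):
        tr = _white_noise_trace(40, 400000, 1e-4, seed=21)  # 40 s
        segs = segment_trace(tr, 10.0)
        avg = average_segment_acfs(segs)
        single = compute_acf(segs.segments[0])
        assert np.abs(avg.G - 1).mean() < np.abs(single.G - 1).mean()
        assert avg.n_segments == 4

    def test_single_segment_falls_back_to_unit_weights(self):
        seg = _white_noise_trace(10, 100000, 1e-4, seed=2)
        curve = average_segment_acfs(TraceSegmentSet(segments=[seg]))
        assert curve.n_segments == 1
        assert np.all(curve.sigma == 1.0)


class TestNormalizeAmplitude:
    def _curve(self, N, seed=0):
        from fcskit import FitParams, synthesize_acf

        params = FitParams(N=N, fractions=(1.0,), taus=(4e-4,), S=5.0)
        lags = np.geomspace(15e-6, 1.0, 100)
        return synthesize_acf(params, lags)

    def test_self_normalization_is_identity(self):
        c = self._curve(2.0)
        out = normalize_amplitude(c, c.G[0] - 1.0)
        np.testing.assert_allclose(out.G, c.G, rtol=1e-12)

    def test_different_N_collapse_after_normalization(self):
        c1, c10 = self._curve(1.0), self._curve(10.0)
        n1 = normalize_amplitude(c1, 1.0)
        n10 = normalize_amplitude(c10, 1.0)
        np.testing.assert_allclose(n1.G, n10.G, rtol=1e-9)

    def test_nonpositive_amplitude_rejected(self):
        from fcskit import CorrelationCurve

        flat = CorrelationCurve(
            lags=np.array([1e-4, 1e-3]),
            G=np.array([1.0, 1.0]),
            sigma=np.array([1.0, 1.0]),
        )
        with pytest.raises(ValueError):
            normalize_amplitude(flat, 1.0)
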