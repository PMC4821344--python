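"""Diffusion-model evaluation and weighted fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcskit import (
    CorrelationCurve,
    FitParams,
    ModelSpec,
    chi_square,
    eval_model,
    fit_acf,
    model_curve,
    synthesize_acf,
)


class TestEvalModel:
    def test_short_lag_limit_is_amplitude_law(self):
        p = FitParams(N=2.5, fractions=(1.0,), taus=(1e-3,), S=5.0)
        g = model_curve(p, [1e-9])
        assert g[0] == pytest.approx(1.0 + 1.0 / 2.5, rel=1e-4)

    def test_half_decay_in_2d_limit(self):
        # S -> infinity removes the axial factor: G(tau1) = 1 + 1/(2N)
        p = FitParams(N=1.0, fractions=(1.0,), taus=(1e-3,), S=1e9)
        g = model_curve(p, [1e-3])
        assert g[0] == pytest.approx(1.5, rel=1e-9)

    def test_2d_limit_matches_closed_form_pointwise(self):
        p = FitParams(N=3.0, fractions=(1.0,), taus=(2e-4,), S=1e9)
        lags = np.geomspace(1e-6, 1.0, 50)
        expected = 1.0 + (1.0 / 3.0) / (1.0 + lags / 2e-4)
        np.testing.assert_allclose(model_curve(p, lags), expected, rtol=1e-9)

    def test_wild_type_fully_decorrelated_at_long_lag(self, wt_params):
        g = model_curve(wt_params, [3.4])
        assert abs(g[0] - 1.0) < 1e-2  # tail of tau3 = 98 ms at 3.4 s

    def test_monotone_nonincreasing_for_alpha_le_1(self, wt_params):
        lags = np.geomspace(1e-6, 10.0, 2000)
        g = model_curve(wt_params, lags)
        assert np.all(np.diff(g) <= 1e-15)

    def test_triplet_factor_raises_early_lags_only(self):
        p = FitParams(
            N=1.0, fractions=(1.0,), taus=(1e-3,), S=5.0,
            triplet_fraction=0.2, triplet_time=5e-6,
        )
        lags = np.array([1e-6, 1e-2])
        plain = model_curve(p, lags, triplet=False)
        trip = model_curve(p, lags, triplet=True)
        assert trip[0] > plain[0] * 1.1
        assert trip[1] == pytest.approx(plain[1], rel=1e-6)

    def test_nonpositive_lags_rejected(self, wt_params):
        with pytest.raises(ValueError):
            model_curve(wt_params, [0.0, 1e-3])

    @given(
        n=st.floats(0.1, 100.0),
        tau=st.floats(1e-5, 1e-1),
        s=st.floats(1.0, 20.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_amplitude_bounded_by_1_over_N(self, n, tau, s):
        p = FitParams(N=n, fractions=(1.0,), taus=(tau,), S=s)
        lags = np.geomspace(1e-6, 1.0, 30)
        g = model_curve(p, lags)
        assert np.all(g - 1.0 <= 1.0 / n + 1e-12)
        assert np.all(g >= 1.0)


class TestFitParamsValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FitParams(N=1.0, fractions=(0.5, 0.4), taus=(1e-4, 1e-3))

    def test_taus_must_ascend(self):
        with pytest.raises(ValueError):
            FitParams(N=1.0, fractions=(0.5, 0.5), taus=(1e-3, 1e-4))


class TestChiSquare:
    def _curve(self, g, sigma):
        n = len(g)
        return CorrelationCurve(
            lags=np.geomspace(1e-4, 1e-2, n),
            G=np.asarray(g, dtype=float),
            sigma=np.asarray(sigma, dtype=float),
        )

    def test_perfect_model_gives_zero(self):
        c = self._curve([1.5, 1.2, 1.1], [0.1, 0.1, 0.1])
        assert chi_square(c, c.G) == 0.0

    def test_single_point_two_sigma_gives_four(self):
        c = self._curve([1.5], [0.05])
        assert chi_square(c, [1.5 + 0.1]) == pytest.approx(4.0)

    def test_three_point_arithmetic(self):
        # residuals of 1, 2 and 3 sigma -> 1 + 4 + 9 = 14
        sig = [0.1, 0.2, 0.05]
        c = self._curve([1.5, 1.3, 1.1], sig)
        model = c.G + np.array([1, 2, 3]) * np.array(sig)
        assert chi_square(c, model) == pytest.approx(14.0)

    def test_empty_mask_rejected(self):
        c = self._curve([1.5, 1.2], [0.1, 0.1])
        with pytest.raises(ValueError):
            chi_square(c, c.G, mask=np.zeros(2, dtype=bool))


class TestFitAcf:
    def test_one_component_exact_recovery(self, lag_grid):
        truth = FitParams(N=2.0, fractions=(1.0,), taus=(4e-4,), S=5.0)
        curve = synthesize_acf(truth, lag_grid)
        res = fit_acf(curve, ModelSpec(n_components=1), starts=4)
        assert res.params.N == pytest.approx(2.0, rel=1e-6)
        assert res.params.taus[0] == pytest.approx(4e-4, rel=1e-6)

    def test_wild_type_refit_from_perturbed_start(self, wt_params, lag_grid):
        curve = synthesize_acf(wt_params, lag_grid)
        init = FitParams(
            N=1.0,
            fractions=(1 / 3, 1 / 3, 1 / 3),
            taus=tuple(2 * t for t in wt_params.taus),
            S=5.0,
        )
        res = fit_acf(curve, ModelSpec(n_components=3), starts=1, init=init)
        assert res.params.fractions[0] * 100 == pytest.approx(45.1, rel=0.01)
        assert res.params.taus[2] * 1e3 == pytest.approx(98.2, rel=0.01)

    def test_nested_model_dominance_on_two_component_truth(self, lag_grid):
        truth = FitParams(N=1.0, fractions=(0.6, 0.4), taus=(3e-4, 5e-3), S=5.0)
        curve = synthesize_acf(truth, lag_grid, noise_sd=1e-4, rng_seed=0)
        r1 = fit_acf(curve, ModelSpec(n_components=1), starts=4)
        r2 = fit_acf(curve, ModelSpec(n_components=2), starts=4)
        assert r1.chi2 > r2.chi2

    def test_refit_fixed_point(self, wt_params, lag_grid):
        # fitting a fit's own model curve reproduces its parameters
        curve = synthesize_acf(wt_params, lag_grid, noise_sd=0.005, rng_seed=4)
        first = fit_acf(curve, ModelSpec(n_components=3), starts=6, rng_seed=1)
        self_curve = synthesize_acf(first.params, lag_grid)
        second = fit_acf(
            self_curve, ModelSpec(n_components=3), starts=1, init=first.params
        )
        for a, b in zip(first.params.taus, second.params.taus):
            assert b == pytest.approx(a, rel=1e-6)

    def test_noisy_tau_recovery_median_under_15pct(self, wt_params, lag_grid):
        errs = []
        for seed in range(20):
            curve = synthesize_acf(wt_params, lag_grid, noise_sd=0.005, rng_seed=seed)
            res = fit_acf(curve, ModelSpec(n_components=3), starts=6, rng_seed=seed)
            errs.append(
                [abs(f / t - 1) for f, t in zip(res.params.taus, wt_params.taus)]
            )
        med = np.median(np.asarray(errs), axis=0)
        assert np.all(med < 0.15)

    def test_amplitude_sum_rule(self, lag_grid):
        truth = FitParams(N=0.8, fractions=(1.0,), taus=(4e-4,), S=5.0)
        curve = synthesize_acf(truth, lag_grid, noise_sd=0.002, rng_seed=2)
        res = fit_acf(curve, ModelSpec(n_components=1), starts=4)
        mask = (curve.lags >= res.spec.fit_range[0])
        amp = curve.G[mask][0] - 1.0
        assert amp <= 1.0 / res.params.N * 1.05

    def test_degenerate_curve_rejected(self):
        flat = CorrelationCurve(
            lags=np.geomspace(1e-4, 1.0, 50),
            G=np.ones(50),
            sigma=np.ones(50),
        )
        with pytest.raises(ValueError):
            fit_acf(flat, ModelSpec(n_components=1))

    def test_deterministic_for_fixed_seed(self, lag_grid):
        truth = FitParams(N=1.0, fractions=(0.6, 0.4), taus=(3e-4, 5e-3), S=5.0)
        curve = synthesize_acf(truth, lag_grid, noise_sd=0.01, rng_seed=3)
        r1 = fit_acf(curve, ModelSpec(n_components=2), starts=6, rng_seed=5)
        r2 = fit_acf(curve, ModelSpec(n_components=2), starts=6, rng_seed=5)
        assert r1.params.taus == r2.params.taus
        assert r1.chi2 == r2.chi2
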