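"""AICc, nested F-tests, dispersion screening and model adjudication."""

import numpy as np
import pytest
from scipy.stats import f as f_dist

from fcskit import (
    FitParams,
    ModelSpec,
    aicc,
    f_test,
    fit_acf,
    screen_dispersion,
    select_model,
    synthesize_acf,
)


class TestAicc:
    def test_zero_when_chi2_equals_n_and_no_params(self):
        assert aicc(100.0, 100, 0) == pytest.approx(0.0)

    def test_arithmetic_oracle(self):
        # 100*ln(0.5) + 2*5 + 2*5*6/94
        expected = 100 * np.log(0.5) + 10 + 60 / 94
        assert aicc(50.0, 100, 5) == pytest.approx(expected)
        assert aicc(50.0, 100, 5) == pytest.approx(-58.676, abs=1e-3)

    def test_penalty_monotone_in_k_at_equal_chi2(self):
        assert aicc(50.0, 100, 7) > aicc(50.0, 100, 5)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            aicc(10.0, 6, 5)


class TestFTest:
    def _fit(self, chi2, n_points, n_free, spec=None):
        from fcskit import FitResult

        spec = spec or ModelSpec(n_components=1)
        params = FitParams(N=1.0, fractions=(1.0,), taus=(1e-3,), S=5.0)
        return FitResult(
            spec=spec, params=params, param_uncertainties={},
            chi2=chi2, n_points=n_points, n_free=n_free,
            dof=n_points - n_free - 1, converged=True,
        )

    def test_identical_chi2_gives_p_one(self):
        simple = self._fit(100.0, 100, 2)
        complex_ = self._fit(100.0, 100, 4, ModelSpec(n_components=2))
        ft = f_test(simple, complex_)
        assert ft.F == 0.0 and ft.p == 1.0

    def test_distribution_oracle(self):
        # chi2 120 vs 100, DF 97 vs 95 -> F = (20/2)/(100/95) = 9.5
        simple = self._fit(120.0, 100, 2)
        complex_ = self._fit(100.0, 100, 4, ModelSpec(n_components=2))
        ft = f_test(simple, complex_)
        assert ft.F == pytest.approx(9.5)
        assert ft.p == pytest.approx(float(f_dist.sf(9.5, 2, 95)))

    def test_complex_fitting_worse_clips_to_zero(self):
        simple = self._fit(90.0, 100, 2)
        complex_ = self._fit(100.0, 100, 4, ModelSpec(n_components=2))
        ft = f_test(simple, complex_)
        assert ft.F == 0.0 and ft.p == 1.0

    def test_non_nested_rejected(self):
        a = self._fit(100.0, 100, 4, ModelSpec(n_components=2))
        b = self._fit(90.0, 100, 4, ModelSpec(n_components=2))
        with pytest.raises(ValueError):
            f_test(a, b)


class TestScreenDispersion:
    def _fits(self, tau3_values):
        spec = ModelSpec(n_components=3)
        out = []
        for t3 in tau3_values:
            params = FitParams(
                N=1.0, fractions=(0.45, 0.41, 0.14),
                taus=(3.4e-4, 3.3e-3, t3), S=5.0,
            )
            from fcskit import FitResult

            out.append(FitResult(
                spec=spec, params=params, param_uncertainties={},
                chi2=1.0, n_points=100, n_free=6, dof=93, converged=True,
            ))
        return out

    def test_identical_replicates_give_zero_cv(self):
        cv = screen_dispersion(self._fits([0.1, 0.1, 0.1]))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in cv.values())

    def test_moderate_spread_is_stable(self):
        # tau3 of 50, 150, 400 ms: sample SD 180.3, mean 200 -> CV 90%
        cv = screen_dispersion(self._fits([0.05, 0.15, 0.4]))
        assert cv["tau3"] == pytest.approx(0.9014, abs=1e-3)
        assert cv["tau3"] < 2.0

    def test_wild_spread_exceeds_200pct(self):
        # one extreme outlier among five replicates drives CV past 200%
        cv = screen_dispersion(self._fits([0.004, 0.004, 0.004, 0.004, 2.4]))
        assert cv["tau3"] > 2.0

    def test_fewer_than_three_replicates_skipped(self):
        assert screen_dispersion(self._fits([0.1, 0.2])) == {}


class TestSelectModel:
    def test_two_component_truth_rejects_third_component(self, lag_grid):
        # a construct with no slow component: adding a third does not
        # improve the fit
        truth = FitParams(
            N=1.0, fractions=(0.769, 0.231), taus=(339.8e-6, 5.99e-3), S=5.0
        )
        specs = [ModelSpec(n_components=m) for m in (1, 2, 3)]
        wins = 0
        for seed in range(5):
            curve = synthesize_acf(truth, lag_grid, noise_sd=0.005, rng_seed=seed)
            report = select_model(curve, specs, starts=4, rng_seed=seed)
            wins += report.selected.n_components == 2
        assert wins >= 4

    def test_one_component_truth_selects_one(self, lag_grid):
        truth = FitParams(N=1.0, fractions=(1.0,), taus=(266.7e-6,), S=5.0)
        specs = [ModelSpec(n_components=m) for m in (1, 2)]
        curve = synthesize_acf(truth, lag_grid, noise_sd=0.005, rng_seed=42)
        report = select_model(curve, specs, starts=4, rng_seed=0)
        assert report.selected.n_components == 1
        # the extra component is either insignificant or unphysical
        assert any("M=2" in r for r in report.rationale)

    def test_selection_deterministic(self, lag_grid, wt_params):
        specs = [ModelSpec(n_components=m) for m in (1, 2, 3)]
        curve = synthesize_acf(wt_params, lag_grid, noise_sd=0.005, rng_seed=8)
        r1 = select_model(curve, specs, starts=4, rng_seed=2)
        r2 = select_model(curve, specs, starts=4, rng_seed=2)
        assert r1.selected == r2.selected
        assert r1.rationale == r2.rationale

    def test_aicc_ranks_true_model_best_on_three_component_truth(
        self, lag_grid, wt_params
    ):
        specs = [ModelSpec(n_components=m) for m in (1, 2, 3)]
        curve = synthesize_acf(wt_params, lag_grid, noise_sd=0.005, rng_seed=3)
        report = select_model(curve, specs, starts=4, rng_seed=0)
        best = min(report.aicc, key=report.aicc.get)
        assert best.n_components == 3
        assert report.selected.n_components == 3
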