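"""Adjudicating the number of diffusion components.

Candidate models (typically one-, two- and three-component free
diffusion) are compared per correlation curve with the sample-size
corrected Akaike criterion

    AICc = N ln(chi^2 / N) + 2K + 2K(K+1)/(N - K - 1)

and the nested F-test

    F = [(chi2_1 - chi2_2)/(DF_1 - DF_2)] / (chi2_2 / DF_2) ,

with DF = N - K - 1, p from the upper tail of F(DF_1-DF_2, DF_2).  A
more complex model is accepted only when the F-test is significant
(p < 0.05) and the AICc agrees; a disagreement falls back to the
simpler model with a warning.  Candidates whose fitted parameters are
unphysical (a component amplitude too low to carry a reliable
diffusion time, or a diffusion time pinned at the fit bounds) are
rejected, and with replicate curves a dispersion screen flags any
candidate whose parameter coefficient of variation across replicates
exceeds 200%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

from .correlate import CorrelationCurve
from .models import FitResult, ModelSpec, TAU_BOUNDS, fit_acf, params_as_dict

logger = logging.getLogger("fcskit")

#: Significance threshold for accepting the more complex nested model.
F_TEST_ALPHA = 0.05

#: Component fraction below which a diffusion time is deemed unreliable.
MIN_COMPONENT_FRACTION = 0.01

#: Relative margin within which a fitted tau counts as "at the bounds".
TAU_BOUND_MARGIN = 1.05

#: Coefficient-of-variation threshold of the replicate dispersion screen.
MAX_PARAMETER_CV = 2.0


def aicc(chi2: float, n_fit: int, k: int) -> float:
    """Corrected Akaike information criterion for a chi^2 fit."""
    if n_fit - k - 1 <= 0:
        raise ValueError("AICc requires n_fit > k + 1")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    with np.errstate(divide="ignore"):
        term = n_fit * np.log(chi2 / n_fit) if chi2 > 0 else -np.inf
    return float(term + 2 * k + 2 * k * (k + 1) / (n_fit - k - 1))


@dataclass
class FTest:
    simple: ModelSpec
    complex: ModelSpec
    F: float
    p: float
    df_num: int
    df_den: int


def f_test(simple: FitResult, complex: FitResult) -> FTest:
    """Nested F-test between a simpler and a more complex fit.

    A complex model fitting worse than the simple one yields F = 0,
    p = 1 (the extra parameters bought nothing).
    """
    if complex.n_free <= simple.n_free:
        raise ValueError("models must be nested: complex needs more parameters")
    if simple.n_points != complex.n_points:
        raise ValueError("fits must share the same data points")
    df1, df2 = simple.dof, complex.dof
    if df1 <= df2 or df2 <= 0:
        raise ValueError("degrees of freedom must satisfy DF1 > DF2 > 0")
    if complex.chi2 <= 0:
        raise ValueError("complex-model chi2 must be positive")
    if simple.chi2 < complex.chi2:
        return FTest(simple.spec, complex.spec, 0.0, 1.0, df1 - df2, df2)
    F = ((simple.chi2 - complex.chi2) / (df1 - df2)) / (complex.chi2 / df2)
    p = float(f_dist.sf(F, df1 - df2, df2))
    return FTest(simple.spec, complex.spec, float(F), p, df1 - df2, df2)


def screen_dispersion(replicate_fits: list[FitResult]) -> dict:
    """Coefficient of variation (SD/mean) per parameter across replicates.

    Requires at least three replicate fits of one model spec; fewer
    yields an empty screen with a warning.  A model is flagged unstable
    when any parameter CV exceeds MAX_PARAMETER_CV (200%).
    """
    if len(replicate_fits) < 3:
        logger.warning("dispersion screen skipped: fewer than 3 replicates")
        return {}
    spec = replicate_fits[0].spec
    if any(fr.spec != spec for fr in replicate_fits):
        raise ValueError("replicate fits must share one model spec")
    tables = [params_as_dict(fr.params) for fr in replicate_fits]
    cv = {}
    for name in tables[0]:
        vals = np.array([t[name] for t in tables])
        mean = vals.mean()
        if abs(mean) < 1e-300:
            continue
        cv[name] = float(vals.std(ddof=1) / abs(mean))
    return cv


def _unphysical_codes(fit: FitResult) -> list[str]:
    codes = []
    for i, (frac, tau) in enumerate(zip(fit.params.fractions, fit.params.taus), 1):
        if frac < MIN_COMPONENT_FRACTION:
            codes.append(f"low_amplitude_component_{i}")
        if tau <= TAU_BOUNDS[0] * TAU_BOUND_MARGIN or tau >= TAU_BOUNDS[1] / TAU_BOUND_MARGIN:
            codes.append(f"tau_{i}_at_bounds")
    if not fit.converged:
        codes.append("not_converged")
    return codes


@dataclass
class ComparisonReport:
    """Outcome of adjudicating candidate component counts."""

    candidates: list[ModelSpec]
    fits: dict  # spec -> list[FitResult], one per replicate curve
    aicc: dict  # spec -> mean AICc across replicates
    f_tests: list[FTest]
    dispersion: dict  # spec -> parameter CV table
    selected: ModelSpec
    rationale: list[str] = field(default_factory=list)


def select_model(
    curves: CorrelationCurve | list[CorrelationCurve],
    candidates: list[ModelSpec],
    starts: int = 8,
    rng_seed: int = 0,
    alpha: float = F_TEST_ALPHA,
) -> ComparisonReport:
    """Fit all candidates to the curve(s) and pick a component count.

    Candidates are ordered by parameter count and compared stepwise; the
    F-test for replicate curves pools chi^2 and degrees of freedom
    across curves.  Rationale codes record every accept/reject decision.
    """
    if isinstance(curves, CorrelationCurve):
        curves = [curves]
    if len(candidates) < 2:
        raise ValueError("need at least two nested candidates")
    order = sorted(candidates, key=lambda s: s.n_free)

    fits: dict[ModelSpec, list[FitResult]] = {}
    for j, spec in enumerate(order):
        fits[spec] = [
            fit_acf(c, spec, starts=starts, rng_seed=rng_seed + 1000 * j + i)
            for i, c in enumerate(curves)
        ]

    aicc_by_spec = {
        spec: float(np.mean([aicc(f.chi2, f.n_points, f.n_free) for f in fs]))
        for spec, fs in fits.items()
    }

    rationale: list[str] = []
    dispersion: dict[ModelSpec, dict] = {}
    eligible: dict[ModelSpec, bool] = {}
    for spec, fs in fits.items():
        tag = f"M={spec.n_components}"
        bad = [c for f in fs for c in _unphysical_codes(f)]
        # with replicates, reject only when over half the curves misbehave
        n_bad = sum(1 for f in fs if _unphysical_codes(f))
        ok = n_bad <= len(fs) // 2
        if not ok:
            rationale.append(f"unphysical:{tag}:" + ",".join(sorted(set(bad))))
        if len(fs) >= 3:
            cv = screen_dispersion(fs)
            dispersion[spec] = cv
            worst = max(cv.values(), default=0.0)
            if worst > MAX_PARAMETER_CV:
                ok = False
                rationale.append(f"unstable:{tag}:max_cv={worst:.2f}")
        eligible[spec] = ok

    f_tests: list[FTest] = []

    def _pooled_ftest(simple_fs, complex_fs) -> FTest:
        chi2_1 = sum(f.chi2 for f in simple_fs)
        chi2_2 = sum(f.chi2 for f in complex_fs)
        df1 = sum(f.dof for f in simple_fs)
        df2 = sum(f.dof for f in complex_fs)
        if chi2_1 < chi2_2:
            return FTest(simple_fs[0].spec, complex_fs[0].spec, 0.0, 1.0, df1 - df2, df2)
        F = ((chi2_1 - chi2_2) / (df1 - df2)) / (chi2_2 / df2)
        return FTest(
            simple_fs[0].spec, complex_fs[0].spec,
            float(F), float(f_dist.sf(F, df1 - df2, df2)), df1 - df2, df2,
        )

    selected = None
    for spec in order:
        if eligible[spec]:
            selected = spec
            break
    if selected is None:
        selected = order[0]
        rationale.append("all_candidates_unstable:fallback_simplest")
    else:
        idx = order.index(selected)
        for nxt in order[idx + 1:]:
            ft = _pooled_ftest(fits[selected], fits[nxt])
            f_tests.append(ft)
            tag = f"M={selected.n_components}->M={nxt.n_components}"
            if not eligible[nxt]:
                rationale.append(f"ftest_not_considered:{tag}:candidate_rejected")
                break
            sig = ft.p < alpha
            aicc_agrees = aicc_by_spec[nxt] < aicc_by_spec[selected]
            if sig and aicc_agrees:
                rationale.append(f"ftest_accept:{tag}:p={ft.p:.3g}")
                selected = nxt
            elif sig and not aicc_agrees:
                logger.warning(
                    "AICc and F-test disagree (%s); keeping the simpler model", tag
                )
                rationale.append(f"aicc_ftest_disagree:{tag}:kept_simple")
                break
            else:
                rationale.append(f"ftest_reject:{tag}:p={ft.p:.3g}")
                break

    return ComparisonReport(
        candidates=order,
        fits=fits,
        aicc=aicc_by_spec,
        f_tests=f_tests,
        dispersion=dispersion,
        selected=selected,
        rationale=rationale,
    )
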