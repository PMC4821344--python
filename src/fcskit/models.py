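"""Multi-component diffusion models for FCS curves and their fitting.

The fluctuation autocorrelation of M species diffusing through a 3D
Gaussian detection volume (lateral 1/e^2 radius omega, axial radius
S*omega) is

    G(tau) = 1 + (1/N) * sum_i F_i
             * [1 + (tau/tau_i)^a_i]^-1
             * [1 + (1/S^2)(tau/tau_i)^a_i]^-1/2 ,

with mean occupancy N, component fractions F_i (sum 1), diffusion times
tau_i, and per-component anomaly exponents a_i (a = 1 free Brownian
diffusion, a < 1 obstructed).  An optional triplet-blinking factor
[1 + T/(1-T) * exp(-tau/tau_T)] multiplies the fluctuating part; it is
off by default because the fit range starts well above the triplet
relaxation time.

Fitting minimizes the per-lag-weighted chi^2 over a restricted lag
window (default 50 us to 3.4 s) with multi-start local optimization;
fractions live on a stick-breaking simplex so they sum to one exactly,
and components are relabeled in ascending tau order afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .correlate import CorrelationCurve

logger = logging.getLogger("fcskit")

#: Hard bounds on diffusion times (s) and anomaly exponents for fitting.
TAU_BOUNDS = (1e-6, 10.0)
ALPHA_BOUNDS = (0.1, 1.0)
N_BOUNDS = (1e-4, 1e6)

#: Default fit window (s): below ~50 us early-lag scatter and triplet
#: relaxation dominate; above 3.4 s segment statistics run out.
DEFAULT_FIT_RANGE = (50e-6, 3.4)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one candidate ACF model.

    ``alpha_mode`` is either a shorthand applying to all components
    ("free" pins every exponent at 1, "anomalous" fits every exponent)
    or a per-component tuple whose entries are a fixed float or the
    string "fit".  ``structure_parameter`` is a fixed value or "fit"
    (free-S fits are ill-conditioned with three components, so fixed is
    the default).
    """

    n_components: int
    alpha_mode: str | tuple = "free"
    triplet: bool = False
    structure_parameter: float | str = 5.0
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE

    def __post_init__(self):
        if not 1 <= self.n_components <= 3:
            raise ValueError("n_components must be 1..3")
        if self.fit_range[0] >= self.fit_range[1]:
            raise ValueError("fit_range must satisfy tau_min < tau_max")
        if isinstance(self.structure_parameter, str):
            if self.structure_parameter != "fit":
                raise ValueError("structure_parameter must be a value or 'fit'")
        elif not self.structure_parameter > 0:
            raise ValueError("fixed structure_parameter must be positive")
        _ = self.alpha_entries()  # validate

    def alpha_entries(self) -> tuple:
        """Per-component alpha treatment as ('fixed', value) or ('fit',)."""
        if self.alpha_mode == "free":
            return tuple(("fixed", 1.0) for _ in range(self.n_components))
        if self.alpha_mode == "anomalous":
            return tuple(("fit",) for _ in range(self.n_components))
        if isinstance(self.alpha_mode, tuple):
            if len(self.alpha_mode) != self.n_components:
                raise ValueError("alpha_mode tuple length must equal n_components")
            out = []
            for a in self.alpha_mode:
                if a == "fit":
                    out.append(("fit",))
                else:
                    a = float(a)
                    if not 0 < a <= 1:
                        raise ValueError("fixed alpha must be in (0, 1]")
                    out.append(("fixed", a))
            return tuple(out)
        raise ValueError(f"unrecognized alpha_mode: {self.alpha_mode!r}")

    @property
    def n_free(self) -> int:
        """Number of free parameters K."""
        m = self.n_components
        k = 1 + (m - 1) + m  # N, fractions simplex, taus
        k += sum(1 for a in self.alpha_entries() if a[0] == "fit")
        if self.structure_parameter == "fit":
            k += 1
        if self.triplet:
            k += 2
        return k


@dataclass
class FitParams:
    """Parameter set of the M-component diffusion model."""

    N: float
    fractions: tuple
    taus: tuple
    alphas: tuple | None = None
    S: float = 5.0
    triplet_fraction: float = 0.0
    triplet_time: float = 1e-6

    def __post_init__(self):
        self.fractions = tuple(float(f) for f in self.fractions)
        self.taus = tuple(float(t) for t in self.taus)
        if self.alphas is None:
            self.alphas = tuple(1.0 for _ in self.taus)
        else:
            self.alphas = tuple(float(a) for a in self.alphas)
        if len(self.fractions) != len(self.taus) or len(self.alphas) != len(self.taus):
            raise ValueError("fractions, taus and alphas must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if any(t <= 0 for t in self.taus) or np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be positive and strictly ascending")
        if any(not 0 < a <= 1 for a in self.alphas):
            raise ValueError("alphas must be in (0, 1]")
        if not (self.N > 0 and self.S > 0):
            raise ValueError("N and S must be positive")
        if not 0 <= self.triplet_fraction < 1:
            raise ValueError("triplet_fraction must be in [0, 1)")
        if self.triplet_time <= 0:
            raise ValueError("triplet_time must be positive")

    @property
    def n_components(self) -> int:
        return len(self.taus)


@dataclass
class FitResult:
    """A fitted model: parameters, uncertainties, chi^2 bookkeeping.

    ``dof`` = n_points - n_free - 1, the degrees of freedom entering the
    AICc and F-test comparisons.
    """

    spec: ModelSpec
    params: FitParams
    param_uncertainties: dict
    chi2: float
    n_points: int
    n_free: int
    dof: int
    converged: bool


def model_curve(params: FitParams, lags, triplet: bool = False) -> np.ndarray:
    """Evaluate the M-component 3D-Gaussian diffusion ACF at ``lags``."""
    tau = np.asarray(lags, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lags must be strictly positive")
    s2 = params.S**2
    acc = np.zeros_like(tau)
    for f, td, a in zip(params.fractions, params.taus, params.alphas):
        x = (tau / td) ** a
        acc += f / (1.0 + x) / np.sqrt(1.0 + x / s2)
    fluct = acc / params.N
    if triplet and params.triplet_fraction > 0:
        T = params.triplet_fraction
        fluct = fluct * (1.0 + T / (1.0 - T) * np.exp(-tau / params.triplet_time))
    return 1.0 + fluct


def eval_model(params: FitParams, spec: ModelSpec, lags) -> np.ndarray:
    """Evaluate ``params`` under the triplet setting of ``spec``."""
    if params.n_components != spec.n_components:
        raise ValueError("params and spec disagree on the number of components")
    return model_curve(params, lags, triplet=spec.triplet)


def fit_range_mask(curve: CorrelationCurve, fit_range) -> np.ndarray:
    lo, hi = fit_range
    return (curve.lags >= lo) & (curve.lags <= hi)


def chi_square(curve: CorrelationCurve, model_values, mask=None) -> float:
    """Weighted chi^2: sum over masked lags of ((model - G)/sigma)^2."""
    model_values = np.asarray(model_values, dtype=float)
    if mask is None:
        mask = np.ones(curve.lags.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty fit mask")
    r = (model_values[mask] - curve.G[mask]) / curve.sigma[mask]
    return float(np.dot(r, r))


# --- parameter packing -------------------------------------------------
#
# theta = [ln N, g_1..g_{M-1}, ln tau_1..ln tau_M,
#          fitted alphas..., ln S (if fitted), T, ln tau_T (if triplet)]
#
# Fractions use stick-breaking: F_1 = g_1, F_2 = (1-g_1) g_2, remainder
# to the last component, so sum F = 1 holds exactly for any g in (0,1).
# Taus are unordered during optimization; components are sorted by tau
# when unpacking (label-switching broken by ordering).


def _pack_structure(spec: ModelSpec):
    m = spec.n_components
    names = ["lnN"] + [f"g{i}" for i in range(1, m)] + [f"lntau{i}" for i in range(1, m + 1)]
    lo = [np.log(N_BOUNDS[0])] + [1e-9] * (m - 1) + [np.log(TAU_BOUNDS[0])] * m
    hi = [np.log(N_BOUNDS[1])] + [1 - 1e-9] * (m - 1) + [np.log(TAU_BOUNDS[1])] * m
    for i, a in enumerate(spec.alpha_entries(), start=1):
        if a[0] == "fit":
            names.append(f"alpha{i}")
            lo.append(ALPHA_BOUNDS[0])
            hi.append(ALPHA_BOUNDS[1])
    if spec.structure_parameter == "fit":
        names.append("lnS")
        lo.append(np.log(0.5))
        hi.append(np.log(100.0))
    if spec.triplet:
        names += ["T", "lntauT"]
        lo += [0.0, np.log(1e-8)]
        hi += [0.999, np.log(1e-3)]
    return names, np.array(lo), np.array(hi)


def _sticks_to_fractions(g: np.ndarray, m: int) -> np.ndarray:
    f = np.empty(m)
    rem = 1.0
    for i in range(m - 1):
        f[i] = rem * g[i]
        rem -= f[i]
    f[m - 1] = rem
    return f


def _fractions_to_sticks(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    g = np.empty(f.size - 1)
    rem = 1.0
    for i in range(f.size - 1):
        g[i] = np.clip(f[i] / rem if rem > 0 else 0.5, 1e-9, 1 - 1e-9)
        rem -= f[i]
    return g


def _unpack(theta: np.ndarray, spec: ModelSpec) -> FitParams:
    m = spec.n_components
    i = 0
    N = float(np.exp(theta[i])); i += 1
    g = theta[i:i + m - 1]; i += m - 1
    fr = _sticks_to_fractions(g, m)
    taus = np.exp(theta[i:i + m]); i += m
    alphas = []
    for a in spec.alpha_entries():
        if a[0] == "fit":
            alphas.append(float(theta[i])); i += 1
        else:
            alphas.append(a[1])
    alphas = np.array(alphas)
    if spec.structure_parameter == "fit":
        S = float(np.exp(theta[i])); i += 1
    else:
        S = float(spec.structure_parameter)
    T, tauT = 0.0, 1e-6
    if spec.triplet:
        T = float(theta[i]); i += 1
        tauT = float(np.exp(theta[i])); i += 1
    order = np.argsort(taus)
    taus = taus[order]
    # guard against exactly degenerate taus after sorting
    for j in range(1, m):
        if taus[j] <= taus[j - 1]:
            taus[j] = taus[j - 1] * (1 + 1e-12)
    return FitParams(
        N=N,
        fractions=tuple(fr[order]),
        taus=tuple(taus),
        alphas=tuple(alphas[order]),
        S=S,
        triplet_fraction=T,
        triplet_time=tauT,
    )


def _pack(params: FitParams, spec: ModelSpec) -> np.ndarray:
    theta = [np.log(params.N)]
    theta.extend(_fractions_to_sticks(params.fractions))
    theta.extend(np.log(params.taus))
    for i, a in enumerate(spec.alpha_entries()):
        if a[0] == "fit":
            theta.append(params.alphas[i])
    if spec.structure_parameter == "fit":
        theta.append(np.log(params.S))
    if spec.triplet:
        theta.extend([params.triplet_fraction, np.log(params.triplet_time)])
    return np.array(theta, dtype=float)


def _heuristic_start(curve, spec, mask) -> FitParams:
    lags = curve.lags[mask]
    amp = max(curve.G[mask][0] - 1.0, 1e-4)
    m = spec.n_components
    lo = max(lags[0] * 2, TAU_BOUNDS[0] * 10)
    hi = min(lags[-1] / 2, TAU_BOUNDS[1] / 10)
    taus = np.geomspace(lo, hi, m) if m > 1 else np.array([np.sqrt(lo * hi)])
    alphas = [a[1] if a[0] == "fixed" else 0.9 for a in spec.alpha_entries()]
    S = 5.0 if spec.structure_parameter == "fit" else float(spec.structure_parameter)
    return FitParams(
        N=float(np.clip(1.0 / amp, *N_BOUNDS)),
        fractions=tuple([1.0 / m] * m),
        taus=tuple(taus),
        alphas=tuple(alphas),
        S=S,
        triplet_fraction=0.1 if spec.triplet else 0.0,
        triplet_time=5e-6,
    )


def fit_acf(
    curve: CorrelationCurve,
    spec: ModelSpec,
    starts: int = 8,
    rng_seed: int = 0,
    init: FitParams | None = None,
) -> FitResult:
    """Weighted least-squares fit of the diffusion model to one curve.

    Runs ``starts`` seeded initializations (the first from ``init`` when
    given, otherwise from an amplitude/lag heuristic; the rest are
    log-normal perturbations of it) and keeps the lowest chi^2.
    Deterministic for a fixed ``rng_seed``.
    """
    mask = fit_range_mask(curve, spec.fit_range)
    n_fit = int(mask.sum())
    K = spec.n_free
    if n_fit <= K + 2:
        raise ValueError(
            f"only {n_fit} points in the fit range for {K} free parameters"
        )
    if curve.G[mask][0] - 1.0 <= 0:
        raise ValueError("degenerate curve: non-positive amplitude in fit range")
    lags = curve.lags[mask]
    g_data = curve.G[mask]
    sig = curve.sigma[mask]
    if np.allclose(curve.sigma, curve.sigma[0]) and curve.n_segments == 1:
        logger.warning(
            "no cross-segment sigma available: unit weights; chi^2 has no "
            "absolute meaning but model comparison remains valid"
        )

    names, lo, hi = _pack_structure(spec)

    def residual(theta):
        p = _unpack(theta, spec)
        return (model_curve(p, lags, triplet=spec.triplet) - g_data) / sig

    base = init if init is not None else _heuristic_start(curve, spec, mask)
    theta0 = np.clip(_pack(base, spec), lo + 1e-12, hi - 1e-12)
    rng = np.random.default_rng(rng_seed)

    best = None
    for s in range(max(1, starts)):
        if s == 0:
            t0 = theta0
        else:
            t0 = theta0 + rng.normal(0.0, 0.5, size=theta0.size)
            t0 = np.clip(t0, lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                residual, t0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        params = base
        return FitResult(
            spec=spec, params=params, param_uncertainties={},
            chi2=chi_square(curve, eval_model(params, spec, curve.lags), mask),
            n_points=n_fit, n_free=K, dof=n_fit - K - 1, converged=False,
        )

    params = _unpack(best.x, spec)
    chi2 = float(2.0 * best.cost)
    dof = n_fit - K - 1
    uncertainties = _uncertainties(best, spec, chi2, dof)
    converged = bool(best.status > 0 and np.all(np.isfinite(best.x)))
    return FitResult(
        spec=spec, params=params, param_uncertainties=uncertainties,
        chi2=chi2, n_points=n_fit, n_free=K, dof=dof, converged=converged,
    )


def _natural_vector(params: FitParams) -> np.ndarray:
    return np.array(
        [params.N, *params.fractions, *params.taus, *params.alphas,
         params.S, params.triplet_fraction, params.triplet_time]
    )


def natural_names(m: int) -> list[str]:
    return (
        ["N"]
        + [f"F{i}" for i in range(1, m + 1)]
        + [f"tau{i}" for i in range(1, m + 1)]
        + [f"alpha{i}" for i in range(1, m + 1)]
        + ["S", "T", "tauT"]
    )


def _uncertainties(res, spec: ModelSpec, chi2: float, dof: int) -> dict:
    """1-sigma uncertainties of the natural parameters by the delta method."""
    m = spec.n_components
    names = natural_names(m)
    try:
        J = res.jac
        cov_theta = np.linalg.pinv(J.T @ J) * (chi2 / max(dof, 1))
        # numeric Jacobian of natural params wrt theta
        eps = 1e-6
        base = _natural_vector(_unpack(res.x, spec))
        Gm = np.zeros((base.size, res.x.size))
        for j in range(res.x.size):
            dx = np.zeros_like(res.x)
            dx[j] = eps
            Gm[:, j] = (_natural_vector(_unpack(res.x + dx, spec)) - base) / eps
        cov_nat = Gm @ cov_theta @ Gm.T
        sd = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
        return dict(zip(names, sd))
    except Exception:  # pragma: no cover - singular fits
        return {n: float("nan") for n in names}


def params_as_dict(params: FitParams) -> dict:
    """Flat name -> value mapping matching ``natural_names``."""
    return dict(zip(natural_names(params.n_components), _natural_vector(params)))
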