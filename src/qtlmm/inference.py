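"""Hypothesis tests and intervals for variance components and beyond.

Nested models are compared by likelihood ratio: the statistic is the drop in
-2 log-likelihood, clipped at zero. When the null pins a parameter at its
boundary (a variance at 0, a correlation at 1) the asymptotic null law is
the half-half mixture chi2_{df-1} : chi2_df rather than chi2_df. For a
variance component the mixture is itself only an approximation, so an exact
finite-sample test is provided by parametric simulation of the restricted
likelihood ratio statistic: fit the null, simulate new responses from it,
refit both models, and compare the observed statistic with the simulated
ones. Confidence intervals come from profiling the deviance: an endpoint is
where the profiled -2ll has risen by the chi-square quantile above its
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .covstruct import RandomTerm, residual_covariance, term_covariance
from .errors import SpecError
from .fitting import _ParamMap, fit, heritability
from .likelihood import GaussianLMM, SpectralLMM, complete_cases, \
    spectral_eligible
from .model import FitResult, ModelSpec, OptimizerConfig, parameter_list

EPS_STAT = 1e-10


@dataclass
class TestResult:
    statistic: float
    df: object           # int, or "mixture(d-1,d)" tag, or None for rlrt_sim
    p_value: float
    method: str          # "lrt_chisq" | "lrt_mixture" | "rlrt_sim"
    note: str | None = None

    def to_dict(self) -> dict:
        return {"statistic": float(self.statistic), "df": self.df,
                "p_value": float(self.p_value), "method": self.method,
                "note": self.note}

    def __str__(self):
        return (f"{self.method}: stat={self.statistic:.4f} df={self.df} "
                f"p={self.p_value:.4g}")


def _chisq_sf(stat: float, df: int) -> float:
    if df == 0:
        return 1.0 if stat <= EPS_STAT else 0.0
    return float(scipy.stats.chi2.sf(stat, df))


def mixture_sf(stat: float, df: int) -> float:
    """Survival of the half-half chi2_{df-1}:chi2_df boundary mixture."""
    return 0.5 * _chisq_sf(stat, df - 1) + 0.5 * _chisq_sf(stat, df)


def lrt(fit_null: FitResult, fit_alt: FitResult,
        null_on_boundary: bool = False) -> TestResult:
    """Likelihood ratio test of a null model nested in an alternative.

    Both fits must use the same criterion and data (n). With
    ``null_on_boundary`` the p-value uses the boundary mixture.
    """
    if fit_null.criterion != fit_alt.criterion:
        raise SpecError(f"criterion mismatch: {fit_null.criterion} vs "
                        f"{fit_alt.criterion}")
    if fit_null.n_obs != fit_alt.n_obs:
        raise SpecError(f"models fitted to different data: n={fit_null.n_obs}"
                        f" vs {fit_alt.n_obs}")
    df = fit_alt.n_params - fit_null.n_params
    if df < 0:
        raise SpecError("null model has more free parameters than the "
                        "alternative; models are not nested")
    stat = max(0.0, fit_null.deviance - fit_alt.deviance)
    if null_on_boundary:
        p = mixture_sf(stat, df) if stat > EPS_STAT else 1.0
        return TestResult(stat, f"mixture({df - 1},{df})", p, "lrt_mixture")
    p = _chisq_sf(stat, df) if df > 0 else 1.0
    return TestResult(stat, df, p, "lrt_chisq")


# ---------------------------------------------------------------------------
# simulated restricted likelihood ratio test

def _drop_term(spec: ModelSpec, term_index: int) -> ModelSpec:
    terms = [t for i, t in enumerate(spec.random_terms) if i != term_index]
    return ModelSpec(response=spec.response, fixed=list(spec.fixed),
                     random_terms=terms, residual=spec.residual,
                     constraints=spec.constraints)


def rlrt_sim(spec: ModelSpec, term_index: int, data: pd.DataFrame,
             n_sim: int = 200, seed: int = 0,
             optimizer: OptimizerConfig | None = None) -> TestResult:
    """Parametric-simulation test that one variance component is zero.

    Fits (REML) the full model and the model without term ``term_index``,
    simulates ``n_sim`` responses from the fitted null, refits both models on
    each, and returns p = (1 + #{sim >= obs}) / (1 + n_sim). Reproducible
    under ``seed``.
    """
    if not 0 <= term_index < len(spec.random_terms):
        raise SpecError(f"term_index {term_index} out of range")
    note = "n_sim < 100: p-value resolution is coarse" if n_sim < 100 else None
    rng = np.random.default_rng(seed)
    null_spec = _drop_term(spec, term_index)

    if spectral_eligible(spec) and not null_spec.random_terms:
        return _rlrt_sim_spectral(spec, data, n_sim, rng, note)

    alt_fit = fit(spec, data, criterion="REML", optimizer=optimizer)
    null_fit = fit(null_spec, data, criterion="REML", optimizer=optimizer)
    obs = max(0.0, null_fit.deviance - alt_fit.deviance)

    data_cc, _ = complete_cases(spec, data)
    eng = GaussianLMM(spec, data_cc, drop_missing=False)
    mu = eng.X @ null_fit.beta.to_numpy()
    draws = _null_draw_factory(null_spec, null_fit, data_cc)
    count = 0
    for _ in range(n_sim):
        sim = data_cc.copy()
        sim[spec.response] = mu + draws(rng)
        a = fit(spec, sim, criterion="REML", optimizer=optimizer)
        b = fit(null_spec, sim, criterion="REML", optimizer=optimizer)
        if max(0.0, b.deviance - a.deviance) >= obs - EPS_STAT:
            count += 1
    p = (1.0 + count) / (1.0 + n_sim)
    return TestResult(obs, None, p, "rlrt_sim", note)


def _null_draw_factory(null_spec, null_fit, data_cc):
    """Sampler of the random part (terms + residual) of the fitted null."""
    factors = []
    for term in null_spec.random_terms:
        t = RandomTerm(grouping=term.grouping, relmat=term.relmat,
                       slopes_factor=term.slopes_factor,
                       params=null_fit.params[term.label], name=term.name)
        V = term_covariance(t, data_cc)
        w, Q = np.linalg.eigh(V)
        keep = w > 1e-10 * max(1.0, w[-1])
        factors.append(Q[:, keep] * np.sqrt(w[keep]))
    res_sd = np.sqrt(np.diag(residual_covariance(null_fit.residual, data_cc)))
    n = len(data_cc)

    def draw(rng):
        out = res_sd * rng.standard_normal(n)
        for L in factors:
            out += L @ rng.standard_normal(L.shape[1])
        return out
    return draw


def _rlrt_sim_spectral(spec, data, n_sim, rng, note) -> TestResult:
    """Fast path: alt has a single structured term, null is fixed-effects
    only; all refits run on the once-rotated data."""
    eng = SpectralLMM(spec, data)
    g_hat, dev_alt, _, _ = eng.fit1d("REML")
    dev_null, s_null, beta_null = eng.dev(0.0, "REML")
    obs = max(0.0, dev_null - dev_alt)
    mu = eng.Xt @ beta_null
    sd = np.sqrt(s_null)
    count = 0
    for _ in range(n_sim):
        yt = mu + sd * rng.standard_normal(eng.n)
        _, da, _, _ = eng.fit1d("REML", yt=yt)
        d0, _, _ = eng.dev(0.0, "REML", yt=yt)
        if max(0.0, d0 - da) >= obs - EPS_STAT:
            count += 1
    p = (1.0 + count) / (1.0 + n_sim)
    return TestResult(obs, None, p, "rlrt_sim", note)


# ---------------------------------------------------------------------------
# profile-deviance confidence intervals

@dataclass
class ProfileCI:
    target: str
    estimate: float
    lower: float
    upper: float
    level: float
    lower_at_bound: bool = False
    upper_at_bound: bool = False

    def to_dict(self) -> dict:
        return {"target": self.target, "estimate": float(self.estimate),
                "lower": float(self.lower), "upper": float(self.upper),
                "level": float(self.level),
                "lower_at_bound": self.lower_at_bound,
                "upper_at_bound": self.upper_at_bound}


def _h2_profile_function(spec: ModelSpec, data: pd.DataFrame,
                         res: FitResult, cfg: OptimizerConfig):
    """Profiled deviance as a function of heritability.

    The genetic variance is pinned by h2 through
    sg^2 = h2/(1-h2) * (other term variances + residual), the overall scale
    is profiled in closed form, and any remaining free ratios are
    re-optimised at each h2 (warm started along the profile).
    """
    criterion = res.criterion
    if spectral_eligible(spec):
        eng = SpectralLMM(spec, data)

        def profile(h2):
            return eng.dev(h2 / (1.0 - h2), criterion)[0]
        return profile

    data_cc, _ = complete_cases(spec, data)
    eng = GaussianLMM(spec, data_cc, drop_missing=False)
    pmap = _ParamMap(eng.params, spec.constraints)
    if pmap.sd_fixed_nonzero():
        raise SpecError("h2 profiling requires freely scaling sds")
    g_path = f"{spec.random_terms[0].label}.sd"
    if g_path not in pmap.group_of:
        raise SpecError("h2 profiling needs an intercept genetic term "
                        "(the first random term)")
    g_group = pmap.group_of[g_path]
    res_groups = [g for g in pmap.free_groups
                  if pmap.kind[g] == "sd" and g.startswith("residual.")]
    if not res_groups:
        raise SpecError("h2 profiling requires a free residual sd")
    ref = res_groups[0]
    inner = [(g, k) for g, k in zip(pmap.free_groups, pmap.free_kinds)
             if g not in (g_group, ref)]
    # warm start from the fitted ratios relative to the residual sd
    ref_sd = None
    for p in eng.params:
        if pmap.group_of[p.path] == ref:
            ref_sd = res.param_values[p.path]
            break
    start = []
    for g, k in inner:
        v = None
        for p in eng.params:
            if pmap.group_of[p.path] == g:
                v = res.param_values[p.path]
                break
        start.append(v / ref_sd if (k == "sd" and ref_sd) else
                     (np.arctanh(np.clip(v, -0.999999, 0.999999))
                      if k == "cor" else 1.0))
    warm = {"x": np.array(start, dtype=float)}
    bounds = [(0.0, cfg.ratio_bound) if k == "sd"
              else (-cfg.cor_z_bound, cfg.cor_z_bound) for _, k in inner]

    def theta_at(h2, x):
        free = {}
        other_var = 1.0  # the pinned residual ratio
        for (g, k), v in zip(inner, x):
            val = np.tanh(v) if k == "cor" else float(v)
            free[g] = val
            if k == "sd":
                other_var += val ** 2
        free[ref] = 1.0
        free[g_group] = float(np.sqrt(h2 / (1.0 - h2) * other_var))
        return pmap.full_theta(np.array([free[g] for g in pmap.free_groups]))

    def profile(h2):
        if not inner:
            return eng.neg2_profiled(theta_at(h2, np.empty(0)), criterion)[0]

        def obj(x):
            try:
                return eng.neg2_profiled(theta_at(h2, x), criterion)[0]
            except Exception:
                return 1e12

        if len(inner) == 1:
            lo, hi = bounds[0]
            r = scipy.optimize.minimize_scalar(
                lambda v: obj(np.array([v])), bounds=(lo, hi),
                method="bounded", options={"xatol": 1e-7})
            v_edge = obj(np.array([lo]))
            if v_edge < r.fun:
                warm["x"] = np.array([lo])
                return float(v_edge)
            warm["x"] = np.array([float(r.x)])
            return float(r.fun)
        r = scipy.optimize.minimize(
            obj, warm["x"], method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxfun": cfg.maxfev})
        warm["x"] = np.asarray(r.x)
        return float(r.fun)
    return profile


def profile_ci(spec: ModelSpec, data: pd.DataFrame, res: FitResult,
               target: str = "h2", level: float = 0.95,
               optimizer: OptimizerConfig | None = None) -> ProfileCI:
    """Profile-deviance confidence interval for h2 or one sd parameter.

    Endpoints solve profile(-2ll) = min + chi2_1 quantile of ``level`` by
    monotone root bracketing; an endpoint that runs into the parameter bound
    is returned at the bound and flagged.
    """
    cfg = optimizer or OptimizerConfig()
    if not res.converged:
        raise SpecError("profile_ci requires a converged fit")
    quant = float(scipy.stats.chi2.ppf(level, 1))

    if target == "h2":
        est = heritability(res)
        prof = _h2_profile_function(spec, data, res, cfg)
        lo_lim, hi_lim = 1e-8, 1.0 - 1e-8
    else:
        est = res.param_values[target]
        prof = _sd_profile_function(spec, data, res, target, cfg)
        lo_lim, hi_lim = 0.0, None

    est_in = min(max(est, lo_lim if target == "h2" else 0.0),
                 hi_lim if hi_lim else np.inf)
    dev_min = min(res.deviance, prof(est_in))
    thr = dev_min + quant

    def f(x):
        return prof(x) - thr

    # lower endpoint
    lower_at_bound = False
    lo_edge = lo_lim if target == "h2" else 0.0
    if est_in - lo_edge < 1e-8 or f(lo_edge if target != "h2" else lo_lim) < 0:
        lower = 0.0
        lower_at_bound = True
    else:
        lower = float(scipy.optimize.brentq(
            f, lo_lim if target == "h2" else 0.0, est_in, xtol=1e-4))

    # upper endpoint
    upper_at_bound = False
    if target == "h2":
        if hi_lim - est_in < 1e-8 or f(hi_lim) < 0:
            upper, upper_at_bound = 1.0, True
        else:
            upper = float(scipy.optimize.brentq(f, est_in, hi_lim, xtol=1e-4))
    else:
        hi = max(2.0 * est_in, est_in + 1.0)
        for _ in range(40):
            if f(hi) > 0:
                break
            hi *= 2.0
        else:
            raise SpecError("profile upper endpoint not bracketed")
        upper = float(scipy.optimize.brentq(f, est_in, hi, xtol=1e-4))

    return ProfileCI(target=target, estimate=est, lower=lower, upper=upper,
                     level=level, lower_at_bound=lower_at_bound,
                     upper_at_bound=upper_at_bound)


def _sd_profile_function(spec, data, res, path, cfg):
    from .model import ConstraintSet

    criterion = res.criterion

    def profile(v):
        cs = ConstraintSet(
            fixes=list(spec.constraints.fixes) + [(path, float(v))],
            equalities=list(spec.constraints.equalities))
        s2 = ModelSpec(response=spec.response, fixed=list(spec.fixed),
                       random_terms=spec.random_terms, residual=spec.residual,
                       constraints=cs)
        return fit(s2, data, criterion=criterion,
                   optimizer=cfg).deviance
    return profile


# ---------------------------------------------------------------------------
# gene-environment interaction test pair

def gxe_test_pair(m_free: FitResult, m_rho1: FitResult, m_eqvar: FitResult
                  ) -> tuple[TestResult, TestResult]:
    """LRTs of the two no-interaction nulls against the free model.

    The rho_g = 1 null sits on the correlation boundary, so its p-value uses
    the half-half mixture; the equal-variance null is interior and uses
    chi2_1.
    """
    t_rho = lrt(m_rho1, m_free, null_on_boundary=True)
    t_eq = lrt(m_eqvar, m_free, null_on_boundary=False)
    return t_rho, t_eq
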