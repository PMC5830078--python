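"""REML/ML estimation of variance components under constraints.

The optimiser works on standard deviations (never variances: the surface is
better behaved near zero) and on atanh-mapped correlations. Whenever no sd is
fixed to a nonzero constant, an overall variance scale is profiled out in
closed form and one residual sd is pinned to 1, so e.g. the classical
polygenic model reduces to a one-dimensional search over the genetic-to-
residual ratio. Equality constraints are imposed exactly by aliasing the
tied parameters to a single free symbol; fixed parameters are removed from
the search. The single-structured-term homoscedastic model dispatches to the
spectral engine, everything else to the generic one.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.optimize

from .covstruct import ParamBlock, ResidualSpec, slopes_levels
from .errors import DegenerateDataError, QtlmmError, SpecError
from .likelihood import (GaussianLMM, SpectralLMM, build_design,
                         complete_cases, spectral_eligible)
from .model import (ConstraintSet, FitResult, ModelSpec, OptimizerConfig,
                    parameter_list)

logger = logging.getLogger("qtlmm")

# large finite deviance for degenerate parameter points (a singular
# covariance has likelihood zero); finite so that finite-difference
# gradients and simplex moves stay defined
_PENALTY = 1e12


# ---------------------------------------------------------------------------
# constraint resolution

class _ParamMap:
    """Mapping between the free optimiser vector and the canonical theta."""

    def __init__(self, params, constraints: ConstraintSet):
        self.params = params
        paths = [p.path for p in params]
        idx = {p: i for i, p in enumerate(paths)}
        kind = {p.path: p.kind for p in params}

        def resolve(path):
            if path not in idx:
                raise SpecError(f"constraint refers to unknown parameter "
                                f"{path!r}; known: {paths}")
            return path

        # union-find over equality groups
        parent = {p: p for p in paths}

        def root(p):
            while parent[p] != p:
                parent[p] = parent[parent[p]]
                p = parent[p]
            return p

        for a, b in constraints.equalities:
            a, b = resolve(a), resolve(b)
            if kind[a] != kind[b]:
                raise SpecError(f"cannot equate parameters of different kinds:"
                                f" {a!r}, {b!r}")
            parent[root(a)] = root(b)

        fixed: dict[str, float] = {}
        for path, value in constraints.fixes:
            path = resolve(path)
            if kind[path] == "sd" and value < 0:
                raise SpecError(f"fixed sd {path!r} must be >= 0")
            if kind[path] == "cor" and abs(value) > 1:
                raise SpecError(f"fixed correlation {path!r} must be in [-1,1]")
            r = root(path)
            if r in fixed and fixed[r] != value:
                raise SpecError(f"conflicting fixed values for {path!r}")
            fixed[r] = value

        groups: dict[str, list[str]] = {}
        for p in paths:
            groups.setdefault(root(p), []).append(p)
        self.group_of = {p: root(p) for p in paths}
        self.fixed = fixed            # group root -> value
        self.free_groups = [g for g in groups if g not in fixed]
        self.free_kinds = [kind[g] for g in self.free_groups]
        self.groups = groups
        self._idx = idx
        self.kind = kind

    @property
    def n_free(self) -> int:
        return len(self.free_groups)

    def full_theta(self, free_values: np.ndarray) -> np.ndarray:
        val = {g: v for g, v in zip(self.free_groups, free_values)}
        val.update(self.fixed)
        theta = np.empty(len(self.params))
        for p in self.params:
            theta[self._idx[p.path]] = val[self.group_of[p.path]]
        return theta

    def sd_fixed_nonzero(self) -> bool:
        return any(self.kind[g] == "sd" and v != 0.0
                   for g, v in self.fixed.items())


# ---------------------------------------------------------------------------
# fit

def fit(spec: ModelSpec, data: pd.DataFrame, criterion: str = "REML",
        optimizer: OptimizerConfig | None = None) -> FitResult:
    """Fit the mixed model by REML (default) or ML.

    Rows with missing values in any used column are dropped (counted in the
    result). Variance parameters honour the spec's ConstraintSet. A constant
    response yields the degenerate boundary fit (all variances zero).
    """
    cfg = optimizer or OptimizerConfig()
    if criterion not in ("ML", "REML"):
        raise ValueError(f"criterion must be 'ML' or 'REML', got {criterion!r}")

    data_cc, n_dropped = complete_cases(spec, data)
    y = np.asarray(data_cc[spec.response], dtype=float)
    if len(y) and float(np.var(y)) == 0.0:
        return _degenerate_fit(spec, data_cc, n_dropped, criterion)

    use_spectral = (cfg.method != "generic" and spectral_eligible(spec))
    if cfg.method == "spectral" and not spectral_eligible(spec):
        raise SpecError("spectral path requires a single intercept term with "
                        "homoscedastic residual and no constraints")
    if use_spectral:
        return _fit_spectral(spec, data_cc, n_dropped, criterion, cfg)
    return _fit_generic(spec, data_cc, n_dropped, criterion, cfg)


def _degenerate_fit(spec, data_cc, n_dropped, criterion) -> FitResult:
    params = parameter_list(spec, data_cc)
    c = float(data_cc[spec.response].iloc[0]) if len(data_cc) else 0.0
    _, X, x_names = build_design(spec, data_cc)
    beta = pd.Series(np.zeros(X.shape[1]), index=x_names)
    beta.iloc[0] = c
    values = {p.path: 0.0 for p in params}
    term_params, residual = _structured_estimates(spec, data_cc, values)
    return FitResult(
        beta=beta, params=term_params, residual=residual, param_values=values,
        deviance=float("-inf"), criterion=criterion, converged=True,
        n_obs=len(data_cc), n_dropped=n_dropped,
        n_params=X.shape[1] + len(params),
        boundary_flags={p.path: True for p in params},
        method="degenerate", constraints=spec.constraints, spec=spec)


def _structured_estimates(spec, data_cc, values: dict):
    """Fold a path->value dict back into ParamBlocks and a ResidualSpec."""
    term_params = {}
    for term in spec.random_terms:
        lab = term.label
        if term.slopes_factor is None:
            term_params[lab] = ParamBlock(sds=[values[f"{lab}.sd"]])
        else:
            levs = slopes_levels(term, data_cc)
            sds = [values[f"{lab}.sd.{lv}"] for lv in levs]
            cors = [values[f"{lab}.cor.{levs[i]}.{levs[j]}"]
                    for i in range(len(levs))
                    for j in range(i + 1, len(levs))]
            term_params[lab] = ParamBlock(sds=sds, correlations=cors)
    if spec.residual.by_group:
        levs = sorted(data_cc[spec.residual.factor].astype(str).unique())
        residual = ResidualSpec(factor=spec.residual.factor,
                                sds={lv: values[f"residual.sd.{lv}"]
                                     for lv in levs})
    else:
        residual = ResidualSpec(sd=values["residual.sd"])
    return term_params, residual


def _fit_spectral(spec, data_cc, n_dropped, criterion, cfg) -> FitResult:
    eng = SpectralLMM(spec, data_cc, drop_missing=False)
    gamma, dev, se2, beta = eng.fit1d(criterion)
    sg = float(np.sqrt(gamma * se2))
    se = float(np.sqrt(se2))
    lab = spec.random_terms[0].label
    values = {f"{lab}.sd": sg, "residual.sd": se}
    term_params, residual = _structured_estimates(spec, data_cc, values)
    flags = {f"{lab}.sd": gamma == 0.0, "residual.sd": False}
    return FitResult(
        beta=pd.Series(beta, index=eng.x_names),
        params=term_params, residual=residual, param_values=values,
        deviance=dev, criterion=criterion, converged=True,
        n_obs=eng.n, n_dropped=n_dropped, n_params=eng.p + 2,
        boundary_flags=flags, method="spectral",
        constraints=spec.constraints, spec=spec)


def _fit_generic(spec, data_cc, n_dropped, criterion, cfg) -> FitResult:
    eng = GaussianLMM(spec, data_cc, drop_missing=False,
                      force_dense=cfg.force_dense)
    pmap = _ParamMap(eng.params, spec.constraints)

    profile_scale = not pmap.sd_fixed_nonzero()
    ref_group = None
    if profile_scale:
        # pin one free residual sd (or any free sd) at 1 as the unit of scale
        for g, k in zip(pmap.free_groups, pmap.free_kinds):
            if k == "sd" and g.startswith("residual."):
                ref_group = g
                break
        if ref_group is None:
            for g, k in zip(pmap.free_groups, pmap.free_kinds):
                if k == "sd":
                    ref_group = g
                    break
        if ref_group is None:
            profile_scale = False

    opt_groups = [g for g in pmap.free_groups if g != ref_group]
    opt_kinds = [k for g, k in zip(pmap.free_groups, pmap.free_kinds)
                 if g != ref_group]
    sd_y = float(np.std(eng.y)) or 1.0
    base = 1.0 if profile_scale else sd_y * 0.5

    def to_theta(x):
        free = dict(zip(opt_groups, _from_opt(x, opt_kinds)))
        if ref_group is not None:
            free[ref_group] = 1.0 if profile_scale else base
        return pmap.full_theta(np.array(
            [free[g] for g in pmap.free_groups]))

    def objective(x):
        theta = to_theta(x)
        try:
            if profile_scale:
                return eng.neg2_profiled(theta, criterion)[0]
            return eng.neg2(theta, criterion)
        except (DegenerateDataError, QtlmmError, np.linalg.LinAlgError):
            return _PENALTY

    bounds = [(0.0, cfg.ratio_bound) if k == "sd"
              else (-cfg.cor_z_bound, cfg.cor_z_bound) for k in opt_kinds]
    starts = _start_points(opt_kinds, profile_scale, sd_y, cfg)
    for values in cfg.extra_starts:
        xs = _start_from_values(pmap, opt_groups, opt_kinds, ref_group,
                                profile_scale, values, bounds)
        if xs is not None:
            starts.append(xs)

    n_opt = len(opt_groups)
    if n_opt == 0:
        x_hat, converged = np.empty(0), True
        dev_hat = objective(x_hat)
    elif n_opt == 1 and opt_kinds[0] == "sd":
        lo, hi = bounds[0]
        res = scipy.optimize.minimize_scalar(
            lambda v: objective(np.array([v])), bounds=(lo, hi),
            method="bounded", options={"xatol": cfg.scalar_xatol})
        cand = [(objective(np.array([lo])), lo), (res.fun, float(res.x))]
        dev_hat, xv = min(cand)
        x_hat, converged = np.array([xv]), np.isfinite(dev_hat)
    else:
        order = np.argsort([objective(s) for s in starts])
        x_hat, dev_hat, converged = None, np.inf, False
        tried = 0
        for si in order:
            res = _local_search(objective, starts[si], bounds, cfg)
            tried += 1
            if res.fun < min(dev_hat, _PENALTY / 2):
                x_hat, dev_hat = np.asarray(res.x), float(res.fun)
                converged = bool(res.success)
            if converged and tried >= cfg.n_starts:
                break
        if x_hat is None:
            x_hat = starts[0]
            dev_hat = objective(x_hat)
            converged = False
            logger.warning("optimiser failed to converge after %d starts",
                           tried)

    theta_hat = to_theta(x_hat)
    if profile_scale:
        dev_hat, s_hat, beta = eng.neg2_profiled(theta_hat, criterion)
        scale = float(np.sqrt(s_hat))
        theta_full = np.array(
            [t * scale if p.kind == "sd" else t
             for t, p in zip(theta_hat, eng.params)])
    else:
        _, _, _, beta = eng.gls_parts(theta_hat)
        theta_full = theta_hat

    values = {p.path: float(v) for p, v in zip(eng.params, theta_full)}
    term_params, residual = _structured_estimates(spec, data_cc, values)

    flags = {}
    opt_vals = dict(zip(opt_groups, _from_opt(x_hat, opt_kinds)))
    for p in eng.params:
        g = pmap.group_of[p.path]
        if g in pmap.fixed or g == ref_group:
            flags[p.path] = False
        elif p.kind == "sd":
            flags[p.path] = opt_vals[g] <= cfg.boundary_tol
        else:
            flags[p.path] = abs(opt_vals[g]) >= 1.0 - cfg.boundary_tol
    n_free_vc = pmap.n_free
    return FitResult(
        beta=pd.Series(beta, index=eng.x_names),
        params=term_params, residual=residual, param_values=values,
        deviance=float(dev_hat), criterion=criterion, converged=converged,
        n_obs=eng.n, n_dropped=n_dropped, n_params=eng.p + n_free_vc,
        boundary_flags=flags, method="generic",
        constraints=spec.constraints, spec=spec)


def _local_search(objective, x0, bounds, cfg):
    """Bounded local minimisation: quasi-Newton first (finite-difference
    gradients on the smooth profiled deviance), with a derivative-free
    Powell pass as polish/fallback near non-smooth boundary solutions."""
    res = scipy.optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxfun": cfg.maxfev, "ftol": 1e-13, "gtol": 1e-9})
    start2 = res.x if np.isfinite(res.fun) else x0
    res2 = scipy.optimize.minimize(
        objective, start2, method="Powell", bounds=bounds,
        options={"xtol": cfg.xtol, "ftol": cfg.ftol, "maxfev": cfg.maxfev})
    if np.isfinite(res.fun) and res.fun < res2.fun:
        return res
    return res2


def _from_opt(x, kinds):
    """Optimiser coordinates -> parameter values (tanh for correlations)."""
    return [np.tanh(v) if k == "cor" else float(v)
            for v, k in zip(np.atleast_1d(x), kinds)]


def _start_from_values(pmap, opt_groups, opt_kinds, ref_group,
                       profiled, values, bounds):
    """Translate a path->value solution into optimiser coordinates."""
    def group_value(g):
        for p, gg in pmap.group_of.items():
            if gg == g and p in values:
                return float(values[p])
        return None

    scale = 1.0
    if profiled and ref_group is not None:
        rv = group_value(ref_group)
        if rv is None or rv <= 1e-10:
            return None
        scale = rv
    x = []
    for (g, k), (lo, hi) in zip(zip(opt_groups, opt_kinds), bounds):
        v = group_value(g)
        if v is None:
            return None
        if k == "cor":
            v = float(np.arctanh(np.clip(v, -0.9999999, 0.9999999)))
        else:
            v = v / scale
        x.append(min(max(v, lo), hi))
    return np.array(x)


def _start_points(kinds, profiled, sd_y, cfg):
    """Deterministic heuristic starts: equal split, residual-dominant,
    genetic(term)-dominant."""
    base = 1.0 if profiled else sd_y * 0.5
    starts = []
    for mult in (1.0, 0.35, 3.0):
        starts.append(np.array([base * mult if k == "sd" else 0.0
                                for k in kinds]))
    return starts


# ---------------------------------------------------------------------------
# derived quantities and the G x E triple

def heritability(res: FitResult, term: str | None = None) -> float:
    """Proportion of phenotypic variance from one (intercept) genetic term:
    sd_term^2 / (sum of all term variances + residual variance)."""
    if res.residual.by_group:
        raise SpecError("heritability is undefined with group-specific "
                        "residual variances; summarise per group instead")
    labels = list(res.params)
    term = term or labels[0]
    pb = res.params[term]
    if pb.correlations or len(pb.sds) != 1:
        raise SpecError(f"term {term!r} is group-specific; no single "
                        "heritability exists")
    total = res.residual.sd ** 2
    for lab in labels:
        other = res.params[lab]
        if len(other.sds) == 1 and not other.correlations:
            total += other.sds[0] ** 2
        else:
            raise SpecError("heritability with group-specific terms is "
                            "undefined; fit the homoscedastic reduction")
    if total == 0.0:
        return 0.0
    return float(pb.sds[0] ** 2 / total)


def _find_gxe_term(spec: ModelSpec, data: pd.DataFrame):
    for term in spec.random_terms:
        if term.slopes_factor is not None:
            levs = slopes_levels(term, data)
            if len(levs) != 2:
                raise SpecError("the interaction tests require a two-level "
                                f"slopes factor; {term.slopes_factor!r} has "
                                f"{len(levs)}")
            return term, levs
    raise SpecError("spec has no group-specific (slopes) random term")


def fit_gxe(spec: ModelSpec, data: pd.DataFrame,
            optimizer: OptimizerConfig | None = None
            ) -> tuple[FitResult, FitResult, FitResult]:
    """Free interaction model plus its two nulls, all fitted by ML.

    Returns (m_free, m_rho1, m_eqvar): the sex-specific (group-specific)
    genetic model, the refit with the cross-group genetic correlation fixed
    at 1, and the refit with the two group sds constrained equal.
    """
    term, (l1, l2) = _find_gxe_term(spec, data)
    lab = term.label
    cor_path = f"{lab}.cor.{l1}.{l2}"
    sd1, sd2 = f"{lab}.sd.{l1}", f"{lab}.sd.{l2}"

    def with_extra(fixes=(), eqs=()):
        cs = ConstraintSet(
            fixes=list(spec.constraints.fixes) + list(fixes),
            equalities=list(spec.constraints.equalities) + list(eqs))
        return ModelSpec(response=spec.response, fixed=list(spec.fixed),
                         random_terms=spec.random_terms,
                         residual=spec.residual, constraints=cs)

    m_rho1 = fit(with_extra(fixes=[(cor_path, 1.0)]), data,
                 criterion="ML", optimizer=optimizer)
    m_eq = fit(with_extra(eqs=[(sd1, sd2)]), data,
               criterion="ML", optimizer=optimizer)
    # the nulls' optima are feasible points of the free model: warm-start
    # from them so the nesting dev(free) <= dev(null) holds numerically
    base = optimizer or OptimizerConfig()
    cfg_free = replace(base, extra_starts=(list(base.extra_starts)
                                           + [m_rho1.param_values,
                                              m_eq.param_values]))
    m_free = fit(spec, data, criterion="ML", optimizer=cfg_free)
    # The free model's closed parameter space contains rho = 1 and equal
    # sds, but the atanh search coordinate only approaches |rho| = 1. If a
    # null's optimum beats the free search, it IS the free optimum (a
    # boundary point): adopt it, keeping the free parameter count.
    for null_res in (m_rho1, m_eq):
        if null_res.deviance < m_free.deviance:
            flags = dict(null_res.boundary_flags)
            flags[cor_path] = True
            m_free = replace(null_res, n_params=m_free.n_params,
                             constraints=spec.constraints,
                             boundary_flags=flags, spec=spec)
    return m_free, m_rho1, m_eq
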