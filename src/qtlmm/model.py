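"""Model specification objects: fixed effects, random terms, constraints."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .covstruct import ParamBlock, RandomTerm, ResidualSpec, slopes_levels
from .errors import SpecError


@dataclass
class ConstraintSet:
    """Restrictions on variance-component parameters.

    fixes : (parameter path, value) pairs; the parameter is removed from the
        search and held at the value (e.g. ``("genetic.cor.female.male", 1.0)``
        for the no-interaction null).
    equalities : pairs of parameter paths forced equal by aliasing them to a
        single free parameter (e.g. equal male/female genetic variances).
    """
    fixes: list[tuple[str, float]] = field(default_factory=list)
    equalities: list[tuple[str, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.fixes and not self.equalities


@dataclass
class ModelSpec:
    """Declarative Gaussian mixed-model specification.

    response : column holding the outcome y.
    fixed : covariate columns (an intercept is always included; categorical
        columns are dummy-coded dropping the first level).
    random_terms : structured random effects (kinship, household, ...).
    residual : homoscedastic or group-specific residual structure.
    constraints : parameter restrictions applied during fitting.
    """
    response: str
    fixed: list[str] = field(default_factory=list)
    random_terms: list[RandomTerm] = field(default_factory=list)
    residual: ResidualSpec = field(default_factory=ResidualSpec)
    constraints: ConstraintSet = field(default_factory=ConstraintSet)

    def used_columns(self) -> list[str]:
        cols = [self.response] + list(self.fixed)
        for t in self.random_terms:
            cols.append(t.grouping)
            if t.slopes_factor is not None:
                cols.append(t.slopes_factor)
        if self.residual.by_group:
            cols.append(self.residual.factor)
        return list(dict.fromkeys(cols))

    def term_labels(self) -> list[str]:
        labels = [t.label for t in self.random_terms]
        if len(set(labels)) != len(labels):
            raise SpecError(f"random-term labels are not unique: {labels}")
        return labels


@dataclass(frozen=True)
class Parameter:
    """One canonical variance parameter: its path string and kind."""
    path: str
    kind: str  # "sd" | "cor"


def parameter_list(spec: ModelSpec, data: pd.DataFrame) -> list[Parameter]:
    """Canonical parameter order: per term sds then correlations, then
    residual sds. This is the order of ``theta`` in ``neg2_loglik``."""
    params: list[Parameter] = []
    for term in spec.random_terms:
        lab = term.label
        if term.slopes_factor is None:
            params.append(Parameter(f"{lab}.sd", "sd"))
        else:
            levs = slopes_levels(term, data)
            for lv in levs:
                params.append(Parameter(f"{lab}.sd.{lv}", "sd"))
            for i in range(len(levs)):
                for j in range(i + 1, len(levs)):
                    params.append(
                        Parameter(f"{lab}.cor.{levs[i]}.{levs[j]}", "cor"))
    if spec.residual.by_group:
        for lv in sorted(data[spec.residual.factor].astype(str).unique()):
            params.append(Parameter(f"residual.sd.{lv}", "sd"))
    else:
        params.append(Parameter("residual.sd", "sd"))
    return params


def parameter_paths(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    return [p.path for p in parameter_list(spec, data)]


@dataclass
class OptimizerConfig:
    """Knobs of the variance-parameter optimiser.

    The search runs on standard deviations (non-negative, expressed relative
    to the residual when the profile-of-scale reduction applies) and on
    atanh-mapped correlations, with a bounded derivative-free local method
    started from deterministic heuristic points.
    """
    n_starts: int = 1          # local searches (more are tried on failure)
    maxfev: int = 20000
    xtol: float = 1e-8
    ftol: float = 1e-11
    ratio_bound: float = 50.0  # upper bound on sd ratios / scaled sds
    cor_z_bound: float = 8.0   # bound on atanh(correlation)
    scalar_xatol: float = 1e-10  # tolerance of the 1-D bounded search
    method: str = "auto"       # "auto" | "generic" | "spectral"
    force_dense: bool = False
    boundary_tol: float = 1e-4
    # additional warm starts: dicts of parameter path -> value (e.g. the
    # solution of a nested model, which is a feasible point of this one)
    extra_starts: list = field(default_factory=list)


@dataclass
class FitResult:
    """Fitted mixed model: estimates, criterion value, convergence state."""
    beta: pd.Series
    params: dict                      # term label -> ParamBlock (fitted)
    residual: ResidualSpec            # with sd values filled in
    param_values: dict                # parameter path -> fitted value
    deviance: float                   # -2 * log-likelihood at the optimum
    criterion: str                    # "ML" | "REML"
    converged: bool
    n_obs: int
    n_dropped: int
    n_params: int                     # free parameters (fixed effects + vc)
    boundary_flags: dict              # parameter path -> at-bound indicator
    method: str = "generic"
    constraints: ConstraintSet | None = None
    spec: ModelSpec | None = None

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    def variance_components(self) -> dict:
        """Term label -> variance (intercept terms only) plus residual."""
        out = {}
        for lab, pb in self.params.items():
            if not pb.correlations and len(pb.sds) == 1:
                out[lab] = pb.sds[0] ** 2
        if not self.residual.by_group:
            out["residual"] = self.residual.sd ** 2
        return out

    def to_dict(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "param_values": {k: float(v) for k, v in self.param_values.items()},
            "deviance": None if math.isinf(self.deviance) else float(self.deviance),
            "criterion": self.criterion,
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_dropped": int(self.n_dropped),
            "n_params": int(self.n_params),
            "boundary_flags": {k: bool(v) for k, v in self.boundary_flags.items()},
            "method": self.method,
            "constraints": None if self.constraints is None else {
                "fixes": [[p, float(v)] for p, v in self.constraints.fixes],
                "equalities": [list(e) for e in self.constraints.equalities],
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
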