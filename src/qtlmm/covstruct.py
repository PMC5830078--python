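"""Random-effect covariance structures and the Z* = Z L substitution.

A random effect u with Var(u) = G and incidence Z contributes Z G Z' to the
phenotypic covariance. Writing G = L L' (Cholesky when G is positive
definite, a truncated eigenfactorization when it is merely positive
semi-definite, e.g. with MZ twins) turns the structured effect into an
unstructured one on the substituted design Z* = Z L:

    Var(Z u) = Z G Z' = (Z L)(Z L)' = Z* (Z*)'

Group-specific (e.g. sex-specific) genetic terms use a small free covariance
K among the k group levels, giving Var(u) = A ⊙ (S K S') with S the level
incidence; for k = 2 the three parameters are the level standard deviations
sigma_g1, sigma_g2 and the cross-level genetic correlation rho_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import NotPSDError, SpecError
from .pedigree import incidence_from_factor
from .relmatrix import RelMatrix

PSD_TOL = 1e-8


@dataclass
class ParamBlock:
    """Variance parameters of one random term.

    ``sds`` holds one standard deviation per level (a single entry for plain
    intercept terms); ``correlations`` the upper-triangle cross-level
    correlations in (i < j) order, empty for intercept terms.
    """
    sds: list[float]
    correlations: list[float] = field(default_factory=list)

    def __post_init__(self):
        if any(s < 0 for s in self.sds):
            raise SpecError("standard deviations must be >= 0")
        if any(abs(c) > 1 for c in self.correlations):
            raise SpecError("correlations must lie in [-1, 1]")
        k = len(self.sds)
        if self.correlations and len(self.correlations) != k * (k - 1) // 2:
            raise SpecError(
                f"expected {k * (k - 1) // 2} correlations for {k} levels, "
                f"got {len(self.correlations)}")

    def k_matrix(self) -> np.ndarray:
        """Level covariance K = D C D (D = diag(sds), C the correlation matrix)."""
        k = len(self.sds)
        C = np.eye(k)
        pos = 0
        for i in range(k):
            for j in range(i + 1, k):
                c = self.correlations[pos] if self.correlations else 0.0
                C[i, j] = C[j, i] = c
                pos += 1
        d = np.asarray(self.sds)
        return C * np.outer(d, d)


@dataclass
class RandomTerm:
    """One random-effect term of a mixed model.

    grouping : column whose levels index the effect (e.g. individual id,
        household id).
    relmat : covariance among grouping levels; None means identity
        (i.i.d. effects, as for a household term).
    slopes_factor : when set, the term carries one effect per level of this
        factor within each group (group-specific genetic variances); when
        None the term is a plain random intercept.
    params : parameter values, where needed (simulation, direct covariance
        evaluation); left None for terms whose parameters are to be fitted.
    name : label used in parameter paths; defaults to the grouping column.
    """
    grouping: str
    relmat: RelMatrix | None = None
    slopes_factor: str | None = None
    params: ParamBlock | None = None
    name: str | None = None

    @property
    def label(self) -> str:
        return self.name if self.name is not None else self.grouping


@dataclass
class ResidualSpec:
    """Residual structure: homoscedastic, or one variance per factor level.

    ``sd`` (homoscedastic) or ``sds`` (mapping level -> sd) carry values when
    the spec is used generatively; they stay None for fitting.
    """
    factor: str | None = None
    sd: float | None = None
    sds: dict[str, float] | None = None

    @property
    def by_group(self) -> bool:
        return self.factor is not None


@dataclass
class Factorization:
    """L with L L' = A; rows follow the RelMatrix ids."""
    L: np.ndarray
    rank: int
    method: str  # "cholesky" | "eigen"
    ids: list[str]


def factor_relmat(A: RelMatrix, psd_tol: float = PSD_TOL) -> Factorization:
    """Factor A = L L', Cholesky when positive definite, else eigen path.

    The eigen path keeps eigenvalues above ``psd_tol`` relative to the
    largest eigenvalue, so L has as many columns as the numerical rank.
    Raises NotPSDError, reporting the offending eigenvalue, when the smallest
    eigenvalue is below -psd_tol (relative).
    """
    M = A.values
    try:
        L = scipy.linalg.cholesky(M, lower=True)
        return Factorization(L=L, rank=M.shape[0], method="cholesky", ids=A.ids)
    except scipy.linalg.LinAlgError:
        pass
    w, V = scipy.linalg.eigh(M)
    scale = max(1.0, w[-1]) if w.size else 1.0
    if w.size and w[0] < -psd_tol * scale:
        raise NotPSDError(
            f"matrix is not positive semi-definite: eigenvalue {w[0]:g} "
            f"below tolerance {-psd_tol * scale:g}", min_eigenvalue=w[0])
    keep = w > psd_tol * scale
    L = V[:, keep] * np.sqrt(w[keep])
    return Factorization(L=L, rank=int(keep.sum()), method="eigen", ids=A.ids)


def substituted_design(Z: np.ndarray, F: Factorization) -> np.ndarray:
    """Z* = Z L, so that Z*(Z*)' = Z A Z'."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != F.L.shape[0]:
        raise ValueError(
            f"incidence matrix has {Z.shape[1]} columns but factor has "
            f"{F.L.shape[0]} rows")
    return Z @ F.L


def _group_incidence(term: RandomTerm, data: pd.DataFrame
                     ) -> tuple[np.ndarray, list[str]]:
    """Incidence of data rows onto the term's grouping levels.

    Level order follows the relmat ids when a relmat is given (subset to the
    levels present, preserving relmat order); otherwise sorted unique data
    levels.
    """
    vals = data[term.grouping].astype(str).tolist()
    if term.relmat is not None:
        present = set(vals)
        levels = [i for i in term.relmat.ids if i in present]
        missing = sorted(present - set(levels))
        if missing:
            from .errors import AlignmentError
            raise AlignmentError(
                f"term {term.label!r}: {len(missing)} grouping levels absent "
                f"from relationship matrix: {missing[:10]}")
    else:
        levels = sorted(set(vals))
    return incidence_from_factor(vals, levels), levels


def term_relmat_values(term: RandomTerm, levels: list[str]) -> np.ndarray:
    """Covariance among grouping levels: relmat subset, or identity."""
    if term.relmat is None:
        return np.eye(len(levels))
    return term.relmat.subset(levels).values


def slopes_levels(term: RandomTerm, data: pd.DataFrame) -> list[str]:
    """Sorted levels of the slopes factor (the order indexing sds)."""
    return sorted(data[term.slopes_factor].astype(str).unique())


def term_covariance(term: RandomTerm, data: pd.DataFrame) -> np.ndarray:
    """Var of the term's contribution Z u over the data rows.

    Intercept terms give sd^2 * Z A Z'. Group-slope terms give
    (Z A Z') ⊙ (S K S') with S the slopes-factor incidence and K the level
    covariance from the term's ParamBlock.
    """
    if term.params is None:
        raise SpecError(f"term {term.label!r} has no parameter values")
    Z, levels = _group_incidence(term, data)
    A = term_relmat_values(term, levels)
    M = Z @ A @ Z.T
    if term.slopes_factor is None:
        return term.params.sds[0] ** 2 * M
    levs = slopes_levels(term, data)
    if len(levs) != len(term.params.sds):
        raise SpecError(
            f"term {term.label!r}: factor {term.slopes_factor!r} has "
            f"{len(levs)} levels but {len(term.params.sds)} sds were given")
    S = incidence_from_factor(data[term.slopes_factor].astype(str).tolist(), levs)
    K = term.params.k_matrix()
    return M * (S @ K @ S.T)


def residual_covariance(spec: ResidualSpec, data: pd.DataFrame) -> np.ndarray:
    """Diagonal residual covariance matrix over the data rows."""
    n = len(data)
    if not spec.by_group:
        if spec.sd is None:
            raise SpecError("homoscedastic residual spec has no sd value")
        return np.diag(np.full(n, spec.sd ** 2))
    if spec.sds is None:
        raise SpecError("by-group residual spec has no sd values")
    vals = data[spec.factor].astype(str)
    missing = sorted(set(vals) - set(spec.sds))
    if missing:
        raise SpecError(
            f"residual factor {spec.factor!r} has levels without a variance: "
            f"{missing}")
    return np.diag(np.array([spec.sds[v] ** 2 for v in vals]))
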