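"""Gaussian mixed-model likelihood evaluation.

The phenotypic covariance is assembled term by term,

    Sigma(theta) = sum_t Var_t(theta) + R(theta),

where each random term contributes sd^2 * Z A Z' (intercept terms) or the
Hadamard form (Z A Z') ⊙ (S K S') (group-specific terms), and R is diagonal.
Fixed effects are profiled out by generalised least squares, so the deviance
is a function of the variance parameters alone:

    ML:   -2ll = n log 2pi + log|Sigma| + r' Sigma^-1 r
    REML: -2ll = (n-p) log 2pi + log|Sigma| + log|X' Sigma^-1 X|
                 + r' Sigma^-1 r

with r = y - X beta_hat. Two evaluation engines share these formulas: a
generic one over arbitrary term structures (dense Cholesky, or sparse LU when
the assembled covariance is sparse enough to profit), and a spectral one for
the single-structured-term homoscedastic model, which rotates the data by the
eigenvectors of Z A Z' once and reduces every subsequent evaluation to O(n).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .covstruct import (RandomTerm, ResidualSpec, _group_incidence,
                        slopes_levels, term_relmat_values)
from .errors import DegenerateDataError, QtlmmError, SpecError
from .model import ModelSpec, Parameter, parameter_list
from .pedigree import incidence_from_factor

logger = logging.getLogger("qtlmm")

LOG2PI = np.log(2.0 * np.pi)

# Assembled covariances at or below this density go through sparse LU.
SPARSE_DENSITY_MAX = 0.45
# Below this size dense algebra always wins.
SPARSE_MIN_N = 150


def build_design(spec: ModelSpec, data: pd.DataFrame
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response vector and fixed-effect design (intercept first).

    Categorical covariates are dummy-coded dropping the first sorted level.
    Raises SpecError naming collinear columns if X is rank deficient.
    """
    y = np.asarray(data[spec.response], dtype=float)
    cols = [np.ones(len(data))]
    names = ["(intercept)"]
    for c in spec.fixed:
        s = data[c]
        if s.dtype.kind in "ifub" and s.dtype.kind != "b":
            cols.append(np.asarray(s, dtype=float))
            names.append(c)
        else:
            levels = sorted(s.astype(str).unique())
            for lv in levels[1:]:
                cols.append((s.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{c}[{lv}]")
    X = np.column_stack(cols)
    # rank check with column identification via pivoted QR
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise SpecError(f"fixed-effect design is rank deficient; "
                        f"collinear columns: {bad}")
    return y, X, names


def complete_cases(spec: ModelSpec, data: pd.DataFrame
                   ) -> tuple[pd.DataFrame, int]:
    """Listwise deletion on the columns the model uses."""
    cols = [c for c in spec.used_columns() if c in data.columns]
    missing_cols = [c for c in spec.used_columns() if c not in data.columns]
    if missing_cols:
        raise SpecError(f"columns not present in data: {missing_cols}")
    keep = data[cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d of %d rows with missing values in %s",
                    n_dropped, len(data), cols)
    return data.loc[keep].reset_index(drop=True), n_dropped


class _Component:
    """One covariance component c(theta) * M."""

    __slots__ = ("M", "kind", "i", "j", "c")

    def __init__(self, M, kind, i, j=None, c=None):
        self.M = M          # dense ndarray or sparse csr
        self.kind = kind    # "var" (sd_i^2) or "cov" (sd_i sd_j cor_c)
        self.i, self.j, self.c = i, j, c

    def coeff(self, theta: np.ndarray) -> float:
        if self.kind == "var":
            return theta[self.i] ** 2
        return theta[self.i] * theta[self.j] * theta[self.c]


class GaussianLMM:
    """Generic likelihood engine over the assembled covariance.

    Built once per (spec, data); evaluations take the canonical theta vector
    of ``parameter_list(spec, data)``.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, *,
                 drop_missing: bool = True, force_dense: bool = False):
        self.spec = spec
        if drop_missing:
            data, self.n_dropped = complete_cases(spec, data)
        else:
            self.n_dropped = 0
        self.data = data
        self.n = len(data)
        if self.n == 0:
            raise DegenerateDataError("no complete-case rows left")
        self.y, self.X, self.x_names = build_design(spec, data)
        self.p = self.X.shape[1]
        self.params: list[Parameter] = parameter_list(spec, data)
        self._pidx = {p.path: k for k, p in enumerate(self.params)}
        self.components: list[_Component] = []
        self._res_masks: list[tuple[np.ndarray, int]] = []
        self._build_components(force_dense)

    # -- construction -----------------------------------------------------

    def _build_components(self, force_dense: bool) -> None:
        spec, data = self.spec, self.data
        want_sparse = (not force_dense and self.n >= SPARSE_MIN_N and
                       all(t.relmat is None or t.relmat.storage == "sparse"
                           for t in spec.random_terms))
        raw = []
        for term in spec.random_terms:
            Z, levels = _group_incidence(term, data)
            A = term_relmat_values(term, levels)
            if want_sparse:
                M = (sp.csr_matrix(Z) @ sp.csr_matrix(A)
                     @ sp.csr_matrix(Z).T).tocsr()
                M.eliminate_zeros()
            else:
                M = Z @ A @ Z.T
            lab = term.label
            if term.slopes_factor is None:
                raw.append(_Component(M, "var", self._pidx[f"{lab}.sd"]))
            else:
                levs = slopes_levels(term, data)
                S = incidence_from_factor(
                    data[term.slopes_factor].astype(str).tolist(), levs)
                for a in range(len(levs)):
                    for b in range(a, len(levs)):
                        mask = np.outer(S[:, a], S[:, b])
                        if a != b:
                            mask = mask + mask.T
                        Mab = (M.multiply(mask).tocsr() if want_sparse
                               else M * mask)
                        if want_sparse:
                            Mab.eliminate_zeros()
                        ia = self._pidx[f"{lab}.sd.{levs[a]}"]
                        ib = self._pidx[f"{lab}.sd.{levs[b]}"]
                        if a == b:
                            raw.append(_Component(Mab, "var", ia))
                        else:
                            ic = self._pidx[f"{lab}.cor.{levs[a]}.{levs[b]}"]
                            raw.append(_Component(Mab, "cov", ia, ib, ic))
        if spec.residual.by_group:
            vals = data[spec.residual.factor].astype(str)
            for lv in sorted(vals.unique()):
                mask = (vals == lv).to_numpy(dtype=float)
                self._res_masks.append((mask, self._pidx[f"residual.sd.{lv}"]))
        else:
            self._res_masks.append(
                (np.ones(self.n), self._pidx["residual.sd"]))

        self._perm = None
        if want_sparse and raw:
            pattern = None
            for comp in raw:
                pat = comp.M != 0
                pattern = pat if pattern is None else (pattern + pat)
            density = (pattern.nnz + self.n) / self.n ** 2
            if density > SPARSE_DENSITY_MAX:
                for comp in raw:
                    comp.M = np.asarray(comp.M.todense())
                want_sparse = False
            else:
                from ._spchol import amd_ordering
                self._perm = amd_ordering(
                    (pattern + sp.eye(self.n)).tocsc())
        self.sparse = want_sparse and bool(raw)
        self.components = raw

    # -- evaluation -------------------------------------------------------

    def sigma(self, theta: np.ndarray):
        """Sigma(theta), dense ndarray or sparse csr."""
        theta = np.asarray(theta, dtype=float)
        res = np.zeros(self.n)
        for mask, k in self._res_masks:
            res += theta[k] ** 2 * mask
        if self.sparse:
            S = sp.diags(res, format="csr")
            for comp in self.components:
                c = comp.coeff(theta)
                if c != 0.0:
                    S = S + c * comp.M
            return S
        S = np.diag(res)
        for comp in self.components:
            c = comp.coeff(theta)
            if c != 0.0:
                S += c * comp.M
        return S

    def _solve_parts(self, theta):
        """logdet(Sigma), Sigma^-1 [X y], for the current theta."""
        S = self.sigma(theta)
        B = np.column_stack([self.X, self.y])
        if self.sparse:
            from ._spchol import SparseCholesky
            try:
                ch = SparseCholesky(S.tocsc(), perm=self._perm)
            except np.linalg.LinAlgError as e:
                raise QtlmmError(f"covariance matrix not PD: {e}") from None
            logdet = ch.logdet
            sol = ch.solve(B)
        else:
            try:
                cho = scipy.linalg.cho_factor(S, lower=True,
                                              check_finite=False)
            except scipy.linalg.LinAlgError as e:
                raise QtlmmError(f"singular covariance matrix: {e}") from None
            logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
            sol = scipy.linalg.cho_solve(cho, B, check_finite=False)
        return logdet, sol[:, :-1], sol[:, -1]

    def gls_parts(self, theta):
        """(logdet Sigma, logdet X'V^-1X, residual quadratic form, beta)."""
        logdet, ViX, Viy = self._solve_parts(theta)
        XtViX = self.X.T @ ViX
        Xty = self.X.T @ Viy
        cho = scipy.linalg.cho_factor(XtViX)
        beta = scipy.linalg.cho_solve(cho, Xty)
        ld_x = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        q = float(self.y @ Viy - beta @ Xty)
        return logdet, ld_x, q, beta

    def neg2(self, theta, criterion: str = "REML") -> float:
        """Exact -2 log-likelihood (deterministic in theta)."""
        logdet, ld_x, q, _ = self.gls_parts(theta)
        if criterion == "ML":
            return self.n * LOG2PI + logdet + q
        if criterion == "REML":
            return (self.n - self.p) * LOG2PI + logdet + ld_x + q
        raise ValueError(f"unknown criterion {criterion!r}")

    def neg2_profiled(self, theta, criterion: str = "REML"):
        """Deviance minimised over an overall variance scale.

        Returns (deviance, optimal variance scale s, beta); the deviance
        equals neg2(sqrt(s) * sds) and beta is the GLS estimate (which is
        scale invariant). Valid only when all sd parameters may scale freely.
        """
        logdet, ld_x, q, beta = self.gls_parts(theta)
        if q <= 0.0:
            raise DegenerateDataError("residual quadratic form vanished")
        if criterion == "ML":
            s = q / self.n
            dev = self.n * LOG2PI + logdet + self.n * np.log(s) + self.n
        elif criterion == "REML":
            df = self.n - self.p
            s = q / df
            dev = df * LOG2PI + logdet + ld_x + df * np.log(s) + df
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        return float(dev), float(s), beta


def neg2_loglik(spec: ModelSpec, theta, data: pd.DataFrame,
                criterion: str = "REML") -> float:
    """-2 log-likelihood of the model at the given variance parameters.

    ``theta`` follows the canonical order of ``parameter_paths(spec, data)``:
    per term its sds (sorted slope levels) then its correlations, then the
    residual sds. Fixed effects are profiled out by GLS; under REML the
    log-determinant of X'Sigma^-1 X is added.
    """
    engine = GaussianLMM(spec, data)
    theta = np.asarray(theta, dtype=float)
    if len(theta) != len(engine.params):
        raise SpecError(f"theta has {len(theta)} entries, model has "
                        f"{len(engine.params)} parameters")
    return engine.neg2(theta, criterion)


def spectral_eligible(spec: ModelSpec) -> bool:
    """Single structured intercept term + homoscedastic residual, no
    constraints: the model the eigen-rotation fast path covers."""
    return (len(spec.random_terms) == 1
            and spec.random_terms[0].slopes_factor is None
            and not spec.residual.by_group
            and spec.constraints.is_empty())


class SpectralLMM:
    """Fast path for y = X beta + u + e with Var(u) = sg^2 K, Var(e) = se^2 I.

    With K = U diag(d) U' the rotated model has diagonal covariance
    se^2 (gamma d + 1), gamma = sg^2 / se^2; se^2 is profiled in closed form
    and the deviance becomes a one-dimensional function of gamma.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, *,
                 drop_missing: bool = True):
        if drop_missing:
            data, self.n_dropped = complete_cases(spec, data)
        else:
            self.n_dropped = 0
        self.spec = spec
        self.data = data
        y, X, self.x_names = build_design(spec, data)
        term = spec.random_terms[0]
        Z, levels = _group_incidence(term, data)
        A = term_relmat_values(term, levels)
        K = Z @ A @ Z.T
        d, U = scipy.linalg.eigh(K)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n, self.p = X.shape

    @classmethod
    def from_rotated(cls, d, yt, Xt, x_names=None):
        obj = cls.__new__(cls)
        obj.d, obj.U = np.asarray(d), None
        obj.yt, obj.Xt = np.asarray(yt), np.asarray(Xt)
        obj.n, obj.p = obj.Xt.shape
        obj.x_names = x_names or [f"x{i}" for i in range(obj.p)]
        obj.n_dropped = 0
        obj.spec = obj.data = None
        return obj

    def dev(self, gamma: float, criterion: str = "REML",
            yt: np.ndarray | None = None, Xt: np.ndarray | None = None):
        """(deviance, profiled residual variance, beta) at a variance ratio."""
        yt = self.yt if yt is None else yt
        Xt = self.Xt if Xt is None else Xt
        n, p = Xt.shape
        w = gamma * self.d + 1.0
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        Xty = Xw.T @ yt
        L = np.linalg.cholesky(XtWX)  # p x p, p small
        beta = np.linalg.solve(XtWX, Xty)
        ld_x = 2.0 * float(np.sum(np.log(np.diag(L))))
        q = float(yt @ (yt / w) - beta @ Xty)
        if q <= 0.0:
            raise DegenerateDataError("residual quadratic form vanished")
        logdet = float(np.sum(np.log(w)))
        if criterion == "ML":
            s = q / n
            dev = n * LOG2PI + logdet + n * np.log(s) + n
        elif criterion == "REML":
            df = n - p
            s = q / df
            dev = df * LOG2PI + logdet + ld_x + df * np.log(s) + df
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        return float(dev), float(s), beta

    def fit1d(self, criterion: str = "REML",
              yt: np.ndarray | None = None, Xt: np.ndarray | None = None):
        """Minimise the deviance over gamma = sg^2/se^2 in [0, inf).

        Optimises over h = gamma/(1+gamma) in [0, 1); returns
        (gamma_hat, deviance, se2_hat, beta).
        """
        import scipy.optimize

        def obj(h):
            return self.dev(h / (1.0 - h), criterion, yt, Xt)[0]

        hi = 1.0 - 1e-9
        res = scipy.optimize.minimize_scalar(
            obj, bounds=(0.0, hi), method="bounded",
            options={"xatol": 1e-12})
        h_hat = float(res.x)
        # compare against the boundary gamma = 0 explicitly
        d0 = self.dev(0.0, criterion, yt, Xt)
        d_hat = self.dev(h_hat / (1.0 - h_hat), criterion, yt, Xt)
        if d0[0] <= d_hat[0]:
            return 0.0, d0[0], d0[1], d0[2]
        gamma = h_hat / (1.0 - h_hat)
        return gamma, d_hat[0], d_hat[1], d_hat[2]
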