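"""Per-SNP association scanning against a structured-LMM null.

Three tests are offered. ``lrt`` refits the SNP model (and, where rows
differ, the null) by ML per SNP and compares deviances on chi2_1. ``wald``
fits the SNP model and tests (beta/se)^2 on chi2_1. ``score2step`` is the
fast two-step mode: the variance components are estimated once under the
no-association null (REML), the phenotypic covariance is frozen at those
estimates, and each SNP is tested by generalised least squares against the
fixed covariance — the whole genome then costs one mixed-model fit plus m
weighted regressions. Missing dosages are handled by per-SNP listwise
deletion; no imputation is attempted and the per-SNP sample size is
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .errors import AlignmentError, DegenerateDataError, SpecError
from .fitting import fit
from .likelihood import (GaussianLMM, SpectralLMM, complete_cases,
                         spectral_eligible)
from .model import ModelSpec, OptimizerConfig

logger = logging.getLogger("qtlmm")

ASSOC_COLUMNS = ["snp", "n_used", "maf", "beta", "se", "stat", "p", "test"]


@dataclass
class GenotypeTable:
    """Dosage matrix (individuals x SNPs), values in [0, 2], NaN = missing."""
    ids: list[str]
    snp_names: list[str]
    dosages: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_names)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_names)} snps")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def m(self) -> int:
        return len(self.snp_names)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(self.ids,
                             [self.snp_names[j] for j in np.flatnonzero(keep)]
                             if keep.dtype == bool else
                             [self.snp_names[j] for j in keep],
                             self.dosages[:, keep])


def maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one dosage column (missing ignored)."""
    d = np.asarray(dosages, dtype=float)
    ok = np.isfinite(d)
    if not ok.any():
        raise DegenerateDataError("all dosages missing for this SNP")
    p = float(d[ok].mean()) / 2.0
    return min(p, 1.0 - p)


def filter_snps(g: GenotypeTable, maf_min: float = 0.01) -> GenotypeTable:
    """Keep SNPs with maf >= maf_min (strictly-below threshold removed)."""
    freqs = np.array([maf(g.dosages[:, j]) for j in range(g.m)])
    keep = freqs >= maf_min
    logger.info("MAF filter at %.4g: kept %d of %d SNPs",
                maf_min, int(keep.sum()), g.m)
    return g.subset_snps(keep)


def _align_genotypes(data: pd.DataFrame, g: GenotypeTable, id_col: str
                     ) -> np.ndarray:
    idx = {i: k for k, i in enumerate(g.ids)}
    ids = data[id_col].astype(str).tolist()
    missing = sorted({i for i in ids if i not in idx})
    if missing:
        raise AlignmentError(
            f"{len(missing)} individuals have no genotypes: {missing[:10]}")
    return g.dosages[[idx[i] for i in ids], :]


def scan(null_spec: ModelSpec, data: pd.DataFrame, g: GenotypeTable,
         test: str = "lrt", workers: int = 1, seed: int | None = None,
         id_col: str | None = None,
         optimizer: OptimizerConfig | None = None) -> pd.DataFrame:
    """Association scan of every SNP in ``g`` against ``null_spec``.

    Returns a table with columns snp, n_used, maf, beta, se, stat, p, test,
    one row per SNP in input order; results are identical for any ``workers``
    value. ``id_col`` defaults to the grouping column of the first random
    term. ``seed`` is accepted for interface uniformity (the scan itself is
    deterministic).
    """
    if test not in ("lrt", "wald", "score2step"):
        raise SpecError(f"unknown test {test!r}")
    if not null_spec.constraints.is_empty():
        raise SpecError("scan expects an unconstrained null spec")
    id_col = id_col or (null_spec.random_terms[0].grouping
                        if null_spec.random_terms else "id")
    cfg = optimizer or OptimizerConfig()

    data_cc, _ = complete_cases(null_spec, data)
    dos = _align_genotypes(data_cc, g, id_col)
    if g.m == 0:
        return pd.DataFrame(columns=ASSOC_COLUMNS)

    ctx = _ScanContext(null_spec, data_cc, dos, g.snp_names, test, cfg)
    chunks = np.array_split(np.arange(g.m), max(1, min(workers, g.m)))
    if workers > 1 and g.m > 1:
        from joblib import Parallel, delayed
        rows_nested = Parallel(n_jobs=workers)(
            delayed(ctx.run_chunk)(c) for c in chunks if len(c))
    else:
        rows_nested = [ctx.run_chunk(c) for c in chunks if len(c)]
    rows = [r for chunk in rows_nested for r in chunk]
    out = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    return out


class _ScanContext:
    """Shared precomputation for a scan; picklable for worker processes."""

    def __init__(self, null_spec, data_cc, dosages, snp_names, test, cfg):
        self.spec = null_spec
        self.data = data_cc
        self.dos = dosages
        self.snp_names = snp_names
        self.test = test
        self.cfg = cfg
        self.spectral = spectral_eligible(null_spec)
        self._prepare()

    def _prepare(self):
        spec, data = self.spec, self.data
        if self.test == "score2step":
            null_fit = fit(spec, data, criterion="REML", optimizer=self.cfg)
            eng = GaussianLMM(spec, data, drop_missing=False)
            theta = np.array([null_fit.param_values[p.path]
                              for p in eng.params])
            Sigma = eng.sigma(theta)
            if not isinstance(Sigma, np.ndarray):
                Sigma = np.asarray(Sigma.todense())
            self.Sigma = Sigma
            R = scipy.linalg.cholesky(Sigma, lower=True)
            self.yw = scipy.linalg.solve_triangular(R, eng.y, lower=True)
            self.Xw = scipy.linalg.solve_triangular(R, eng.X, lower=True)
            self.y, self.X = eng.y, eng.X
        elif self.spectral:
            eng = SpectralLMM(spec, data, drop_missing=False)
            self.seng = eng
            _, self.dev_null, _, _ = eng.fit1d("ML")
        else:
            self.null_fit_ml = fit(spec, data, criterion="ML",
                                   optimizer=self.cfg)
            self.geng = GaussianLMM(spec, data, drop_missing=False)

    def run_chunk(self, snp_idx):
        return [self._one_snp(j) for j in snp_idx]

    def _one_snp(self, j):
        d = self.dos[:, j]
        ok = np.isfinite(d)
        name = self.snp_names[j]
        n_used = int(ok.sum())
        base = {"snp": name, "n_used": n_used, "maf": np.nan, "beta": np.nan,
                "se": np.nan, "stat": np.nan, "p": np.nan, "test": self.test}
        if n_used == 0:
            return base
        base["maf"] = maf(d)
        if np.nanstd(d) == 0.0:
            return base  # monomorphic among used rows: untestable
        try:
            if self.test == "score2step":
                vals = self._gls_snp(d, ok)
            elif self.spectral:
                vals = self._spectral_snp(d, ok)
            else:
                vals = self._generic_snp(d, ok)
        except (SpecError, DegenerateDataError, np.linalg.LinAlgError):
            return base
        base.update(vals)
        return base

    # -- per-test workers -------------------------------------------------

    def _gls_snp(self, d, ok):
        if ok.all():
            D = np.column_stack([self.Xw, self._whiten_full(d)])
            yw = self.yw
        else:
            idx = np.flatnonzero(ok)
            S = self.Sigma[np.ix_(idx, idx)]
            R = scipy.linalg.cholesky(S, lower=True)
            yw = scipy.linalg.solve_triangular(R, self.y[idx], lower=True)
            Xw = scipy.linalg.solve_triangular(R, self.X[idx], lower=True)
            dw = scipy.linalg.solve_triangular(R, d[idx], lower=True)
            D = np.column_stack([Xw, dw])
        beta, se = _gls_last(D, yw)
        stat = (beta / se) ** 2
        return {"beta": beta, "se": se, "stat": stat,
                "p": float(scipy.stats.chi2.sf(stat, 1))}

    def _whiten_full(self, d):
        R = getattr(self, "_R", None)
        if R is None:
            self._R = R = scipy.linalg.cholesky(self.Sigma, lower=True)
        return scipy.linalg.solve_triangular(R, d, lower=True)

    def _spectral_snp(self, d, ok):
        eng = self.seng
        if ok.all():
            dt = eng.U.T @ d
            Xt = np.column_stack([eng.Xt, dt])
            gam, dev_alt, s, beta = eng.fit1d("ML", Xt=Xt)
            dev_null = self.dev_null
            w = gam * eng.d + 1.0
            Xw = Xt / w[:, None]
            cov = np.linalg.inv(Xt.T @ Xw)
            se = float(np.sqrt(s * cov[-1, -1]))
        else:
            return self._generic_snp(d, ok, force=True)
        b = float(beta[-1])
        if self.test == "wald":
            stat = (b / se) ** 2
            return {"beta": b, "se": se, "stat": stat,
                    "p": float(scipy.stats.chi2.sf(stat, 1))}
        stat = max(0.0, dev_null - dev_alt)
        return {"beta": b, "se": se, "stat": stat,
                "p": float(scipy.stats.chi2.sf(stat, 1))}

    def _generic_snp(self, d, ok, force=False):
        data = self.data.copy()
        data["_snp_"] = d
        spec_alt = ModelSpec(
            response=self.spec.response, fixed=list(self.spec.fixed) + ["_snp_"],
            random_terms=self.spec.random_terms, residual=self.spec.residual,
            constraints=self.spec.constraints)
        sub = data if ok.all() else data.loc[ok].reset_index(drop=True)
        alt = fit(spec_alt, sub, criterion="ML", optimizer=self.cfg)
        b = float(alt.beta["_snp_"])
        se = _wald_se(spec_alt, alt, sub)
        if self.test == "wald":
            stat = (b / se) ** 2
            return {"beta": b, "se": se, "stat": stat,
                    "p": float(scipy.stats.chi2.sf(stat, 1))}
        if ok.all() and not force and hasattr(self, "null_fit_ml"):
            dev_null = self.null_fit_ml.deviance
        else:
            dev_null = fit(self.spec, sub, criterion="ML",
                           optimizer=self.cfg).deviance
        stat = max(0.0, dev_null - alt.deviance)
        return {"beta": b, "se": se, "stat": stat,
                "p": float(scipy.stats.chi2.sf(stat, 1))}


def _gls_last(D, yw):
    """OLS on whitened data; (coef, se) of the last column."""
    DtD = D.T @ D
    Dty = D.T @ yw
    cov = np.linalg.inv(DtD)
    beta = cov @ Dty
    return float(beta[-1]), float(np.sqrt(cov[-1, -1]))


def _wald_se(spec_alt, fit_res, data) -> float:
    """SE of the last fixed effect at the fitted variance parameters."""
    eng = GaussianLMM(spec_alt, data, drop_missing=False)
    theta = np.array([fit_res.param_values[p.path] for p in eng.params])
    _, ViX, _ = eng._solve_parts(theta)
    cov = np.linalg.inv(eng.X.T @ ViX)
    return float(np.sqrt(cov[-1, -1]))


def bonferroni_alpha(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide per-test threshold alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def write_assoc(table: pd.DataFrame, path) -> None:
    """Write an association table as TSV with the stable column order."""
    table.to_csv(path, sep="\t", index=False, columns=ASSOC_COLUMNS,
                 na_rep="NA")
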