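"""Synthetic family studies: pedigrees, genotypes, phenotypes.

The generator emulates the family-based study designs the fitting machinery
targets: a set of independent extended families, an additive polygenic effect
with covariance proportional to the pedigree relationship matrix A, a
household effect shared within each family, and i.i.d. (or sex-specific)
residuals. The total phenotypic variance is normalised to 1 so that the
heritability h2 and household fraction c2 are directly the simulated variance
fractions. Genotypes are produced by gene dropping: founders draw two alleles
i.i.d. Bernoulli(maf), descendants inherit one uniformly chosen allele per
parent, and MZ-twin members copy their co-twin's genotype; such SNPs are null
(independent of the polygenic term) unless a causal dosage is added
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covstruct import factor_relmat
from .errors import SpecError
from .pedigree import Pedigree, PedigreeRecord, incidence_from_factor
from .relmatrix import RelMatrix


@dataclass
class SexSpecific:
    """Sex-specific architecture: genetic sds per sex, their genetic
    correlation, and sex-specific residual sds."""
    sg_male: float = 0.7
    sg_female: float = 0.7
    rho_g: float = 1.0
    sde_male: float = 0.7
    sde_female: float = 0.7

    def __post_init__(self):
        if abs(self.rho_g) > 1:
            raise SpecError("|rho_g| must be <= 1")


@dataclass
class SimConfig:
    """Study-design and architecture parameters for one synthetic study.

    Defaults describe a mid-sized family study: 30 nuclear families of 10
    (two founders, eight children), a trait with heritability 0.5 and a
    household fraction 0.2, SNPs at minor allele frequency 0.3.
    """
    n_families: int = 30
    family_structure: str = "nuclear"  # nuclear | three_generation | with_mz_twins
    k_children: int = 8
    mz_rate: float = 0.0               # P(sibship starts with an MZ pair)
    h2: float = 0.5
    c2_household: float = 0.2
    sex_specific: SexSpecific | None = None
    beta: dict = field(default_factory=lambda: {
        "intercept": 0.0, "age": 0.01, "sex_male": 0.2})
    maf: float = 0.3
    m_snps: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.sex_specific is None and self.h2 + self.c2_household > 1:
            raise SpecError("h2 + c2 must be <= 1")
        if not 0 < self.maf <= 0.5:
            raise SpecError("maf must be in (0, 0.5]")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-operation substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Independent families of the configured structure, sexes randomised."""
    rng = _rng(cfg.seed, 1)
    records: list[PedigreeRecord] = []

    def child_sex():
        return "male" if rng.random() < 0.5 else "female"

    for f in range(cfg.n_families):
        fam = f"F{f:03d}"
        if cfg.family_structure in ("nuclear", "with_mz_twins"):
            pa, ma = f"{fam}_P1", f"{fam}_P2"
            records.append(PedigreeRecord(fam, pa, None, None, "male"))
            records.append(PedigreeRecord(fam, ma, None, None, "female"))
            mz_here = (cfg.family_structure == "with_mz_twins"
                       and cfg.k_children >= 2 and rng.random() < cfg.mz_rate)
            twin_sex = child_sex()
            for c in range(cfg.k_children):
                cid = f"{fam}_C{c + 1}"
                if mz_here and c < 2:
                    records.append(PedigreeRecord(
                        fam, cid, pa, ma, twin_sex, mz_group=f"{fam}_MZ1"))
                else:
                    records.append(PedigreeRecord(fam, cid, pa, ma, child_sex()))
        elif cfg.family_structure == "three_generation":
            gf, gm = f"{fam}_G1", f"{fam}_G2"
            records.append(PedigreeRecord(fam, gf, None, None, "male"))
            records.append(PedigreeRecord(fam, gm, None, None, "female"))
            mid = f"{fam}_P1"
            mid_sex = child_sex()
            records.append(PedigreeRecord(fam, mid, gf, gm, mid_sex))
            spouse = f"{fam}_P2"
            spouse_sex = "female" if mid_sex == "male" else "male"
            records.append(PedigreeRecord(fam, spouse, None, None, spouse_sex))
            father, mother = (mid, spouse) if mid_sex == "male" else (spouse, mid)
            for c in range(cfg.k_children):
                records.append(PedigreeRecord(
                    fam, f"{fam}_C{c + 1}", father, mother, child_sex()))
        else:
            raise SpecError(
                f"unknown family structure {cfg.family_structure!r}")
    return Pedigree(records)


def simulate_genotypes(ped: Pedigree, m_snps: int, maf: float, seed: int = 0):
    """Gene-dropped dosages (0/1/2) for every pedigree member.

    Founders draw two alleles i.i.d. Bernoulli(maf); each non-founder
    inherits one uniformly chosen allele from each parent; MZ-group members
    share one genotype. Returns a GenotypeTable.
    """
    from .scan import GenotypeTable

    rng = _rng(seed, 2)
    rep: dict[str, str] = {}
    first: dict[str, str] = {}
    for r in ped:
        rep[r.id] = (r.id if r.mz_group is None
                     else first.setdefault(r.mz_group, r.id))
    alleles: dict[str, np.ndarray] = {}  # genome id -> (2, m) 0/1 array
    for iid in ped.topological_order():
        g = rep[iid]
        if g in alleles:
            continue
        r = ped.record(g)
        if r.father_id is None and r.mother_id is None:
            alleles[g] = (rng.random((2, m_snps)) < maf).astype(np.int8)
        else:
            pair = np.empty((2, m_snps), dtype=np.int8)
            for slot, parent in enumerate((r.father_id, r.mother_id)):
                if parent is None:
                    pair[slot] = (rng.random(m_snps) < maf).astype(np.int8)
                else:
                    src = alleles[rep[parent]]
                    pick = rng.integers(0, 2, size=m_snps)
                    pair[slot] = src[pick, np.arange(m_snps)]
            alleles[g] = pair
    ids = ped.ids
    dosages = np.array([alleles[rep[i]].sum(axis=0) for i in ids], dtype=float)
    names = [f"snp{j + 1}" for j in range(m_snps)]
    return GenotypeTable(ids=ids, snp_names=names, dosages=dosages)


def _generation_depth(ped: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}
    for iid in ped.topological_order():
        r = ped.record(iid)
        ds = [depth[p] + 1 for p in (r.father_id, r.mother_id) if p is not None]
        depth[iid] = max(ds) if ds else 0
    return depth


def simulate_phenotype(ped: Pedigree, A: RelMatrix, cfg: SimConfig,
                       causal: tuple[np.ndarray, float] | None = None
                       ) -> pd.DataFrame:
    """Phenotype table (id, family, hhid, sex, age, trait) under cfg.

    y = X beta + u + c + e with Var(u) = h2 * A, a household effect shared
    within each family with variance c2, and residual variance 1 - h2 - c2.
    Under ``sex_specific`` the genetic effect has covariance
    A ⊙ (S K S') built from (sg_male, sg_female, rho_g) and the residual sd
    differs by sex. ``causal`` = (dosage vector over ped ids, effect size)
    adds a genuine SNP effect.
    """
    rng = _rng(cfg.seed, 3)
    ids = ped.ids
    n = len(ids)
    A_sub = A.subset(ids)

    depth = _generation_depth(ped)
    age = np.array([rng.uniform(*((60.0, 80.0) if depth[i] == 0 and
                                  cfg.family_structure == "three_generation"
                                  else (35.0, 60.0) if depth[i] == 0
                                  else (35.0, 60.0) if depth[i] == 1 and
                                  cfg.family_structure == "three_generation"
                                  else (18.0, 35.0)))
                    for i in ids])
    sex = np.array([ped.record(i).sex for i in ids])
    male = (sex == "male").astype(float)

    b = cfg.beta
    xb = (b.get("intercept", 0.0) + b.get("age", 0.0) * (age - age.mean())
          + b.get("sex_male", 0.0) * male)

    if cfg.sex_specific is None:
        L = factor_relmat(A_sub).L
        u = np.sqrt(cfg.h2) * (L @ rng.standard_normal(L.shape[1]))
        e = np.sqrt(1.0 - cfg.h2 - cfg.c2_household) * rng.standard_normal(n)
    else:
        ss = cfg.sex_specific
        levs = ["female", "male"]
        S = incidence_from_factor(list(sex), levs)
        K = np.array([[ss.sg_female ** 2,
                       ss.rho_g * ss.sg_female * ss.sg_male],
                      [ss.rho_g * ss.sg_female * ss.sg_male,
                       ss.sg_male ** 2]])
        G = A_sub.values * (S @ K @ S.T)
        Lg = factor_relmat(RelMatrix(ids, G, validate=False)).L
        u = Lg @ rng.standard_normal(Lg.shape[1])
        sde = np.where(male == 1.0, ss.sde_male, ss.sde_female)
        e = sde * rng.standard_normal(n)

    fam = [ped.record(i).family_id for i in ids]
    hh = {f: rng.standard_normal() for f in dict.fromkeys(fam)}
    c = np.sqrt(cfg.c2_household) * np.array([hh[f] for f in fam]) \
        if cfg.sex_specific is None else np.zeros(n)

    y = xb + u + c + e
    if causal is not None:
        dosage, beta_snp = causal
        y = y + beta_snp * np.asarray(dosage, dtype=float)
    return pd.DataFrame({
        "id": ids, "family": fam, "hhid": [f"H_{f}" for f in fam],
        "sex": sex, "age": age, "trait": y})


def simulate_study(cfg: SimConfig):
    """Convenience wrapper: pedigree, A matrix, phenotypes, genotypes."""
    from .pedigree import additive_relationship

    ped = simulate_pedigree(cfg)
    A = additive_relationship(ped)
    pheno = simulate_phenotype(ped, A, cfg)
    geno = simulate_genotypes(ped, cfg.m_snps, cfg.maf, cfg.seed)
    return ped, A, pheno, geno
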