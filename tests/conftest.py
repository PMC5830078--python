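import numpy as np
import pandas as pd
import pytest

from qtlmm import (ModelSpec, RandomTerm, SimConfig, additive_relationship,
                   simulate_study)


@pytest.fixture(scope="session")
def trio_ped_file(tmp_path_factory):
    """Founder couple + child, LINKAGE layout."""
    p = tmp_path_factory.mktemp("ped") / "trio.ped"
    p.write_text("FAM1 dad 0 0 1\nFAM1 mum 0 0 2\nFAM1 kid dad mum 1\n")
    return p


@pytest.fixture(scope="session")
def small_study():
    """5 nuclear families x 6 members (n=30) with phenotypes and SNPs."""
    cfg = SimConfig(n_families=5, k_children=4, m_snps=20, seed=101)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def medium_study():
    """30 families x 10 members (n=300), the parameter-recovery design."""
    cfg = SimConfig(seed=2024)
    return simulate_study(cfg)


@pytest.fixture
def polygenic_spec():
    def make(A, household=False):
        terms = [RandomTerm(grouping="id", relmat=A, name="genetic")]
        if household:
            terms.append(RandomTerm(grouping="hhid", name="household"))
        return ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=terms)
    return make


def random_pedigree(rng, n_families=3, max_children=4, p_mz=0.0):
    """Small random multi-generation pedigree for property tests."""
    from qtlmm import Pedigree, PedigreeRecord
    records = []
    for f in range(n_families):
        fam = f"F{f}"
        pa, ma = f"{fam}_a", f"{fam}_b"
        records.append(PedigreeRecord(fam, pa, None, None, "male"))
        records.append(PedigreeRecord(fam, ma, None, None, "female"))
        kids = []
        k = rng.integers(1, max_children + 1)
        mz = rng.random() < p_mz and k >= 2
        sex_tw = "male" if rng.random() < 0.5 else "female"
        for c in range(k):
            cid = f"{fam}_c{c}"
            if mz and c < 2:
                records.append(PedigreeRecord(fam, cid, pa, ma, sex_tw,
                                              mz_group=f"{fam}_mz"))
            else:
                records.append(PedigreeRecord(
                    fam, cid, pa, ma,
                    "male" if rng.random() < 0.5 else "female"))
            kids.append(cid)
        # possibly a grandchild via the first kid and an in-law
        if rng.random() < 0.5 and kids:
            sp_id = f"{fam}_s"
            kid0 = records[[r.id for r in records].index(kids[0])]
            sp_sex = "female" if kid0.sex == "male" else "male"
            records.append(PedigreeRecord(fam, sp_id, None, None, sp_sex))
            father, mother = ((kids[0], sp_id) if kid0.sex == "male"
                              else (sp_id, kids[0]))
            records.append(PedigreeRecord(fam, f"{fam}_g", father, mother,
                                          "male"))
    return Pedigree(records)
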