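import numpy as np
import pytest

from qtlmm import (Pedigree, PedigreeRecord, PedigreeError, RelMatrix,
                   additive_relationship, densify, incidence_from_factor,
                   matrix_sparsity, read_pedigree)
from conftest import random_pedigree


def rec(fam, iid, f=None, m=None, sex="male", mz=None):
    return PedigreeRecord(fam, iid, f, m, sex, mz)


class TestReadPedigree:
    def test_trio_parses(self, trio_ped_file):
        ped = read_pedigree(trio_ped_file)
        assert len(ped) == 3
        kid = ped.record("kid")
        assert kid.father_id == "dad" and kid.mother_id == "mum"
        assert ped.ids == ["dad", "mum", "kid"]  # row order preserved

    def test_self_parent_is_cycle_error(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("F x x 0 1\n")
        with pytest.raises(PedigreeError, match="cycle"):
            read_pedigree(p)

    def test_unknown_parent_named_in_error(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("F a 99 0 1\n")
        with pytest.raises(PedigreeError, match="99"):
            read_pedigree(p)

    def test_two_generation_cycle_listed(self):
        with pytest.raises(PedigreeError, match="->"):
            Pedigree([rec("F", "a", "b"), rec("F", "b", "a")])


class TestAdditiveRelationship:
    def test_unrelated_founders_identity(self):
        ped = Pedigree([rec("F", "a"), rec("F", "b", sex="female")])
        A = additive_relationship(ped)
        assert np.allclose(A.values, np.eye(2))

    def test_basic_relative_pairs(self):
        ped = Pedigree([
            rec("F", "pa"), rec("F", "ma", sex="female"),
            rec("F", "ma2", sex="female"),
            rec("F", "s1", "pa", "ma"), rec("F", "s2", "pa", "ma"),
            rec("F", "h1", "pa", "ma2"),
        ])
        A = additive_relationship(ped)
        i = {x: k for k, x in enumerate(A.ids)}
        assert A.values[i["pa"], i["s1"]] == pytest.approx(0.5)   # parent-offspring
        assert A.values[i["s1"], i["s2"]] == pytest.approx(0.5)   # full sibs
        assert A.values[i["s1"], i["h1"]] == pytest.approx(0.25)  # half sibs

    def test_fullsib_mating_inbreeding(self):
        ped = Pedigree([
            rec("F", "pa"), rec("F", "ma", sex="female"),
            rec("F", "s1", "pa", "ma"), rec("F", "s2", "pa", "ma", "female"),
            rec("F", "kid", "s1", "s2"),
        ])
        A = additive_relationship(ped)
        i = {x: k for k, x in enumerate(A.ids)}
        assert A.values[i["kid"], i["kid"]] == pytest.approx(1.25)

    def test_mz_twins_unit_block_and_rank_deficiency(self):
        ped = Pedigree([
            rec("F", "pa"), rec("F", "ma", sex="female"),
            rec("F", "t1", "pa", "ma", mz="tw"),
            rec("F", "t2", "pa", "ma", mz="tw"),
        ])
        A = additive_relationship(ped)
        i = {x: k for k, x in enumerate(A.ids)}
        blk = A.values[np.ix_([i["t1"], i["t2"]], [i["t1"], i["t2"]])]
        assert np.allclose(blk, 1.0)
        assert np.linalg.matrix_rank(A.values) < A.n
        # still PSD
        assert np.linalg.eigvalsh(A.values)[0] >= -1e-8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, n_families=2, p_mz=0.5)
        A1 = additive_relationship(ped)
        order = rng.permutation(len(ped))
        ped2 = Pedigree([ped.records[k] for k in order])
        A2 = additive_relationship(ped2)
        pos = {x: k for k, x in enumerate(A2.ids)}
        sel = [pos[x] for x in A1.ids]
        assert np.allclose(A1.values, A2.values[np.ix_(sel, sel)])

    def test_every_random_pedigree_is_psd(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            ped = random_pedigree(rng, n_families=int(rng.integers(1, 4)),
                                  p_mz=0.3)
            A = additive_relationship(ped)
            w = np.linalg.eigvalsh(0.5 * (A.values + A.values.T))
            assert w[0] >= -1e-8

    def test_gene_dropping_oracle_small_pedigree(self):
        # Monte-Carlo IBD sharing (2x kinship) agrees with the recursion
        rng = np.random.default_rng(42)
        ped = random_pedigree(rng, n_families=1, max_children=3, p_mz=0.0)
        A = additive_relationship(ped)
        est, se = _gene_drop_relationship(ped, n_rep=4000, rng=rng)
        diff = np.abs(est - A.values)
        assert np.all(diff <= 3 * se + 1e-12)


def _gene_drop_relationship(ped, n_rep, rng):
    """Independent oracle: drop two labelled alleles per founder, estimate
    A_ij = 2 * P(random allele of i IBD to random allele of j) as the mean
    number of shared alleles / 2 ... computed as expected IBD dosage."""
    ids = ped.ids
    n = len(ids)
    lab = {}
    next_allele = [0]
    alleles = {}
    order = ped.topological_order()
    out = np.zeros((n, n))
    A_acc = np.zeros((n, n))
    for _ in range(n_rep):
        alleles = {}
        c = 0
        for iid in order:
            r = ped.record(iid)
            if r.father_id is None and r.mother_id is None:
                alleles[iid] = (c, c + 1)
                c += 2
            else:
                fa = alleles[r.father_id]
                mo = alleles[r.mother_id]
                alleles[iid] = (fa[rng.integers(2)], mo[rng.integers(2)])
        # MZ twins share a genome
        for r in ped:
            if r.mz_group is not None:
                first = next(x for x in ped if x.mz_group == r.mz_group)
                alleles[r.id] = alleles[first.id]
        av = np.array([alleles[i] for i in ids])
        for i in range(n):
            share = ((av[i, 0] == av[:, 0]).astype(float)
                     + (av[i, 0] == av[:, 1])
                     + (av[i, 1] == av[:, 0])
                     + (av[i, 1] == av[:, 1]))
            A_acc[i] += share / 2.0
    est = A_acc / n_rep
    se = np.sqrt(np.maximum(est * (2.0 - est), 1e-4) / n_rep)
    return est, se


class TestIncidence:
    def test_examples(self):
        Z = incidence_from_factor(["a", "a", "b"], ["a", "b"])
        assert np.array_equal(Z, [[1, 0], [1, 0], [0, 1]])
        Z2 = incidence_from_factor(["x", "y", "z"], ["x", "y", "z"])
        assert np.array_equal(Z2, np.eye(3))
        with pytest.raises(ValueError, match="'c'"):
            incidence_from_factor(["a", "c"], ["a", "b"])


class TestSparsityAndDensify:
    def test_sparsity_examples(self):
        assert matrix_sparsity(RelMatrix(list("abcdefghij"), np.eye(10))) == 0.9
        ones = RelMatrix(["a", "b"], np.ones((2, 2)), validate=False)
        assert matrix_sparsity(ones) == 0.0

    def test_simulated_pedigree_matrix_is_sparse(self):
        from qtlmm import SimConfig, simulate_pedigree
        ped = simulate_pedigree(SimConfig(n_families=20, k_children=3, seed=9))
        A = additive_relationship(ped)
        assert A.n == 100
        assert A.sparsity >= 0.7

    def test_densify_noop_at_current_sparsity(self):
        A = RelMatrix(list("abcde"), np.eye(5))
        out = densify(A, A.sparsity, fill_value=0.05, seed=0)
        assert np.array_equal(out.values, A.values)

    def test_densify_to_zero_fills_everything(self):
        A = RelMatrix([f"i{k}" for k in range(10)], np.eye(10))
        out = densify(A, 0.0, fill_value=0.05, seed=0)
        assert matrix_sparsity(out) == 0.0

    def test_densify_hits_target_and_stays_psd(self):
        from qtlmm import SimConfig, simulate_pedigree
        ped = simulate_pedigree(SimConfig(n_families=30, k_children=3, seed=3))
        A = additive_relationship(ped)
        for target in (0.8, 0.6, 0.4):
            out = densify(A, target, fill_value=0.01, seed=7)
            assert abs(out.sparsity - target) <= 0.01
            assert np.linalg.eigvalsh(out.values)[0] >= -1e-10

    def test_densify_reproducible_and_validates_target(self):
        A = RelMatrix([f"i{k}" for k in range(12)], np.eye(12))
        a = densify(A, 0.5, fill_value=0.02, seed=5)
        b = densify(A, 0.5, fill_value=0.02, seed=5)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ValueError, match="exceeds"):
            densify(a, 0.95, fill_value=0.02, seed=5)
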