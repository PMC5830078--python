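import numpy as np
import pandas as pd
import pytest

from qtlmm import (ConstraintSet, ModelSpec, OptimizerConfig, RandomTerm,
                   RelMatrix, ResidualSpec, SexSpecific, SimConfig, SpecError,
                   fit, fit_gxe, heritability, simulate_phenotype,
                   simulate_study)
from qtlmm.likelihood import GaussianLMM

from oracles import anova_oneway_reml


class TestFitBasics:
    def test_constant_response_degenerate_boundary(self, small_study):
        ped, A, pheno, _ = small_study
        pheno = pheno.copy()
        pheno["trait"] = 7.5
        spec = ModelSpec(response="trait",
                         random_terms=[RandomTerm(grouping="id", relmat=A)])
        res = fit(spec, pheno)
        assert res.converged
        assert res.beta["(intercept)"] == pytest.approx(7.5)
        assert all(v == 0.0 for v in res.param_values.values())
        assert all(res.boundary_flags.values())

    def test_missing_rows_dropped_and_counted(self, small_study):
        ped, A, pheno, _ = small_study
        pheno = pheno.copy()
        pheno.loc[pheno.index[:4], "trait"] = np.nan
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A)])
        res = fit(spec, pheno)
        assert res.n_dropped == 4
        assert res.n_obs == len(pheno) - 4

    def test_balanced_oneway_matches_anova(self):
        """Interior REML estimates equal the closed-form mean-square
        estimators on balanced one-way designs (20 random designs)."""
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(20):
            g, r = int(rng.integers(8, 25)), int(rng.integers(3, 8))
            su, se = rng.uniform(0.5, 1.5), rng.uniform(0.5, 1.5)
            y = (np.repeat(rng.normal(0, su, g), r)
                 + rng.normal(0, se, g * r))
            df = pd.DataFrame({
                "y": y, "grp": np.repeat([f"g{i}" for i in range(g)], r)})
            su2_hat, se2_hat = anova_oneway_reml(y, g, r)
            if su2_hat <= 0:
                continue  # boundary case: closed form not applicable
            spec = ModelSpec(response="y",
                             random_terms=[RandomTerm(grouping="grp")])
            res = fit(spec, df)
            assert res.param_values["grp.sd"] ** 2 == pytest.approx(
                su2_hat, abs=1e-6)
            assert res.param_values["residual.sd"] ** 2 == pytest.approx(
                se2_hat, abs=1e-6)
            checked += 1
        assert checked >= 15

    def test_two_family_pedigree_matches_grid_oracle(self):
        """Fit equals a brute-force grid+polish minimiser over (sg, se)."""
        import scipy.optimize

        cfg = SimConfig(n_families=2, k_children=18, seed=17)  # n = 40
        ped, A, pheno, _ = simulate_study(cfg)
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  name="genetic")])
        res = fit(spec, pheno)
        eng = GaussianLMM(spec, pheno)

        def dev(v):
            return eng.neg2(np.asarray(v), "REML")

        grid = [(sg, se) for sg in np.linspace(0.05, 2.0, 25)
                for se in np.linspace(0.05, 2.0, 25)]
        best = min(grid, key=dev)
        polished = scipy.optimize.minimize(
            dev, best, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12})
        assert res.param_values["genetic.sd"] == pytest.approx(
            abs(polished.x[0]), abs=1e-3)
        assert res.param_values["residual.sd"] == pytest.approx(
            abs(polished.x[1]), abs=1e-3)

    def test_row_permutation_invariance(self, medium_study):
        ped, A, pheno, _ = medium_study
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  name="genetic"),
                                       RandomTerm(grouping="hhid",
                                                  name="household")])
        res1 = fit(spec, pheno)
        rng = np.random.default_rng(4)
        shuffled = pheno.iloc[rng.permutation(len(pheno))].reset_index(
            drop=True)
        res2 = fit(spec, shuffled)
        for k in res1.param_values:
            assert res1.param_values[k] == pytest.approx(
                res2.param_values[k], abs=1e-6)

    def test_scale_equivariance(self, small_study):
        ped, A, pheno, _ = small_study
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  name="genetic")])
        res1 = fit(spec, pheno)
        scaled = pheno.copy()
        scaled["trait"] = scaled["trait"] * 3.7
        res2 = fit(spec, scaled)
        for k in res1.param_values:
            assert res2.param_values[k] == pytest.approx(
                3.7 * res1.param_values[k], abs=1e-6)
        assert heritability(res2) == pytest.approx(heritability(res1),
                                                   abs=1e-6)


class TestConstraints:
    def test_fixed_parameter_removed_from_search(self, small_study):
        ped, A, pheno, _ = small_study
        spec = ModelSpec(
            response="trait", fixed=["age", "sex"],
            random_terms=[RandomTerm(grouping="id", relmat=A, name="genetic")],
            constraints=ConstraintSet(fixes=[("genetic.sd", 0.0)]))
        res = fit(spec, pheno)
        assert res.param_values["genetic.sd"] == 0.0
        free = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  name="genetic")])
        assert res.n_params == fit(free, pheno).n_params - 1

    def test_unknown_path_rejected(self, small_study):
        ped, A, pheno, _ = small_study
        spec = ModelSpec(
            response="trait",
            random_terms=[RandomTerm(grouping="id", relmat=A, name="genetic")],
            constraints=ConstraintSet(fixes=[("nope.sd", 1.0)]))
        with pytest.raises(SpecError, match="nope.sd"):
            fit(spec, pheno)

    def test_equality_aliases_exact(self):
        cfg = SimConfig(n_families=20, k_children=4,
                        sex_specific=SexSpecific(), seed=31)
        ped, A, pheno, _ = simulate_study(cfg)
        spec = ModelSpec(
            response="trait", fixed=["age", "sex"],
            random_terms=[RandomTerm(grouping="id", relmat=A,
                                     slopes_factor="sex", name="g")],
            constraints=ConstraintSet(
                fixes=[("g.cor.female.male", 1.0)],
                equalities=[("g.sd.female", "g.sd.male")]))
        res = fit(spec, pheno, criterion="ML")
        assert res.param_values["g.sd.female"] == res.param_values["g.sd.male"]
        assert res.param_values["g.cor.female.male"] == 1.0


class TestGxE:
    def test_triple_has_expected_free_parameters(self):
        cfg = SimConfig(n_families=25, k_children=4,
                        sex_specific=SexSpecific(0.8, 0.5, 0.4, 0.6, 0.9),
                        seed=7)
        ped, A, pheno, _ = simulate_study(cfg)
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  slopes_factor="sex",
                                                  name="genetic")],
                         residual=ResidualSpec(factor="sex"))
        m3, m4, m5 = fit_gxe(spec, pheno)
        assert m3.criterion == m4.criterion == m5.criterion == "ML"
        assert m4.n_params == m3.n_params - 1
        assert m5.n_params == m3.n_params - 1
        # nesting: the free model fits at least as well
        assert m3.deviance <= m4.deviance + 1e-6
        assert m3.deviance <= m5.deviance + 1e-6

    def test_double_constraint_reproduces_polygenic_fit(self):
        """rho_g=1 + equal sds + homoscedastic residual is exactly the
        polygenic model; deviances agree to 1e-6 on identical data."""
        cfg = SimConfig(n_families=25, k_children=4, h2=0.5,
                        c2_household=0.0, seed=13)
        ped, A, pheno, _ = simulate_study(cfg)
        constrained = ModelSpec(
            response="trait", fixed=["age", "sex"],
            random_terms=[RandomTerm(grouping="id", relmat=A,
                                     slopes_factor="sex", name="genetic")],
            constraints=ConstraintSet(
                fixes=[("genetic.cor.female.male", 1.0)],
                equalities=[("genetic.sd.female", "genetic.sd.male")]))
        polygenic = ModelSpec(
            response="trait", fixed=["age", "sex"],
            random_terms=[RandomTerm(grouping="id", relmat=A,
                                     name="genetic")])
        for crit in ("ML", "REML"):
            d1 = fit(constrained, pheno, criterion=crit).deviance
            d2 = fit(polygenic, pheno, criterion=crit).deviance
            assert d1 == pytest.approx(d2, abs=1e-6)

    def test_native_hetero_residual_equals_dummy_trick(self):
        """Group-specific residual variances fitted natively agree with the
        workaround that adds a per-individual diagonal random effect per
        group on top of a homoscedastic residual (total group variances and
        maximised likelihood match)."""
        cfg = SimConfig(n_families=25, k_children=4,
                        sex_specific=SexSpecific(0.7, 0.7, 1.0, 0.5, 1.0),
                        seed=23)
        ped, A, pheno, _ = simulate_study(cfg)
        pheno = pheno.copy()
        pheno["rid"] = pheno["id"]
        native = ModelSpec(
            response="trait", fixed=["age", "sex"],
            random_terms=[RandomTerm(grouping="id", relmat=A, name="genetic")],
            residual=ResidualSpec(factor="sex"))
        dummy = ModelSpec(
            response="trait", fixed=["age", "sex"],
            random_terms=[
                RandomTerm(grouping="id", relmat=A, name="genetic"),
                RandomTerm(grouping="rid", slopes_factor="sex", name="dummy")],
            constraints=ConstraintSet(
                fixes=[("dummy.cor.female.male", 0.0)]))
        rn = fit(native, pheno, criterion="ML")
        rd = fit(dummy, pheno, criterion="ML",
                 optimizer=OptimizerConfig(n_starts=3))
        assert rd.deviance == pytest.approx(rn.deviance, abs=1e-3)
        for lev in ("female", "male"):
            tot_native = rn.param_values[f"residual.sd.{lev}"] ** 2
            tot_dummy = (rd.param_values[f"dummy.sd.{lev}"] ** 2
                         + rd.param_values["residual.sd"] ** 2)
            assert tot_dummy == pytest.approx(tot_native, abs=5e-2)


class TestHeritability:
    def test_closed_forms(self):
        from qtlmm.covstruct import ParamBlock
        from qtlmm.model import FitResult

        def mk(sg, sc, se):
            params = {"genetic": ParamBlock(sds=[sg])}
            if sc is not None:
                params["household"] = ParamBlock(sds=[sc])
            return FitResult(
                beta=pd.Series([0.0], index=["(intercept)"]), params=params,
                residual=ResidualSpec(sd=se), param_values={},
                deviance=0.0, criterion="REML", converged=True, n_obs=10,
                n_dropped=0, n_params=3, boundary_flags={})

        assert heritability(mk(np.sqrt(2), None, np.sqrt(2))) == pytest.approx(0.5)
        assert heritability(mk(1.0, 1.0, np.sqrt(2))) == pytest.approx(0.25)
        assert heritability(mk(0.0, None, 1.0)) == 0.0

    def test_heteroscedastic_residual_rejected(self):
        from qtlmm.covstruct import ParamBlock
        from qtlmm.model import FitResult
        res = FitResult(
            beta=pd.Series([0.0], index=["(intercept)"]),
            params={"genetic": ParamBlock(sds=[1.0])},
            residual=ResidualSpec(factor="sex", sds={"m": 1.0, "f": 2.0}),
            param_values={}, deviance=0.0, criterion="REML", converged=True,
            n_obs=10, n_dropped=0, n_params=3, boundary_flags={})
        with pytest.raises(SpecError, match="group"):
            heritability(res)


class TestParameterRecovery:
    def test_mean_estimates_near_truth(self):
        """Moderate replicate check of h2/c2 recovery at the 30x10 design
        (the full-scale version runs in the acceptance suite)."""
        h2s, c2s = [], []
        for seed in range(20):
            cfg = SimConfig(seed=seed + 500)
            ped, A, pheno, _ = simulate_study(cfg)
            spec = ModelSpec(
                response="trait", fixed=["age", "sex"],
                random_terms=[RandomTerm(grouping="id", relmat=A,
                                         name="genetic"),
                              RandomTerm(grouping="hhid", name="household")])
            res = fit(spec, pheno)
            tot = sum(v ** 2 for v in res.param_values.values())
            h2s.append(res.param_values["genetic.sd"] ** 2 / tot)
            c2s.append(res.param_values["household.sd"] ** 2 / tot)
        assert abs(np.mean(h2s) - 0.5) < 0.08
        assert abs(np.mean(c2s) - 0.2) < 0.08
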