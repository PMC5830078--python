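import numpy as np
import pandas as pd
import pytest
import scipy.stats

from qtlmm import (ConstraintSet, ModelSpec, OptimizerConfig, RandomTerm,
                   ResidualSpec, SexSpecific, SimConfig, SpecError, fit,
                   fit_gxe, gxe_test_pair, heritability, lrt, profile_ci,
                   rlrt_sim, simulate_study)
from qtlmm.inference import mixture_sf
from qtlmm.model import FitResult


def _fake_fit(dev, n_params, criterion="ML", n_obs=100):
    return FitResult(beta=pd.Series(dtype=float), params={},
                     residual=ResidualSpec(sd=1.0), param_values={},
                     deviance=dev, criterion=criterion, converged=True,
                     n_obs=n_obs, n_dropped=0, n_params=n_params,
                     boundary_flags={})


class TestLRT:
    def test_identical_fits_stat_zero_p_one(self):
        t = lrt(_fake_fit(100.0, 3), _fake_fit(100.0, 4))
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_chisq_quantile(self):
        t = lrt(_fake_fit(103.84, 3), _fake_fit(100.0, 4))
        assert t.p_value == pytest.approx(0.050, abs=2e-3)

    def test_boundary_mixture_one_sided(self):
        t = lrt(_fake_fit(102.706, 3), _fake_fit(100.0, 4),
                null_on_boundary=True)
        assert t.method == "lrt_mixture"
        assert t.p_value == pytest.approx(0.050, abs=2e-3)

    def test_criterion_mismatch_rejected(self):
        with pytest.raises(SpecError, match="criterion"):
            lrt(_fake_fit(1.0, 3, "REML"), _fake_fit(0.0, 4, "ML"))

    def test_n_mismatch_rejected(self):
        with pytest.raises(SpecError, match="data"):
            lrt(_fake_fit(1.0, 3, n_obs=50), _fake_fit(0.0, 4, n_obs=60))

    def test_naive_chisq_conservative_vs_mixture(self):
        # p_naive >= p_mixture pointwise for a variance-component test
        for stat in np.linspace(0.01, 12.0, 60):
            assert scipy.stats.chi2.sf(stat, 1) >= mixture_sf(stat, 1)

    def test_statistic_invariant_to_covariate_affine_transform(self,
                                                               small_study):
        ped, A, pheno, _ = small_study
        def pair(data):
            null = ModelSpec(response="trait", fixed=["sex"],
                             random_terms=[RandomTerm(grouping="id",
                                                      relmat=A)])
            alt = ModelSpec(response="trait", fixed=["sex", "age"],
                            random_terms=[RandomTerm(grouping="id",
                                                     relmat=A)])
            return lrt(fit(null, data, "ML"), fit(alt, data, "ML"))
        t1 = pair(pheno)
        scaled = pheno.copy()
        scaled["age"] = 3.0 * scaled["age"] - 40.0
        t2 = pair(scaled)
        assert t2.statistic == pytest.approx(t1.statistic, abs=1e-6)


class TestRLRT:
    def test_same_seed_same_p(self, small_study):
        ped, A, pheno, _ = small_study
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A)])
        t1 = rlrt_sim(spec, 0, pheno, n_sim=60, seed=5)
        t2 = rlrt_sim(spec, 0, pheno, n_sim=60, seed=5)
        assert t1.p_value == t2.p_value
        assert t1.note is not None  # n_sim < 100 flagged

    def test_general_and_fast_paths_agree_in_distribution(self, small_study):
        """The generic parametric-bootstrap path and the rotated fast path
        compute the same statistic on the same data."""
        ped, A, pheno, _ = small_study
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A)])
        fast = rlrt_sim(spec, 0, pheno, n_sim=10, seed=1)
        alt = fit(spec, pheno)
        null = fit(ModelSpec(response="trait", fixed=["age", "sex"]), pheno)
        obs = max(0.0, null.deviance - alt.deviance)
        assert fast.statistic == pytest.approx(obs, abs=1e-6)

    def test_power_at_high_heritability(self):
        cfg = SimConfig(n_families=30, k_children=8, h2=0.8,
                        c2_household=0.0, seed=303)
        ped, A, pheno, _ = simulate_study(cfg)
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A)])
        t = rlrt_sim(spec, 0, pheno, n_sim=199, seed=8)
        assert t.p_value <= 0.01


class TestProfileCI:
    def test_point_estimate_inside_and_levels_nested(self, medium_study):
        ped, A, pheno, _ = medium_study
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  name="genetic")])
        res = fit(spec, pheno)
        ci95 = profile_ci(spec, pheno, res, "h2", 0.95)
        ci99 = profile_ci(spec, pheno, res, "h2", 0.99)
        h2 = heritability(res)
        assert ci95.lower <= h2 <= ci95.upper
        assert ci99.lower <= ci95.lower and ci95.upper <= ci99.upper

    def test_sd_parameter_profile(self, medium_study):
        ped, A, pheno, _ = medium_study
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  name="genetic")])
        res = fit(spec, pheno)
        ci = profile_ci(spec, pheno, res, "genetic.sd", 0.95)
        assert ci.lower <= res.param_values["genetic.sd"] <= ci.upper

    def test_generic_and_spectral_profiles_agree(self, medium_study):
        ped, A, pheno, _ = medium_study
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  name="genetic")])
        res_s = fit(spec, pheno)
        ci_s = profile_ci(spec, pheno, res_s, "h2", 0.95)
        res_g = fit(spec, pheno, optimizer=OptimizerConfig(method="generic"))
        from qtlmm.inference import _h2_profile_function
        prof_g = _h2_profile_function(spec, pheno, res_g, OptimizerConfig())
        from qtlmm.inference import _h2_profile_function as hp
        # evaluate the generic profile at the spectral endpoints: it should
        # sit at the chi-square threshold above the minimum
        thr = res_g.deviance + scipy.stats.chi2.ppf(0.95, 1)
        for endpoint in (ci_s.lower, ci_s.upper):
            if 0 < endpoint < 1:
                assert prof_g(endpoint) == pytest.approx(thr, abs=5e-3)


class TestGxEPair:
    def test_null_tests_behave_under_truth_with_interaction(self):
        cfg = SimConfig(n_families=40, k_children=6,
                        sex_specific=SexSpecific(1.0, 0.45, 0.9, 0.55, 0.7),
                        seed=71)
        ped, A, pheno, _ = simulate_study(cfg)
        spec = ModelSpec(response="trait", fixed=["age", "sex"],
                         random_terms=[RandomTerm(grouping="id", relmat=A,
                                                  slopes_factor="sex",
                                                  name="genetic")],
                         residual=ResidualSpec(factor="sex"))
        m3, m4, m5 = fit_gxe(spec, pheno)
        t_rho, t_eq = gxe_test_pair(m3, m4, m5)
        assert t_rho.method == "lrt_mixture"
        assert t_eq.method == "lrt_chisq"
        assert 0.0 <= t_rho.p_value <= 1.0
        assert t_eq.p_value < 0.05  # variances differ 1.0 vs 0.45 at n=480
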