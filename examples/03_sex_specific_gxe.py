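"""Sex-specific genetic variance: a gene-environment interaction model.

The genetic random effect carries one standard deviation per sex
(sg_male, sg_female) and a cross-sex genetic correlation rho_g; the
residual variance also differs by sex. "No interaction" means rho_g = 1 AND
sg_male = sg_female, so the model is tested against two null restrictions:
rho_g fixed at 1 (a boundary null, half-half chi-square mixture) and the
two sds constrained equal (interior, chi2_1). Data are simulated WITH
interaction (sg differs by sex), so at least the equal-variance test should
reject.
"""

from qtlmm import (ModelSpec, RandomTerm, ResidualSpec, SexSpecific,
                   SimConfig, fit_gxe, gxe_test_pair, simulate_study)

cfg = SimConfig(
    n_families=50, k_children=6,
    sex_specific=SexSpecific(sg_male=1.0, sg_female=0.5, rho_g=0.8,
                             sde_male=0.6, sde_female=0.8),
    seed=21)
ped, A, pheno, _ = simulate_study(cfg)

spec = ModelSpec(
    response="trait", fixed=["age", "sex"],
    random_terms=[RandomTerm(grouping="id", relmat=A, slopes_factor="sex",
                             name="genetic")],
    residual=ResidualSpec(factor="sex"))

m_free, m_rho1, m_eqvar = fit_gxe(spec, pheno)   # all ML, for valid LRTs
print("free model estimates:")
for path, v in m_free.param_values.items():
    print(f"  {path:25s} = {v:.3f}")

t_rho, t_eq = gxe_test_pair(m_free, m_rho1, m_eqvar)
print(f"H0 rho_g = 1     : stat = {t_rho.statistic:.3f}, "
      f"p = {t_rho.p_value:.4f}  ({t_rho.method})")
print(f"H0 equal variances: stat = {t_eq.statistic:.3f}, "
      f"p = {t_eq.p_value:.4f}  ({t_eq.method})")
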