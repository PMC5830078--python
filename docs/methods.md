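# Methods

## Model

For n observations the Gaussian mixed model is y = Xβ + Σ_t Z_t u_t + e.
Each random term t has Var(u_t) = G_t built from a grouping factor, an
optional relationship matrix A over the grouping levels (identity when
absent, as for a household effect) and a parameter block:

* intercept terms: G_t = σ_t² A, contributing σ_t² · Z A Zᵀ;
* group-specific ("slopes") terms with a k-level factor (k = 2 in the
  sex-specific case): contribution (Z A Zᵀ) ⊙ (S K Sᵀ), where S is the
  level incidence and K = D C D with D = diag(σ_1 … σ_k) and C the
  correlation matrix (parameters σ_g1, σ_g2, ρ_g for k = 2).

The residual is diagonal: one variance, or one per level of a factor
(heteroscedastic residuals are native rather than emulated by an extra
per-observation random effect; the two parameterisations are equivalent —
the total group variance σe² + σ_dummy,g² is what is identified — and the
equivalence is asserted by a test).

The additive relationship matrix is built by the classical tabular
recursion over a topologically sorted pedigree (so input row order is
irrelevant); inbreeding enters through the recursion itself. MZ-twin groups
are collapsed to a single genome before the recursion and expanded
afterwards, which yields exact unit correlation between twins and a
positive semi-definite, rank-deficient A — the case the eigen path of the
factorization handles.

## Likelihood and optimisation

Fixed effects are profiled by GLS; the ML deviance is
n log 2π + log|Σ| + rᵀΣ⁻¹r and REML adds log|XᵀΣ⁻¹X| (with (n−p) replacing
n in the constant). Three evaluation strategies share these formulas:

* **dense**: Cholesky of the assembled Σ (default below n = 150 or for
  dense matrices);
* **sparse**: when every term's relationship matrix has at least half
  exact zeros and the assembled pattern stays below 45% density, Σ is kept
  in CSC form and factored by a sparse Cholesky (see below);
* **spectral**: for the single-structured-term homoscedastic model the data
  are rotated once by the eigenvectors of Z A Zᵀ; the deviance becomes a
  1-D function of γ = σg²/σe² with σe² profiled in closed form, and every
  refit (profile point, bootstrap replicate, scanned SNP) costs O(n).
  The spectral and generic paths agree to ~1e-13 in deviance (tested).

Optimisation runs on standard deviations — never variances, whose curvature
degenerates at 0 — and atanh-mapped correlations, inside box bounds
(sd ratios in [0, 50], atanh ρ in [−8, 8]). Whenever no sd is fixed at a
nonzero constant, the overall variance scale is additionally profiled in
closed form (ŝ = q/n for ML, q/(n−p) for REML) with one residual sd pinned
at 1, so the polygenic model reduces to a single free ratio solved by
bounded Brent search. Multi-parameter models use a bounded quasi-Newton
search (finite-difference gradients on the smooth profiled deviance)
followed by a derivative-free Powell polish, started from the best of three
deterministic heuristics (equal split, residual-dominant, term-dominant)
plus any warm starts supplied (nested-model solutions during the
interaction analysis, which also enforces the deviance nesting numerically).
Degenerate parameter points (singular Σ) receive a large finite penalty
(1e12) so that line searches remain defined. Equality constraints alias
parameters to one free symbol — exact, not penalised; fixed parameters
leave the search space. Estimated sds within 1e-4 of zero (and |ρ| within
1e-4 of one) are flagged as boundary estimates. A constant response returns
the degenerate boundary fit (β₀ = mean, all variances 0) rather than an
error. Because the atanh coordinate only approaches |ρ| = 1, the
interaction analysis adopts a null model's optimum as the free model's
boundary solution whenever it attains a lower deviance.

## Sparse Cholesky

SciPy provides no sparse Cholesky, and SuperLU's supernodal LU — besides
ignoring symmetry — has wall time that is *not* monotone in fill at high
densities (BLAS panel effects make a 40%-dense factor slightly faster than
a 25%-dense one), which contradicts the intended cost model of the sparse
path. The package therefore ships a compact up-looking sparse Cholesky
(elimination-tree reachability for the row patterns, a sparse triangular
solve per row), numba-compiled, whose cost is proportional to fill flops;
its symbolic fill was verified exactly against dense Cholesky structure.
The fill-reducing permutation is taken from SuperLU's symmetric
minimum-degree ordering of the pattern, computed once per model. With this
factorization, median fit time increases monotonically as a family-sparse
n = 900 matrix is densified from 98% to 60% zeros — the qualitative
sparsity-runtime law the sparse path is designed around — at roughly a
2× cost ratio at this problem size.

## Inference

* **LRT**: statistic max(0, −2Δll) on χ²_df, or the ½χ²_{df−1} + ½χ²_df
  mixture when the null pins a parameter at a boundary (a variance at 0, a
  correlation at 1). The naive χ²₁ p-value is provably conservative
  relative to the mixture (asserted pointwise in tests).
* **Simulated RLRT** for a variance component: parametric bootstrap — fit
  the null by REML, simulate y* from it, refit both models, and use
  p = (1 + #{stat* ≥ stat}) / (1 + n_sim), which cannot return zero. The
  bootstrap (rather than a spectral approximation of the null law) was
  chosen because it extends unchanged to models with several structured
  terms. n_sim < 100 flags the result. When the alternative is the
  single-term model the whole simulation runs in the rotated
  representation, so 200 bootstrap refits cost well under a second at
  n = 300.
* **Profile-deviance CIs**: an endpoint solves profile(−2ll) = min + χ²₁
  quantile. Heritability is profiled directly through
  σg² = h²/(1−h²) · (other variances), with the remaining free ratios
  re-optimised at each h² (warm-started along the profile) and the scale
  profiled in closed form; endpoints are found by Brent root bracketing
  (tolerance 1e-4 on the h² scale). Endpoints that run into 0 or 1 are
  returned at the bound and flagged one-sided.
* **Interaction test pair**: LRT of ρ_g = 1 (boundary mixture) and of
  σ_g1 = σ_g2 (interior, χ²₁) against the free model, all fitted by ML.
  Under the no-interaction truth the equal-variance p-values are uniform;
  the boundary test's p-value by construction places ≈ half its mass at 1
  and is uniform on (0, ½) doubled — the calibration tests check exactly
  that (plus non-anti-conservatism at α = 0.05), since literal uniformity
  on (0,1) is impossible for a boundary-mixture p-value.

## Association scan

The scan aligns genotype dosages (0–2, NA allowed) to the phenotype rows,
then per SNP: `lrt` refits the SNP model by ML (the no-SNP model is fitted
once and reused whenever no dosages are missing) and compares on χ²₁;
`wald` uses (β̂/se)² with the GLS standard error at the fitted variance
parameters; `score2step` freezes Σ at the null REML estimates, whitens
once, and tests each SNP by GLS — the two-step approximation whose
p-values rank-correlate ≥ 0.99 with the full LRT in the calibration test.
Missing dosages are handled by per-SNP listwise deletion with n_used
reported; MAF filtering removes variants strictly below the threshold
(boundary kept). Work is SNP-sliced across joblib workers and reassembled
by index, so results are identical for any worker count.

## Simulator

The generator emulates a mid-sized family study: by default 30 nuclear
families of 10 (two founders, eight children), total phenotypic variance
normalised to 1 so the simulated fractions are directly h² = 0.5 and
household c² = 0.2; three-generation and MZ-twin variants cover the deeper
recursion and the PSD case. Sexes are random; age is uniform within
generation (children 18–35, parents 35–60, grandparents 60–80) with fixed
effects β_age = 0.01 per year and β_male = 0.2 — small, realistic nuisance
effects whose exact values are immaterial to the variance-component
machinery. Genotypes are gene-dropped (founders i.i.d. Bernoulli(maf),
default maf 0.3; Mendelian transmission; MZ members share genotypes) and
are therefore null SNPs unless a causal dosage with a stated effect is
added explicitly. One integer seed drives deterministic per-operation
substreams; everything is bit-reproducible. Features of real data the
generator does not emulate: ascertainment through probands,
linkage disequilibrium between SNPs, genotyping error, non-Gaussian
phenotypes — so passing calibration here shows correctness of the
machinery under the model, not robustness to those violations.

## Simulation sizes used by the test suite and acceptance script

Chosen as the package's own validation designs: likelihood-oracle
equivalence at 50 configurations × 20 parameter points (n ≤ 60); kinship
vs gene dropping on 20 pedigrees × 10,000 drops; recovery/coverage at 200
studies of 30×10; RLRT size at 200 null replicates (n_sim = 200, n = 300)
and power at 100 replicates (h² = 0.8); interaction-null calibration at
200 replicates of 40 families × 10 (chosen large enough for the χ²₁
asymptotics of the interior test, which is visibly conservative at half
that size); scan calibration at 500 null SNPs,
n = 600; sparsity-runtime at n = 900 with 5 timed fits per density. The
acceptance script runs the same chain at somewhat smaller replicate counts
(50 recovery studies, 100 + 50 RLRT replicates, 25 interaction studies)
and reports the computed numbers.

## Known limitations

Gaussian phenotypes only (no generalised mixed models); no dominance or
epistatic relationship matrices and no marker-based GRM estimation; no
X-chromosome kinship; residuals are independent (group heteroscedasticity
is the only departure); no Satterthwaite/Kenward-Roger small-sample
corrections; no SNP×sex interaction scan (the marginal+interaction
association model is left as future work); profile CIs rather than
Hessian-based standard errors for variance components; bootstrap of fitted
models is not provided.
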