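# Methods

## Model and scope

`smoltherit` estimates additive and dominance genomic variance for a binary
early-life-history trait (migratory vs resident, stored on the 1/2 coding
and analysed as 0/1) in one or two small populations genotyped on a few
thousand biallelic SNPs. The linear mixed model is

    y = Xb + a + d + e,
    var(a) = σ²_a A_g,  var(d) = σ²_d D_g,  var(e) = σ²_e I,

with sex as the only fixed effect. Sex enters as a three-level factor
(female, male, unknown) because wild cohorts contain fish whose sex was
never recorded; the reference level is dropped so the design has full
column rank, and the restricted likelihood is invariant to which level is
the reference (tested).

The binary trait is analysed on the observed 0/1 scale with a linear model,
not with a probit GLMM. The threshold-model (probit) conversion
h²_liability = h²_obs·P(1−P)/z² is applied post hoc; the conversion factor
is minimised at prevalence 0.5 where it equals π/2, so liability-scale
estimates exceed 1 for every prevalence exactly when the observed-scale
estimate exceeds 2/π ≈ 0.64. Estimates above 1 are reported unclamped: they
are a known artefact of the conversion, not an error, and the observed-scale
numbers are the ones to interpret. The prevalence used by default is the
sample case proportion; a population-level prevalence can be supplied.

## Relationship matrices

The codings realise the classical partition of a genotypic value into a
breeding value and a dominance deviation: additive entry `x − 2p`, dominance
entries `−2q², 2pq, −2p²` for dosages 2, 1, 0, with per-marker frequencies
`p` estimated from the analysed individuals. Normalisers are Σ2pq (additive)
and Σ(2pq)² (dominance), so the mean diagonal of either matrix tends to 1
under Hardy–Weinberg proportions as the panel grows. Missing genotypes are
mean-imputed, i.e. contribute exactly zero to both codings; this preserves
the exact row-sum identity A_g·1 = 0 and keeps both matrices invariant to
which allele is counted at any marker (both identities are asserted in
tests).

Frequencies come from the combined sample when one joint matrix is needed
(between-population correlations) and from the single population when each
population is analysed separately, matching the analysis design the package
implements (per-population variance components, joint correlation summary).

Genomic correlations are the diagonal-normalised form
c_ij = g_ij/√(g_ii g_jj), the only normalisation guaranteed to lie in
[−1, 1]. Individuals with a nonpositive diagonal (possible in degenerate
tiny panels) make the correlation undefined and either raise or are dropped
explicitly. Group means (within each population, between populations) are
compared with Welch t-tests under Holm correction; pairwise correlations
sharing an individual are dependent, so these P-values are approximate and a
label-permutation P-value is available as a dependence-robust check.

## REML estimation

The restricted log-likelihood (constant terms omitted) is

    l = −½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy ],
    V = σ²_a A_g + σ²_d D_g + σ²_e I,
    P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹.

Two maximisers are provided:

* **EM-REML** (default): σ²_i ← σ²_i + (σ²_i)²(yᵀPG_iPy − tr(PG_i))/n.
  The recursion increases the likelihood monotonically and approaches
  boundary components multiplicatively, which is why collapsed components
  appear as very small positive numbers (10⁻¹² and below) rather than exact
  zeros. Its drawback is a sub-linear tail: a component heading to the
  boundary decays roughly harmonically, so the relative-change criterion
  (every component, tolerance 1e-8, cap 5000 iterations) is supplemented by
  two pragmatic rules — components below 10⁻¹² of the initial phenotypic
  variance are exempt from the parameter criterion, and an absolute
  log-likelihood stall below 1e-12 also terminates. Non-convergence is
  reported with a warning, never silently.
* **Bounded quasi-Newton** (`optimizer="bounded"`): L-BFGS-B on
  log-variances with the analytic gradient
  ∂l/∂σ²_i = ½(yᵀPG_iPy − tr(PG_i)). It reaches the optimum in tens of
  iterations and is the recommended choice for simulation studies with
  hundreds of individuals; the simulation-based acceptance tests use it at
  n = 500 for exactly this reason. A built-in cross-check refits with the
  other optimizer and warns when any heritability disagrees by more than
  1e-4.

Initial values split the phenotypic variance equally across active
components (deterministic, no seed). Small-n restricted-likelihood surfaces
can be genuinely multimodal — a six-individual toy in our test suite has an
additive-only and a dominance-only local maximum — so `fit_greml` offers
deterministic corner-biased multistart (`restarts` up to 5); toy-scale
verification against an independent grid-plus-simplex oracle uses it.

Heritabilities are variance fractions of the component sum; tabular output
rounds them to 3 decimals. No standard errors are reported.

## GBLUP

At the converged components, â = σ̂²_a A_g P y and d̂ = σ̂²_d D_g P y (the
closed-form equivalents of Henderson's mixed-model equations, which serve as
an independent test oracle), and ĝ = â + d̂ exactly. P annihilates the
fixed-effect column space, so predictions are invariant to phenotype shifts
and scale linearly with the phenotype. Class-separation reports state
whether the two trait classes' prediction ranges are disjoint and, if not,
how many individuals fall inside the other class's range; separation is
scale-free, so a collapsed component (σ̂²_a ~ 10⁻⁵⁹) can still order the
classes.

A note on when complete separation is achievable: with mutually unrelated
individuals A_g is close to the identity, σ²_a and σ²_e are then weakly
identified, and predictions cannot perfectly rank fish adjacent to the
class threshold. Complete separation of a binary trait by GBLUP_a is the
signature of genomic stratification aligned with the trait — two genetic
clusters, one predominantly migratory — and that is the configuration the
separation tests construct.

## Per-SNP tests

Each SNP is tested with `y = μ + sex + genotype` by ordinary least squares,
dropping individuals missing that SNP only. P_m is the partial
(Type III-style) F-test of the genotype factor (2 df with three observed
classes, 1 df with two); the additive and dominance contrasts are computed
on sex-adjusted least-squares means (equal weights over observed sex
levels) and tested with 1-df F-tests. With fewer than three observed
classes the contrasts are not estimable and are reported missing; a SNP
whose genotype classes are confounded with sex raises a named error, which
the genome-wide scan logs and records with missing P-values. The
genome-wide threshold is α/(3m), counting three tests per SNP — for
m = 5,215 and α = 0.05 this gives 3.2 × 10⁻⁶, whereas α/m would give
9.6 × 10⁻⁶; α/m remains available as a configuration option.

## Synthetic data

The simulator generates the statistical structure the analysis assumes and
nothing more: no linkage disequilibrium, no pedigree, no migration or
selection dynamics. Components:

* **Allele frequencies.** Ancestral frequencies uniform on (0.05, 0.95);
  each population draws from a Beta with mean p and variance F_ST·p(1−p)
  (Balding–Nichols). Default F_ST = 0.05, a typical magnitude for
  conspecific salmonid populations a few drainages apart.
* **Genotypes.** HWE binomial draws within each population. Default panel
  m = 5215 markers (the post-QC scale of the motivating datasets);
  simulation studies in the tests use 300–2000 for speed.
* **Liability.** Sum of a fixed sex effect (default 0.1 SD, small enough
  not to dominate but enough to exercise the fixed-effect machinery),
  breeding values from i.i.d. normal effects at 200 additive causal markers
  on the centered-dosage coding, dominance deviations at 200 causal markers
  on the dominance coding, and a normal residual. The three random parts
  are orthogonalised in-sample and rescaled so the realized variance
  fractions equal the targets exactly; with cohorts of ~180 fish,
  expected-value targeting would be noisy. Default architecture is
  additive-dominated (0.95, 0.05); a dominance-dominated switch (e.g. 0,
  0.4) reproduces the opposite estimation ranking.
* **Binary trait.** Rank thresholding of the liability within each
  population at its configured prevalence (defaults 29/127 and 28/55), so
  class counts are exact and downstream examples deterministic.
* **Missingness.** Genotype calls missing at a configurable rate (default
  2%) on a configurable slice of markers; sex set to unknown for a fixed
  number of migratory fish per population (defaults 7 and 4).

Everything is driven by one `numpy` Generator seeded from the config:
byte-identical outputs under a fixed seed.

What passing recovery tests on these data do *not* show: robustness to LD
between causal and panel markers, to genotyping error, or to
binary-scale analysis of structured samples — fitting the binary trait on a
combined two-population cohort lets between-population prevalence
differences masquerade as additive variance (a Wahlund-type confounding),
which is why per-population analysis is the supported design and the
recovery tests evaluate the continuous liability.

## Numerical choices and limitations

* Cholesky factorisation of V with an explicit inverse for P; problems here
  are a few hundred individuals, so dense algebra is the right tool.
* QC thresholds follow the "strictly exceeding" / "at least" reading:
  missing fraction exactly 0.20 and MAF exactly 0.05 both pass. Missingness
  uses all individuals as denominator; MAF is computed on the combined
  sample by default, with an optional subset.
* Variance components are floored only by the quasi-Newton optimizer's
  log-scale bounds (10⁻¹² of the phenotypic variance); EM never clamps.
* The package does not fit threshold (probit) mixed models, does not
  compute prediction reliabilities or cross-validated accuracies, and does
  not model marker weighting or leave-one-chromosome-out relationship
  matrices.
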