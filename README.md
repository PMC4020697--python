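# smoltherit

Genomic additive + dominance heritability analysis of a binary life-history
trait — smoltification, the parr–smolt transformation that decides whether a
juvenile *Oncorhynchus mykiss* becomes a migratory steelhead or a resident
rainbow trout — in small two-population SNP samples.

The package is aimed at population geneticists working with wild salmonid
cohorts genotyped on a few thousand SNPs: it quantifies how much of the
migratory/resident dichotomy is explained by additive genetic merit versus
dominance interactions, predicts per-fish genetic values, and scans each SNP
for genotypic, additive and dominance effects. Because wild datasets of this
kind are rarely shareable, a faithful two-population simulator is part of the
tested surface, so every stage runs end-to-end without external data.

## The model

Phenotypes (SMOLT, 1 = migratory, 2 = nonmigratory, analysed as 0/1) follow
the mixed model

    y = Xb + a + d + e,
    var(a) = σ²_a A_g,   var(d) = σ²_d D_g,   var(e) = σ²_e I,

with sex the only fixed effect. The genomic relationship matrices use the
breeding-value / dominance-deviation partition of the genotypic value: with
counted-allele frequency `p_j` and dosage `x ∈ {0,1,2}`,

    additive coding:   x − 2p_j
    dominance coding:  −2q_j² (x=2),  2p_j q_j (x=1),  −2p_j² (x=0)

    A_g = T_α T_αᵀ / Σ_j 2 p_j q_j,
    D_g = T_δ T_δᵀ / Σ_j (2 p_j q_j)².

Variance components are estimated by REML (EM recursion, with a bounded
quasi-Newton maximiser for large problems), giving heritabilities
h²_a = σ²_a/σ²_p, h²_d = σ²_d/σ²_p, H² = h²_a + h²_d. Observed-scale
estimates for the binary trait convert to the liability scale by the probit
threshold-model adjustment

    h²_liability = h²_observed · P₁(1 − P₁) / z²,

where P₁ is the trait prevalence and z the standard normal density at the
threshold; the conversion exceeds 1 for every prevalence once h²_observed
passes 2/π ≈ 0.64. GBLUP predictions of breeding values, dominance
deviations and total genetic values are evaluated at the converged
components. Per-SNP tests fit `y = μ + sex + genotype` by least squares and
report P_m (genotype factor), P_a (additive contrast (m₂−m₀)/2) and P_d
(dominance contrast m₁−(m₂+m₀)/2) against a Bonferroni threshold of
α/(3m) — 3.2 × 10⁻⁶ for 5,215 markers at α = 0.05.

## Worked example

Simulate a two-population cohort at the default study dimensions (127 + 55
fish) and run the full pipeline:

```sh
smoltherit simulate --n1 127 --n2 55 --m 1500 --h2-a 0.8 --h2-d 0.1 --seed 7 --out sim
# simulated 182 individuals x 1500 markers (realized h2_a=0.800, h2_d=0.100)

smoltherit all --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
    --optimizer bounded --out results
# QC: 1500 -> 1437 markers
# GREML UYR/additive_dominance: h2_a=0.470 h2_d=0.221 (17 iterations)
# ...
```

`results/variance_components.tsv` then holds one row per population and
model variant (additive-only, additive + dominance):

```
population              model  sigma2_a  sigma2_d     sigma2_e  h2_a  h2_d    H2
       UMC      additive_only  0.243476  0.000000 8.494123e-08 1.000 0.000 1.000
       UMC additive_dominance  0.146371  0.094402 2.545455e-13 0.608 0.392 1.000
       UYR      additive_only  0.066895  0.000000 7.689636e-02 0.465 0.000 0.465
       UYR additive_dominance  0.068095  0.032065 4.468785e-02 0.470 0.221 0.691
```

The binary trait's observed-scale heritabilities and sample prevalences feed
the liability conversion (`results/liability.tsv`) — note the smaller
population's estimate of 1.00 converts to 1.57, illustrating the above-1
behaviour of the threshold-model adjustment:

```
population  prevalence  h2_observed  h2_liability
       UMC    0.509091     1.000000      1.571092
       UYR    0.228346     0.465224      0.896298
```

Genomic correlations (`results/correlations.tsv`) summarise within- and
between-population genomic similarity; between-population additive
correlations are negative because the two samples carry diverged allele
frequencies:

```
    which      group  n_pairs      mean       se
 additive within-UMC     1485  0.088565 0.000703
 additive within-UYR     8001  0.013907 0.000316
 additive    between     6985 -0.047730 0.000328
```

`results/gblup.tsv` lists per-fish GBLUP_a / GBLUP_d / GBLUP_g and
`results/snp_tests.tsv` the per-SNP effect estimates and P-values (here one
SNP clears the genome-wide threshold).

The same machinery is importable as a library, sklearn-style:

```python
from smoltherit import GREML, MarkerQC
qc = MarkerQC(max_missing=0.20, min_maf=0.05).fit(codes)   # codes: n x m, NaN = missing
model = GREML(optimizer="bounded").fit(qc.transform(codes), y, sex=sex)
model.h2_a_, model.h2_d_, model.H2_   # variance fractions
model.gblup_a_                         # predicted breeding values
```

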