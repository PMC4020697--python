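"""Two-population genotype/phenotype simulator with a liability-threshold trait.

The generator emulates the statistical structure the analysis assumes: two
differentiated populations (Balding-Nichols allele-frequency model at a given
F_ST), HWE genotypes within each population, a polygenic liability composed
of additive breeding values, dominance deviations, a small fixed sex effect
and a normal residual, and a binary migratory trait produced by thresholding
the liability within each population at its configured prevalence. Defaults
reproduce the study conditions of the wild O. mykiss samples the analysis
was designed for: 127 + 55 fish, 5215 post-QC markers, prevalences 29/127
and 28/55, and 7 + 4 migratory fish with missing sex.

Effect sizes are rescaled after sampling so the *realized* variance
fractions match the targets exactly (the additive, dominance and residual
parts are orthogonalised in-sample first); with the small cohorts involved,
expected-value targeting would be noisy. Class counts are exact by
construction (rank thresholding), which keeps downstream examples
deterministic.

No linkage disequilibrium, pedigree or migration dynamics are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CohortTable, GenotypeMatrix
from .grm import additive_model_matrix, dominance_model_matrix
from .io import allele_frequencies


@dataclass
class SimulationConfig:
    n1: int = 127
    n2: int = 55
    m: int = 5215
    fst: float = 0.05
    n_causal_add: int = 200
    n_causal_dom: int = 200
    h2_a_target: float = 0.95
    h2_d_target: float = 0.05
    prevalence1: float = 29 / 127
    prevalence2: float = 28 / 55
    sex_effect: float = 0.1
    missing_geno_rate: float = 0.02
    missing_marker_fraction: float = 1.0
    missing_sex_count1: int = 7
    missing_sex_count2: int = 4
    pop_labels: tuple = ("UYR", "UMC")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")
        if self.h2_a_target + self.h2_d_target > 1 + 1e-12:
            raise ValueError("h2_a_target + h2_d_target must not exceed 1")
        for n, prev in ((self.n1, self.prevalence1), (self.n2, self.prevalence2)):
            if not (0 < prev < 1):
                raise ValueError("prevalences must lie in (0, 1)")
            if round(n * prev) < 1 or round(n * prev) >= n:
                raise ValueError(f"prevalence {prev} infeasible for population of {n}")


@dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery checks."""

    breeding_values: np.ndarray
    dominance_deviations: np.ndarray
    residuals: np.ndarray
    liability: np.ndarray
    causal_add: np.ndarray
    causal_dom: np.ndarray
    realized_h2_a: float
    realized_h2_d: float
    ancestral_freqs: np.ndarray = field(repr=False, default=None)
    pop_freqs: tuple = field(repr=False, default=None)

    def to_frame(self, ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame({
            "id": ids,
            "breeding_value": self.breeding_values,
            "dominance_deviation": self.dominance_deviations,
            "residual": self.residuals,
            "liability": self.liability,
        })


def simulate_frequencies(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Ancestral and per-population allele frequencies.

    Ancestral frequencies are uniform on (0.05, 0.95); each population draws
    its frequency from a Beta distribution with mean p and variance
    fst * p * (1 - p) (the Balding-Nichols parameterisation), so the expected
    Wright F_ST between the populations matches ``cfg.fst``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(0.05, 0.95, size=cfg.m)
    if cfg.fst == 0:
        return p, (p.copy(), p.copy())
    a = p * (1 - cfg.fst) / cfg.fst
    b = (1 - p) * (1 - cfg.fst) / cfg.fst
    p1 = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    p2 = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    return p, (p1, p2)


def _residualize(v: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Remove the in-sample projection of v onto [1, others...]."""
    Q = np.column_stack([np.ones(v.size)] + others)
    coef, *_ = np.linalg.lstsq(Q, v, rcond=None)
    return v - Q @ coef


def _scale_to_variance(v: np.ndarray, target: float) -> np.ndarray:
    if target <= 0:
        return np.zeros_like(v)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot scale a constant component to positive variance")
    return v * np.sqrt(target) / sd


def simulate_cohort(cfg: SimulationConfig):
    """Generate (GenotypeMatrix, CohortTable, TruthRecord) under ``cfg``.

    Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    anc, (p1, p2) = simulate_frequencies(cfg, rng)

    g1 = rng.binomial(2, p1, size=(cfg.n1, cfg.m)).astype(float)
    g2 = rng.binomial(2, p2, size=(cfg.n2, cfg.m)).astype(float)
    codes = np.vstack([g1, g2])
    n = cfg.n1 + cfg.n2
    ids = [f"{cfg.pop_labels[0]}_{k + 1:04d}" for k in range(cfg.n1)] + \
          [f"{cfg.pop_labels[1]}_{k + 1:04d}" for k in range(cfg.n2)]
    pops = np.array([cfg.pop_labels[0]] * cfg.n1 + [cfg.pop_labels[1]] * cfg.n2)

    # polygenic liability on combined-sample codings
    p_hat = np.clip(allele_frequencies(codes), 1e-6, 1 - 1e-6)
    n_add = min(cfg.n_causal_add, cfg.m)  # small panels: everything is causal
    n_dom = min(cfg.n_causal_dom, cfg.m)
    causal_add = np.sort(rng.choice(cfg.m, size=n_add, replace=False))
    causal_dom = np.sort(rng.choice(cfg.m, size=n_dom, replace=False))
    alpha = rng.standard_normal(n_add)
    delta = rng.standard_normal(n_dom)
    a_raw = additive_model_matrix(codes[:, causal_add], p_hat[causal_add]) @ alpha
    d_raw = dominance_model_matrix(codes[:, causal_dom], p_hat[causal_dom]) @ delta
    e_raw = rng.standard_normal(n)

    a = _residualize(a_raw, []) if cfg.h2_a_target > 0 else np.zeros(n)
    a = _scale_to_variance(a, cfg.h2_a_target)
    d = _residualize(d_raw, [a]) if cfg.h2_d_target > 0 else np.zeros(n)
    d = _scale_to_variance(d, cfg.h2_d_target)
    e = _scale_to_variance(_residualize(e_raw, [a, d]), 1 - cfg.h2_a_target - cfg.h2_d_target)

    sex = np.where(rng.random(n) < 0.5, "M", "F").astype(object)
    liability = a + d + e + cfg.sex_effect * (sex == "M").astype(float)

    genetic_var = np.var(a + d + e)
    truth = TruthRecord(
        breeding_values=a, dominance_deviations=d, residuals=e,
        liability=liability, causal_add=causal_add, causal_dom=causal_dom,
        realized_h2_a=float(np.var(a) / genetic_var),
        realized_h2_d=float(np.var(d) / genetic_var),
        ancestral_freqs=anc, pop_freqs=(p1, p2),
    )

    # rank-threshold the liability within each population: exact class counts
    smolt = np.full(n, 2, dtype=int)
    for label, prev in zip(cfg.pop_labels, (cfg.prevalence1, cfg.prevalence2)):
        rows = np.flatnonzero(pops == label)
        n_cases = int(round(len(rows) * prev))
        top = rows[np.argsort(-liability[rows])[:n_cases]]
        smolt[top] = 1

    # missing sex among migratory fish, as in the study samples
    for label, count in zip(cfg.pop_labels, (cfg.missing_sex_count1, cfg.missing_sex_count2)):
        migr = np.flatnonzero((pops == label) & (smolt == 1))
        take = rng.choice(migr, size=min(count, len(migr)), replace=False)
        sex[take] = "NA"

    # missing genotype calls on a configurable slice of the marker panel
    if cfg.missing_geno_rate > 0 and cfg.missing_marker_fraction > 0:
        n_affected = int(round(cfg.m * cfg.missing_marker_fraction))
        affected = rng.choice(cfg.m, size=n_affected, replace=False)
        mask = rng.random((n, n_affected)) < cfg.missing_geno_rate
        cols = codes[:, affected]
        cols[mask] = np.nan
        codes[:, affected] = cols

    genotypes = GenotypeMatrix(ids, [f"snp{j + 1:05d}" for j in range(cfg.m)], codes)
    cohort = CohortTable(pd.DataFrame({
        "id": ids, "population": pops, "sex": sex, "smolt": smolt,
    }))
    return genotypes, cohort, truth
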