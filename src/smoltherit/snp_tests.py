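"""Single-SNP fixed-effects tests of genotypic, additive and dominance effects.

Each SNP is tested with the general linear model

    y = mu + sex + genotype + e,

genotype entering as a 3-level factor (dosages 0/1/2). Three tests are
reported per SNP:

* P_m — partial F-test of the whole genotype factor (2 df when all three
  classes are observed, 1 df when only two are);
* P_a — 1-df F-test of the additive contrast alpha = (m2 - m0)/2;
* P_d — 1-df F-test of the dominance contrast delta = m1 - (m2 + m0)/2,

where m_k are sex-adjusted least-squares genotype means. The additive and
dominance contrasts are estimable only when all three genotype classes are
observed; otherwise they are reported as missing. Family-wise error is
controlled by Bonferroni over 3 tests per SNP, threshold alpha / (3 m);
with m = 5215 markers and alpha = 0.05 that is 3.2e-6.

The tests use partial (Type III-style) sums of squares computed directly
from the projection geometry of the design, so they remain correct under
class imbalance and missing genotypes (individuals missing a SNP are dropped
for that SNP only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable, GenotypeMatrix

logger = logging.getLogger(__name__)


class ConfoundingError(ValueError):
    """Genotype classes are confounded with sex (rank-deficient design)."""


@dataclass
class SnpTestRecord:
    marker_id: str
    n0: int
    n1: int
    n2: int
    means: tuple  # sex-adjusted LS means for codes 0,1,2 (nan when class absent)
    alpha_hat: float
    delta_hat: float
    p_m: float
    p_a: float
    p_d: float
    df_m: int
    df_resid: int

    @property
    def n_classes(self) -> int:
        return int((np.array([self.n0, self.n1, self.n2]) > 0).sum())


def _contrast_f_test(beta, XtX_inv, sigma2, df_resid, C):
    """F-test of C beta = 0 with C a (k x p) contrast matrix."""
    C = np.atleast_2d(C)
    Cb = C @ beta
    M = C @ XtX_inv @ C.T
    F = float(Cb @ np.linalg.solve(M, Cb)) / (C.shape[0] * sigma2)
    p = float(stats.f.sf(F, C.shape[0], df_resid))
    return F, p


def snp_glm_test(y: np.ndarray, sex: np.ndarray | None, genotype: np.ndarray,
                 marker_id: str = "snp") -> SnpTestRecord:
    """Fit y = mu + sex + genotype by OLS and test the three SNP effects.

    ``genotype`` holds dosages in {0,1,2} with NaN for missing; individuals
    with a missing call are dropped here only.
    """
    y = np.asarray(y, dtype=float).ravel()
    genotype = np.asarray(genotype, dtype=float).ravel()
    ok = ~np.isnan(genotype)
    y, genotype = y[ok], genotype[ok]
    sex = None if sex is None else np.asarray(sex, dtype=object).ravel()[ok]
    n = y.size

    counts = [int((genotype == k).sum()) for k in (0, 1, 2)]
    observed = [k for k in (0, 1, 2) if counts[k] > 0]
    if len(observed) < 2:
        raise ConfoundingError(f"SNP {marker_id}: only one genotype class observed")

    cols = [np.ones(n)]
    sex_levels: list = []
    if sex is not None:
        sex_levels = sorted(set(sex))
        for lev in sex_levels[1:]:
            cols.append((sex == lev).astype(float))
    geno_col_of = {}
    for k in observed[1:]:
        geno_col_of[k] = len(cols)
        cols.append((genotype == k).astype(float))
    X = np.column_stack(cols)
    p = X.shape[1]
    if n < p + 1:
        raise ConfoundingError(f"SNP {marker_id}: too few observations ({n}) for {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ConfoundingError(f"SNP {marker_id}: genotype confounded with sex")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid

    # genotype effect vector in coefficient space: g_ref = 0
    def geno_effect(k):
        if k == observed[0] or counts[k] == 0:
            return np.zeros(p)
        e = np.zeros(p)
        e[geno_col_of[k]] = 1.0
        return e

    # overall genotype (marker) test
    C_m = np.array([geno_effect(k) for k in observed[1:]])
    _, p_m = _contrast_f_test(beta, XtX_inv, sigma2, df_resid, C_m)
    df_m = len(observed) - 1

    # sex-adjusted LS means: intercept + genotype effect + average sex effect
    sex_avg = np.zeros(p)
    sex_avg[0] = 1.0
    if sex_levels:
        for j in range(1, len(sex_levels)):
            sex_avg[j] = 1.0 / len(sex_levels)
    means = tuple(
        float(sex_avg @ beta + geno_effect(k) @ beta) if counts[k] > 0 else np.nan
        for k in (0, 1, 2)
    )

    alpha_hat = delta_hat = p_a = p_d = np.nan
    if len(observed) == 3:
        c_a = (geno_effect(2) - geno_effect(0)) / 2.0
        c_d = geno_effect(1) - (geno_effect(2) + geno_effect(0)) / 2.0
        alpha_hat = float(c_a @ beta)
        delta_hat = float(c_d @ beta)
        _, p_a = _contrast_f_test(beta, XtX_inv, sigma2, df_resid, c_a)
        _, p_d = _contrast_f_test(beta, XtX_inv, sigma2, df_resid, c_d)

    return SnpTestRecord(marker_id, *counts, means, alpha_hat, delta_hat,
                         p_m, p_a, p_d, df_m, df_resid)


def bonferroni_threshold(n_markers: int, alpha: float = 0.05,
                         mode: str = "3m") -> float:
    """Genome-wide significance threshold: alpha/(3m) for the three tests per
    SNP (default), or alpha/m counting each SNP once."""
    if mode == "3m":
        return alpha / (3 * n_markers)
    if mode == "m":
        return alpha / n_markers
    raise ValueError(f"mode must be '3m' or 'm', got {mode!r}")


def genomewide_scan(g: GenotypeMatrix, cohort: CohortTable, alpha: float = 0.05,
                    bonferroni_mode: str = "3m",
                    y: np.ndarray | None = None) -> tuple[pd.DataFrame, float]:
    """Run the three-effect test at every SNP; returns a record table and the
    Bonferroni threshold. SNPs whose model cannot be fitted (single genotype
    class, sex confounding) are logged and reported with missing P-values."""
    cohort = cohort.aligned_to(g)
    if y is None:
        y = cohort.smolt01()
    sex = cohort.table["sex"].to_numpy()
    threshold = bonferroni_threshold(g.n_markers, alpha, bonferroni_mode)
    rows = []
    for j, mid in enumerate(g.marker_ids):
        try:
            rec = snp_glm_test(y, sex, g.codes[:, j], marker_id=mid)
        except ConfoundingError as err:
            logger.warning("skipping SNP %s: %s", mid, err)
            rows.append({"marker_id": mid, "n0": np.nan, "n1": np.nan, "n2": np.nan,
                         "alpha_hat": np.nan, "delta_hat": np.nan,
                         "p_m": np.nan, "p_a": np.nan, "p_d": np.nan,
                         "significant": False})
            continue
        sig = bool(np.nanmin([rec.p_m, rec.p_a, rec.p_d]) <= threshold)
        rows.append({"marker_id": mid, "n0": rec.n0, "n1": rec.n1, "n2": rec.n2,
                     "alpha_hat": rec.alpha_hat, "delta_hat": rec.delta_hat,
                     "p_m": rec.p_m, "p_a": rec.p_a, "p_d": rec.p_d,
                     "significant": sig})
    return pd.DataFrame(rows), threshold
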