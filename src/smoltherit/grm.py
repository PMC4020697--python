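"""Additive and dominance genomic relationship matrices and genomic correlations.

The genotypic value at each SNP is partitioned into a breeding value and a
dominance deviation. With counted-allele frequency ``p`` (``q = 1 - p``) and
dosage ``x`` in {0, 1, 2}:

* additive (breeding-value) coding: ``x - 2p``;
* dominance-deviation coding: ``-2q**2`` (x=2), ``2*p*q`` (x=1), ``-2p**2`` (x=0).

Both codings have zero mean under Hardy-Weinberg proportions at frequency
``p``. Missing dosages are mean-imputed, i.e. enter both codings as exact
zeros, which preserves the additive row-sum identity ``A_g @ 1 = 0`` when the
frequencies are estimated from the same individuals.

The relationship matrices are the cross-products normalised by the expected
per-locus variance summed over loci:

    A_g = T_a T_a' / sum_j 2 p_j q_j
    D_g = T_d T_d' / sum_j (2 p_j q_j)**2

so that the mean diagonal of either matrix tends to 1 as the marker panel
grows under HWE. Genomic correlations are the diagonal-normalised
(cosine) form c_ij = g_ij / sqrt(g_ii g_jj), the only normalisation
guaranteed to lie in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .datatypes import CohortTable, GenotypeMatrix
from .io import allele_frequencies


class DegenerateMarkerError(ValueError):
    """A marker is monomorphic (p in {0, 1}) so neither coding is defined."""


class DegenerateIndividualError(ValueError):
    """An individual has a nonpositive GRM diagonal entry."""


@dataclass
class GrmPair:
    """Additive and dominance GRMs with their normalisation bookkeeping."""

    individual_ids: list[str]
    A: np.ndarray
    D: np.ndarray
    k_alpha: float  # sum_j 2 p_j q_j
    k_delta: float  # sum_j (2 p_j q_j)^2
    freqs: np.ndarray
    n_markers: int


def _check_freqs(p: np.ndarray) -> None:
    if np.any((p <= 0) | (p >= 1)) or np.any(np.isnan(p)):
        j = int(np.argmax((p <= 0) | (p >= 1) | np.isnan(p)))
        raise DegenerateMarkerError(f"marker index {j} has frequency {p[j]!r} outside (0,1)")


def additive_model_matrix(codes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Centered dosage matrix T_a; missing entries become exactly 0."""
    p = np.asarray(freqs, dtype=float)
    _check_freqs(p)
    X = np.asarray(codes, dtype=float)
    T = X - 2.0 * p
    T[np.isnan(X)] = 0.0
    return T


def dominance_model_matrix(codes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Dominance-deviation design T_d; missing entries become exactly 0."""
    p = np.asarray(freqs, dtype=float)
    _check_freqs(p)
    q = 1.0 - p
    X = np.asarray(codes, dtype=float)
    T = np.empty_like(X)
    T[...] = 0.0
    T = np.where(X == 2.0, -2.0 * q**2, T)
    T = np.where(X == 1.0, 2.0 * p * q, T)
    T = np.where(X == 0.0, -2.0 * p**2, T)
    T[np.isnan(X)] = 0.0
    return T


def build_grms(g: GenotypeMatrix, freq_subset: list[str] | None = None) -> GrmPair:
    """Build A_g and D_g from post-QC genotypes.

    ``freq_subset`` names the individuals whose codes supply the allele
    frequencies for the codings (default: all individuals in ``g``). Pass a
    single population here to build that population's own matrices, or leave
    the default for the joint two-population matrix used for
    between-population correlations.
    """
    if g.n_markers == 0:
        raise ValueError("empty marker panel: no markers survive to build GRMs")
    src = g if freq_subset is None else g.subset_individuals(list(freq_subset))
    p = allele_frequencies(src.codes)
    _check_freqs(p)
    q = 1.0 - p
    k_alpha = float(np.sum(2.0 * p * q))
    k_delta = float(np.sum((2.0 * p * q) ** 2))
    Ta = additive_model_matrix(g.codes, p)
    Td = dominance_model_matrix(g.codes, p)
    A = (Ta @ Ta.T) / k_alpha
    D = (Td @ Td.T) / k_delta
    A = (A + A.T) / 2.0
    D = (D + D.T) / 2.0
    return GrmPair(list(g.individual_ids), A, D, k_alpha, k_delta, p, g.n_markers)


class GenomicRelationship(BaseEstimator, TransformerMixin):
    """Kernel transformer producing genomic relationship rows.

    ``fit(X)`` learns per-marker frequencies from the dosage matrix ``X``
    (NaN = missing); ``transform(X2)`` returns the n2 x n relationship block
    between the rows of ``X2`` and the fitted individuals, normalised by the
    fitted panel's constant — so ``transform(X)`` on the training matrix is
    A_g (or D_g) itself.
    """

    def __init__(self, kind: str = "additive"):
        self.kind = kind

    def _design(self, X):
        if self.kind == "additive":
            return additive_model_matrix(X, self.freqs_)
        if self.kind == "dominance":
            return dominance_model_matrix(X, self.freqs_)
        raise ValueError(f"kind must be 'additive' or 'dominance', got {self.kind!r}")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.freqs_ = allele_frequencies(X)
        _check_freqs(self.freqs_)
        pq2 = 2.0 * self.freqs_ * (1.0 - self.freqs_)
        self.scale_ = float(np.sum(pq2)) if self.kind == "additive" else float(np.sum(pq2**2))
        self.T_fit_ = self._design(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (self._design(X) @ self.T_fit_.T) / self.scale_


def genomic_correlations(grm: GrmPair, which: str = "additive",
                         drop_degenerate: bool = False):
    """Diagonal-normalised pairwise genomic correlations c_ij = g_ij/sqrt(g_ii g_jj).

    Individuals with a nonpositive diagonal entry make the correlation
    undefined; by default this raises, with ``drop_degenerate=True`` they are
    excluded and the kept ids are returned alongside the matrix.

    Returns
    -------
    (ids, C) : kept individual ids and the correlation matrix.
    """
    G = grm.A if which == "additive" else grm.D if which == "dominance" else None
    if G is None:
        raise ValueError(f"which must be 'additive' or 'dominance', got {which!r}")
    d = np.diag(G)
    bad = d <= 0
    if bad.any():
        names = [grm.individual_ids[i] for i in np.flatnonzero(bad)]
        if not drop_degenerate:
            raise DegenerateIndividualError(
                f"nonpositive {which} GRM diagonal for individuals {names[:5]}"
            )
        keep = np.flatnonzero(~bad)
        G = G[np.ix_(keep, keep)]
        d = np.diag(G)
        ids = [grm.individual_ids[i] for i in keep]
    else:
        ids = list(grm.individual_ids)
    s = 1.0 / np.sqrt(d)
    C = G * np.outer(s, s)
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return ids, C


@dataclass
class CorrelationSummary:
    group: str  # within-pop labels or "between"
    n_pairs: int
    mean: float
    se: float


def _pair_values(C: np.ndarray, idx1: np.ndarray, idx2: np.ndarray | None = None) -> np.ndarray:
    """Off-diagonal pairwise values within idx1, or all cross pairs idx1 x idx2."""
    if idx2 is None:
        sub = C[np.ix_(idx1, idx1)]
        iu = np.triu_indices(len(idx1), k=1)
        return sub[iu]
    return C[np.ix_(idx1, idx2)].ravel()


def summarize_correlations(ids: list[str], C: np.ndarray, cohort: CohortTable,
                           n_permutations: int = 0, seed: int | None = None):
    """Group-wise means of pairwise genomic correlations plus mean-difference tests.

    Pairs are grouped as within-population-1, within-population-2 and
    between-populations. Mean differences use Welch two-sample t-tests with
    Holm correction; because pairwise values sharing an individual are
    dependent, the P-values are approximate. With ``n_permutations > 0`` a
    label-permutation P-value is added for each comparison as a
    dependence-robust check.

    Returns
    -------
    (summaries, tests) : list of CorrelationSummary and a DataFrame of the
    three pairwise comparisons with columns group_a, group_b, t, p_welch,
    p_holm (and p_perm when requested).
    """
    cohort = CohortTable(cohort.table[cohort.table["id"].isin(ids)])
    pops = cohort.populations
    if len(pops) != 2:
        raise ValueError(f"expected exactly two populations, got {pops}")
    pos = {iid: k for k, iid in enumerate(ids)}
    pop_of = dict(zip(cohort.table["id"], cohort.table["population"]))
    idx = {p: np.array([pos[i] for i in ids if pop_of[i] == p]) for p in pops}
    for p in pops:
        if len(idx[p]) < 2:
            raise ValueError(f"population {p} has < 2 individuals; within-group summary undefined")

    groups = {
        f"within-{pops[0]}": _pair_values(C, idx[pops[0]]),
        f"within-{pops[1]}": _pair_values(C, idx[pops[1]]),
        "between": _pair_values(C, idx[pops[0]], idx[pops[1]]),
    }
    summaries = [
        CorrelationSummary(name, len(v), float(np.mean(v)),
                           float(np.std(v, ddof=1) / np.sqrt(len(v))))
        for name, v in groups.items()
    ]

    rng = np.random.default_rng(seed)
    rows = []
    names = list(groups)
    for a in range(3):
        for b in range(a + 1, 3):
            va, vb = groups[names[a]], groups[names[b]]
            t, p = stats.ttest_ind(va, vb, equal_var=False)
            row = {"group_a": names[a], "group_b": names[b], "t": float(t), "p_welch": float(p)}
            if n_permutations > 0:
                obs = abs(np.mean(va) - np.mean(vb))
                pooled = np.concatenate([va, vb])
                hits = 0
                for _ in range(n_permutations):
                    rng.shuffle(pooled)
                    if abs(pooled[: len(va)].mean() - pooled[len(va):].mean()) >= obs:
                        hits += 1
                row["p_perm"] = (hits + 1) / (n_permutations + 1)
            rows.append(row)
    tests = pd.DataFrame(rows)
    tests["p_holm"] = multipletests(tests["p_welch"], method="holm")[1]
    return summaries, tests


# ---------------------------------------------------------------------------
# GCTA-style plain-text serialization
# ---------------------------------------------------------------------------

def write_grm_text(ids: list[str], G: np.ndarray, n_markers: int, prefix: str) -> None:
    """Write ``prefix.grm`` (lower triangle: i j n_markers value) and ``prefix.grm.id``."""
    n = len(ids)
    with open(prefix + ".grm", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_markers}\t{float(G[i, j])!r}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_text(prefix: str) -> tuple[list[str], np.ndarray, int]:
    ids = []
    with open(prefix + ".grm.id") as fh:
        for line in fh:
            ids.append(line.split()[1])
    n = len(ids)
    G = np.zeros((n, n))
    n_markers = 0
    with open(prefix + ".grm") as fh:
        for line in fh:
            i, j, m, v = line.split()
            G[int(i) - 1, int(j) - 1] = G[int(j) - 1, int(i) - 1] = float(v)
            n_markers = int(m)
    return ids, G, n_markers


def write_grm_square(ids: list[str], G: np.ndarray, path: str) -> None:
    """Square whitespace matrix with an id header row — convenient for small n."""
    with open(path, "w") as fh:
        fh.write(" ".join(ids) + "\n")
        for row in G:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
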