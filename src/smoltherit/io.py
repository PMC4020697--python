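"""Reading and writing genotype / phenotype tables, and marker quality control.

Two genotype dialects are supported:

* ``tsv`` — header row of marker ids; one row per individual, first column the
  individual id, remaining columns dosages in {0,1,2} with ``NA`` for missing.
* ``plink_raw`` — the PLINK ``--recode A`` text layout: whitespace separated,
  six leading columns (FID IID PAT MAT SEX PHENOTYPE), genotype columns named
  ``marker_allele`` where the trailing letter is the counted allele.

QC follows the two-stage filter used in wild salmonid SNP panels: markers with
missing calls in more than ``max_missing`` of all individuals are removed
first, then markers with minor allele frequency below ``min_maf`` in the
combined sample. Ties at either threshold are kept (removal requires strictly
exceeding the missingness bound; retention requires MAF >= the bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CohortTable, GenotypeMatrix, GenotypeValidationError

PLINK_LEAD_COLUMNS = 6
_VALID_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0}


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files; carries the offending line number."""


class UndefinedFrequencyError(ValueError):
    """Raised when an allele frequency is requested for an all-missing marker."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_code(token: str, na_token: str, path: str, lineno: int) -> float:
    if token == na_token:
        return np.nan
    try:
        return _VALID_TOKENS[token]
    except KeyError:
        raise GenotypeParseError(
            f"{path}:{lineno}: genotype token {token!r} is not 0/1/2/{na_token}"
        ) from None


def read_genotypes(path: str, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the given dialect."""
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "plink_raw":
        return _read_plink_raw(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'plink_raw'")


def _read_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeParseError(f"{path}:1: empty header")
        marker_ids = header.split("\t")[1:]
        if not marker_ids:
            raise GenotypeParseError(f"{path}:1: header names no markers")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(marker_ids) + 1:
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(marker_ids) + 1} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            rows.append([_parse_code(t, "NA", path, lineno) for t in parts[1:]])
    if not rows:
        raise GenotypeParseError(f"{path}: no individuals")
    return GenotypeMatrix(ids, marker_ids, np.array(rows, dtype=float))


def _read_plink_raw(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:PLINK_LEAD_COLUMNS] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise GenotypeParseError(f"{path}:1: not a PLINK .raw header")
        marker_cols = header[PLINK_LEAD_COLUMNS:]
        marker_ids, counted = [], []
        for col in marker_cols:
            name, _, allele = col.rpartition("_")
            if not name:
                name, allele = col, "A"
            marker_ids.append(name)
            counted.append(allele)
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            rows.append([_parse_code(t, "NA", path, lineno) for t in parts[PLINK_LEAD_COLUMNS:]])
    if not rows:
        raise GenotypeParseError(f"{path}: no individuals")
    return GenotypeMatrix(ids, marker_ids, np.array(rows, dtype=float), counted)


def write_genotypes(g: GenotypeMatrix, path: str, dialect: str = "tsv") -> None:
    """Write a genotype matrix; round-trips exactly with :func:`read_genotypes`."""
    def fmt(v: float) -> str:
        return "NA" if np.isnan(v) else str(int(v))

    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("id\t" + "\t".join(g.marker_ids) + "\n")
            for iid, row in zip(g.individual_ids, g.codes):
                fh.write(iid + "\t" + "\t".join(fmt(v) for v in row) + "\n")
        elif dialect == "plink_raw":
            cols = [f"{m}_{a}" for m, a in zip(g.marker_ids, g.counted_allele)]
            fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(cols) + "\n")
            for iid, row in zip(g.individual_ids, g.codes):
                fh.write(f"{iid} {iid} 0 0 0 -9 " + " ".join(fmt(v) for v in row) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_phenotypes(path: str) -> CohortTable:
    """Read the phenotype TSV: columns id, population, sex (F/M/NA), smolt (1/2)."""
    tab = pd.read_csv(path, sep="\t", dtype={"id": str, "population": str, "sex": str},
                      keep_default_na=False, na_values=[""])
    tab["sex"] = tab["sex"].replace("", "NA")
    tab["smolt"] = tab["smolt"].astype(int)
    return CohortTable(tab)


def write_phenotypes(cohort: CohortTable, path: str) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele frequencies and QC
# ---------------------------------------------------------------------------

def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per marker from non-missing codes only."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    return p


def compute_allele_frequency(g: GenotypeMatrix, marker: str,
                             subset: list[str] | None = None) -> float:
    """Frequency of the counted allele at ``marker`` within ``subset``.

    Missing codes do not contribute to numerator or denominator.
    """
    j = g.marker_ids.index(marker)
    sub = g if subset is None else g.subset_individuals(list(subset))
    col = sub.codes[:, j]
    ok = ~np.isnan(col)
    if not ok.any():
        raise UndefinedFrequencyError(f"marker {marker}: all codes missing in subset")
    return float(col[ok].sum() / (2.0 * ok.sum()))


@dataclass
class MarkerQcReport:
    """Per-marker QC metrics over all input markers (pre-filter)."""

    marker_ids: list[str]
    missing_fraction: np.ndarray
    minor_allele_frequency: np.ndarray  # nan where undefined (all missing)
    pass_missingness: np.ndarray
    pass_maf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "missing_fraction": self.missing_fraction,
            "maf": self.minor_allele_frequency,
            "pass_missingness": self.pass_missingness,
            "pass_maf": self.pass_maf,
        })

    @property
    def n_pass(self) -> int:
        return int((self.pass_missingness & self.pass_maf).sum())


class MarkerQC(BaseEstimator, TransformerMixin):
    """Two-stage marker filter: missingness, then minor allele frequency.

    sklearn-style transformer over the raw dosage matrix (n x m float with
    NaN for missing). ``fit`` computes the per-marker report; ``transform``
    drops failing columns. Stage order matters for bookkeeping only — MAF is
    evaluated for every marker, but a marker removed at stage 1 is reported
    with its MAF regardless.

    Parameters
    ----------
    max_missing : float, default 0.20
        Markers whose missing fraction strictly exceeds this are removed.
    min_maf : float, default 0.05
        Markers whose MAF (on ``maf_rows`` individuals, default all — the
        combined sample) is below this are removed; exactly at threshold
        passes.
    """

    def __init__(self, max_missing: float = 0.20, min_maf: float = 0.05):
        self.max_missing = max_missing
        self.min_maf = min_maf

    def fit(self, X, y=None, marker_ids=None, maf_rows=None):
        if not (0 <= self.max_missing < 1):
            raise ValueError("max_missing must be in [0, 1)")
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if marker_ids is None:
            marker_ids = [f"m{j}" for j in range(m)]
        miss = np.isnan(X).sum(axis=0) / n
        rows = X if maf_rows is None else X[np.asarray(maf_rows)]
        p = allele_frequencies(rows)
        maf = np.minimum(p, 1.0 - p)
        pass_miss = miss <= self.max_missing
        # markers undefined in the MAF subset fail MAF
        pass_maf = np.where(np.isnan(maf), False, maf >= self.min_maf)
        self.report_ = MarkerQcReport(list(marker_ids), miss, maf, pass_miss, pass_maf)
        self.keep_ = pass_miss & pass_maf
        self.n_features_in_ = m
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.keep_]


def apply_marker_qc(g: GenotypeMatrix, max_missing: float = 0.20,
                    min_maf: float = 0.05,
                    maf_subset: list[str] | None = None) -> tuple[GenotypeMatrix, MarkerQcReport]:
    """Filter markers by missingness then MAF; returns survivors and full report.

    ``maf_subset`` selects the individuals on which MAF is computed (default:
    all individuals, i.e. the combined two-population sample). Missingness is
    always computed over all individuals.
    """
    rows = None
    if maf_subset is not None:
        pos = {iid: k for k, iid in enumerate(g.individual_ids)}
        rows = [pos[i] for i in maf_subset]
    qc = MarkerQC(max_missing=max_missing, min_maf=min_maf)
    qc.fit(g.codes, marker_ids=g.marker_ids, maf_rows=rows)
    return g.subset_markers(qc.keep_), qc.report_
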