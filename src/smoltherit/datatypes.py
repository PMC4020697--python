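"""Core in-memory containers for genotype and cohort data.

Genotype codes count copies of a designated allele at each biallelic SNP,
so every entry is 0, 1 or 2; missing calls are stored as NaN in a float
matrix, which keeps all downstream linear algebra vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_LEVELS = ("F", "M", "NA")


class GenotypeValidationError(ValueError):
    """Raised when a genotype matrix or cohort table violates an invariant."""


@dataclass
class GenotypeMatrix:
    """An n x m diploid SNP dosage matrix with missing values.

    Parameters
    ----------
    individual_ids : list of str
        Unique row identifiers.
    marker_ids : list of str
        Unique column identifiers.
    codes : ndarray of shape (n, m), dtype float
        Counted-allele dosages in {0, 1, 2}; missing calls are ``nan``.
    counted_allele : list of str, optional
        Per-marker label of the allele whose copies are counted (e.g. the
        trailing letter of a PLINK ``.raw`` column name). Defaults to "A".
    """

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    counted_allele: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise GenotypeValidationError("codes must be a 2-D matrix")
        n, m = self.codes.shape
        if n < 1:
            raise GenotypeValidationError("need at least one individual")
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise GenotypeValidationError("id lists do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise GenotypeValidationError("duplicate individual id")
        if len(set(self.marker_ids)) != m:
            raise GenotypeValidationError("duplicate marker id")
        finite = self.codes[~np.isnan(self.codes)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise GenotypeValidationError(f"genotype code {bad!r} outside {{0,1,2,NA}}")
        if not self.counted_allele:
            self.counted_allele = ["A"] * m

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {iid: k for k, iid in enumerate(self.individual_ids)}
        idx = [pos[i] for i in ids]
        return GenotypeMatrix(
            individual_ids=list(ids),
            marker_ids=list(self.marker_ids),
            codes=self.codes[idx, :].copy(),
            counted_allele=list(self.counted_allele),
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the markers in boolean/index array ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[j] for j in keep],
            codes=self.codes[:, keep].copy(),
            counted_allele=[self.counted_allele[j] for j in keep],
        )


@dataclass
class CohortTable:
    """Per-individual phenotype records: population, sex and the binary trait.

    The migratory life-history trait keeps its original 1/2 coding in storage
    (1 = migratory/smolt, 2 = nonmigratory/resident); analysis modules recode
    to 0/1 internally. Sex is a three-level factor ("F", "M", "NA") because
    real cohorts contain fish of unknown sex.
    """

    table: pd.DataFrame  # columns: id, population, sex, smolt

    def __post_init__(self) -> None:
        required = ["id", "population", "sex", "smolt"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise GenotypeValidationError(f"cohort table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["id"].duplicated().any():
            raise GenotypeValidationError("duplicate individual id in cohort table")
        if not self.table["smolt"].isin([1, 2]).all():
            raise GenotypeValidationError("smolt codes must be 1 (migratory) or 2 (nonmigratory)")
        self.table["sex"] = self.table["sex"].fillna("NA").astype(str)
        if not self.table["sex"].isin(SEX_LEVELS).all():
            raise GenotypeValidationError(f"sex must be one of {SEX_LEVELS}")

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    def aligned_to(self, genotypes: GenotypeMatrix) -> "CohortTable":
        """Reorder rows to match the genotype matrix; every id must be present."""
        missing = set(genotypes.individual_ids) - set(self.ids)
        if missing:
            raise GenotypeValidationError(f"cohort lacks genotyped individuals: {sorted(missing)[:5]}")
        tab = self.table.set_index("id").loc[genotypes.individual_ids].reset_index()
        return CohortTable(tab)

    def smolt01(self) -> np.ndarray:
        """Binary trait recoded 1/2 -> 1/0 (1 = migratory)."""
        return (self.table["smolt"].to_numpy() == 1).astype(float)
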