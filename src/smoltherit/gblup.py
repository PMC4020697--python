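"""Genomic best linear unbiased prediction at converged variance components.

With P evaluated at the REML estimates, the BLUPs of the random effects are

    a_hat = sigma2_a A_g P y      (breeding values)
    d_hat = sigma2_d D_g P y      (dominance deviations)
    g_hat = a_hat + d_hat         (total genetic values)

These are the closed-form equivalents of solving Henderson's mixed-model
equations at the same components; the MME route is kept as a test oracle
only. Because P annihilates the fixed-effects column space, predictions are
invariant to adding a constant to the phenotype, and they scale linearly
with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CohortTable
from .greml import MixedModelSpec, VarianceEstimate, _reml_parts


@dataclass
class PredictionSet:
    individual_ids: list[str]
    gblup_a: np.ndarray
    gblup_d: np.ndarray
    gblup_g: np.ndarray
    cohort: CohortTable | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "id": self.individual_ids,
            "gblup_a": self.gblup_a,
            "gblup_d": self.gblup_d,
            "gblup_g": self.gblup_g,
        })
        if self.cohort is not None:
            meta = self.cohort.table[["id", "population", "smolt"]]
            out = out.merge(meta, on="id", how="left")
            out = out[["id", "population", "smolt", "gblup_a", "gblup_d", "gblup_g"]]
        return out


def predict(spec: MixedModelSpec, est: VarianceEstimate,
            individual_ids: list[str] | None = None,
            cohort: CohortTable | None = None) -> PredictionSet:
    """BLUPs of additive, dominance and total genetic effects for the fitted
    individuals, evaluated at the converged variance components."""
    n = spec.n
    if individual_ids is None:
        individual_ids = [f"i{k}" for k in range(n)]
    if len(individual_ids) != n:
        raise ValueError("individual_ids not aligned with the model spec")
    _, _, Py = _reml_parts(est.components(), spec)
    a = est.sigma2_a * (spec.A @ Py)
    d = est.sigma2_d * (spec.D @ Py)
    return PredictionSet(list(individual_ids), a, d, a + d, cohort)


@dataclass
class SeparationReport:
    component: str
    complete: bool
    overlap_count: int
    positive_class: int | None  # smolt code of the class with the larger mean
    class_ranges: dict


def separation_report(preds: PredictionSet, cohort: CohortTable,
                      component: str = "a") -> SeparationReport:
    """Do the predictions for the two trait classes overlap?

    Complete separation means the maximum of one class lies below the minimum
    of the other. Otherwise the overlap count is the number of individuals
    whose value falls inside the other class's range. Separation is
    scale-free, so near-zero components (e.g. additive predictions of order
    1e-59 when sigma2_a has collapsed) can still separate the classes.
    """
    values = {"a": preds.gblup_a, "d": preds.gblup_d, "g": preds.gblup_g}.get(component)
    if values is None:
        raise ValueError("component must be 'a', 'd' or 'g'")
    aligned = cohort.table.set_index("id").loc[preds.individual_ids]
    smolt = aligned["smolt"].to_numpy()
    classes = np.unique(smolt)
    if len(classes) < 2:
        raise ValueError("both trait classes must be present to assess separation")
    v1, v2 = values[smolt == classes[0]], values[smolt == classes[1]]
    complete = (v1.max() < v2.min()) or (v2.max() < v1.min())
    overlap = 0
    if not complete:
        overlap += int(np.sum((v1 >= v2.min()) & (v1 <= v2.max())))
        overlap += int(np.sum((v2 >= v1.min()) & (v2 <= v1.max())))
    positive = int(classes[0] if v1.mean() > v2.mean() else classes[1])
    return SeparationReport(
        component=component, complete=bool(complete), overlap_count=overlap,
        positive_class=positive,
        class_ranges={int(c): (float(values[smolt == c].min()),
                               float(values[smolt == c].max())) for c in classes},
    )
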