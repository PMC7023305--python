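"""Dual missing-value imputation for case-control panels.

Missing cells carry information, and the right fill depends on why the
value is absent:

* **structural zeros** — drug and tobacco-metabolite sub-pathways, where
  a missing value means the compound genuinely is not in the subject's
  blood; imputed as 0;
* **below-LOD minima** — everything else is biologically required even
  when undetected, so a missing value is left-censored; imputed as that
  metabolite's minimum observed value over all subjects, both cohorts
  pooled ("within the project").

The report also stratifies the biologically required metabolites by
missingness burden (complete / missing in <=20% of subjects / more),
the audit a reader needs to judge how much of the matrix is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .panel_data import (
    Cohort,
    DEFAULT_STRUCTURAL_ZERO_MARKERS,
    ImputationClass,
    MetaboliteAnnotation,
    PanelDataset,
    is_structural_zero_subpathway,
)

__all__ = [
    "ImputationReport",
    "classify_imputation",
    "impute_dataset",
    "missingness_strata",
]

#: Fraction-of-subjects boundary between the low- and high-missingness
#: strata. Exactly-at-boundary metabolites fall in the lower stratum.
STRATUM_BOUNDARY = 0.20


@dataclass(frozen=True)
class ImputationReport:
    """Audit of the missingness and the imputations performed."""

    n_cells: int
    n_missing: int
    n_zero_imputed: int
    n_min_imputed: int
    #: Over biological_min metabolites only:
    n_complete: int
    n_low_missing: int  # missing in (0, 20%] of subjects
    n_high_missing: int  # missing in > 20% of subjects
    per_cohort_missing: Mapping[Cohort, int]

    @property
    def strata(self) -> tuple[int, int, int]:
        return (self.n_complete, self.n_low_missing, self.n_high_missing)


def classify_imputation(
    annotation: MetaboliteAnnotation,
    structural_zero_markers: Sequence[str] = DEFAULT_STRUCTURAL_ZERO_MARKERS,
) -> ImputationClass:
    """Imputation class implied by a metabolite's sub-pathway."""
    if is_structural_zero_subpathway(annotation.sub_pathway, structural_zero_markers):
        return ImputationClass.STRUCTURAL_ZERO
    return ImputationClass.BIOLOGICAL_MIN


def missingness_strata(dataset: PanelDataset) -> tuple[int, int, int]:
    """(complete, low, high) metabolite counts among biological_min rows.

    ``low`` is missing in at most 20% of subjects (but at least one),
    ``high`` strictly more than 20%.
    """
    n_complete = n_low = n_high = 0
    n_sub = dataset.n_subjects
    for i, ann in enumerate(dataset.annotations):
        if ann.imputation_class is not ImputationClass.BIOLOGICAL_MIN:
            continue
        n_miss = int(dataset.mask[i].sum())
        if n_miss == 0:
            n_complete += 1
        elif n_sub and n_miss / n_sub <= STRATUM_BOUNDARY:
            n_low += 1
        else:
            n_high += 1
    return (n_complete, n_low, n_high)


def impute_dataset(dataset: PanelDataset) -> tuple[PanelDataset, ImputationReport]:
    """Fill every missing cell; return the complete dataset and the audit.

    Observed values are never touched; imputing an already-complete
    dataset is the identity. A biological_min metabolite missing in all
    subjects has no observed minimum and is a hard error.
    """
    out = dataset.copy()
    n_zero = n_min = 0
    for i, ann in enumerate(out.annotations):
        miss = out.mask[i]
        if not miss.any():
            continue
        if ann.imputation_class is ImputationClass.STRUCTURAL_ZERO:
            out.values[i, miss] = 0.0
            n_zero += int(miss.sum())
        else:
            observed = out.values[i, ~miss]
            if observed.size == 0:
                raise ValueError(
                    f"metabolite {ann.metabolite_id!r} ({ann.name}) is missing in all "
                    "subjects; no minimum exists for below-LOD imputation"
                )
            out.values[i, miss] = observed.min()
            n_min += int(miss.sum())

    per_cohort = {
        c: int(dataset.mask[:, dataset.cohort_columns(c)].sum()) for c in Cohort
    }
    strata = missingness_strata(dataset)
    report = ImputationReport(
        n_cells=dataset.n_metabolites * dataset.n_subjects,
        n_missing=dataset.n_missing,
        n_zero_imputed=n_zero,
        n_min_imputed=n_min,
        n_complete=strata[0],
        n_low_missing=strata[1],
        n_high_missing=strata[2],
        per_cohort_missing=per_cohort,
    )
    out.mask[:] = False
    return out, report
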