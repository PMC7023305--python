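"""Inclusive sub-pathway summary: averaged controls/patients median ratios.

Formal enrichment statistics discard every metabolite that misses an
identifier or a significance threshold; this summary instead keeps the
whole panel in view. Per metabolite it takes the ratio of the cohort
medians (controls/patients; medians because panel abundances span wide
ranges and means are outlier-prone), then averages those ratios
arithmetically over each sub-pathway. A sub-pathway whose members all
drift the same way stands out even when no single member survives
multiple-testing correction.

Ratios are undefined when the patient median is 0 while the control
median is positive (zero-imputed drug compounds); those members are
excluded from the average and counted, never clamped. For display, the
drug sub-pathways and tobacco metabolites — dominated by structural
zeros — are conventionally omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import AbstractSet, Sequence

import numpy as np

from .panel_data import (
    Cohort,
    DEFAULT_STRUCTURAL_ZERO_MARKERS,
    MetaboliteAnnotation,
    PanelDataset,
    is_structural_zero_subpathway,
)

__all__ = [
    "SubPathwayRatio",
    "median_ratio",
    "subpathway_ratios",
    "default_display_exclusions",
]


@dataclass(frozen=True)
class SubPathwayRatio:
    """Averaged median fold change (controls/patients) for one sub-pathway."""

    sub_pathway: str
    super_pathway: str
    n_members: int
    mean_median_ratio: float  # nan when no member has a defined ratio
    n_undefined: int


def median_ratio(
    values: Sequence[float], cohorts: Sequence[Cohort | str]
) -> float | None:
    """controls-median / patients-median for one metabolite.

    ``None`` when the patient median is 0 with a positive control median;
    1.0 when both medians are 0. Both cohorts must be represented.
    """
    v = np.asarray(values, dtype=float)
    labels = np.array([Cohort(c).value for c in cohorts])
    ctrl = v[labels == Cohort.CONTROL.value]
    pat = v[labels == Cohort.PATIENT.value]
    if ctrl.size == 0 or pat.size == 0:
        raise ValueError("both cohorts must be represented")
    mc, mp = float(np.median(ctrl)), float(np.median(pat))
    if mp == 0.0:
        return 1.0 if mc == 0.0 else None
    return mc / mp


def default_display_exclusions(
    annotations: Sequence[MetaboliteAnnotation],
    markers: Sequence[str] = DEFAULT_STRUCTURAL_ZERO_MARKERS,
) -> set[str]:
    """The drug + tobacco sub-pathways conventionally omitted from plots."""
    return {
        a.sub_pathway
        for a in annotations
        if is_structural_zero_subpathway(a.sub_pathway, markers)
    }


def subpathway_ratios(
    dataset: PanelDataset,
    exclusions: AbstractSet[str] = frozenset(),
    average: str = "arithmetic",
) -> list[SubPathwayRatio]:
    """One averaged median ratio per non-excluded sub-pathway.

    The dataset must be complete (imputed). Sub-pathways appear in order
    of first appearance. ``average`` is ``arithmetic`` (default, matching
    the plain average of ratios) or ``geometric`` (symmetric under cohort
    swap, offered as an alternative).
    """
    if dataset.n_missing:
        raise ValueError("dataset contains missing cells; impute first")
    if average not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown average {average!r}")
    cohorts = [s.cohort for s in dataset.subjects]

    order: list[str] = []
    members: dict[str, list[int]] = {}
    supers: dict[str, str] = {}
    for i, ann in enumerate(dataset.annotations):
        if ann.sub_pathway in exclusions:
            continue
        if ann.sub_pathway not in members:
            order.append(ann.sub_pathway)
            members[ann.sub_pathway] = []
            supers[ann.sub_pathway] = ann.super_pathway
        members[ann.sub_pathway].append(i)

    out: list[SubPathwayRatio] = []
    for sub in order:
        ratios: list[float] = []
        n_undef = 0
        for i in members[sub]:
            r = median_ratio(dataset.values[i], cohorts)
            if r is None:
                n_undef += 1
            else:
                ratios.append(r)
        if ratios:
            if average == "arithmetic":
                mean_ratio = float(np.mean(ratios))
            else:
                mean_ratio = float(np.exp(np.mean(np.log(ratios))))
        else:
            mean_ratio = math.nan
        out.append(
            SubPathwayRatio(
                sub_pathway=sub,
                super_pathway=supers[sub],
                n_members=len(members[sub]),
                mean_median_ratio=mean_ratio,
                n_undefined=n_undef,
            )
        )
    return out
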