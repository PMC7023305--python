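"""Chemical-set (ChemRICH-style) cluster enrichment.

A cluster is a set of metabolites sharing a chemical class — here the
vendor sub-pathway partition, or any user-supplied map. Under the null,
a cluster's member p-values are i.i.d. Uniform(0,1); enrichment is a
one-sided Kolmogorov-Smirnov test (alternative: stochastically smaller
than uniform, D+ statistic), so a cluster scores well only when its
members are collectively shifted toward small p-values. Per-cluster
results carry the counts a reviewer wants from an enrichment table:
members altered at the raw-p threshold, split by fold direction
(patients vs controls), plus the best-scoring key compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .panel_data import (
    DEFAULT_STRUCTURAL_ZERO_MARKERS,
    MetaboliteAnnotation,
    is_structural_zero_subpathway,
)
from .univariate_stats import Direction, MetaboliteTestResult, bh_adjust

logger = logging.getLogger("metabopanel")

__all__ = ["ClusterResult", "build_clusters", "enrich_clusters", "ks_uniform_pvalue"]

#: Clusters smaller than this are dropped: a KS test on one or two points
#: is uninformative.
DEFAULT_MIN_CLUSTER_SIZE = 3


@dataclass(frozen=True)
class ClusterResult:
    """Enrichment summary for one metabolite cluster."""

    cluster_name: str
    size: int
    p_value: float
    q_value: float
    n_altered: int
    n_increased: int  # altered members higher in patients
    n_decreased: int  # altered members lower in patients
    key_compound: str  # member with the smallest raw p
    is_drug: bool = False


def build_clusters(
    annotations: Sequence[MetaboliteAnnotation],
    scheme: str = "sub_pathway",
    external_map: Mapping[str, str] | None = None,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> dict[str, list[str]]:
    """Partition metabolites into named clusters.

    ``scheme='sub_pathway'`` groups by the annotation field;
    ``scheme='external_map'`` uses a metabolite_id -> cluster_name map,
    which must not reference unknown ids. Clusters below ``min_size`` are
    dropped (logged).
    """
    known = {a.metabolite_id for a in annotations}
    clusters: dict[str, list[str]] = {}
    if scheme == "sub_pathway":
        for a in annotations:
            clusters.setdefault(a.sub_pathway, []).append(a.metabolite_id)
    elif scheme == "external_map":
        if external_map is None:
            raise ValueError("external_map scheme requires a mapping")
        unknown = sorted(set(external_map) - known)
        if unknown:
            raise ValueError(f"external map references unknown metabolite ids: {unknown}")
        for a in annotations:  # annotation order; unmapped metabolites excluded
            name = external_map.get(a.metabolite_id)
            if name is not None:
                clusters.setdefault(name, []).append(a.metabolite_id)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    small = [name for name, members in clusters.items() if len(members) < min_size]
    if small:
        logger.info("dropping %d clusters below min size %d", len(small), min_size)
    for name in small:
        del clusters[name]
    return clusters


def ks_uniform_pvalue(p_values: np.ndarray) -> float:
    """One-sided KS p: are these p-values stochastically smaller than U(0,1)?"""
    res = stats.ks_1samp(p_values, stats.uniform.cdf, alternative="greater")
    return float(res.pvalue)


def enrich_clusters(
    results: Sequence[MetaboliteTestResult],
    clusters: Mapping[str, Sequence[str]],
    alpha_altered: float = 0.05,
    drug_markers: Sequence[str] = DEFAULT_STRUCTURAL_ZERO_MARKERS,
) -> list[ClusterResult]:
    """Score every cluster; q-values are BH over the retained clusters.

    Every cluster member must have a test result. Altered members are
    those with raw p below ``alpha_altered``; they split into increased /
    decreased in patients by the controls/patients mean fold change
    (fc < 1 means higher in patients). Drug clusters are scored like any
    other but flagged so reports can filter them.
    """
    if not results:
        raise ValueError("empty result list")
    by_id = {r.metabolite_id: r for r in results}
    names = list(clusters.keys())
    out: list[ClusterResult] = []
    pvals = []
    for name in names:
        members = clusters[name]
        missing = [m for m in members if m not in by_id]
        if missing:
            raise ValueError(f"cluster {name!r} has members without test results: {missing}")
        member_p = np.array([by_id[m].p_value for m in members], dtype=float)
        ks_p = ks_uniform_pvalue(member_p)
        pvals.append(ks_p)

        altered = [by_id[m] for m in members if by_id[m].p_value < alpha_altered]
        n_inc = sum(1 for r in altered if r.direction is Direction.UP_IN_PATIENTS)
        n_dec = sum(1 for r in altered if r.direction is Direction.DOWN_IN_PATIENTS)
        # flat-direction altered members are counted as neither; keep the
        # ClusterResult invariant by folding them into the smaller side
        n_flat = len(altered) - n_inc - n_dec
        n_dec += n_flat
        best_p = member_p.min()
        key = min(m for m in members if by_id[m].p_value == best_p)
        out.append(
            ClusterResult(
                cluster_name=name,
                size=len(members),
                p_value=ks_p,
                q_value=np.nan,  # filled below
                n_altered=len(altered),
                n_increased=n_inc,
                n_decreased=n_dec,
                key_compound=key,
                is_drug=is_structural_zero_subpathway(name, drug_markers),
            )
        )
    qvals = bh_adjust(pvals)
    return [replace(r, q_value=float(q)) for r, q in zip(out, qvals)]
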