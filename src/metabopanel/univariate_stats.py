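"""Per-metabolite differential-abundance statistics.

Non-parametric throughout: two-sided Wilcoxon rank-sum tests per
metabolite, Benjamini-Hochberg FDR either over the whole panel or
dichotomized within super-pathways (regaining power in a small cohort),
controls/patients fold changes of means and of medians, and volcano-style
joint selection (|fold change| >= 2 combined with p < 0.1). Rank tests
are invariant to monotone transforms, so testing happens on the natural
scale; ``normalize_matrix`` / ``filter_features`` implement the separate
log + autoscale + dispersion-filter preprocessing path used by
projection-style analyses.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_data import Cohort, PanelDataset

logger = logging.getLogger("metabopanel")

__all__ = [
    "Direction",
    "QScope",
    "MetaboliteTestResult",
    "rank_sum_test",
    "bh_adjust",
    "fold_change",
    "test_all",
    "volcano_select",
    "dichotomized_adjust",
    "normalize_matrix",
    "filter_features",
]


class Direction(str, Enum):
    UP_IN_PATIENTS = "up_in_patients"
    DOWN_IN_PATIENTS = "down_in_patients"
    FLAT = "flat"


class QScope(str, Enum):
    WHOLE_PANEL = "whole_panel"
    SUPER_PATHWAY = "super_pathway"


@dataclass(frozen=True)
class MetaboliteTestResult:
    """Differential-abundance result for one metabolite.

    Fold changes are oriented controls/patients (ratio > 1 means lower in
    patients); ``None`` marks the undefined-divergent case where the
    patient center is 0 while the control center is positive.
    """

    metabolite_id: str
    p_value: float
    q_value: float
    q_scope: QScope
    fc_mean: float | None
    fc_median: float | None
    direction: Direction


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 24  # enumeration guard for the tie-aware exact path


def _exact_enumeration_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all label assignments.

    Midranks make this valid under ties. p = 2 * min(P(W <= w), P(W >= w))
    capped at 1, with W the rank sum of sample ``a``.
    """
    pooled = np.concatenate([a, b])
    n = pooled.size
    if n > _EXACT_MAX_N:
        raise ValueError(
            f"exact enumeration limited to pooled n <= {_EXACT_MAX_N}; use normal_approx"
        )
    ranks = stats.rankdata(pooled)
    w_obs = ranks[: a.size].sum()
    sums = np.fromiter(
        (ranks[list(c)].sum() for c in itertools.combinations(range(n), a.size)),
        dtype=float,
    )
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``exact`` enumerates the permutation null (small samples only);
    ``normal_approx`` uses midranks with tie-corrected variance and a 0.5
    continuity correction; ``auto`` picks exact when the pooled sample has
    at most 20 values and no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0  # no evidence convention: identical constant samples
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (pooled.size <= 20 and not has_ties) else "normal_approx"
    if method == "exact":
        if has_ties:
            return _exact_enumeration_p(a, b)
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    if method == "normal_approx":
        return float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dichotomized_adjust(
    results: Sequence[MetaboliteTestResult],
    groups: Sequence[str] | Mapping[str, str],
) -> list[MetaboliteTestResult]:
    """Re-adjust p-values independently within each group (super-pathway).

    ``groups`` is either a sequence aligned with ``results`` or a mapping
    metabolite_id -> group label. Results come back in input order with
    ``q_scope`` set to super_pathway.
    """
    if isinstance(groups, Mapping):
        labels = [groups[r.metabolite_id] for r in results]
    else:
        labels = list(groups)
        if len(labels) != len(results):
            raise ValueError("groups must align with results")
    out: list[MetaboliteTestResult | None] = [None] * len(results)
    by_group: dict[str, list[int]] = {}
    for i, g in enumerate(labels):
        by_group.setdefault(g, []).append(i)
    for idxs in by_group.values():
        q = bh_adjust([results[i].p_value for i in idxs])
        for i, qi in zip(idxs, q):
            out[i] = replace(results[i], q_value=float(qi), q_scope=QScope.SUPER_PATHWAY)
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def fold_change(
    a: Sequence[float], b: Sequence[float], center: str = "mean"
) -> float | None:
    """controls/patients fold change of the chosen center.

    ``a`` are controls, ``b`` patients. Returns ``None`` (undefined,
    divergent) when the patient center is 0 with a positive control
    center; 1.0 when both centers are 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    fn = np.mean if center == "mean" else np.median
    if center not in ("mean", "median"):
        raise ValueError(f"unknown center {center!r}")
    ca, cb = float(fn(a)), float(fn(b))
    if cb == 0.0:
        return 1.0 if ca == 0.0 else None
    return ca / cb


def _direction(fc: float | None) -> Direction:
    if fc is None:  # divergent: controls positive, patients 0
        return Direction.DOWN_IN_PATIENTS
    if fc > 1.0:
        return Direction.DOWN_IN_PATIENTS
    if fc < 1.0:
        return Direction.UP_IN_PATIENTS
    return Direction.FLAT


# ---------------------------------------------------------------------------
# Panel-wide testing
# ---------------------------------------------------------------------------

def test_all(
    dataset: PanelDataset,
    method: str = "normal_approx",
    allow_missing: bool = False,
) -> list[MetaboliteTestResult]:
    """One test result per metabolite; q-values are BH over the whole panel.

    The dataset is expected to be imputed; ``allow_missing`` instead drops
    masked cells per metabolite (the robustness check that ignores missing
    datapoints rather than imputing them).
    """
    if dataset.n_missing and not allow_missing:
        raise ValueError("dataset contains missing cells; impute first or pass allow_missing")
    ctrl = dataset.cohort_columns(Cohort.CONTROL)
    pat = dataset.cohort_columns(Cohort.PATIENT)
    if ctrl.size < 2 or pat.size < 2:
        raise ValueError("each cohort needs at least 2 subjects")

    n = dataset.n_metabolites
    pvals = np.empty(n)
    fc_means: list[float | None] = []
    fc_medians: list[float | None] = []

    if not dataset.mask.any() and method == "normal_approx":
        # vectorized fast path over rows
        xa, xb = dataset.values[:, ctrl], dataset.values[:, pat]
        constant = np.ptp(dataset.values, axis=1) == 0
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(
                xa, xb, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=-1,
            )
            pvals = np.asarray(res.pvalue, dtype=float)
        pvals[constant] = 1.0
        for i in range(n):
            fc_means.append(fold_change(xa[i], xb[i], "mean"))
            fc_medians.append(fold_change(xa[i], xb[i], "median"))
    else:
        for i in range(n):
            keep_a = ctrl[~dataset.mask[i, ctrl]]
            keep_b = pat[~dataset.mask[i, pat]]
            if keep_a.size == 0 or keep_b.size == 0:
                pvals[i] = 1.0
                fc_means.append(None)
                fc_medians.append(None)
                continue
            va, vb = dataset.values[i, keep_a], dataset.values[i, keep_b]
            pvals[i] = rank_sum_test(va, vb, method=method)
            fc_means.append(fold_change(va, vb, "mean"))
            fc_medians.append(fold_change(va, vb, "median"))

    qvals = bh_adjust(pvals)
    return [
        MetaboliteTestResult(
            metabolite_id=ann.metabolite_id,
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            q_scope=QScope.WHOLE_PANEL,
            fc_mean=fc_means[i],
            fc_median=fc_medians[i],
            direction=_direction(fc_means[i]),
        )
        for i, ann in enumerate(dataset.annotations)
    ]


def volcano_select(
    results: Iterable[MetaboliteTestResult],
    fc_min: float = 2.0,
    p_max: float = 0.1,
    center: str = "mean",
) -> list[MetaboliteTestResult]:
    """Joint fold-change / p-value selection.

    Keeps metabolites whose fold change is at least ``fc_min`` in either
    direction (fc >= fc_min or fc <= 1/fc_min; a divergent undefined fold
    change counts as exceeding any threshold) and whose raw p < ``p_max``.
    """
    selected = []
    for r in results:
        fc = r.fc_mean if center == "mean" else r.fc_median
        big = fc is None or fc >= fc_min or (fc > 0 and fc <= 1.0 / fc_min)
        if big and r.p_value < p_max:
            selected.append(r)
    return selected


# ---------------------------------------------------------------------------
# Preprocessing transforms (projection-analysis path)
# ---------------------------------------------------------------------------

def normalize_matrix(
    matrix: np.ndarray,
    log_transform: bool = True,
    autoscale: bool = True,
    log_base: float = 10.0,
    zero_policy: str = "half_min",
) -> np.ndarray:
    """Optional elementwise log then per-metabolite (row) autoscaling.

    Zeros under the log are replaced by half the smallest positive value
    in the matrix (``zero_policy='half_min'``). Autoscaling centers each
    row to mean 0 and scales to sd 1; zero-variance rows become all zeros
    with a warning.
    """
    x = np.asarray(matrix, dtype=float).copy()
    if log_transform:
        if (x < 0).any():
            raise ValueError("log transform requires non-negative values")
        if (x == 0).any():
            if zero_policy != "half_min":
                raise ValueError(f"unknown zero_policy {zero_policy!r}")
            positive = x[x > 0]
            if positive.size == 0:
                raise ValueError("cannot log-transform an all-zero matrix")
            x[x == 0] = positive.min() / 2.0
        x = np.log(x) / np.log(log_base)
    if autoscale:
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            logger.warning("%d zero-variance rows set to all zeros by autoscaling", flat.sum())
        sd[sd == 0] = 1.0
        x = (x - mean) / sd
        x[flat] = 0.0
    return x


_DISPERSION = {
    "iqr": lambda x: np.subtract(*np.percentile(x, [75, 25], axis=1)),
    "rsd": lambda x: np.where(
        x.mean(axis=1) == 0, 0.0, x.std(axis=1, ddof=1) / np.where(x.mean(axis=1) == 0, 1.0, x.mean(axis=1))
    ),
    "mad_over_median": lambda x: np.where(
        np.median(x, axis=1) == 0,
        0.0,
        stats.median_abs_deviation(x, axis=1)
        / np.where(np.median(x, axis=1) == 0, 1.0, np.median(x, axis=1)),
    ),
}


def filter_features(
    matrix: np.ndarray, method: str = "iqr", drop_fraction: float = 0.0
) -> np.ndarray:
    """Drop the least-dispersed rows.

    Rows are ranked by the chosen dispersion statistic (IQR, RSD = sd/mean,
    or the non-parametric MAD/median) and the lowest ``drop_fraction`` is
    removed; ties keep input order (stable sort). Surviving rows keep
    their input order.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    x = np.asarray(matrix, dtype=float)
    if drop_fraction == 0 or x.shape[0] == 0:
        return x.copy()
    try:
        stat = np.abs(_DISPERSION[method](x))
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None
    n_drop = int(drop_fraction * x.shape[0])
    dropped = set(np.argsort(stat, kind="stable")[:n_drop].tolist())
    keep = [i for i in range(x.shape[0]) if i not in dropped]
    return x[keep]
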