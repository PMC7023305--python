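"""Data model and I/O for annotated metabolomics panels.

A panel is a wide matrix of metabolite abundances (rows) over subjects
(columns), where every metabolite carries a two-level chemical-class
annotation (super-pathway / sub-pathway) in the style of vendor panels
such as Metabolon's. Missingness is first-class: a cell is either a
non-negative abundance or explicitly missing, and the two are never
conflated with zero or a sentinel value, because downstream imputation
must distinguish "compound genuinely absent" (structural zero, e.g. a
drug the subject never took) from "below the limit of detection"
(a biologically required metabolite imputed from its observed minimum).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("metabopanel")

#: Sub-pathway names assigned the structural-zero imputation class by default:
#: any sub-pathway whose name contains "Drug", plus tobacco metabolites.
#: Missing values there mean the compound is truly absent from the subject's
#: blood, not undetected. Overridable everywhere a classification happens.
DEFAULT_STRUCTURAL_ZERO_MARKERS: tuple[str, ...] = ("Drug", "Tobacco Metabolites")


class PanelKind(str, Enum):
    """Which vendor panel a metabolite was measured on."""

    GLOBAL = "global"
    LIPID = "lipid"


class ImputationClass(str, Enum):
    """How a missing cell for this metabolite is to be filled."""

    STRUCTURAL_ZERO = "structural_zero"
    BIOLOGICAL_MIN = "biological_min"


class Cohort(str, Enum):
    CONTROL = "control"
    PATIENT = "patient"


class ValueSemantics(str, Enum):
    """Relative ion intensities (global panel) vs absolute concentrations."""

    RELATIVE_INTENSITY = "relative_intensity"
    CONCENTRATION = "concentration"


def is_structural_zero_subpathway(
    sub_pathway: str,
    markers: Sequence[str] = DEFAULT_STRUCTURAL_ZERO_MARKERS,
) -> bool:
    """True when the sub-pathway belongs to the structural-zero set.

    A marker matches if it is a substring of the sub-pathway name
    ("Drug" matches "Drug - Analgesics, Anesthetics") or equals it.
    """
    return any(m in sub_pathway for m in markers)


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """Identity and chemical-class annotation of one measured metabolite."""

    metabolite_id: str
    name: str
    super_pathway: str
    sub_pathway: str
    hmdb_id: str | None = None
    panel: PanelKind = PanelKind.GLOBAL
    imputation_class: ImputationClass = ImputationClass.BIOLOGICAL_MIN


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject: cohort label plus optional covariates."""

    subject_id: str
    cohort: Cohort
    age: float | None = None
    bmi: float | None = None


@dataclass
class PanelDataset:
    """Annotated metabolite x subject abundance matrix.

    ``values`` holds non-negative floats; ``mask`` is True where the cell
    is missing (``values`` is 0.0 there but must never be read). Rows
    biject with ``annotations``, columns with ``subjects``.
    """

    annotations: list[MetaboliteAnnotation]
    subjects: list[SubjectRecord]
    values: np.ndarray
    mask: np.ndarray
    value_semantics: ValueSemantics = ValueSemantics.RELATIVE_INTENSITY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_met, n_sub = len(self.annotations), len(self.subjects)
        if self.values.shape != (n_met, n_sub):
            raise ValueError(
                f"abundance matrix shape {self.values.shape} does not match "
                f"{n_met} metabolites x {n_sub} subjects"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match value matrix shape")
        ids = [a.metabolite_id for a in self.annotations]
        dup = [m for m, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate metabolite ids: {dup}")
        sids = [s.subject_id for s in self.subjects]
        dup = [s for s, c in Counter(sids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate subject ids: {dup}")
        observed = self.values[~self.mask]
        if observed.size and (observed < 0).any():
            raise ValueError("negative abundance values are not allowed")

    # -- convenience accessors -------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.annotations)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def metabolite_ids(self) -> list[str]:
        return [a.metabolite_id for a in self.annotations]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def cohort_columns(self, cohort: Cohort) -> np.ndarray:
        """Column indices of the subjects in ``cohort``."""
        return np.array(
            [j for j, s in enumerate(self.subjects) if s.cohort == cohort], dtype=int
        )

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            annotations=list(self.annotations),
            subjects=list(self.subjects),
            values=self.values.copy(),
            mask=self.mask.copy(),
            value_semantics=self.value_semantics,
        )


@dataclass(frozen=True)
class PanelSummary:
    n_metabolites: int
    n_subjects: int
    n_cells: int
    per_super_pathway_counts: Mapping[str, int]
    per_sub_pathway_counts: Mapping[str, int]
    n_missing: int
    missing_by_class: Mapping[ImputationClass, int]

    @property
    def missing_percent(self) -> float:
        """Share of missing cells, percent, one decimal, round-half-up."""
        if self.n_cells == 0:
            return 0.0
        return round_half_up(100.0 * self.n_missing / self.n_cells, 1)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal -> 0.1), for report percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ("metabolite_id", "name", "super_pathway", "sub_pathway", "hmdb_id")


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv" or dialect is None and path.suffix.lower() != ".csv":
        return "\t"
    return ","


def read_panel(
    path: str | Path,
    panel_kind: PanelKind | str = PanelKind.GLOBAL,
    dialect: str | None = None,
    structural_zero_markers: Sequence[str] = DEFAULT_STRUCTURAL_ZERO_MARKERS,
    value_semantics: ValueSemantics | None = None,
    known_sub_pathways: Iterable[str] | None = None,
) -> PanelDataset:
    """Read a wide-format panel table (TSV by default, CSV accepted).

    Row 1 must carry the five annotation column names followed by subject
    ids; each further row is one metabolite. Empty cells become the
    missing state. The imputation class of each metabolite is derived from
    its sub-pathway via ``structural_zero_markers``. When
    ``known_sub_pathways`` is given, sub-pathways outside it are accepted
    (classed biological_min unless a marker matches) with a warning.
    """
    path = Path(path)
    panel_kind = PanelKind(panel_kind)
    if value_semantics is None:
        value_semantics = (
            ValueSemantics.CONCENTRATION
            if panel_kind is PanelKind.LIPID
            else ValueSemantics.RELATIVE_INTENSITY
        )
    delim = _sniff_delimiter(path, dialect)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise ValueError(f"{path}: empty panel file")
    header = rows[0]
    if tuple(header[: len(_ANNOTATION_COLUMNS)]) != _ANNOTATION_COLUMNS:
        raise ValueError(
            f"{path}: header must start with {', '.join(_ANNOTATION_COLUMNS)}; "
            f"got {header[:5]}"
        )
    subject_ids = header[len(_ANNOTATION_COLUMNS):]
    if known_sub_pathways is not None:
        known_sub_pathways = set(known_sub_pathways)

    annotations: list[MetaboliteAnnotation] = []
    values = np.zeros((len(rows) - 1, len(subject_ids)))
    mask = np.zeros_like(values, dtype=bool)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise ValueError(f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}")
        mid, name, super_pw, sub_pw, hmdb = row[:5]
        if known_sub_pathways is not None and sub_pw not in known_sub_pathways:
            logger.warning(
                "unknown sub-pathway %r for metabolite %r; classed biological_min",
                sub_pw, mid,
            )
        annotations.append(
            MetaboliteAnnotation(
                metabolite_id=mid,
                name=name,
                super_pathway=super_pw,
                sub_pathway=sub_pw,
                hmdb_id=hmdb or None,
                panel=panel_kind,
                imputation_class=(
                    ImputationClass.STRUCTURAL_ZERO
                    if is_structural_zero_subpathway(sub_pw, structural_zero_markers)
                    else ImputationClass.BIOLOGICAL_MIN
                ),
            )
        )
        for j, cell in enumerate(row[5:]):
            if cell.strip() == "":
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric abundance {cell!r} at metabolite "
                        f"{mid!r}, subject {subject_ids[j]!r}"
                    ) from None

    subjects = [SubjectRecord(subject_id=s, cohort=Cohort.CONTROL) for s in subject_ids]
    return PanelDataset(
        annotations=annotations,
        subjects=subjects,
        values=values,
        mask=mask,
        value_semantics=value_semantics,
    )


def read_subjects(path: str | Path, dialect: str | None = None) -> list[SubjectRecord]:
    """Read the subject metadata table (subject_id, cohort, age, bmi)."""
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    records: list[SubjectRecord] = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delim):
            records.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    cohort=Cohort(row["cohort"]),
                    age=float(row["age"]) if row.get("age") else None,
                    bmi=float(row["bmi"]) if row.get("bmi") else None,
                )
            )
    ids = [r.subject_id for r in records]
    dup = [s for s, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"{path}: duplicate subject ids {dup}")
    return records


def attach_subjects(dataset: PanelDataset, subjects: Sequence[SubjectRecord]) -> PanelDataset:
    """Replace the dataset's placeholder subject records with real metadata.

    Subjects are matched by id; every panel column must be covered.
    """
    by_id = {s.subject_id: s for s in subjects}
    missing = [s for s in dataset.subject_ids if s not in by_id]
    if missing:
        raise ValueError(f"subjects without metadata: {missing}")
    out = dataset.copy()
    out.subjects = [by_id[s] for s in dataset.subject_ids]
    return out


def write_panel(dataset: PanelDataset, path: str | Path, dialect: str | None = None) -> Path:
    """Write a panel so that ``read_panel`` round-trips it cell-for-cell."""
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(list(_ANNOTATION_COLUMNS) + dataset.subject_ids)
        for i, ann in enumerate(dataset.annotations):
            cells = [
                "" if dataset.mask[i, j] else repr(float(dataset.values[i, j]))
                for j in range(dataset.n_subjects)
            ]
            w.writerow(
                [ann.metabolite_id, ann.name, ann.super_pathway, ann.sub_pathway, ann.hmdb_id or ""]
                + cells
            )
    return path


def write_subjects(subjects: Sequence[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["subject_id", "cohort", "age", "bmi"])
        for s in subjects:
            w.writerow(
                [s.subject_id, s.cohort.value,
                 "" if s.age is None else s.age, "" if s.bmi is None else s.bmi]
            )
    return path


# ---------------------------------------------------------------------------
# Summaries and merging
# ---------------------------------------------------------------------------

def summarize_panel(dataset: PanelDataset) -> PanelSummary:
    """Bookkeeping counts: dimensions, per-category partition, missingness."""
    super_counts: Counter[str] = Counter(a.super_pathway for a in dataset.annotations)
    sub_counts: Counter[str] = Counter(a.sub_pathway for a in dataset.annotations)
    missing_by_class = {c: 0 for c in ImputationClass}
    for i, ann in enumerate(dataset.annotations):
        missing_by_class[ann.imputation_class] += int(dataset.mask[i].sum())
    return PanelSummary(
        n_metabolites=dataset.n_metabolites,
        n_subjects=dataset.n_subjects,
        n_cells=dataset.n_metabolites * dataset.n_subjects,
        per_super_pathway_counts=dict(super_counts),
        per_sub_pathway_counts=dict(sub_counts),
        n_missing=dataset.n_missing,
        missing_by_class=missing_by_class,
    )


def merge_panels(a: PanelDataset, b: PanelDataset) -> PanelDataset:
    """Row-concatenate two panels measured on the same subjects.

    Metabolite-id collisions are resolved by prefixing with the panel kind.
    Column order follows ``a``; ``b``'s columns are permuted to match.
    """
    if b.n_metabolites == 0:
        return a.copy()
    if a.n_metabolites == 0:
        return b.copy()
    sa, sb = set(a.subject_ids), set(b.subject_ids)
    if sa != sb:
        diff = sorted(sa.symmetric_difference(sb))
        raise ValueError(f"subject sets differ between panels: {diff}")
    order = [b.subject_ids.index(s) for s in a.subject_ids]

    ann_a, ann_b = list(a.annotations), list(b.annotations)
    collisions = {x.metabolite_id for x in ann_a} & {x.metabolite_id for x in ann_b}
    if collisions:
        ann_a = [
            replace(x, metabolite_id=f"{x.panel.value}:{x.metabolite_id}")
            if x.metabolite_id in collisions else x
            for x in ann_a
        ]
        ann_b = [
            replace(x, metabolite_id=f"{x.panel.value}:{x.metabolite_id}")
            if x.metabolite_id in collisions else x
            for x in ann_b
        ]
    semantics = (
        a.value_semantics if a.value_semantics == b.value_semantics
        else ValueSemantics.RELATIVE_INTENSITY
    )
    return PanelDataset(
        annotations=ann_a + ann_b,
        subjects=list(a.subjects),
        values=np.vstack([a.values, b.values[:, order]]),
        mask=np.vstack([a.mask, b.mask[:, order]]),
        value_semantics=semantics,
    )
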