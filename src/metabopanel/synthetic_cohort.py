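"""Synthetic case-control cohort generator.

Emulates the structure of a dual-panel plasma metabolomics study: a
"global" panel of 768 identified small molecules over 9 super-pathways /
94 sub-pathways (relative intensities) and a complex-lipid panel of 1007
species over 11 super-pathways / 19 sub-pathways (concentrations),
measured on 26 controls + 26 patients.

The generative model, per metabolite m and subject j:

    log x_mj = mu + b_m + s_j + eps_mj            (natural log)

with a panel-wide baseline ``mu``, a per-metabolite offset ``b_m``
(metabolites span orders of magnitude), a per-subject multiplicative
scale ``s_j`` (technical/biological subject effect), and i.i.d. noise
``eps_mj``. Group effects are multiplicative: an effect with multiplier
``r`` on a sub-pathway divides every affected patient value by ``r``, so
``r`` is the expected controls/patients abundance ratio.

Two missingness mechanisms mirror real panels:

* biologically required metabolites are left-censored: values below the
  per-metabolite pooled ``lod_quantile`` become missing (MNAR);
* xenobiotic drug/tobacco compounds are structurally absent: each
  subject-compound pair is present only with ``xenobiotic_usage_prob``.

Everything is driven by one integer seed; identical configs produce
byte-identical written panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel_data import (
    Cohort,
    ImputationClass,
    MetaboliteAnnotation,
    PanelDataset,
    PanelKind,
    SubjectRecord,
    ValueSemantics,
    is_structural_zero_subpathway,
)

__all__ = [
    "TemplateEntry",
    "EffectSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_template",
    "global_template",
    "lipid_template",
    "default_effects",
    "generate_cohort",
]


@dataclass(frozen=True)
class TemplateEntry:
    """One sub-pathway of a panel template: where it sits and how big it is."""

    super_pathway: str
    sub_pathway: str
    n_members: int
    panel: PanelKind


# Global-panel template: 768 compounds, 9 super-pathways, 94 sub-pathways.
# Printed sub-pathway names and sizes are used where known (the seven
# xenobiotic categories, the drug split into eight sub-pathways totalling
# 64 compounds, 6 tobacco metabolites, 7 acyl cholines, 18 androgenic
# steroids, 2 vitamin B6 compounds, 6 dipeptides, a 39-member acyl
# carnitine and 5-member cytidine sub-pathway); the remaining sub-pathway
# names and member counts are plausible placeholders chosen so that every
# super-pathway total matches its printed count
# (196, 25, 29, 10, 259, 33, 2, 33, 181).
_GLOBAL_TEMPLATE: tuple[tuple[str, str, int], ...] = (
    # Amino Acids (196)
    ("Amino Acids", "Glutamate Metabolism", 12),
    ("Amino Acids", "Glycine, Serine and Threonine Metabolism", 14),
    ("Amino Acids", "Lysine Metabolism", 14),
    ("Amino Acids", "Phenylalanine Metabolism", 8),
    ("Amino Acids", "Tyrosine Metabolism", 14),
    ("Amino Acids", "Tryptophan Metabolism", 16),
    ("Amino Acids", "Leucine, Isoleucine and Valine Metabolism", 24),
    ("Amino Acids", "Methionine, Cysteine, SAM and Taurine Metabolism", 18),
    ("Amino Acids", "Urea cycle; Arginine and Proline Metabolism", 16),
    ("Amino Acids", "Histidine Metabolism", 10),
    ("Amino Acids", "Alanine and Aspartate Metabolism", 6),
    ("Amino Acids", "Glutathione Metabolism", 5),
    ("Amino Acids", "Polyamine Metabolism", 6),
    ("Amino Acids", "Creatine Metabolism", 4),
    ("Amino Acids", "Guanidino and Acetamido Metabolism", 4),
    ("Amino Acids", "Amino Acid Metabolism (Unannotated I)", 5),
    ("Amino Acids", "Amino Acid Metabolism (Unannotated II)", 4),
    ("Amino Acids", "Amino Acid Metabolism (Unannotated III)", 4),
    ("Amino Acids", "Amino Acid Metabolism (Unannotated IV)", 3),
    ("Amino Acids", "Amino Acid Metabolism (Unannotated V)", 3),
    ("Amino Acids", "Amino Acid Metabolism (Unannotated VI)", 3),
    ("Amino Acids", "Amino Acid Metabolism (Unannotated VII)", 3),
    # Carbohydrates (25)
    ("Carbohydrates", "Glycolysis, Gluconeogenesis, and Pyruvate Metabolism", 9),
    ("Carbohydrates", "Pentose Metabolism", 6),
    ("Carbohydrates", "Fructose, Mannose and Galactose Metabolism", 5),
    ("Carbohydrates", "Aminosugar Metabolism", 3),
    ("Carbohydrates", "Glycogen Metabolism", 2),
    # Cofactors and Vitamins (29)
    ("Cofactors and Vitamins", "Nicotinate and Nicotinamide Metabolism", 7),
    ("Cofactors and Vitamins", "Vitamin B6 Metabolism", 2),
    ("Cofactors and Vitamins", "Ascorbate and Aldarate Metabolism", 4),
    ("Cofactors and Vitamins", "Tocopherol Metabolism", 4),
    ("Cofactors and Vitamins", "Riboflavin Metabolism", 3),
    ("Cofactors and Vitamins", "Hemoglobin and Porphyrin Metabolism", 7),
    ("Cofactors and Vitamins", "Pantothenate and CoA Metabolism", 2),
    # Energy (10)
    ("Energy", "TCA Cycle", 7),
    ("Energy", "Oxidative Phosphorylation", 3),
    # Lipids (259)
    ("Lipids", "Acyl Cholines", 7),
    ("Lipids", "Androgenic Steroids", 18),
    ("Lipids", "Progestin Steroids", 6),
    ("Lipids", "Corticosteroids", 4),
    ("Lipids", "Pregnenolone Steroids", 4),
    ("Lipids", "Acyl Carnitines", 39),
    ("Lipids", "Acyl Glutamine", 1),
    ("Lipids", "Acyl Glycine", 4),
    ("Lipids", "Primary Bile Acid Metabolism", 8),
    ("Lipids", "Secondary Bile Acid Metabolism", 12),
    ("Lipids", "Long Chain Fatty Acids", 16),
    ("Lipids", "Medium Chain Fatty Acids", 10),
    ("Lipids", "Polyunsaturated Fatty Acid (n3 and n6)", 16),
    ("Lipids", "Monoacylglycerol", 8),
    ("Lipids", "Diacylglycerol", 6),
    ("Lipids", "Phospholipid Metabolism", 10),
    ("Lipids", "Lysophospholipid", 12),
    ("Lipids", "Sphingolipid Metabolism", 14),
    ("Lipids", "Fatty Acid, Dicarboxylate", 10),
    ("Lipids", "Fatty Acid, Monohydroxy", 9),
    ("Lipids", "Endocannabinoid", 6),
    ("Lipids", "Sterol", 6),
    ("Lipids", "Fatty Acid Metabolism (also BCAA Metabolism)", 6),
    ("Lipids", "Ketone Bodies", 3),
    ("Lipids", "Inositol Metabolism", 4),
    ("Lipids", "Plasmalogen", 6),
    ("Lipids", "Carnitine Metabolism", 5),
    ("Lipids", "Eicosanoid", 3),
    ("Lipids", "Lipid Metabolism (Unannotated I)", 1),
    ("Lipids", "Lipid Metabolism (Unannotated II)", 1),
    ("Lipids", "Lipid Metabolism (Unannotated III)", 1),
    ("Lipids", "Lipid Metabolism (Unannotated IV)", 1),
    ("Lipids", "Lipid Metabolism (Unannotated V)", 1),
    ("Lipids", "Lipid Metabolism (Unannotated VI)", 1),
    # Nucleotides (33)
    ("Nucleotides", "Purine Metabolism, (Hypo)Xanthine/Inosine containing", 10),
    ("Nucleotides", "Purine Metabolism, Adenine containing", 8),
    ("Nucleotides", "Pyrimidine Metabolism (Cytidine containing)", 5),
    ("Nucleotides", "Pyrimidine Metabolism, Uracil containing", 7),
    ("Nucleotides", "Pyrimidine Metabolism, Thymine containing", 3),
    # Partially Characterized Molecules (2)
    ("Partially Characterized Molecules", "Partially Characterized Molecules", 2),
    # Peptides (33)
    ("Peptides", "Dipeptide", 6),
    ("Peptides", "Gamma-glutamyl Amino Acid", 15),
    ("Peptides", "Acetylated Peptides", 6),
    ("Peptides", "Fibrinogen Cleavage Peptide", 6),
    # Xenobiotics (181): 6 non-drug sub-pathways + 8 drug sub-pathways (64 total)
    ("Xenobiotics", "Bacterial/Fungal", 3),
    ("Xenobiotics", "Benzoate Metabolism", 21),
    ("Xenobiotics", "Chemical", 23),
    ("Xenobiotics", "Food Component/Plant", 49),
    ("Xenobiotics", "Tobacco Metabolites", 6),
    ("Xenobiotics", "Xanthine Metabolism", 15),
    ("Xenobiotics", "Drug - Analgesics, Anesthetics", 20),
    ("Xenobiotics", "Drug - Antibiotic", 8),
    ("Xenobiotics", "Drug - Cardiovascular", 7),
    ("Xenobiotics", "Drug - Psychoactive", 7),
    ("Xenobiotics", "Drug - Gastrointestinal", 5),
    ("Xenobiotics", "Drug - Antihistamine", 4),
    ("Xenobiotics", "Drug - Metabolic", 6),
    ("Xenobiotics", "Drug - Topical Agents", 7),
)

# Lipid-panel template: 1007 species, 11 super-pathways, 19 sub-pathways.
# Super-pathway totals are the printed ones (26, 58, 25, 18, 17, 26, 103,
# 127, 28, 61, 518); sub-pathway splits are placeholders except the
# 12-member ceramide and sphingomyelin classes.
_LIPID_TEMPLATE: tuple[tuple[str, str, int], ...] = (
    ("Cholesterol Esters", "Cholesterol Esters", 26),
    ("Diacylglycerols", "Diacylglycerols (Saturated)", 20),
    ("Diacylglycerols", "Diacylglycerols (Unsaturated)", 38),
    ("Free Fatty Acids", "Free Fatty Acids", 25),
    ("Lysophosphatidylcholines", "Lysophosphatidylcholines", 18),
    ("Lysophosphatidylethanolamines", "Lysophosphatidylethanolamines", 17),
    ("Monoacylglycerols", "Monoacylglycerols", 26),
    ("Phosphatidylcholines", "Phosphatidylcholines (Saturated)", 30),
    ("Phosphatidylcholines", "Phosphatidylcholines (Unsaturated)", 73),
    ("Phosphatidylethanolamines", "Phosphatidylethanolamines (Saturated)", 40),
    ("Phosphatidylethanolamines", "Phosphatidylethanolamines (Unsaturated)", 87),
    ("Phosphatidylinositols", "Phosphatidylinositols", 28),
    ("Sphingolipids", "Ceramides", 12),
    ("Sphingolipids", "Dihydroceramides", 12),
    ("Sphingolipids", "Hexosylceramides", 13),
    ("Sphingolipids", "Lactosylceramides", 12),
    ("Sphingolipids", "Sphingomyelins", 12),
    ("Triacylglycerols", "Triacylglycerols (Saturated)", 200),
    ("Triacylglycerols", "Triacylglycerols (Unsaturated)", 318),
)


def global_template() -> list[TemplateEntry]:
    """Template of the 768-compound global metabolomics panel."""
    return [TemplateEntry(sp, sub, n, PanelKind.GLOBAL) for sp, sub, n in _GLOBAL_TEMPLATE]


def lipid_template() -> list[TemplateEntry]:
    """Template of the 1007-species complex lipid panel."""
    return [TemplateEntry(sp, sub, n, PanelKind.LIPID) for sp, sub, n in _LIPID_TEMPLATE]


def default_template() -> list[TemplateEntry]:
    """Both panel templates concatenated (global first)."""
    return global_template() + lipid_template()


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect on one sub-pathway.

    ``multiplier`` is the expected controls/patients abundance ratio
    (2.0 means the sub-pathway is twice as low in patients); ``fraction``
    restricts the effect to a random subset of the members.
    """

    sub_pathway: str
    multiplier: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.multiplier > 0:
            raise ValueError("multiplier must be positive")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


def default_effects() -> list[EffectSpec]:
    """The study-analogue planted effects: acyl cholines twice as low and
    androgenic steroids 1.7x lower in patients."""
    return [EffectSpec("Acyl Cholines", 2.0), EffectSpec("Androgenic Steroids", 1.7)]


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the reference design: 26 + 26 female subjects,
    abundances spanning orders of magnitude (``metabolite_log_sd``),
    a small residual per-subject scale (panels arrive vendor-normalized,
    so most technical sample scale is already removed), ~8% left-censoring
    of biologically required metabolites and drug / tobacco compounds
    present in ~14% of subject-compound pairs — together reproducing the
    ~15% overall missingness of such panels with about half of it in the
    structural-zero classes. All log-scale parameters are natural log.
    """

    n_controls: int = 26
    n_patients: int = 26
    template: Sequence[TemplateEntry] = field(default_factory=default_template)
    baseline_log_mean: float = 11.5
    baseline_log_sd: float = 0.3  # ~30% CV per metabolite, typical post-normalization
    metabolite_log_sd: float = 1.5
    subject_scale_sd: float = 0.05
    lod_quantile: float = 0.08
    xenobiotic_usage_prob: float = 0.14
    effects: Sequence[EffectSpec] = field(default_factory=tuple)
    seed: int = 2034

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0 <= self.xenobiotic_usage_prob <= 1:
            raise ValueError("xenobiotic_usage_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Echoed generator internals for parameter-recovery checks."""

    multipliers: dict[str, float]  # metabolite_id -> controls/patients ratio
    latent: np.ndarray  # uncensored abundance matrix (metabolite x subject)


def _expand_template(
    template: Sequence[TemplateEntry],
) -> list[MetaboliteAnnotation]:
    annotations: list[MetaboliteAnnotation] = []
    counters = {PanelKind.GLOBAL: 0, PanelKind.LIPID: 0}
    prefix = {PanelKind.GLOBAL: "G", PanelKind.LIPID: "L"}
    for entry in template:
        for k in range(entry.n_members):
            counters[entry.panel] += 1
            mid = f"{prefix[entry.panel]}{counters[entry.panel]:04d}"
            annotations.append(
                MetaboliteAnnotation(
                    metabolite_id=mid,
                    name=f"{entry.sub_pathway} {k + 1}",
                    super_pathway=entry.super_pathway,
                    sub_pathway=entry.sub_pathway,
                    hmdb_id=None,
                    panel=entry.panel,
                    imputation_class=(
                        ImputationClass.STRUCTURAL_ZERO
                        if is_structural_zero_subpathway(entry.sub_pathway)
                        else ImputationClass.BIOLOGICAL_MIN
                    ),
                )
            )
    return annotations


def generate_cohort(config: SyntheticConfig) -> tuple[PanelDataset, GroundTruth]:
    """Draw one case-control panel dataset from the generative model.

    Returns the dataset (with censoring / structural absence applied) and
    the ground truth: per-metabolite planted multipliers and the latent
    uncensored matrix.
    """
    annotations = _expand_template(config.template)
    n_met = len(annotations)
    n_sub = config.n_controls + config.n_patients
    known_subs = {a.sub_pathway for a in annotations}
    for eff in config.effects:
        if eff.sub_pathway not in known_subs:
            raise ValueError(f"effect references unknown sub-pathway {eff.sub_pathway!r}")

    rng = np.random.default_rng(config.seed)
    met_offset = rng.normal(0.0, config.metabolite_log_sd, size=n_met)
    subj_offset = rng.normal(0.0, config.subject_scale_sd, size=n_sub)
    noise = rng.normal(0.0, config.baseline_log_sd, size=(n_met, n_sub))

    multipliers = np.ones(n_met)
    sub_of = np.array([a.sub_pathway for a in annotations])
    for eff in config.effects:
        members = np.flatnonzero(sub_of == eff.sub_pathway)
        if eff.fraction < 1.0:
            k = max(1, int(round(eff.fraction * members.size)))
            members = rng.choice(members, size=k, replace=False)
        multipliers[members] *= eff.multiplier

    latent = np.exp(
        config.baseline_log_mean + met_offset[:, None] + subj_offset[None, :] + noise
    )
    is_patient = np.zeros(n_sub, dtype=bool)
    is_patient[config.n_controls:] = True
    latent[:, is_patient] /= multipliers[:, None]

    values = latent.copy()
    mask = np.zeros((n_met, n_sub), dtype=bool)
    is_structural = np.array(
        [a.imputation_class is ImputationClass.STRUCTURAL_ZERO for a in annotations]
    )

    # Left-censoring of biologically required metabolites: per-metabolite
    # pooled quantile threshold (panel abundances span orders of magnitude,
    # so a global absolute cutoff would censor whole metabolites).
    if config.lod_quantile > 0:
        bio = ~is_structural
        thresholds = np.quantile(latent[bio], config.lod_quantile, axis=1)
        mask[bio] = latent[bio] < thresholds[:, None]

    # Structural absence of drug / tobacco compounds.
    if is_structural.any():
        present = rng.random((int(is_structural.sum()), n_sub)) < config.xenobiotic_usage_prob
        mask[is_structural] = ~present

    values[mask] = 0.0

    subjects = [
        SubjectRecord(subject_id=f"C{j + 1:02d}", cohort=Cohort.CONTROL)
        for j in range(config.n_controls)
    ] + [
        SubjectRecord(subject_id=f"P{j + 1:02d}", cohort=Cohort.PATIENT)
        for j in range(config.n_patients)
    ]
    semantics = (
        ValueSemantics.CONCENTRATION
        if all(a.panel is PanelKind.LIPID for a in annotations) and annotations
        else ValueSemantics.RELATIVE_INTENSITY
    )
    dataset = PanelDataset(
        annotations=annotations,
        subjects=subjects,
        values=values,
        mask=mask,
        value_semantics=semantics,
    )
    truth = GroundTruth(
        multipliers={a.metabolite_id: float(m) for a, m in zip(annotations, multipliers)},
        latent=latent,
    )
    return dataset, truth
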