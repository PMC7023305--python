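import numpy as np
import pytest

from metabopanel import (
    Cohort,
    ImputationClass,
    MetaboliteAnnotation,
    PanelDataset,
    PanelKind,
    SubjectRecord,
)


def make_panel(values, mask, sub_pathways, cohorts, panel=PanelKind.GLOBAL):
    """Small hand-built panel; imputation class follows the sub-pathway."""
    from metabopanel.panel_data import is_structural_zero_subpathway

    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    annotations = [
        MetaboliteAnnotation(
            metabolite_id=f"M{i}",
            name=f"met-{i}",
            super_pathway="Lipids",
            sub_pathway=sub,
            panel=panel,
            imputation_class=(
                ImputationClass.STRUCTURAL_ZERO
                if is_structural_zero_subpathway(sub)
                else ImputationClass.BIOLOGICAL_MIN
            ),
        )
        for i, sub in enumerate(sub_pathways)
    ]
    subjects = [
        SubjectRecord(subject_id=f"S{j}", cohort=Cohort(c)) for j, c in enumerate(cohorts)
    ]
    return PanelDataset(annotations=annotations, subjects=subjects, values=values, mask=mask)


@pytest.fixture
def toy_panel():
    """4 metabolites x 6 subjects (3 controls, 3 patients), mixed classes."""
    values = [
        [5.0, 0.0, 2.0, 0.0, 3.0, 4.0],
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        [0.0, 0.0, 7.0, 0.0, 0.0, 2.0],
        [2.0, 4.0, 6.0, 1.0, 2.0, 3.0],
    ]
    mask = [
        [False, True, False, True, False, False],
        [False] * 6,
        [True, True, False, True, True, False],
        [False] * 6,
    ]
    subs = ["Acyl Cholines", "Dipeptide", "Tobacco Metabolites", "Acyl Cholines"]
    cohorts = ["control"] * 3 + ["patient"] * 3
    return make_panel(values, mask, subs, cohorts)
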