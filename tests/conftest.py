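"""Shared fixtures: a scaled-down synthetic cohort with a fitted SOM.

The small cohort keeps the default design's structure (six planted modules,
five subtypes plus a contaminated LIV-like group, multi-lesion patients,
survival linked to modules A and E) at 1200 genes x 60 samples on a 20 x 20
grid so the whole unit suite stays fast; full-scale runs live in the
acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

import somscape as sc
from somscape.synthetic_cohort import (
    CohortDesign,
    ModuleSpec,
    attach_survival,
    default_design,
    generate_cohort,
)


def scaled_design(seed: int = 1, n_genes: int = 1200, n_samples: int = 60, **overrides):
    base = default_design()
    modules = [ModuleSpec(m.label, max(30, m.n_genes // 5), dict(m.levels)) for m in base.modules]
    kwargs = dict(
        n_genes=n_genes,
        n_samples=n_samples,
        subtype_proportions=dict(base.subtype_proportions),
        modules=modules,
        contamination_module=base.contamination_module,
        contamination_fraction=base.contamination_fraction,
        contamination_level=base.contamination_level,
        noise_sd=base.noise_sd,
        intra_patient_sd=base.intra_patient_sd,
        lesions_per_patient=dict(base.lesions_per_patient),
        survival_betas=dict(base.survival_betas),
        censor_fraction=base.censor_fraction,
        seed=seed,
    )
    kwargs.update(overrides)
    design = CohortDesign(**kwargs)
    design.validate()
    return design


@pytest.fixture(scope="session")
def small_cohort():
    design = scaled_design(seed=1)
    matrix, truth, annotation = generate_cohort(design)
    return {
        "design": design,
        "matrix": matrix,
        "centralized": sc.centralize(matrix),
        "truth": truth,
        "annotation": annotation,
        "subtypes": truth.sample_info["subtype"],
    }


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    results = sc.SOMPortrayal(
        small_cohort["centralized"], grid=(20, 20), epochs=20, seed=0
    ).fit()
    return results


@pytest.fixture(scope="session")
def small_survival(small_cohort):
    return attach_survival(small_cohort["truth"], seed=77)


@pytest.fixture(scope="session")
def small_spots(small_fit, small_cohort):
    return small_fit.detect_spots(summary="group", labels=small_cohort["subtypes"])


@pytest.fixture()
def micro_matrix():
    """4 genes x 3 samples with easily hand-checked values."""
    df = pd.DataFrame(
        {
            "S1": [1.0, 2.0, 3.0, 6.0],
            "S2": [4.0, 3.0, 2.0, 1.0],
            "S3": [0.0, 1.0, -1.0, 2.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return sc.ExpressionMatrix(df, scale="log10")


def rng_matrix(n_genes, n_samples, seed=0, scale="log10"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return sc.ExpressionMatrix(df, scale=scale)
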