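import numpy as np
import pandas as pd
import pytest

from atrasens import (
    CohortSimParams,
    GrowthSimParams,
    SliceSimParams,
    simulate_cellline_cohort,
    simulate_growth_assay,
    simulate_slice_cohort,
)


@pytest.fixture
def clean_assay():
    """Noise-free Hill-inhibition assay on the default screen grid."""
    params = GrowthSimParams(od0=0.1, td_days=1.5, imax=0.8, ec50_um=0.1,
                             hill=1.0, cv=0.0, seed=0)
    return simulate_growth_assay(params)


@pytest.fixture
def small_cohort():
    """Small expression cohort with 5 planted score-associated genes."""
    return simulate_cellline_cohort(
        CohortSimParams(n_lines=30, n_genes=200, n_informative=5,
                        beta=1.0, noise_sd=0.2, seed=7)
    )


@pytest.fixture
def slice_cohort():
    """11 Lum + 5 TN slice cohort with one Lum-specific planted gene."""
    return simulate_slice_cohort(SliceSimParams(
        n_genes=300,
        effects={"Lum": {"G00000": 1.0}},
        ki67_drop={"Lum": 0.4, "TN": 0.0},
        seed=11,
    ))


@pytest.fixture
def tiny_matrix():
    from atrasens import ExpressionMatrix
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)
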