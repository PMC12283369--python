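import numpy as np
import pandas as pd
import pytest

from sliminer.core_data import (
    DependencyMatrix,
    ExpressionMatrix,
    GeneId,
    Scale,
)
from sliminer.synthetic_cohort import CohortConfig, generate_cell_line_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (300 genes x 250 lines, 5 planted pairs)."""
    return generate_cell_line_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_scan(default_cohort):
    from sliminer.sli_scoring import score_pairs

    return score_pairs(default_cohort.expression, default_cohort.dependency)


def make_expression(values, samples=None, genes=None, scale=Scale.log2_tpm_plus1):
    """Small helper building an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    samples = samples or [f"s{j}" for j in range(n_s)]
    return ExpressionMatrix(
        genes=[GeneId(g) for g in genes],
        data=pd.DataFrame(values, index=genes, columns=samples),
        scale=scale,
    )


def make_dependency(values, samples=None, genes=None):
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    samples = samples or [f"s{j}" for j in range(n_s)]
    return DependencyMatrix(
        genes=[GeneId(g) for g in genes],
        data=pd.DataFrame(values, index=genes, columns=samples),
    )
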