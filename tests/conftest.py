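import numpy as np
import pandas as pd
import pytest

from olfscreen.io import apply_fpkm_floor
from olfscreen.simulate import (
    SimulationConfig,
    simulate_expression_study,
    simulate_paired_study,
)


SMALL_CFG = SimulationConfig(
    seed=11, n_genes=1500, n_or_intact=150, n_or_pseudo=180,
    n_planted_overexpressed=20, n_respiratory_contaminants=5)


@pytest.fixture(scope="session")
def small_study():
    return simulate_expression_study(SMALL_CFG)


@pytest.fixture(scope="session")
def small_paired():
    return simulate_paired_study(SMALL_CFG)


@pytest.fixture(scope="session")
def floored(small_study):
    return apply_fpkm_floor(small_study.expression)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, samples=None, groups=None, genes=None, floor=None):
    """Small-matrix helper for hand-built cases."""
    from olfscreen.types import ExpressionMatrix
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    groups = groups or {s: "OE" for s in samples}
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, groups, floor=floor)
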