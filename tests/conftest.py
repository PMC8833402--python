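import numpy as np
import pandas as pd
import pytest

from cirblood import AnalysisConfig, SimulationConfig, generate_dataset
from cirblood.io import ExpressionMatrix
from cirblood.preprocess import virtual_pool_normalize


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (14 patients, 5 with one missing timepoint),
    pool-normalized, with its ground truth."""
    x, meta, truth = generate_dataset(
        SimulationConfig(n_missing_patients=5), seed=1)
    return virtual_pool_normalize(x), meta, truth


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    genes = genes or [f"g{i}" for i in range(g)]
    samples = samples or [f"s{j}" for j in range(s)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
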