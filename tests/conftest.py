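import numpy as np
import pandas as pd
import pytest

from cordnet.containers import ExpressionStudy
from cordnet.io import default_metadata
from cordnet.simulate import (
    SimulationConfig,
    generate_reference_expression,
    generate_test_studies,
)


def make_study(matrix: np.ndarray, study_id: str = "toy", **meta_cols) -> ExpressionStudy:
    """Wrap a raw matrix in an ExpressionStudy with default metadata."""
    n_genes, n_samples = matrix.shape
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    df = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=samples)
    meta = default_metadata(samples, study_id)
    for col, vals in meta_cols.items():
        meta[col] = vals
    return ExpressionStudy(df, meta)


@pytest.fixture(scope="session")
def small_config():
    """A small planted-structure configuration shared by fast tests."""
    return SimulationConfig(
        n_genes=300,
        module_sizes=(40, 30, 30),
        n_samples_ref=40,
        n_test_studies=3,
        samples_per_study=20,
        de_effect=(2.0, -2.0, 0.0),
        sign_flip_module=None,
        curated_target_modules=(0,),
        curated_size=60,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference_expression(small_config)


@pytest.fixture(scope="session")
def small_studies(small_config, small_reference):
    _, truth = small_reference
    return generate_test_studies(small_config, truth)
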