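import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from melnet.dataio import ExpressionMatrix
from melnet.preprocess import batch_median_scale
from melnet.synthetic import (
    GeneratorConfig,
    generate_truth,
    simulate_perturbation_dataset,
    simulate_survival,
    simulate_tumour_cohort,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def truth(default_cfg):
    return generate_truth(default_cfg)


@pytest.fixture(scope="session")
def perturbation(truth, default_cfg):
    return simulate_perturbation_dataset(truth, default_cfg)


@pytest.fixture(scope="session")
def scaled(perturbation):
    expr, _design = perturbation
    return batch_median_scale(expr)


@pytest.fixture(scope="session")
def tumours(truth, default_cfg):
    return simulate_tumour_cohort(truth, default_cfg)


@pytest.fixture(scope="session")
def survival_table(truth, tumours, default_cfg):
    return simulate_survival(truth, tumours, default_cfg)


@pytest.fixture(scope="session")
def small_net_cfg() -> GeneratorConfig:
    """50-gene configuration used for network-scale checks."""
    return GeneratorConfig(n_genes=50, module_size_range=(8, 10))


def make_expr(arr, genes=None, samples=None, batches=None) -> ExpressionMatrix:
    """Helper: ExpressionMatrix from a plain array."""
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    batch = None
    if batches is not None:
        batch = pd.Series(batches, index=samples)
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), batch)
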