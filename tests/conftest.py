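import numpy as np
import pandas as pd
import pytest

from cispairs import (
    ExpressionMatrix,
    GeneratorConfig,
    generate_annotation,
    generate_array_experiment,
)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def annotation(default_config):
    return generate_annotation(default_config)


@pytest.fixture(scope="session")
def array_matrix(annotation, default_config):
    return generate_array_experiment(annotation, default_config)


def make_matrix(values, samples=None, conditions=None, features=None) -> ExpressionMatrix:
    """Small expression matrix helper for hand-constructed examples."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    samples = samples or [f"s{j + 1}" for j in range(m)]
    features = features or [f"f{i + 1}" for i in range(n)]
    conditions = conditions or ["control"] * (m // 2) + ["treated"] * (m - m // 2)
    design = pd.DataFrame(
        {"condition": conditions, "replicate": list(range(1, m + 1))},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), design)
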