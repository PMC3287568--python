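import numpy as np
import pandas as pd
import pytest

from plsprog import (
    ClinicalTable, ExpressionMatrix, SyntheticSpec, generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def small_expression():
    """3 samples x 4 probes, fully observed."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [2.0, 1.0, 0.5, 3.0],
        [0.0, 5.0, 2.5, 1.0],
    ])
    return ExpressionMatrix(
        values, [f"probe_{j}_at" for j in range(4)], ["S0", "S1", "S2"]
    )


@pytest.fixture
def toy_clinical():
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(6)],
        "time_months": [24.0, 48.0, 20.0, 40.0, 36.0, 70.0],
        "event": [1, 1, 0, 0, 1, 0],
        "age": [60.0, 65.0, 70.0, 55.0, 62.0, 58.0],
        "gender": ["F", "M", "M", "F", "F", "M"],
        "stage": [1, 2, 1, 3, 2, 1],
    }))


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium cohort with clear planted structure, shared across tests."""
    spec = SyntheticSpec(
        n_samples=200, n_features=500, n_informative=20, effect_size=1.5,
        seed=77,
    )
    return generate_dataset(spec)
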