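import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirnet import datagen
from mirnet.io_core import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast structural tests."""
    return datagen.CohortConfig(
        n_patients=40, n_mirna=50, n_gene=300, n_regulators=3,
        targets_per_regulator=25, n_de_decoys=4, seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return datagen.generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (shared across tests)."""
    return datagen.generate_cohort(datagen.CohortConfig(seed=2024))


def make_matrix(values, features=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples))
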