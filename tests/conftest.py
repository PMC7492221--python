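import numpy as np
import pandas as pd
import pytest

from rhythm_mtl.pipeline import cohort_matrices
from rhythm_mtl.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort shared by feature/pipeline tests."""
    cfg = CohortConfig(
        n_patients=4,
        n_days=36,
        seed=11,
        modalities=("light", "sound", "screen", "sms"),
        subtype_spec=((0.5, "light"), (0.5, "screen")),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_data(small_cohort):
    return cohort_matrices(small_cohort)


@pytest.fixture(scope="session")
def tiny_model_data():
    """Random per-patient regression blocks for protocol-level tests."""
    rng = np.random.default_rng(3)
    symptoms = [f"s{i}" for i in range(10)]
    data = {}
    for u in ("p0", "p1", "p2"):
        X = pd.DataFrame(
            rng.normal(size=(10, 6)), columns=[f"f{j}" for j in range(6)]
        )
        Y = pd.DataFrame(rng.normal(size=(10, 10)), columns=symptoms)
        data[u] = (X, Y)
    return data
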