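import numpy as np
import pandas as pd
import pytest

from transcohort import ExpressionDataset
from transcohort.synthetic import SimulationConfig, generate_cohort_pair


@pytest.fixture(scope="session")
def sim_pair():
    """Default-condition paired cohorts with full planted structure."""
    cfg = SimulationConfig(seed=11)
    ds_a, ds_b, truth = generate_cohort_pair(cfg)
    return cfg, ds_a, ds_b, truth


@pytest.fixture(scope="session")
def subtype_only_pair():
    """Paired cohorts with subtype structure but flat ECM blocks."""
    cfg = SimulationConfig(seed=13, ecm3_block=(25, 25, 0.0), ecm1_block=(20, 20, 0.0))
    ds_a, ds_b, truth = generate_cohort_pair(cfg)
    return cfg, ds_a, ds_b, truth


@pytest.fixture()
def toy_dataset():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionDataset(values=values, cohort="toy")


def make_dataset(X, prefix_f="g", prefix_s="s", cohort=""):
    X = np.asarray(X, dtype=float)
    values = pd.DataFrame(
        X,
        index=[f"{prefix_f}{i}" for i in range(X.shape[0])],
        columns=[f"{prefix_s}{j}" for j in range(X.shape[1])],
    )
    return ExpressionDataset(values=values, cohort=cohort)
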