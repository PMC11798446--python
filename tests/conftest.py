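import numpy as np
import pandas as pd
import pytest

from crosskey.deg import ExpressionDataset
from crosskey.synthdata import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down study: 3 platforms x 2 datasets, 60-gene universes."""
    return SyntheticConfig(
        universe_size_per_platform=60,
        shared_core_size=40,
        samples_per_group=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture()
def two_group_dataset() -> ExpressionDataset:
    """20 probes x 16 samples of pure noise around a per-probe baseline."""
    rng = np.random.default_rng(11)
    samples = [f"c{i}" for i in range(8)] + [f"n{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.normal(7.0, 0.5, size=(20, 16)) + rng.uniform(4, 10, size=(20, 1)),
        index=[f"p{i:02d}" for i in range(20)],
        columns=samples,
    )
    groups = pd.Series(["case"] * 8 + ["control"] * 8, index=samples)
    return ExpressionDataset(values=values, groups=groups)
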