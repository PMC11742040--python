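import numpy as np
import pandas as pd
import pytest

from devocoevol.profiles import ExpressionDataset
from devocoevol.synthetic import ProfilesSimConfig, simulate_profiles


@pytest.fixture(scope="session")
def small_profiles_sim():
    """40 genes per class on the default rodent grid (32 samples)."""
    cfg = ProfilesSimConfig(n_per_class={"simple": 40, "species": 40,
                                         "tooth": 40, "complex": 40})
    return simulate_profiles(cfg, seed=101)


@pytest.fixture(scope="session")
def default_grid_samples(small_profiles_sim) -> pd.DataFrame:
    return small_profiles_sim.dataset.samples


def make_dataset(counts: np.ndarray, samples: pd.DataFrame) -> ExpressionDataset:
    df = pd.DataFrame(np.asarray(counts, dtype=np.int64),
                      index=[f"g{i}" for i in range(len(counts))],
                      columns=samples.index)
    return ExpressionDataset(df, samples)
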