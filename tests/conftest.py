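import numpy as np
import pandas as pd
import pytest

import homeotrip as ht


def make_count_matrix(counts: dict, conditions=None) -> ht.CountMatrix:
    """Small CountMatrix helper: counts = {sample: [per-gene counts]}."""
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    samples = list(df.columns)
    if conditions is None:
        conditions = ["control" if "c" in s else "cold" for s in samples]
    meta = pd.DataFrame(
        {"condition": conditions, "replicate": list(range(1, len(samples) + 1))},
        index=pd.Index(samples, name="sample"),
    )
    return ht.CountMatrix(df, meta)


@pytest.fixture(scope="session")
def small_run():
    """One small end-to-end pipeline run shared by several test modules."""
    cfg = ht.SimulationConfig(n_triplets=60, n_singletons=30, seed=3)
    return ht.run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = ht.SimulationConfig(n_triplets=120, n_singletons=30, seed=2)
    return ht.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
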