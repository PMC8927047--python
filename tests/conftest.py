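import numpy as np
import pandas as pd
import pytest

from stressrna.config import RunConfig
from stressrna.simulate import SimConfig, simulate_dataset
from stressrna.types import CountMatrix

SMALL_SIM = dict(
    n_coding=300, n_lnc=60, n_mirna=24, n_circ=30,
    n_cis_pairs=6, n_antisense_pairs=4, n_trans_pairs=5,
    n_sponge_modules=2, n_hub_modules=1, n_lnc_only_pairs=2,
    cis_fraction=0.15, antisense_fraction=0.10,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(**SMALL_SIM), seed=7)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def toy_matrix():
    """2 transcripts x 6 samples, 3 vs 3."""
    counts = pd.DataFrame(
        [[10, 12, 11, 5, 6, 4], [0, 1, 0, 8, 9, 10]],
        index=["t1", "t2"],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    groups = {f"s{i}": ("stress" if i <= 3 else "control") for i in range(1, 7)}
    return CountMatrix("mRNA", counts, groups)


def make_matrix(counts: np.ndarray, layer: str = "mRNA", n_stress: int | None = None
                ) -> CountMatrix:
    counts = np.asarray(counts)
    n = counts.shape[1]
    n_stress = n // 2 if n_stress is None else n_stress
    cols = [f"s{i}" for i in range(n)]
    groups = {c: ("stress" if i < n_stress else "control") for i, c in enumerate(cols)}
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(counts.shape[0])],
                      columns=cols)
    return CountMatrix(layer, df, groups)
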