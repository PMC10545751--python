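import networkx as nx
import numpy as np
import pandas as pd
import pytest

from seamod.config import RunConfig
from seamod.pipeline import run_all


@pytest.fixture
def four_leaf_tree() -> str:
    """Balanced ultrametric 4-leaf tree with unit branch lengths."""
    return "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def two_triangle_graph() -> nx.Graph:
    """Two 3-cliques joined by one bridge (c-d); m = 7 edges."""
    return nx.Graph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
    )


@pytest.fixture
def two_triangle_partition() -> dict:
    return {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2}


@pytest.fixture
def random_counts() -> pd.DataFrame:
    rng = np.random.default_rng(11)
    x = rng.integers(0, 50, size=(12, 20))
    x[rng.random(x.shape) < 0.4] = 0
    return pd.DataFrame(
        x,
        index=[f"s{i}" for i in range(12)],
        columns=[f"asv{j:02d}" for j in range(20)],
    )


def make_tiny_config(seed=3) -> RunConfig:
    """Small, fast pipeline configuration used by pipeline/CLI tests."""
    return RunConfig(
        seed=seed,
        n_stations=6,
        depths=(20, 200),
        fractions=("0.2-3",),
        n_boot=19,
        n_rewire=9,
        n_null_assembly=29,
        max_pairs_per_group=10,
        n_drifters=60,
        trajectory_days=120,
        n_years=2,
    )


@pytest.fixture
def tiny_config_factory():
    return make_tiny_config


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default toy config (shared; ~25 s)."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_all(RunConfig(seed=1), outdir)
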