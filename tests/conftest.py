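import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

# make tests/oracles.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "edrw",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("edrw")


@pytest.fixture()
def small_expression() -> pd.DataFrame:
    """3 genes x 4 samples, deterministic values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 10.0, 5.0, 5.0], [2.0, 2.0, 1.0, 3.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture()
def binary_labels() -> pd.Series:
    return pd.Series([0, 0, 1, 1], index=["s1", "s2", "s3", "s4"], name="label")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted two-network cohort shared across tests."""
    from edrw.synthetic import SyntheticSpec, simulate

    spec = SyntheticSpec(
        n_genes=200, n_pathways=12, pathway_size=(5, 15), n_normal=24,
        n_tumor=24, effect_size=2.0, seed=7,
    )
    net_a, net_b, pathways, expr, labels, truth = simulate(spec)
    return {
        "spec": spec, "net_a": net_a, "net_b": net_b,
        "pathways": pathways, "expr": expr, "labels": labels, "truth": truth,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
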