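import numpy as np
import pandas as pd
import pytest

from aneumir import (
    Karyotype,
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_interactions,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_mrna=300, n_mirna=40, rng_seed=7)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def tetrasomy5() -> Karyotype:
    return Karyotype.with_gains("5/4", {"5": 4})


@pytest.fixture(scope="session")
def small_bundle(small_config, small_annotation, tetrasomy5):
    """Annotation + interactions + paired counts for one aneuploid line."""
    interactions = simulate_interactions(small_annotation, small_config)
    matrix = simulate_counts(small_annotation, tetrasomy5, small_config, interactions)
    return {
        "config": small_config,
        "annotation": small_annotation,
        "karyotype": tetrasomy5,
        "interactions": interactions,
        "matrix": matrix,
    }


def make_de_table(log2fc, padj=None, call=None, p=None):
    """Construct a minimal DE table for unit tests."""
    log2fc = np.asarray(log2fc, dtype=float)
    n = len(log2fc)
    df = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(n)],
            "base_mean": np.full(n, 100.0),
            "log2fc": log2fc,
            "se": np.full(n, 0.1),
            "p": np.asarray(p, dtype=float) if p is not None else np.full(n, 0.5),
        }
    )
    if padj is not None:
        df["padj"] = np.asarray(padj, dtype=float)
    if call is not None:
        df["call"] = list(call)
    return df
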