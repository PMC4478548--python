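import numpy as np
import pandas as pd
import pytest

from polymap.cluster_engine import ClusterComponent, ClusterModel


def make_model(marker, comps, n_samples=200):
    """Build a ClusterModel from (mean_theta, sd_theta, weight, genotype) tuples."""
    components = [
        ClusterComponent(
            mean_theta=m, sd_theta=s, mean_r=1.0, sd_r=0.1, weight=w, genotype=g
        )
        for m, s, w, g in comps
    ]
    return ClusterModel(marker=marker, components=components, n_samples=n_samples)


@pytest.fixture
def canonical_diploid_model():
    """The calibration marker: homozygotes at 0.05/0.95, het at 0.50, sd 0.03."""
    return make_model(
        "canon",
        [
            (0.05, 0.03, 0.25, "AA"),
            (0.50, 0.03, 0.50, "AB"),
            (0.95, 0.03, 0.25, "BB"),
        ],
    )


@pytest.fixture
def abh_matrix():
    """Small hand-written ABH matrix (3 markers x 5 individuals)."""
    return pd.DataFrame(
        {
            "i1": ["A", "A", "A"],
            "i2": ["H", "H", "H"],
            "i3": ["B", "B", "B"],
            "i4": ["A", "A", "H"],
            "i5": ["-", "H", "H"],
        },
        index=["m1", "m2", "m3"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
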