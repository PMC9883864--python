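import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lncloc.graph import build_similarity_graph, extract_local_graphs
from lncloc.synthetic_data import SyntheticSpec, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_labeled_features():
    """Small labeled feature set: 3 well-separated classes, 3-mer features."""
    from lncloc.features import kmer_frequencies

    spec = SyntheticSpec(
        class_counts={"A": 30, "B": 20, "C": 12},
        length_range=(80, 150),
        separation=4.0,
        seed=7,
    )
    records = generate_dataset(spec)
    X = np.array([kmer_frequencies(r.sequence, 3) for r in records])
    labels = [r.label for r in records]
    return X, labels


def random_local_graphs(rng, n_nodes=12, dim=6, tau=0.3, layers=1):
    """A random similarity graph over non-negative vectors plus its ego graphs."""
    feats = rng.uniform(0.1, 1.0, size=(n_nodes, dim))
    labels = [str(rng.integers(0, 3)) for _ in range(n_nodes)]
    g = build_similarity_graph(feats, labels, tau)
    return g, extract_local_graphs(g, layers=layers)
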