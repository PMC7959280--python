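import numpy as np
import pandas as pd
import pytest

import gesturenet as gn


@pytest.fixture(scope="session")
def small_montage() -> gn.Montage:
    """18-channel montage with the 3-cortex structure (8/6/4)."""
    return gn.simulated_montage(8, 6, 4)


@pytest.fixture(scope="session")
def coupled_config(small_montage) -> gn.SimulationConfig:
    """Two classes with strong, distinct planted coupling."""
    specs = gn.cortex_group_specs(
        small_montage,
        [("Suturing", "dominant"), ("Idle", "dominant")],
        counts=[4, 3], coupling=0.9)
    return gn.SimulationConfig(n_channels=small_montage.n_channels,
                               classes=specs, seed=11,
                               duration_range_s=(2.0, 3.5))


@pytest.fixture(scope="session")
def coupled_epoch(coupled_config):
    rec, ann = gn.generate_dataset(coupled_config)
    return gn.extract_epochs(rec, ann)[0]


@pytest.fixture(scope="session")
def epoch_features(coupled_epoch, small_montage):
    """Full 60-feature vector of one strongly coupled epoch."""
    tensor = gn.build_tensor(coupled_epoch)
    cfg = gn.CommunityConfig(repetitions=10, null_permutations=10, seed=5)
    partition, mam, _ = gn.detect_communities(tensor, cfg)
    return gn.assemble_features(coupled_epoch, tensor, partition, mam,
                                small_montage)


def random_weighted_graph(n: int, seed: int, density: float = 1.0) -> np.ndarray:
    """Symmetric weighted graph with unit diagonal, weights in (0, 1]."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.uniform(size=(n, n)) < density
    w = np.triu(w * mask, 1)
    w = w + w.T
    np.fill_diagonal(w, 1.0)
    return w
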