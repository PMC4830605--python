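import numpy as np
import pytest

import blastmap as bm


@pytest.fixture(scope="session")
def panel():
    return bm.default_panel()


@pytest.fixture(scope="session")
def healthy_spec(panel):
    return bm.healthy_marrow_spec(panel)


@pytest.fixture(scope="session")
def marrow_sample(healthy_spec):
    """One healthy marrow draw with truth labels (n=2000, fixed seed)."""
    m, truth = bm.generate_sample(healthy_spec, "marrow", 2000, seed=5)
    return m, truth.labels["marrow"]


N_MAP_SEEDS = 10
MAP_N = 1200


@pytest.fixture(scope="session")
def healthy_maps(healthy_spec):
    """Ten seeded healthy-marrow embeddings with truth labels.

    Shared by the island-recovery and distance-ordering properties so the
    t-SNE cost is paid once per seed.
    """
    maps = []
    for seed in range(N_MAP_SEEDS):
        m, truth = bm.generate_sample(healthy_spec, "marrow", MAP_N, seed=100 + seed)
        emb = bm.fit_embedding(m, bm.EmbeddingParams(seed=seed))
        maps.append((m, emb, truth.labels["marrow"]))
    return maps


def make_coords_embedding(coords, source=None):
    """Wrap raw 2-D coordinates as an EmbeddingResult for island tests."""
    coords = np.asarray(coords, dtype=float)
    if source is None:
        source = np.zeros(len(coords), dtype=np.int64)
    return bm.EmbeddingResult(
        coords=coords, source_sample_index=source,
        params=bm.EmbeddingParams(seed=0),
    )
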