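import numpy as np
import pytest

from connnlm import (
    ConnectomeMatrix,
    HybridConnectivity,
    ParcellationVolume,
    Volume3D,
    normalize_sc,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_case(rng, shape, n_nodes, mask_p=0.85):
    """A seeded volume + parcellation + normalized SC + hybrid weighting."""
    data = rng.random(shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask.flat[0] = True
    vol = Volume3D(data=data, mask=mask)
    labels = rng.integers(0, n_nodes + 1, shape)
    parc = ParcellationVolume(labels=labels)
    raw = rng.random((n_nodes, n_nodes)) * 50
    raw = (raw + raw.T) / 2
    np.fill_diagonal(raw, 0)
    sc = normalize_sc(ConnectomeMatrix(values=raw, node_ids=list(range(1, n_nodes + 1))))
    return vol, parc, sc


def hybrid(sc, lam):
    return HybridConnectivity(sc_norm=sc, lam=lam)


@pytest.fixture(scope="session")
def small_phantom():
    """One small phantom bundle shared across tests that only need plumbing."""
    from connnlm import PhantomConfig, generate_phantom

    cfg = PhantomConfig(
        shape=(24, 24, 16),
        n_nodes=6,
        lesion_specs=[
            ("connected_lesion_1", 1, 1.2, 2.5),
            ("connected_lesion_2", 3, 1.2, 1.8),
            ("isolated_lesion", 5, 1.2, 2.5),
        ],
        connected_pairs=[(1, 3, 1.0)],
        seed=7,
    )
    return generate_phantom(cfg)
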