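import numpy as np
import pytest

from fmg import GenerationConfig, VectorSpace, make_synthetic_space


@pytest.fixture(scope="session")
def clustered():
    """Moderately separated clustered space: 12 x 160 items, 50-dim."""
    return make_synthetic_space(
        n_clusters=12, items_per_cluster=160, dim=50, within_spread=0.15, seed=3
    )


@pytest.fixture(scope="session")
def well_separated():
    """Tightly concentrated clusters for parameter-recovery checks."""
    return make_synthetic_space(
        n_clusters=12, items_per_cluster=120, dim=50, within_spread=0.05, seed=7
    )


@pytest.fixture
def tiny_space():
    """Three hand-placed 2-D items."""
    return VectorSpace(
        labels=["a", "b", "c"],
        vectors=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )


@pytest.fixture(scope="session")
def small_config():
    """A configuration sized for the 12 x 160 fixture."""
    return GenerationConfig(
        n_lists=4,
        close_space_size=50,
        n_studied=15,
        n_targets=6,
        n_critical=1,
        n_unrelated=5,
        method="random",
        classical_critical_lure=True,
        seed=11,
    )


def brute_force_ranking(space, reference, excluded=()):
    """Independent neighbor ranking: per-item cosine via raw dot products."""
    ref = np.asarray(reference, dtype=float)
    out = []
    for label, vec in zip(space.labels, space.vectors):
        if label in excluded:
            continue
        cos = float(vec @ ref / (np.linalg.norm(vec) * np.linalg.norm(ref)))
        out.append((1.0 - cos, label))
    out.sort(key=lambda t: (t[0], t[1]))
    return out
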