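import numpy as np
import pytest

from cryoclust.commonline import SimilarityGraph
from cryoclust.simulate import ProjectionSet, make_dataset


@pytest.fixture
def rng():
    # function-scoped so every test sees the same stream
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """3 shape classes x 8 clean projections at 64 px (fast)."""
    return make_dataset(3, (8, 8), image_size=64, noisy=False, seed=1,
                        grid_size=32)


@pytest.fixture(scope="session")
def texture_toyset():
    """3-class toy image set where class identity is stripe orientation.

    Global statistics are matched across classes (random phase and
    frequency jitter, additive noise), so pooled random conv features
    separate the classes only weakly — room for fine-tuning to help.
    """
    rng = np.random.default_rng(0)
    size, n_per = 32, 8
    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    imgs, labs = [], []
    for c in range(3):
        for _ in range(n_per):
            ph = rng.uniform(0, 2 * np.pi)
            f = rng.uniform(0.8, 1.2) * 2 * np.pi / 6
            if c == 0:
                img = np.sin(f * jj + ph)
            elif c == 1:
                img = np.sin(f * ii + ph)
            else:
                img = np.sin(f * (ii + jj) / np.sqrt(2) + ph)
            imgs.append(img + rng.normal(0, 0.6, (size, size)))
            labs.append(c)
    return ProjectionSet(images=np.stack(imgs), labels=np.array(labs))


def make_graph(src, dst, n, directed=True, weight=None):
    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    w = np.ones(len(src)) if weight is None else np.asarray(weight, float)
    return SimilarityGraph(
        n_nodes=n, src=src, dst=dst, raw_score=w.copy(), weight=w,
        angle_src=np.zeros(len(src)), angle_dst=np.zeros(len(src)),
        directed=directed,
    )


@pytest.fixture(scope="session")
def two_cliques_graph():
    """Two disjoint directed 6-cliques (unit weights)."""
    src, dst = [], []
    for base in (0, 6):
        for i in range(6):
            for j in range(6):
                if i != j:
                    src.append(base + i)
                    dst.append(base + j)
    return make_graph(src, dst, 12)


@pytest.fixture
def blobs():
    """Three tight well-separated Gaussian blobs in 3-D with labels."""
    rng = np.random.default_rng(7)
    X = np.vstack([
        rng.normal((0, 0, 0), 0.05, (10, 3)),
        rng.normal((2, 0, 0), 0.05, (10, 3)),
        rng.normal((0, 4, 0), 0.05, (10, 3)),
    ])
    return X, np.repeat([0, 1, 2], 10)
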