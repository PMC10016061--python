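import numpy as np
import pytest

from semiconn.core import RegionTable, WeightedConnectome


@pytest.fixture(scope="session")
def aal90():
    return RegionTable.aal90()


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


def random_connected_connectome(
    rng: np.random.Generator,
    n: int,
    density: float = 0.6,
    regions: RegionTable | None = None,
    normalized: bool = True,
) -> WeightedConnectome:
    """A random symmetric connectome guaranteed connected (ring + extras)."""
    w = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order, np.roll(order, 1)):  # spanning ring
        w[a, b] = w[b, a] = rng.uniform(0.1, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    extra = rng.random(len(iu)) < density
    for i, j in zip(iu[extra], ju[extra]):
        if w[i, j] == 0:
            v = rng.uniform(0.05, 1.0)
            w[i, j] = w[j, i] = v
    if normalized:
        w = w / w.max()
    if regions is None:
        half = n // 2
        hemis = tuple("L" if k < half else "R" for k in range(n))
        regions = RegionTable(tuple(f"r{k}" for k in range(n)), hemis)
    return WeightedConnectome(w, regions, "random")


@pytest.fixture
def make_random_connectome(rng):
    def _make(n, density=0.6, normalized=True):
        return random_connected_connectome(rng, n, density, normalized=normalized)

    return _make
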