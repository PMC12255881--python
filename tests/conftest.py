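import numpy as np
import pytest

from bmephylo import DistanceMatrix, gen_rdsm, gen_rim


def random_dm(n: int, seed: int, low: float = 0.5, high: float = 10.0
              ) -> DistanceMatrix:
    """Generic random symmetric positive distance matrix."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(low, high, size=(n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(v)


def family_dm(family: str, n: int, seed: int) -> DistanceMatrix:
    """Instance from one of the synthetic benchmark families."""
    return gen_rdsm(n, seed) if family == "C" else gen_rim(n, seed)


@pytest.fixture
def quartet_dm() -> DistanceMatrix:
    """Additive 4-taxon matrix of the tree with cherries {1,2} and {3,4}."""
    return DistanceMatrix(
        np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
                 dtype=float))


@pytest.fixture
def quartet_plm() -> np.ndarray:
    return np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]])
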