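import numpy as np
import pytest

from tensorevd import Kernel


def make_psd_kernel(n: int, seed: int, rank: int | None = None, prefix: str = "L") -> Kernel:
    """Random PSD kernel A A' / m with optional rank deficiency."""
    rng = np.random.default_rng(seed)
    m = rank if rank is not None else n + 2
    A = rng.standard_normal((n, m))
    return Kernel(values=A @ A.T / m, labels=np.array([f"{prefix}{i}" for i in range(n)]))


def full_crossing(labels1, labels2):
    """ID vectors enumerating every (row of K1, row of K2) pair exactly once."""
    id1 = np.repeat(labels1, len(labels2))
    id2 = np.tile(labels2, len(labels1))
    return id1, id2


def random_design(labels1, labels2, n: int, seed: int):
    rng = np.random.default_rng(seed)
    return rng.choice(labels1, n), rng.choice(labels2, n)


@pytest.fixture
def psd_kernel():
    return make_psd_kernel


@pytest.fixture
def toy_pair():
    """The 3-observation worked example: 2x2 kernel crossed with a 1x1 kernel."""
    K1 = Kernel(values=np.array([[1.0, 0.5], [0.5, 1.0]]), labels=np.array(["A", "B"]))
    K2 = Kernel(values=np.array([[1.0]]), labels=np.array(["e"]))
    ID1 = np.array(["A", "A", "B"])
    ID2 = np.array(["e", "e", "e"])
    return K1, K2, ID1, ID2
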