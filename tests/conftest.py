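import numpy as np
import pytest

from skewotsu import Histogram


def random_histogram(rng: np.random.Generator, levels: int = 256) -> Histogram:
    """A varied random histogram: dense, sparse or spiky, never empty."""
    kind = rng.integers(0, 3)
    if kind == 0:
        counts = rng.integers(0, 200, size=levels)
    elif kind == 1:
        counts = np.zeros(levels, dtype=int)
        idx = rng.choice(levels, size=rng.integers(2, max(3, levels // 4)), replace=False)
        counts[idx] = rng.integers(1, 1000, size=idx.size)
    else:
        centers = rng.integers(0, levels, size=2)
        i = np.arange(levels)
        counts = sum(
            np.round(1000 * np.exp(-0.5 * ((i - c) / (1 + 0.1 * levels)) ** 2)) for c in centers
        ).astype(int)
    if counts.sum() == 0:
        counts[rng.integers(0, levels)] = 1
    return Histogram(counts.astype(np.int64))


def assert_same_argmax(a, b, rtol=1e-9, atol=1e-12):
    """Argmax indices agree, treating numerically tied maxima as equal."""
    a = np.asarray(a)
    b = np.asarray(b)
    ta, tb = int(np.argmax(a)), int(np.argmax(b))
    if ta == tb:
        return
    assert a[tb] >= a[ta] - (rtol * abs(a[ta]) + atol), (ta, tb)
    assert b[ta] >= b[tb] - (rtol * abs(b[tb]) + atol), (ta, tb)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def two_spike() -> Histogram:
    """Half the mass at gray level 50, half at 200."""
    counts = np.zeros(256, dtype=np.int64)
    counts[50] = counts[200] = 100
    return Histogram(counts)
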