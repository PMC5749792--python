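import numpy as np
import pytest

from georeg.describe import generate_pattern


@pytest.fixture(scope="session")
def pattern():
    return generate_pattern()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fast9_oracle(arr: np.ndarray, xi: float) -> set[tuple[int, int]]:
    """Exhaustive per-pixel segment test, independent of the vectorized path.

    For every interior pixel the 16 circle intensities are gathered and the
    longest cyclic run of uniformly-brighter / uniformly-darker neighbors is
    measured with an explicit loop.
    """
    offsets = [
        (0, -3), (1, -3), (2, -2), (3, -1), (3, 0), (3, 1), (2, 2), (1, 3),
        (0, 3), (-1, 3), (-2, 2), (-3, 1), (-3, 0), (-3, -1), (-2, -2), (-1, -3),
    ]
    h, w = arr.shape
    found = set()
    for y in range(3, h - 3):
        for x in range(3, w - 3):
            c = arr[y, x]
            vals = [arr[y + dy, x + dx] for dx, dy in offsets]
            if _max_cyclic_run([v > c + xi for v in vals]) >= 9:
                found.add((x, y))
            elif _max_cyclic_run([v < c - xi for v in vals]) >= 9:
                found.add((x, y))
    return found


def _max_cyclic_run(bits: list[bool]) -> int:
    if all(bits):
        return len(bits)
    best = cur = 0
    for b in bits + bits:  # doubled to see wrap-around runs
        cur = cur + 1 if b else 0
        best = max(best, cur)
    return best
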