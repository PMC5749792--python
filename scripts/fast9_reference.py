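"""Reference segment-test detector: exhaustive per-pixel evaluation.

Deliberately written without the vectorized machinery of the package so it can
serve as an independent cross-check of the detector.
"""

from __future__ import annotations

import numpy as np

CIRCLE = [
    (0, -3), (1, -3), (2, -2), (3, -1), (3, 0), (3, 1), (2, 2), (1, 3),
    (0, 3), (-1, 3), (-2, 2), (-3, 1), (-3, 0), (-3, -1), (-2, -2), (-1, -3),
]


def fast9_reference(arr: np.ndarray, xi: float) -> set[tuple[int, int]]:
    h, w = arr.shape
    found = set()
    for y in range(3, h - 3):
        for x in range(3, w - 3):
            c = arr[y, x]
            vals = [arr[y + dy, x + dx] for dx, dy in CIRCLE]
            if (
                _longest_cyclic_run([v > c + xi for v in vals]) >= 9
                or _longest_cyclic_run([v < c - xi for v in vals]) >= 9
            ):
                found.add((float(x), float(y)))
    return found


def _longest_cyclic_run(bits: list[bool]) -> int:
    if all(bits):
        return len(bits)
    best = cur = 0
    for b in bits + bits:
        cur = cur + 1 if b else 0
        best = max(best, cur)
    return best
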