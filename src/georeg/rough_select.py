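"""Rough match selection on descriptor distances.

Three primitives:

* :func:`hamming_distance` — popcount of the XOR of two 256-bit descriptors.
* :func:`distance_window_filter` — data-driven selection window centered on
  the mean Hamming distance D-bar, with half-widths at the midpoints between
  D-bar and the extreme distances: retain D with
  (D-bar + D_min)/2 <= D <= (D-bar + D_max)/2.  Replaces the brittle fixed
  threshold D < eps, which over-prunes images with dense feature clusters.
* :func:`bidirectional_ratio_match` — Lowe-style optimal/sub-optimal ratio
  test applied in both directions plus mutual-nearest-neighbor consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .describe import BinaryDescriptor
from .errors import DescriptorError, ParameterError
from .types import MatchCandidate

DEFAULT_RATIO_T = 0.65


@dataclass(frozen=True)
class DistanceWindow:
    """Mean-centered Hamming-distance selection window [lo, hi]."""

    d_bar: float
    eps1: float
    eps2: float

    @property
    def lo(self) -> float:
        return self.d_bar - self.eps1

    @property
    def hi(self) -> float:
        return self.d_bar + self.eps2


def _packed(desc) -> np.ndarray:
    if isinstance(desc, BinaryDescriptor):
        return desc.packed
    arr = np.asarray(desc, dtype=np.uint8)
    if arr.ndim == 1 and arr.shape == (256,):
        return np.packbits(arr)
    if arr.shape[-1] != 32:
        raise DescriptorError(f"descriptor must be 256 bits / 32 bytes, got {arr.shape}")
    return arr


def hamming_distance(a, b) -> int:
    """D = popcount(a XOR b), 0 <= D <= 256."""
    pa, pb = _packed(a), _packed(b)
    if pa.shape != pb.shape:
        raise DescriptorError("descriptor length mismatch")
    return int(np.bitwise_count(pa ^ pb).sum())


def hamming_matrix(desc_a, desc_b) -> np.ndarray:
    """All-pairs Hamming distances between two packed descriptor sets.

    ``desc_a``: (Na, 32) uint8, ``desc_b``: (Nb, 32) uint8 -> (Na, Nb) int16.
    Chunked over the first axis to bound the XOR broadcast at ~32 MB.
    """
    A = np.atleast_2d(_packed(desc_a))
    B = np.atleast_2d(_packed(desc_b))
    out = np.empty((A.shape[0], B.shape[0]), dtype=np.int16)
    chunk = max(1, (32 << 20) // max(1, B.shape[0] * 32))
    for i in range(0, A.shape[0], chunk):
        xor = A[i : i + chunk, None, :] ^ B[None, :, :]
        out[i : i + chunk] = np.bitwise_count(xor).sum(axis=2, dtype=np.int16)
    return out


def distance_window_filter(
    matches: list[MatchCandidate],
) -> tuple[list[MatchCandidate], DistanceWindow | None]:
    """Retain matches whose Hamming distance falls in the mean-centered window.

    D-bar is the arithmetic mean of the match distances; eps1 is the midpoint
    half-width (D-bar - D_min)/2 and eps2 = (D_max - D-bar)/2, so the window
    is [(D-bar + D_min)/2, (D-bar + D_max)/2], inclusive on both ends.  With
    all distances equal the window collapses onto that distance and every
    match is retained.
    """
    if not matches:
        return [], None
    d = np.array([m.hamming for m in matches], dtype=np.float64)
    d_bar = float(d.mean())
    window = DistanceWindow(
        d_bar=d_bar, eps1=(d_bar - float(d.min())) / 2.0, eps2=(float(d.max()) - d_bar) / 2.0
    )
    retained = [m for m in matches if window.lo <= m.hamming <= window.hi]
    return retained, window


def bidirectional_ratio_match(
    desc_a, desc_b, t: float = DEFAULT_RATIO_T
) -> list[MatchCandidate]:
    """Mutual nearest neighbors passing the ratio test in both directions.

    For each query the nearest (D1) and second-nearest (D2) opposite-side
    descriptors are found; the query passes iff D1/D2 < t.  Pairs must pass in
    both directions *and* be mutual nearest neighbors.  Nearest-neighbor ties
    resolve to the lower index and the ratio uses the tied value (so an exact
    tie, ratio 1.0, is rejected for any t < 1).  A side with a single
    descriptor has no sub-optimal competitor; its ratio is taken as 0 (pass).
    """
    if not 0 < t <= 1:
        raise ParameterError(f"t must lie in (0, 1], got {t}")
    A = np.atleast_2d(_packed(desc_a))
    B = np.atleast_2d(_packed(desc_b))
    if A.shape[0] == 0 or B.shape[0] == 0:
        return []
    D = hamming_matrix(A, B).astype(np.float64)

    nn_a, pass_a = _nn_and_ratio_pass(D, t)
    nn_b, pass_b = _nn_and_ratio_pass(D.T, t)

    out = []
    for i in range(A.shape[0]):
        j = nn_a[i]
        if pass_a[i] and pass_b[j] and nn_b[j] == i:
            out.append(
                MatchCandidate(query_idx=i, train_idx=j, hamming=int(D[i, j]),
                               quality=-float(D[i, j]))
            )
    return out


def _nn_and_ratio_pass(D: np.ndarray, t: float):
    """Per-row nearest-neighbor index and ratio-test verdict."""
    nn = D.argmin(axis=1)  # argmin takes the lower index on ties
    d1 = D[np.arange(D.shape[0]), nn]
    if D.shape[1] < 2:
        return nn, np.ones(D.shape[0], dtype=bool)
    part = np.partition(D, 1, axis=1)
    d2 = part[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d2 > 0, d1 / np.maximum(d2, 1e-300), np.where(d1 == 0, 1.0, np.inf))
    return nn, ratio < t
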