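"""Steered sub-window BRIEF: 256-bit binary descriptors.

Each descriptor bit is a comparison test between the box-filtered intensities
at two sample points of a fixed 256-pair pattern, the pattern being rotated by
the keypoint orientation before sampling.  Box sums over the
``subwindow`` x ``subwindow`` neighborhood (default 5x5, via an integral
image) stand in for single-pixel reads, which makes the test robust to noise.
Bit i is 1 iff boxsum(m_i) < boxsum(n_i), strict inequality (ties give 0).

The canonical pattern is drawn once from an isotropic Gaussian with a fixed
seed; a greedy de-correlating selection over a training corpus is available
for users who have one (`learn_pattern_greedy`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import BorderError, DescriptorError, ParameterError
from .types import KeyPoint, as_gray

N_PAIRS = 256
DEFAULT_PATCH_HALF = 15
DEFAULT_SUBWINDOW = 5
DEFAULT_PATTERN_SEED = 42
#: number of discrete steering angles cached per pattern (12 degrees / bin)
N_ANGLE_BINS = 30
#: keypoint-to-border clearance required to describe (steered sample radius
#: patch_half-2, +1 rounding guard, + subwindow half-width 2)
DESCRIPTOR_BORDER = DEFAULT_PATCH_HALF + 1


@dataclass(frozen=True)
class SamplingPattern:
    """256 ordered point pairs in patch-centered (x, y) pixel coordinates.

    ``pairs`` has shape (256, 2, 2): pairs[i] = ((x_m, y_m), (x_n, y_n)).
    All points lie inside the disc of radius ``patch_half - margin`` so any
    steering angle keeps the box-sum support inside the patch.
    """

    pairs: np.ndarray
    patch_half: int = DEFAULT_PATCH_HALF

    def __post_init__(self):
        arr = np.asarray(self.pairs, dtype=np.float64)
        # the canonical descriptor uses 256 pairs; learned subsets may be
        # smaller (describe_all enforces 256 where bits must pack to 32 bytes)
        if arr.ndim != 3 or arr.shape[1:] != (2, 2) or arr.shape[0] < 1:
            raise ParameterError(f"pattern must have shape (n, 2, 2), got {arr.shape}")
        object.__setattr__(self, "pairs", arr)

    @property
    def matrix(self) -> np.ndarray:
        """The 2 x 512 stack of all pattern point coordinates (x row, y row)."""
        flat = self.pairs.reshape(-1, 2)
        return flat.T.copy()


@dataclass(frozen=True)
class BinaryDescriptor:
    """Ordered 256-bit string packed into 32 bytes (big-endian within bytes)."""

    packed: np.ndarray  # (32,) uint8

    def __post_init__(self):
        arr = np.asarray(self.packed, dtype=np.uint8)
        if arr.shape != (32,):
            raise DescriptorError(f"descriptor must pack to 32 bytes, got {arr.shape}")
        object.__setattr__(self, "packed", arr)

    @classmethod
    def from_bits(cls, bits) -> "BinaryDescriptor":
        b = np.asarray(bits, dtype=np.uint8)
        if b.shape != (N_PAIRS,):
            raise DescriptorError(f"descriptor must have 256 bits, got {b.shape}")
        return cls(np.packbits(b))

    @property
    def bits(self) -> np.ndarray:
        return np.unpackbits(self.packed)

    def to_hex(self) -> str:
        return self.packed.tobytes().hex()

    @classmethod
    def from_hex(cls, s: str) -> "BinaryDescriptor":
        raw = bytes.fromhex(s)
        if len(raw) != 32:
            raise DescriptorError(f"hex descriptor must be 64 chars, got {len(s)}")
        return cls(np.frombuffer(raw, dtype=np.uint8).copy())


def generate_pattern(
    seed: int = DEFAULT_PATTERN_SEED, patch_half: int = DEFAULT_PATCH_HALF
) -> SamplingPattern:
    """Draw the 256-pair pattern from an isotropic Gaussian (sigma = patch_half/2).

    Points falling outside the safe disc of radius ``patch_half - 2`` (the
    sub-window margin) are radially clipped onto it, so the pattern steers to
    any angle without leaving the patch.  Deterministic for fixed arguments.
    """
    if patch_half < 8:
        raise ParameterError(f"patch_half must be >= 8, got {patch_half}")
    rng = np.random.default_rng(seed)
    pts = rng.normal(0.0, patch_half / 2.0, size=(N_PAIRS, 2, 2))
    # radial clip keeps |p| <= limit for every steering angle; a small margin
    # absorbs the rounding to integer offsets
    limit = patch_half - DEFAULT_SUBWINDOW // 2
    r = np.linalg.norm(pts, axis=-1, keepdims=True)
    factor = np.where(r > limit - 1.0, (limit - 1.0) / np.maximum(r, 1e-12), 1.0)
    return SamplingPattern(pairs=np.rint(pts * factor), patch_half=patch_half)


def steer_pattern(pattern: SamplingPattern, alpha: float) -> SamplingPattern:
    """Rotate every pattern point by ``alpha`` and round to integer offsets.

    (x, y) -> (x cos a - y sin a, x sin a + y cos a) in the image frame
    (y down), i.e. the steered pattern tracks content rotated by ``alpha``,
    which is what makes the descriptor rotation-covariant when ``alpha`` is
    the intensity-centroid orientation.
    """
    c, s = math.cos(alpha), math.sin(alpha)
    rot = np.array([[c, -s], [s, c]])
    steered = np.rint(pattern.pairs @ rot.T)
    return SamplingPattern(pairs=steered, patch_half=pattern.patch_half)


def integral_image(image) -> np.ndarray:
    """Zero-padded summed-area table: ii[y, x] = sum of arr[:y, :x]."""
    arr = as_gray(image)
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def box_sums(ii: np.ndarray, xs, ys, half: int) -> np.ndarray:
    """Sums of (2*half+1)^2 boxes centered at integer (xs, ys) via the SAT."""
    xs = np.asarray(xs, dtype=np.intp)
    ys = np.asarray(ys, dtype=np.intp)
    x1, x2 = xs - half, xs + half + 1
    y1, y2 = ys - half, ys + half + 1
    return ii[y2, x2] - ii[y1, x2] - ii[y2, x1] + ii[y1, x1]


def _quantized_angle(alpha: float) -> float:
    step = 2 * math.pi / N_ANGLE_BINS
    return round(alpha / step) * step


_STEER_CACHE: dict[tuple[int, int], SamplingPattern] = {}


def _steered(pattern: SamplingPattern, alpha: float, exact: bool) -> SamplingPattern:
    if exact:
        return steer_pattern(pattern, alpha)
    step = 2 * math.pi / N_ANGLE_BINS
    bin_idx = int(round(alpha / step)) % N_ANGLE_BINS
    key = (id(pattern), bin_idx)
    cached = _STEER_CACHE.get(key)
    if cached is None:
        cached = _STEER_CACHE[key] = steer_pattern(pattern, bin_idx * step)
        if len(_STEER_CACHE) > 4 * N_ANGLE_BINS:  # drop stale pattern entries
            for k in list(_STEER_CACHE)[: 2 * N_ANGLE_BINS]:
                _STEER_CACHE.pop(k, None)
    return cached


def describe(
    image,
    kp: KeyPoint,
    pattern: SamplingPattern | None = None,
    subwindow: int = DEFAULT_SUBWINDOW,
    exact_steering: bool = False,
) -> BinaryDescriptor:
    """Describe a single keypoint (convenience wrapper over `describe_all`)."""
    descs = describe_all(
        image, [kp], pattern=pattern, subwindow=subwindow,
        exact_steering=exact_steering, drop_border=False,
    )
    return BinaryDescriptor(descs[0])


def describe_all(
    image,
    keypoints: list[KeyPoint],
    pattern: SamplingPattern | None = None,
    subwindow: int = DEFAULT_SUBWINDOW,
    exact_steering: bool = False,
    drop_border: bool = True,
):
    """Describe many keypoints; returns an (N, 32) uint8 packed array.

    With ``drop_border=True`` (pipeline policy) keypoints too close to the
    border are silently removed and the surviving list is returned as a second
    value; with ``drop_border=False`` a :class:`BorderError` is raised instead.
    """
    if pattern is None:
        pattern = default_pattern()
    if subwindow % 2 != 1 or subwindow < 1:
        raise ParameterError(f"subwindow must be odd and positive, got {subwindow}")
    half = subwindow // 2
    arr = as_gray(image)
    h, w = arr.shape
    # worst-case steered sample offset: disc radius (patch_half - 2) + 1 for
    # rounding; box sum adds `half`
    border = pattern.patch_half - 2 + 1 + half
    inside, outside = [], []
    for kp in keypoints:
        x0, y0 = int(round(kp.x)), int(round(kp.y))
        ok = border <= x0 < w - border and border <= y0 < h - border
        (inside if ok else outside).append(kp)
    if outside and not drop_border:
        kp = outside[0]
        raise BorderError(
            f"descriptor patch at ({kp.x}, {kp.y}) exceeds image bounds {h}x{w}"
        )
    ii = integral_image(arr)
    out = np.zeros((len(inside), 32), dtype=np.uint8)
    for i, kp in enumerate(inside):
        sp = _steered(pattern, kp.orientation, exact_steering)
        x0, y0 = int(round(kp.x)), int(round(kp.y))
        pts = sp.pairs.astype(np.intp)  # (256, 2, 2)
        sums = box_sums(ii, x0 + pts[..., 0], y0 + pts[..., 1], half)  # (256, 2)
        bits = (sums[:, 0] < sums[:, 1]).astype(np.uint8)
        out[i] = np.packbits(bits)
    if drop_border:
        return out, inside
    return out


_DEFAULT_PATTERN: SamplingPattern | None = None


def default_pattern() -> SamplingPattern:
    """The package-wide canonical pattern (seed 42, 31x31 patch)."""
    global _DEFAULT_PATTERN
    if _DEFAULT_PATTERN is None:
        _DEFAULT_PATTERN = generate_pattern(DEFAULT_PATTERN_SEED, DEFAULT_PATCH_HALF)
    return _DEFAULT_PATTERN


def learn_pattern_greedy(
    candidate_tests,
    training_patches,
    corr_threshold: float = 0.2,
    subwindow: int = DEFAULT_SUBWINDOW,
    patch_half: int = DEFAULT_PATCH_HALF,
    n_select: int = N_PAIRS,
) -> SamplingPattern:
    """Greedy de-correlating selection of ``n_select`` tests.

    Each candidate test is evaluated (unsteered, at the patch center) on every
    training patch, giving one bit column per candidate.  Candidates are
    ranked by |mean(bit) - 0.5| ascending (most discriminative first) and
    accepted greedily when the absolute Pearson correlation with every
    already-accepted column stays below ``corr_threshold``; the threshold is
    relaxed in steps of 0.05 until ``n_select`` tests are found.
    """
    cands = np.asarray(candidate_tests, dtype=np.float64)
    if cands.ndim != 3 or cands.shape[1:] != (2, 2):
        raise ParameterError("candidate_tests must have shape (n, 2, 2)")
    if len(cands) < n_select:
        raise ParameterError(
            f"need >= {n_select} candidate tests, got {len(cands)}"
        )
    half = subwindow // 2
    bit_columns = np.zeros((len(cands), len(training_patches)))
    for j, patch in enumerate(training_patches):
        arr = as_gray(patch)
        ii = integral_image(arr)
        cy, cx = arr.shape[0] // 2, arr.shape[1] // 2
        pts = np.rint(cands).astype(np.intp)
        xs = np.clip(cx + pts[..., 0], half, arr.shape[1] - 1 - half)
        ys = np.clip(cy + pts[..., 1], half, arr.shape[0] - 1 - half)
        sums = box_sums(ii, xs, ys, half)
        bit_columns[:, j] = sums[:, 0] < sums[:, 1]

    order = np.lexsort((np.arange(len(cands)), np.abs(bit_columns.mean(axis=1) - 0.5)))
    selected = _greedy_decorrelate(bit_columns, order, corr_threshold, n_select)
    return SamplingPattern(pairs=cands[selected], patch_half=patch_half)


def _greedy_decorrelate(bit_columns, order, threshold, n_select):
    selected: list[int] = []
    while len(selected) < n_select and threshold <= 1.0 + 1e-9:
        for idx in order:
            if idx in selected:
                continue
            if all(
                _abs_corr(bit_columns[idx], bit_columns[s]) < threshold
                for s in selected
            ):
                selected.append(idx)
                if len(selected) == n_select:
                    break
        threshold += 0.05
    if len(selected) < n_select:
        raise ParameterError(
            f"could not find {n_select} tests below correlation 1.0"
        )
    return selected


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson correlation| of two bit columns; constant columns correlate
    1.0 with identical columns and 0.0 otherwise."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))
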