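"""FAST-9 corner detection, Harris response selection, and intensity-centroid
orientation.

The detector is the classic segment test: a pixel ``p`` is a corner when at
least 9 *contiguous* pixels of the 16-pixel Bresenham circle (radius 3) are all
brighter than ``G(p) + xi`` or all darker than ``G(p) - xi``.  The accumulated
absolute contrast over the circle (the sum of |G(i) - G(p)| restricted to
pixels exceeding the threshold) is kept as a per-candidate score and is used
for 3x3 non-maximum suppression; final ranking uses the Harris corner
response det(M) - k * trace(M)^2 of the gradient structure tensor.

Keypoint orientation is the intensity-centroid angle
``alpha = atan2(M01, M10)`` of the circular patch moments
``M_pq = sum x^p y^q I(x, y)`` with coordinates relative to the keypoint
(x = column offset, y = row offset, y increasing downward).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .errors import BorderError, DimensionError, ParameterError
from .types import MIN_IMAGE_SIDE, KeyPoint, as_gray

#: default FAST segment-test contrast threshold
DEFAULT_XI = 40.0
#: circle offsets (dx, dy) in cyclic order, radius-3 Bresenham circle
CIRCLE_OFFSETS = (
    (0, -3), (1, -3), (2, -2), (3, -1), (3, 0), (3, 1), (2, 2), (1, 3),
    (0, 3), (-1, 3), (-2, 2), (-3, 1), (-3, 0), (-3, -1), (-2, -2), (-1, -3),
)
FAST_RADIUS = 3
SEGMENT_LENGTH = 9
#: default circular-patch radius for the orientation moments
DEFAULT_ORIENTATION_RADIUS = 15


def _check_size(arr: np.ndarray) -> None:
    h, w = arr.shape
    if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
        raise DimensionError(
            f"image {h}x{w} smaller than minimum {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
        )


def fast9_detect(image, xi: float = DEFAULT_XI, return_scores: bool = False):
    """Run the FAST-9 segment test at every interior pixel.

    Returns every pixel (outside the 3-px border) with >= 9 contiguous circle
    neighbors all brighter or all darker than the center by more than ``xi``.
    Candidates carry position only; ``response``/``orientation`` are filled by
    later stages.  With ``return_scores=True``, also returns the map of
    accumulated absolute contrast (used for non-maximum suppression).
    """
    arr = as_gray(image)
    _check_size(arr)
    if not 0 < xi < 255:
        raise ParameterError(f"xi must lie in (0, 255), got {xi}")

    r = FAST_RADIUS
    center = arr[r:-r, r:-r]
    h, w = center.shape
    diffs = np.empty((16, h, w))
    for k, (dx, dy) in enumerate(CIRCLE_OFFSETS):
        diffs[k] = arr[r + dy : r + dy + h, r + dx : r + dx + w] - center

    brighter = diffs > xi
    darker = diffs < -xi
    corner = _contiguous_run(brighter) | _contiguous_run(darker)

    ys, xs = np.nonzero(corner)
    kps = [KeyPoint(x=float(x + r), y=float(y + r)) for y, x in zip(ys, xs)]
    if not return_scores:
        return kps
    score = np.zeros(arr.shape)
    absd = np.abs(diffs)
    score[r:-r, r:-r] = np.where(corner, (absd * (absd > xi)).sum(axis=0), 0.0)
    return kps, score


def _contiguous_run(mask: np.ndarray) -> np.ndarray:
    """True where >= SEGMENT_LENGTH cyclically contiguous entries are set."""
    ext = np.concatenate([mask, mask[: SEGMENT_LENGTH - 1]], axis=0)
    out = np.zeros(mask.shape[1:], dtype=bool)
    for start in range(16):
        out |= ext[start : start + SEGMENT_LENGTH].all(axis=0)
    return out


def suppress_nonmax(candidates: list[KeyPoint], score: np.ndarray) -> list[KeyPoint]:
    """3x3 non-maximum suppression of FAST candidates on a score map.

    A candidate survives when its score equals the 3x3 neighborhood maximum of
    the candidate-masked score map (plateau ties all survive; they are rare
    because scores are sums of many absolute differences).
    """
    if not candidates:
        return []
    masked = np.zeros_like(score)
    ys = np.array([int(k.y) for k in candidates])
    xs = np.array([int(k.x) for k in candidates])
    masked[ys, xs] = score[ys, xs]
    local_max = ndimage.maximum_filter(masked, size=3, mode="constant")
    keep = masked[ys, xs] >= local_max[ys, xs]
    return [k for k, f in zip(candidates, keep) if f]


def harris_response_map(
    image, k: float = 0.04, window: int = 7, sigma: float = 1.5
) -> np.ndarray:
    """Harris corner response at every pixel.

    Sobel gradients; structure tensor smoothed with a Gaussian truncated to a
    ``window`` x ``window`` support; response = det(M) - k * trace(M)^2.
    """
    arr = as_gray(image)
    gx = ndimage.sobel(arr, axis=1, mode="nearest")
    gy = ndimage.sobel(arr, axis=0, mode="nearest")
    radius = window // 2

    def smooth(a):
        return ndimage.gaussian_filter(a, sigma=sigma, radius=radius, mode="nearest")

    sxx, syy, sxy = smooth(gx * gx), smooth(gy * gy), smooth(gx * gy)
    det = sxx * syy - sxy * sxy
    trace = sxx + syy
    return det - k * trace * trace


def harris_select(
    image,
    candidates: list[KeyPoint],
    n_keep: int = 500,
    k: float = 0.04,
    window: int = 7,
) -> list[KeyPoint]:
    """Fill Harris responses and keep the ``n_keep`` strongest candidates.

    Output is sorted by response descending, ties broken by (y, x)
    lexicographic order, truncated to ``n_keep``.
    """
    if n_keep < 0:
        raise ParameterError(f"n_keep must be >= 0, got {n_keep}")
    if not candidates or n_keep == 0:
        return []
    resp = harris_response_map(image, k=k, window=window)
    scored = []
    for kp in candidates:
        scored.append(
            KeyPoint(
                x=kp.x, y=kp.y,
                response=float(resp[int(kp.y), int(kp.x)]),
                orientation=kp.orientation, level=kp.level, scale=kp.scale,
            )
        )
    scored.sort(key=lambda p: (-p.response, p.y, p.x))
    return scored[:n_keep]


@lru_cache(maxsize=8)
def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    inside = dx * dx + dy * dy <= radius * radius
    return dx[inside], dy[inside]


def compute_orientation(
    image, kp: KeyPoint, radius: int = DEFAULT_ORIENTATION_RADIUS
) -> float:
    """Intensity-centroid orientation of the circular patch around ``kp``.

    alpha = atan2(M01, M10) in (-pi, pi]; a point-symmetric patch
    (M01 = M10 = 0) returns 0 by convention.  The angle is stored on the
    keypoint as a side effect.
    """
    arr = as_gray(image)
    x0, y0 = int(round(kp.x)), int(round(kp.y))
    h, w = arr.shape
    if not (radius <= x0 < w - radius and radius <= y0 < h - radius):
        raise BorderError(
            f"orientation patch radius {radius} at ({x0}, {y0}) exceeds image {h}x{w}"
        )
    dx, dy = _disc_offsets(radius)
    vals = arr[y0 + dy, x0 + dx]
    m10 = float(np.dot(dx, vals))
    m01 = float(np.dot(dy, vals))
    alpha = 0.0 if (m10 == 0.0 and m01 == 0.0) else math.atan2(m01, m10)
    if alpha == -math.pi:
        alpha = math.pi
    kp.orientation = alpha
    return alpha


def orient_keypoints(
    image, keypoints: list[KeyPoint], radius: int = DEFAULT_ORIENTATION_RADIUS
) -> list[KeyPoint]:
    """Vectorized intensity-centroid orientation for many keypoints.

    Keypoints whose patch does not fit are dropped (border policy of the
    pipeline; `compute_orientation` raises instead for a single point).
    """
    arr = as_gray(image)
    h, w = arr.shape
    kept = [
        kp for kp in keypoints
        if radius <= int(round(kp.x)) < w - radius
        and radius <= int(round(kp.y)) < h - radius
    ]
    if not kept:
        return []
    dx, dy = _disc_offsets(radius)
    xs = np.array([int(round(kp.x)) for kp in kept])
    ys = np.array([int(round(kp.y)) for kp in kept])
    patches = arr[ys[:, None] + dy[None, :], xs[:, None] + dx[None, :]]
    m10 = patches @ dx.astype(np.float64)
    m01 = patches @ dy.astype(np.float64)
    alphas = np.arctan2(m01, m10)
    alphas[(m10 == 0) & (m01 == 0)] = 0.0
    alphas[alphas == -math.pi] = math.pi
    for kp, a in zip(kept, alphas):
        kp.orientation = float(a)
    return kept
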