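"""Deterministic synthetic fixtures with known ground-truth transforms.

Three generators cover the scenario families the registration pipeline is
meant for: corner-rich textured scenes with rotation/illumination change,
low-texture star fields with a high dynamic range, and bare labeled point
correspondences for the matcher/consensus stages.  Every generator is a pure
function of its arguments (one seeded RNG, no global state), so regenerating
with the same meta reproduces byte-identical data.

Warping convention matches the pipeline: truth maps image_a coordinates to
image_b coordinates ((x, y), 0-based, x = column); image_b is produced by
inverse-mapping with bilinear interpolation and constant-zero padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .errors import CoverageError, ParameterError
from .types import GrayImage, SimilarityTransform

STAR_PSF_SIGMA = 1.2  # px
STAR_MIN_SEPARATION = 6 * STAR_PSF_SIGMA  # keeps local-maxima counts exact
STAR_PEAK_MAX = 250.0
DEFAULT_TEXTURE_SIZE = 256
DEFAULT_N_STARS = 80
DEFAULT_DYN_RANGE = 1000.0


@dataclass
class FixturePair:
    image_a: GrayImage
    image_b: GrayImage
    truth: SimilarityTransform  # maps a-coordinates to b-coordinates
    meta: dict


def warp_image(arr: np.ndarray, transform: SimilarityTransform, out_shape=None) -> np.ndarray:
    """Forward-warp ``arr`` by ``transform`` (implemented as inverse mapping).

    Output pixel q receives arr sampled at transform^-1(q), bilinear,
    constant-zero outside.
    """
    if out_shape is None:
        out_shape = arr.shape
    h, w = out_shape
    inv = transform.inverse()
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    src = inv.apply(pts)
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    return ndimage.map_coordinates(arr, coords, order=1, mode="constant", cval=0.0)


def _check_coverage(arr_shape, transform: SimilarityTransform, out_shape) -> None:
    h, w = out_shape
    inv = transform.inverse()
    corners_and_grid = np.column_stack(
        [g.ravel() for g in np.meshgrid(np.linspace(0, w - 1, 8), np.linspace(0, h - 1, 8))]
    )
    src = inv.apply(corners_and_grid)
    ah, aw = arr_shape
    inside = (
        (src[:, 0] >= 0) & (src[:, 0] <= aw - 1) & (src[:, 1] >= 0) & (src[:, 1] <= ah - 1)
    )
    if inside.mean() < 0.05:
        raise CoverageError("transform pushes (nearly) all content out of frame")


def synth_texture_pair(
    seed: int = 0,
    size: int = DEFAULT_TEXTURE_SIZE,
    transform: SimilarityTransform | None = None,
    noise_sigma: float = 0.0,
    gain: float = 1.0,
    offset: float = 0.0,
) -> FixturePair:
    """Corner-rich textured scene and its warped, re-exposed, noisy copy.

    image_a = band-limited noise background + sharp random convex polygons
    (the corner supply); image_b = warp(image_a, transform), then intensity
    gain/offset (clipped to [0, 255]) plus Gaussian pixel noise.
    """
    if size < 128:
        raise ParameterError(f"size must be >= 128, got {size}")
    if gain <= 0:
        raise ParameterError(f"gain must be > 0, got {gain}")
    transform = transform or SimilarityTransform()
    rng = np.random.default_rng(seed)

    background = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=3.0)
    background = (background - background.min()) / np.ptp(background)
    img = 60.0 + 120.0 * background

    n_blobs = max(10, size // 18)
    for _ in range(n_blobs):
        cx, cy = rng.uniform(20, size - 20, size=2)
        radius = rng.uniform(8, min(30, size / 8))
        n_vert = rng.integers(3, 8)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
        vx = cx + radius * np.cos(angles)
        vy = cy + radius * np.sin(angles)
        rr, cc = draw_polygon(vy, vx, shape=img.shape)
        img[rr, cc] = rng.uniform(0, 255)
    img = np.clip(np.round(img), 0, 255)

    _check_coverage(img.shape, transform, img.shape)
    warped = warp_image(img, transform)
    warped = np.clip(gain * warped + offset, 0.0, 255.0)
    if noise_sigma > 0:
        warped = warped + rng.normal(0.0, noise_sigma, size=warped.shape)
    warped = np.clip(np.round(warped), 0, 255)

    meta = {
        "scenario": "texture", "seed": seed, "size": size,
        "noise_sigma": noise_sigma, "gain": gain, "offset": offset,
    }
    return FixturePair(GrayImage(img), GrayImage(warped), transform, meta)


def synth_starfield_pair(
    seed: int = 0,
    size: int = DEFAULT_TEXTURE_SIZE,
    n_stars: int = DEFAULT_N_STARS,
    dyn_range: float = DEFAULT_DYN_RANGE,
    transform: SimilarityTransform | None = None,
    noise_sigma: float = 0.0,
) -> FixturePair:
    """Low-texture star field: dark background with Gaussian point spreads.

    Peak intensities are log-spread over ``dyn_range`` below STAR_PEAK_MAX;
    the background sits at STAR_PEAK_MAX / dyn_range, so the scene's dynamic
    range is ``dyn_range`` by construction.  Stars are separated by at least
    6 PSF sigmas so each remains an isolated local maximum.
    """
    if n_stars < 10:
        raise ParameterError(f"n_stars must be >= 10, got {n_stars}")
    transform = transform or SimilarityTransform()
    rng = np.random.default_rng(seed)

    margin = 24
    positions = []
    attempts = 0
    while len(positions) < n_stars and attempts < 200 * n_stars:
        attempts += 1
        cand = rng.uniform(margin, size - margin, size=2)
        if all(np.hypot(*(cand - p)) >= STAR_MIN_SEPARATION for p in positions):
            positions.append(cand)
    if len(positions) < n_stars:
        raise ParameterError(
            f"could not place {n_stars} stars at separation {STAR_MIN_SEPARATION} in {size} px"
        )
    positions = np.array(positions)  # (n, 2) as (x, y)
    peaks = STAR_PEAK_MAX * dyn_range ** (-rng.uniform(0.0, 1.0, size=n_stars))

    background = STAR_PEAK_MAX / dyn_range
    img = np.full((size, size), background)
    ys, xs = np.mgrid[0:size, 0:size]
    rad = int(np.ceil(5 * STAR_PSF_SIGMA))
    for (x0, y0), peak in zip(positions, peaks):
        xi, yi = int(round(x0)), int(round(y0))
        sl = np.s_[max(0, yi - rad) : yi + rad + 1, max(0, xi - rad) : xi + rad + 1]
        dx = xs[sl] - x0
        dy = ys[sl] - y0
        img[sl] += peak * np.exp(-(dx * dx + dy * dy) / (2 * STAR_PSF_SIGMA**2))
    img = np.clip(img, 0.0, 255.0)

    _check_coverage(img.shape, transform, img.shape)
    warped = warp_image(img, transform)
    if noise_sigma > 0:
        warped = warped + rng.normal(0.0, noise_sigma, size=warped.shape)
    warped = np.clip(warped, 0.0, 255.0)

    meta = {
        "scenario": "starfield", "seed": seed, "size": size, "n_stars": n_stars,
        "dyn_range": dyn_range, "noise_sigma": noise_sigma,
        "star_positions": positions.tolist(), "star_peaks": peaks.tolist(),
    }
    return FixturePair(GrayImage(img), GrayImage(warped), transform, meta)


def synth_correspondences(
    seed: int = 0,
    n: int = 100,
    transform: SimilarityTransform | None = None,
    outlier_frac: float = 0.0,
    noise_sigma: float = 0.0,
    box: float = 300.0,
):
    """Labeled point correspondences under a known transform.

    src points are uniform in [0, box)^2; inlier dst = truth(src) + isotropic
    Gaussian noise; round(n * outlier_frac) randomly chosen points get a
    uniform random dst instead.  Returns (src, dst, inlier_labels).
    """
    if not 0 <= outlier_frac < 1:
        raise ParameterError(f"outlier_frac must lie in [0, 1), got {outlier_frac}")
    transform = transform or SimilarityTransform()
    rng = np.random.default_rng(seed)
    src = rng.uniform(0.0, box, size=(n, 2))
    dst = transform.apply(src)
    if noise_sigma > 0:
        dst = dst + rng.normal(0.0, noise_sigma, size=dst.shape)
    labels = np.ones(n, dtype=bool)
    n_out = round(n * outlier_frac)
    if n_out:
        out_idx = rng.choice(n, size=n_out, replace=False)
        labels[out_idx] = False
        lo = dst[labels].min(axis=0) if labels.any() else np.zeros(2)
        hi = dst[labels].max(axis=0) if labels.any() else np.full(2, box)
        dst[out_idx] = rng.uniform(lo, hi, size=(n_out, 2))
    return src, dst, labels
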