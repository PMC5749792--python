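"""Scale invariance: Gaussian image pyramid + scale-ratio histogram filtering.

Keypoints are detected on every pyramid level, so a physical feature observed
at different magnifications in the two images is matched across levels.  The
per-match scale ratio (query level scale / train level scale) of correct
matches clusters at the true inter-image scale; mismatches scatter.  The
filter histograms the ratios on a log axis, keeps matches inside a window of
half-width ``omega`` around the dominant bin, estimates the dominant ratio
``d`` as the mean of the survivors, and finally keeps only matches with
0.6*d <= ratio <= 1.4*d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .types import MIN_IMAGE_SIDE, GrayImage, MatchCandidate, as_gray

DEFAULT_OMEGA = 0.25  # window half-width, ratio units (valid range 0.20-0.35)
DEFAULT_N_LEVELS = 4
DEFAULT_FACTOR = 2.0
MAX_BINS = 32
MIN_BIN_RELATIVE_WIDTH = 0.05


@dataclass(frozen=True)
class PyramidLevel:
    image: GrayImage
    level: int
    scale: float  # cumulative downsampling factor, >= 1


@dataclass
class ScaleHistogram:
    """Diagnostics of the ratio-histogram filter."""

    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    peak_bin: int = -1
    omega: float = DEFAULT_OMEGA
    d: float = float("nan")

    @property
    def window(self) -> tuple[float, float]:
        if self.peak_bin < 0:
            return (float("nan"), float("nan"))
        center = float(
            np.sqrt(self.bin_edges[self.peak_bin] * self.bin_edges[self.peak_bin + 1])
        )
        return (center - self.omega, center + self.omega)

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])


def build_pyramid(
    image,
    n_levels: int = DEFAULT_N_LEVELS,
    factor: float = DEFAULT_FACTOR,
) -> list[PyramidLevel]:
    """Gaussian low-pass + downsample pyramid.

    Level 0 is the input; each subsequent level is the previous one blurred
    with an anti-alias Gaussian (sigma = 0.5 * factor) and resampled by
    1/factor in both axes (bilinear).  Levels that would fall below the
    minimum detection size are truncated with a warning.
    """
    if n_levels < 1:
        raise ParameterError(f"n_levels must be >= 1, got {n_levels}")
    if factor <= 1:
        raise ParameterError(f"factor must be > 1, got {factor}")
    arr = as_gray(image)
    levels = [PyramidLevel(GrayImage(arr), 0, 1.0)]
    current = arr
    for lvl in range(1, n_levels):
        blurred = ndimage.gaussian_filter(current, sigma=0.5 * factor, mode="nearest")
        new_shape = (
            int((current.shape[0] - 1) // factor) + 1,
            int((current.shape[1] - 1) // factor) + 1,
        )
        if min(new_shape) < MIN_IMAGE_SIDE:
            warnings.warn(
                f"pyramid truncated at level {lvl}: next level {new_shape} "
                f"smaller than {MIN_IMAGE_SIDE} px",
                stacklevel=2,
            )
            break
        # sample the blurred level at coordinates (i*factor, j*factor): level
        # coordinates then map to the parent level as exactly x * factor, so
        # xy0 = x * scale holds without position-dependent bias
        rows = np.arange(new_shape[0]) * factor
        cols = np.arange(new_shape[1]) * factor
        grid = np.meshgrid(rows, cols, indexing="ij")
        current = ndimage.map_coordinates(
            blurred, np.stack(grid), order=1, mode="nearest"
        )
        current = np.clip(current, 0.0, 255.0)
        levels.append(PyramidLevel(GrayImage(current), lvl, factor**lvl))
    return levels


def filter_matches_by_scale(
    matches: list[MatchCandidate],
    omega: float = DEFAULT_OMEGA,
    use_gmm: bool = False,
) -> tuple[list[MatchCandidate], ScaleHistogram]:
    """Histogram the scale ratios, window around the peak, keep 0.6d..1.4d.

    ``d`` is the arithmetic mean of the in-window ratios by default; with
    ``use_gmm=True`` it is the mean of the dominant component of a
    2-component 1-D Gaussian mixture fitted to the in-window log-ratios.
    """
    if omega <= 0:
        raise ParameterError(f"omega must be > 0, got {omega}")
    if not matches:
        return [], ScaleHistogram(omega=omega)

    ratios = np.array([m.scale_ratio for m in matches])
    edges = _log_edges(ratios)
    # np.histogram puts values equal to the top edge into the last bin
    counts, _ = np.histogram(ratios, bins=edges)

    centers = np.sqrt(edges[:-1] * edges[1:])
    peak = _peak_bin(counts, centers)
    hist = ScaleHistogram(bin_edges=edges, counts=counts, peak_bin=peak, omega=omega)

    lo, hi = hist.window
    in_window = [m for m in matches if lo <= m.scale_ratio <= hi]
    if not in_window:
        hist.d = float(centers[peak])
        return [], hist

    win_ratios = np.array([m.scale_ratio for m in in_window])
    hist.d = _dominant_mean_gmm(win_ratios) if use_gmm else float(win_ratios.mean())
    retained = [
        m for m in in_window if 0.6 * hist.d <= m.scale_ratio <= 1.4 * hist.d
    ]
    return retained, hist


def _log_edges(ratios: np.ndarray) -> np.ndarray:
    """Log-spaced bin edges; bin count capped so each bin spans at least
    ~5% relative width, with a single padded bin for degenerate ranges."""
    rmin, rmax = float(ratios.min()), float(ratios.max())
    if rmin == rmax:
        pad = 1.0 + MIN_BIN_RELATIVE_WIDTH / 2
        return np.array([rmin / pad, rmin * pad])
    span = np.log(rmax / rmin)
    n_bins = int(min(MAX_BINS, max(1, np.ceil(span / np.log1p(MIN_BIN_RELATIVE_WIDTH)))))
    return np.geomspace(rmin, rmax, n_bins + 1)


def _peak_bin(counts: np.ndarray, centers: np.ndarray) -> int:
    best = int(counts.max())
    tied = np.nonzero(counts == best)[0]
    # ties broken toward the bin whose center is nearest ratio 1
    return int(tied[np.argmin(np.abs(np.log(centers[tied])))])


def _dominant_mean_gmm(ratios: np.ndarray) -> float:
    from sklearn.mixture import GaussianMixture

    if len(ratios) < 4 or np.ptp(ratios) == 0:
        return float(ratios.mean())
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    logr = np.log(ratios).reshape(-1, 1)
    gm.fit(logr)
    dominant = int(np.argmax(gm.weights_))
    return float(np.exp(gm.means_[dominant, 0]))
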