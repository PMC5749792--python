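"""Shared domain types.

Coordinate convention used throughout the package: 0-based pixel coordinates,
``x`` = column, ``y`` = row, origin at the top-left corner.  Keypoints detected
on coarser pyramid levels carry their level-local coordinates plus the
cumulative downsampling factor ``scale``; level-0 coordinates are obtained by
multiplying by ``scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, DimensionError

#: minimum image side for detection (patch and border requirements)
MIN_IMAGE_SIDE = 32


def as_gray(image) -> np.ndarray:
    """Coerce input to a 2-D float64 intensity array in [0, 255].

    Accepts a :class:`GrayImage`, a 2-D array (any float/int dtype), or an
    RGB(A) array, which is converted with the usual luminance weights.
    """
    if isinstance(image, GrayImage):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {arr.shape}")
    return arr.astype(np.float64)


@dataclass(frozen=True)
class GrayImage:
    """2-D intensity raster with values in [0, 255].

    Pixels are stored as float64 so synthetic scenes with sub-unit dynamic
    range (faint star fields) survive; 8-bit inputs round-trip exactly.
    """

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise DimensionError(f"GrayImage must be 2-D, got shape {arr.shape}")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise DimensionError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class KeyPoint:
    """Located, oriented, scale-tagged interest point."""

    x: float
    y: float
    response: float = 0.0
    orientation: float = 0.0  # radians, (-pi, pi]
    level: int = 0
    scale: float = 1.0

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)

    @property
    def xy0(self) -> tuple[float, float]:
        """Position mapped to level-0 (full resolution) coordinates."""
        return (self.x * self.scale, self.y * self.scale)


@dataclass
class MatchCandidate:
    """A (query, train) keypoint pairing with its screening statistics."""

    query_idx: int
    train_idx: int
    hamming: int = 0
    scale_ratio: float = 1.0
    quality: float = 0.0

    def __post_init__(self):
        if not 0 <= self.hamming <= 256:
            raise ValueError(f"hamming must be in [0, 256], got {self.hamming}")
        if self.scale_ratio <= 0:
            raise ValueError("scale_ratio must be > 0")


@dataclass
class SimilarityTransform:
    """Rotation + translation (+ optional isotropic scale) in the plane.

    Maps source coordinates ``(u', v')`` to target coordinates ``(u, v)``:
    ``[u, v]^T = s * R(alpha) @ [u', v']^T + [du, dv]^T``.
    """

    alpha: float = 0.0
    du: float = 0.0
    dv: float = 0.0
    s: float = 1.0

    def __post_init__(self):
        if self.s <= 0:
            raise DegenerateGeometryError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix."""
        c, si = math.cos(self.alpha), math.sin(self.alpha)
        return np.array(
            [
                [self.s * c, -self.s * si, self.du],
                [self.s * si, self.s * c, self.dv],
                [0.0, 0.0, 1.0],
            ]
        )

    def apply(self, points) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    def inverse(self) -> "SimilarityTransform":
        inv_s = 1.0 / self.s
        c, si = math.cos(-self.alpha), math.sin(-self.alpha)
        du = -inv_s * (c * self.du - si * self.dv)
        dv = -inv_s * (si * self.du + c * self.dv)
        return SimilarityTransform(alpha=-self.alpha, du=du, dv=dv, s=inv_s)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return SimilarityTransform(
            alpha=_wrap_angle(self.alpha + other.alpha),
            s=self.s * other.s,
            du=float(self.apply(np.array([[other.du, other.dv]]))[0, 0]),
            dv=float(self.apply(np.array([[other.du, other.dv]]))[0, 1]),
        )

    @classmethod
    def about_center(
        cls, shape, alpha: float = 0.0, du: float = 0.0, dv: float = 0.0, s: float = 1.0
    ) -> "SimilarityTransform":
        """Rotation/scale about the image center followed by a translation.

        ``shape`` is (height, width); the fixed point is the geometric center
        ((w-1)/2, (h-1)/2), which keeps warped content in frame.
        """
        h, w = shape[:2]
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        c, si = math.cos(alpha), math.sin(alpha)
        tx = cx - s * (c * cx - si * cy) + du
        ty = cy - s * (si * cx + c * cy) + dv
        return cls(alpha=alpha, du=tx, dv=ty, s=s)

    def to_dict(self) -> dict:
        return {
            "alpha_rad": self.alpha,
            "du": self.du,
            "dv": self.dv,
            "s": self.s,
            "matrix_3x3_row_major": self.matrix.ravel().tolist(),
        }


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2 * math.pi) - math.pi
    return math.pi if a == -math.pi else a
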