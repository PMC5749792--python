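"""Geometric-invariant matching on inter-point distance profiles.

Each retained keypoint is described by the vector of Euclidean distances from
itself to every other retained keypoint in the same image — a quantity
invariant under rotation and translation, and (after dividing by the profile
mean) under isotropic scaling.  Two profiles are compared with a Gaussian
coincidence score

    F(i, j) = sum_s sum_t exp(-(D_i(s) - D_j(t))^2 / sigma^2),

where ``sigma`` acts as a distance-error tolerance in pixels: only pairs of
entries that agree to within a few sigma contribute, so profiles of truly
corresponding points (which share most inter-point distances) score far above
unrelated ones.  A candidate is accepted only when it is *distinctive*: the
runner-up score must be below ``T`` times the best score.

When profiles are normalized, ``sigma`` is mapped into normalized units by
dividing by the geometric mean of the two normalization factors, preserving
its pixel-tolerance meaning (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateGeometryError,
    InsufficientPointsError,
    ParameterError,
)
from .types import MatchCandidate

DEFAULT_SIGMA = 1.0
DEFAULT_T = 0.8
DEFAULT_K = 2
GAUSSIAN = "gaussian"
AS_PRINTED = "as-printed"


@dataclass(frozen=True)
class DistanceProfile:
    """Sorted distances from one keypoint to all other retained keypoints."""

    owner_idx: int
    dists: np.ndarray  # ascending, pixels at level-0 scale (or normalized)
    normalized: bool = False
    norm_factor: float = 1.0  # mean distance before normalization


@dataclass(frozen=True)
class GeomCost:
    value: float
    sigma: float
    mode: str = GAUSSIAN


def distance_profiles(points, normalize: bool = True) -> list[DistanceProfile]:
    """Build one distance profile per point.

    Profiles are sorted ascending (the cost sums over all entry pairs, so
    order does not change F; sorting gives deterministic serialization).
    Duplicate coordinates are rejected: a zero distance would be ambiguous
    under normalization and signals an upstream screening bug.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"points must have shape (n, 2), got {pts.shape}")
    if len(pts) < 2:
        raise InsufficientPointsError(f"need >= 2 points, got {len(pts)}")
    dmat = squareform(pdist(pts))
    if np.any(dmat[np.triu_indices(len(pts), k=1)] == 0.0):
        raise DegenerateGeometryError("coincident points in profile set")
    profiles = []
    for i in range(len(pts)):
        d = np.sort(np.delete(dmat[i], i))
        norm = float(d.mean())
        if normalize:
            profiles.append(
                DistanceProfile(i, d / norm, normalized=True, norm_factor=norm)
            )
        else:
            profiles.append(DistanceProfile(i, d))
    return profiles


def _effective_sigma(pi: DistanceProfile, pj: DistanceProfile, sigma: float) -> float:
    if pi.normalized and pj.normalized:
        return sigma / float(np.sqrt(pi.norm_factor * pj.norm_factor))
    return sigma


def geometric_cost(
    prof_i: DistanceProfile,
    prof_j: DistanceProfile,
    sigma: float = DEFAULT_SIGMA,
    mode: str = GAUSSIAN,
) -> GeomCost:
    """Cross-profile coincidence score F(i, j).

    ``gaussian`` (default) scores coincidences with exp(-delta^2/sigma^2);
    ``as-printed`` flips the exponent sign (diagnostic only — it is unbounded
    and rewards disagreement, which makes the ratio test vacuous).
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if mode not in (GAUSSIAN, AS_PRINTED):
        raise ParameterError(f"unknown mode {mode!r}")
    s_eff = _effective_sigma(prof_i, prof_j, sigma)
    delta = prof_i.dists[:, None] - prof_j.dists[None, :]
    sign = -1.0 if mode == GAUSSIAN else 1.0
    return GeomCost(
        value=float(np.exp(sign * (delta / s_eff) ** 2).sum()), sigma=sigma, mode=mode
    )


# exp(-x) underflows to exactly 0.0 beyond x ~ 745.13, so entry pairs farther
# apart than sqrt(746) * sigma contribute an exact IEEE zero and can be
# skipped without changing the result
_CUTOFF_SIGMAS = float(np.sqrt(746.0))


def cost_matrix(
    profiles_a: list[DistanceProfile],
    profiles_b: list[DistanceProfile],
    sigma: float = DEFAULT_SIGMA,
    mode: str = GAUSSIAN,
) -> np.ndarray:
    """Full (len_a, len_b) matrix of F values.

    In gaussian mode the sorted profiles are compared through a window search:
    only entry pairs within the kernel's non-underflow range are evaluated,
    which is exact (terms outside are IEEE zeros) and far cheaper than the
    dense double sum on realistic point counts.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if mode not in (GAUSSIAN, AS_PRINTED):
        raise ParameterError(f"unknown mode {mode!r}")
    F = np.empty((len(profiles_a), len(profiles_b)))
    for i, pa in enumerate(profiles_a):
        for j, pb in enumerate(profiles_b):
            s_eff = _effective_sigma(pa, pb, sigma)
            if mode == GAUSSIAN:
                F[i, j] = _windowed_gauss_sum(pa.dists, pb.dists, s_eff)
            else:
                delta = pa.dists[:, None] - pb.dists[None, :]
                F[i, j] = np.exp((delta / s_eff) ** 2).sum()
    return F


def _windowed_gauss_sum(da: np.ndarray, db: np.ndarray, sigma: float) -> float:
    """sum exp(-((da[s]-db[t])/sigma)^2) over pairs inside the cutoff window."""
    cut = _CUTOFF_SIGMAS * sigma
    lo = np.searchsorted(db, da - cut, side="left")
    hi = np.searchsorted(db, da + cut, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return 0.0
    if total >= da.size * db.size // 2:  # dense is cheaper
        delta = da[:, None] - db[None, :]
        return float(np.exp(-((delta / sigma) ** 2)).sum())
    # ragged windows flattened: db index = lo[s] + offset within each window
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    t_idx = np.repeat(lo, counts) + offsets
    a_vals = np.repeat(da, counts)
    return float(np.exp(-(((a_vals - db[t_idx]) / sigma) ** 2)).sum())


def geometric_match(
    profiles_a: list[DistanceProfile],
    profiles_b: list[DistanceProfile],
    T: float = DEFAULT_T,
    K: int = DEFAULT_K,
    sigma: float = DEFAULT_SIGMA,
    mode: str = GAUSSIAN,
) -> list[MatchCandidate]:
    """Distinctiveness-gated best-F assignment between two profile sets.

    For each profile in A the B-candidates are ranked by F descending; the
    best candidate j* is accepted iff every runner-up among ranks 2..K scores
    F(i, j_m) < T * F(i, j*).  Accepted pairs are made one-to-one: when two
    A-points claim the same B-point, the higher F wins and the loser is
    dropped.  ``quality`` on the output is 1 - runner-up/best, used downstream
    to order matches for progressive sampling.
    """
    if not profiles_a or not profiles_b:
        raise InsufficientPointsError("both profile sets must be non-empty")
    if not 0 < T <= 1:
        raise ParameterError(f"T must lie in (0, 1], got {T}")
    if K < 2:
        raise ParameterError(f"K must be >= 2, got {K}")
    F = cost_matrix(profiles_a, profiles_b, sigma=sigma, mode=mode)
    accepted: dict[int, tuple[float, int, float]] = {}  # b_idx -> (F, a_idx, quality)
    for i in range(F.shape[0]):
        order = np.argsort(-F[i], kind="stable")
        j_star = int(order[0])
        best = F[i, j_star]
        if best <= 0:
            continue
        runners = F[i, order[1:K]]
        if runners.size and np.any(runners / best >= T):
            continue
        quality = 1.0 - (float(runners[0]) / best if runners.size else 0.0)
        prev = accepted.get(j_star)
        if prev is None or best > prev[0]:
            accepted[j_star] = (best, i, quality)
    out = []
    for j, (best, i, quality) in sorted(accepted.items(), key=lambda kv: kv[1][1]):
        out.append(
            MatchCandidate(
                query_idx=profiles_a[i].owner_idx,
                train_idx=profiles_b[j].owner_idx,
                quality=quality,
            )
        )
    return out
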