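"""Transform estimation and progressive sample consensus.

`estimate_transform` is the closed-form least-squares (Procrustes) fit of a
rigid or similarity transform mapping src points onto dst points.

`prosac_filter` removes mismatches by progressive sampling: matches are
sorted by quality, minimal sets are drawn preferentially from the top-ranked
prefix (3 uniform draws from the prefix plus the prefix's last member), the
transform is fitted on each sample and scored by its inlier count under the
squared-residual bound ``tau_in``.  Sampling stops when the inlier fraction
exceeds ``tau_ratio``, when the best inlier count grows more slowly than
``tau_grow`` inliers/iteration over a patience window, or at ``max_iter``.
`ransac_baseline` is the classic uniform-sampling variant used for A/B
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientMatchesError
from .types import MatchCandidate, SimilarityTransform, _wrap_angle

DEFAULT_TAU_IN = 9.0  # px^2 (3-px residual)
DEFAULT_TAU_RATIO = 0.5
DEFAULT_TAU_GROW = 0.1  # new inliers per iteration (1 per 10-iteration window)
DEFAULT_PATIENCE = 10
DEFAULT_MAX_ITER = 500
DEFAULT_ETA0 = 4  # initial sample size; over-determined minimal sets


@dataclass
class ConsensusResult:
    transform: SimilarityTransform | None
    inlier_flags: np.ndarray  # bool per match
    n_iterations: int
    termination_reason: str  # "ratio" | "growth" | "max_iter" | "degenerate"

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_flags.sum())


def estimate_transform(src, dst, allow_scale: bool = False) -> SimilarityTransform:
    """Least-squares rigid (or similarity) transform src -> dst.

    Closed form via the centered cross-covariance (Procrustes/Umeyama): the
    rotation comes from the SVD of the covariance with the determinant sign
    corrected so only proper rotations are returned; a reflection-only
    correspondence therefore yields the best proper rotation with a large
    residual rather than a flip.
    """
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise DegenerateGeometryError("src/dst must be matching (n, 2) arrays")
    n = src.shape[0]
    if n < 2:
        raise DegenerateGeometryError(f"need >= 2 point pairs, got {n}")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cs, cd = src - mu_s, dst - mu_d
    var_s = float((cs**2).sum()) / n
    if var_s == 0.0:
        raise DegenerateGeometryError("source points are coincident")
    cov = cd.T @ cs / n
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    alpha = math.atan2(R[1, 0], R[0, 0])
    s = float((S @ np.diag([1.0, d]).diagonal()) / var_s) if allow_scale else 1.0
    if s <= 0:
        raise DegenerateGeometryError("estimated scale is non-positive")
    t = mu_d - s * (R @ mu_s)
    return SimilarityTransform(alpha=_wrap_angle(alpha), du=float(t[0]), dv=float(t[1]), s=s)


def _residuals_sq(tf: SimilarityTransform, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return ((tf.apply(src) - dst) ** 2).sum(axis=1)


def prosac_filter(
    matches: list[MatchCandidate],
    src_pts,
    dst_pts,
    tau_in: float = DEFAULT_TAU_IN,
    tau_ratio: float = DEFAULT_TAU_RATIO,
    tau_grow: float = DEFAULT_TAU_GROW,
    max_iter: int = DEFAULT_MAX_ITER,
    eta0: int = DEFAULT_ETA0,
    patience: int = DEFAULT_PATIENCE,
    allow_scale: bool = True,
    seed: int | np.random.Generator = 0,
) -> ConsensusResult:
    """Progressive-sample-consensus mismatch removal.

    ``src_pts[k]``/``dst_pts[k]`` are the coordinates of ``matches[k]``.  The
    quality ordering uses ``MatchCandidate.quality`` descending (geometric
    distinctiveness when present, negative Hamming distance otherwise), ties
    broken by list position.  The returned flags and transform are
    reproducible for a fixed seed.
    """
    src = np.atleast_2d(np.asarray(src_pts, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst_pts, dtype=np.float64))
    n = len(matches)
    if n < eta0:
        raise InsufficientMatchesError(f"need >= {eta0} matches, got {n}")
    if src.shape[0] != n or dst.shape[0] != n:
        raise DegenerateGeometryError("points must align 1:1 with matches")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ranked = sorted(range(n), key=lambda k: (-matches[k].quality, k))
    best_count = 0
    best_flags = np.zeros(n, dtype=bool)
    history: list[int] = []
    reason = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        eta = min(eta0 + (it - 1), n)
        prefix = ranked[: eta - 1]
        draw = rng.choice(len(prefix), size=min(3, len(prefix)), replace=False)
        sample = [prefix[k] for k in draw] + [ranked[eta - 1]]
        try:
            tf = estimate_transform(src[sample], dst[sample], allow_scale=allow_scale)
        except DegenerateGeometryError:
            history.append(best_count)
            continue
        flags = _residuals_sq(tf, src, dst) <= tau_in
        count = int(flags.sum())
        if count > best_count:
            best_count, best_flags = count, flags
        history.append(best_count)
        if best_count / n > tau_ratio:
            reason = "ratio"
            break
        if (
            len(history) > patience
            and best_count >= eta0
            and history[-1] - history[-1 - patience] < tau_grow * patience
        ):
            reason = "growth"
            break

    return _refit(matches, src, dst, best_flags, tau_in, allow_scale, it, reason)


def _refit(matches, src, dst, flags, tau_in, allow_scale, n_iter, reason) -> ConsensusResult:
    """Re-fit on the consensus set and re-flag under the final transform."""
    if flags.sum() < 2:
        return ConsensusResult(None, np.zeros(len(matches), dtype=bool), n_iter, "degenerate")
    tf = None
    for _ in range(3):  # fit/flag fixed point, usually reached in 1-2 rounds
        try:
            tf = estimate_transform(src[flags], dst[flags], allow_scale=allow_scale)
        except DegenerateGeometryError:
            return ConsensusResult(None, np.zeros(len(matches), dtype=bool), n_iter, "degenerate")
        new_flags = _residuals_sq(tf, src, dst) <= tau_in
        if new_flags.sum() < 2 or np.array_equal(new_flags, flags):
            break
        flags = new_flags
    final_flags = _residuals_sq(tf, src, dst) <= tau_in
    return ConsensusResult(tf, final_flags, n_iter, reason)


def ransac_baseline(
    matches: list[MatchCandidate],
    src_pts,
    dst_pts,
    tau_in: float = DEFAULT_TAU_IN,
    tau_ratio: float = DEFAULT_TAU_RATIO,
    max_iter: int = DEFAULT_MAX_ITER,
    sample_size: int = DEFAULT_ETA0,
    allow_scale: bool = True,
    seed: int | np.random.Generator = 0,
) -> ConsensusResult:
    """Classic uniform-sampling RANSAC with the same model and inlier rule."""
    src = np.atleast_2d(np.asarray(src_pts, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst_pts, dtype=np.float64))
    n = len(matches)
    if n < sample_size:
        raise InsufficientMatchesError(f"need >= {sample_size} matches, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_count = 0
    best_flags = np.zeros(n, dtype=bool)
    reason = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        sample = rng.choice(n, size=sample_size, replace=False)
        try:
            tf = estimate_transform(src[sample], dst[sample], allow_scale=allow_scale)
        except DegenerateGeometryError:
            continue
        flags = _residuals_sq(tf, src, dst) <= tau_in
        count = int(flags.sum())
        if count > best_count:
            best_count, best_flags = count, flags
        if best_count / n > tau_ratio:
            reason = "ratio"
            break
    return _refit(matches, src, dst, best_flags, tau_in, allow_scale, it, reason)
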