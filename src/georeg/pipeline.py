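"""End-to-end registration pipeline and Table-style match metrics.

Stage order: detect -> describe (per pyramid level, both images) ->
brute-force mutual-nearest Hamming matching -> scale-ratio filter ->
mean-centered distance window -> bidirectional KNN ratio test -> geometric
distance-profile matching -> progressive sample consensus.  Every stage's
survivors are retained on the result for diagnostics, and (with the default
``intersect_geom``) each stage's match list is a subset of the previous one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from . import detect, geom_match, rough_select, scale_filter
from .config import RegistrationConfig
from .describe import describe_all, generate_pattern
from .robust_estimate import ConsensusResult, prosac_filter, ransac_baseline
from .types import KeyPoint, MatchCandidate, SimilarityTransform

log = logging.getLogger(__name__)

STAGES = ("initial", "scale", "window", "bidirectional", "geometric", "prosac")


@dataclass
class MatchMetrics:
    """Screening metrics: counts before/after, mismatches, and the rate."""

    n_initial: int
    n_screened: int
    n_mismatch: int

    def __post_init__(self):
        if not 0 <= self.n_mismatch <= self.n_screened <= max(self.n_initial, self.n_screened):
            raise ValueError("need 0 <= n_mismatch <= n_screened")

    @property
    def rate(self) -> float:
        """Matching rate in percent: 100*(screened - mismatches)/screened,
        rounded half-up to 2 decimals; 0 when nothing survived screening."""
        return matching_rate(self.n_screened, self.n_mismatch)


def matching_rate(n_screened: int, n_mismatch: int) -> float:
    if n_screened == 0:
        return 0.0
    raw = Decimal(100) * (Decimal(n_screened) - Decimal(n_mismatch)) / Decimal(n_screened)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RegistrationResult:
    keypoints_a: list[KeyPoint]
    keypoints_b: list[KeyPoint]
    stages: dict[str, list[MatchCandidate]] = field(default_factory=dict)
    transform: SimilarityTransform | None = None
    consensus: ConsensusResult | None = None
    scale_histogram: scale_filter.ScaleHistogram | None = None
    distance_window: rough_select.DistanceWindow | None = None
    termination_stage: str | None = None  # stage that emptied the match set

    def stage_points(self, stage: str):
        """(src, dst) level-0 coordinate arrays for a stage's matches."""
        ms = self.stages.get(stage, [])
        src = np.array([self.keypoints_a[m.query_idx].xy0 for m in ms]).reshape(-1, 2)
        dst = np.array([self.keypoints_b[m.train_idx].xy0 for m in ms]).reshape(-1, 2)
        return src, dst

    def to_dict(self) -> dict:
        return {
            "stages": {
                name: [
                    {
                        "query_idx": m.query_idx, "train_idx": m.train_idx,
                        "hamming": m.hamming, "scale_ratio": m.scale_ratio,
                        "quality": m.quality, "stage": name,
                    }
                    for m in ms
                ]
                for name, ms in self.stages.items()
            },
            "transform": self.transform.to_dict() if self.transform else None,
            "termination_stage": self.termination_stage,
            "n_keypoints": [len(self.keypoints_a), len(self.keypoints_b)],
        }


def detect_and_describe(image, cfg: RegistrationConfig):
    """Multi-level detection + description; returns (keypoints, descriptors).

    Keypoints keep level-local coordinates plus their level scale; the
    per-level budget is proportional to level area.
    """
    pattern = generate_pattern(cfg.pattern_seed)
    levels = scale_filter.build_pyramid(image, cfg.pyramid_levels, cfg.pyramid_factor)
    weights = np.array([1.0 / lv.scale**2 for lv in levels])
    budgets = np.maximum(1, np.round(cfg.n_features * weights / weights.sum())).astype(int)

    all_kps: list[KeyPoint] = []
    all_desc = []
    for lv, budget in zip(levels, budgets):
        cands, score = detect.fast9_detect(lv.image, cfg.xi_fast, return_scores=True)
        cands = detect.suppress_nonmax(cands, score)
        for kp in cands:
            kp.level, kp.scale = lv.level, lv.scale
        kps = detect.harris_select(lv.image, cands, n_keep=int(budget))
        kps = detect.orient_keypoints(lv.image, kps)
        descs, kps = describe_all(
            lv.image, kps, pattern=pattern, subwindow=cfg.subwindow
        )
        all_kps.extend(kps)
        all_desc.append(descs)
        log.info("level %d (scale %.2f): %d keypoints", lv.level, lv.scale, len(kps))
    descs = (
        np.concatenate(all_desc, axis=0) if all_desc else np.zeros((0, 32), dtype=np.uint8)
    )
    return all_kps, descs


def _initial_matches(kps_a, desc_a, kps_b, desc_b) -> list[MatchCandidate]:
    """Brute-force mutual-nearest Hamming pairs (no ratio test)."""
    if len(kps_a) == 0 or len(kps_b) == 0:
        return []
    D = rough_select.hamming_matrix(desc_a, desc_b)
    nn_a = D.argmin(axis=1)
    nn_b = D.argmin(axis=0)
    out = []
    for i, j in enumerate(nn_a):
        if nn_b[j] == i:
            out.append(
                MatchCandidate(
                    query_idx=i, train_idx=int(j), hamming=int(D[i, j]),
                    scale_ratio=kps_a[i].scale / kps_b[j].scale,
                    quality=-float(D[i, j]),
                )
            )
    return out


def register(image_a, image_b, config: RegistrationConfig | None = None) -> RegistrationResult:
    """Run the full pipeline; deterministic for a fixed config.

    A stage that empties the match set terminates the pipeline early and is
    recorded on ``termination_stage`` (partial result, not an exception).
    """
    cfg = config or RegistrationConfig()
    kps_a, desc_a = detect_and_describe(image_a, cfg)
    kps_b, desc_b = detect_and_describe(image_b, cfg)
    result = RegistrationResult(keypoints_a=kps_a, keypoints_b=kps_b)

    matches = _initial_matches(kps_a, desc_a, kps_b, desc_b)
    result.stages["initial"] = matches
    if not matches:
        result.termination_stage = "initial"
        return result

    matches, hist = scale_filter.filter_matches_by_scale(
        matches, omega=cfg.omega, use_gmm=cfg.use_gmm
    )
    result.stages["scale"] = matches
    result.scale_histogram = hist
    if not matches:
        result.termination_stage = "scale"
        return result

    matches, window = rough_select.distance_window_filter(matches)
    result.stages["window"] = matches
    result.distance_window = window
    if not matches and cfg.intersect_geom:
        result.termination_stage = "window"
        return result

    if matches:
        matches = _bidirectional_stage(matches, desc_a, desc_b, cfg.t)
    result.stages["bidirectional"] = matches
    if not matches and cfg.intersect_geom:
        result.termination_stage = "bidirectional"
        return result

    if cfg.intersect_geom:
        geo = _geometric_stage(matches, kps_a, kps_b, cfg)
    else:
        # replace mode (low-texture scenes): the geometric matcher is the
        # primary matcher, pairing over the full described keypoint sets
        geo = _geometric_repair(kps_a, kps_b, cfg)
    result.stages["geometric"] = geo
    if len(geo) < cfg.eta0:
        result.termination_stage = "geometric"
        return result

    src = np.array([kps_a[m.query_idx].xy0 for m in geo])
    dst = np.array([kps_b[m.train_idx].xy0 for m in geo])
    consensus = prosac_filter(
        geo, src, dst,
        tau_in=cfg.tau_in, tau_ratio=cfg.tau_ratio, tau_grow=cfg.tau_grow,
        max_iter=cfg.max_iter, eta0=cfg.eta0, patience=cfg.patience,
        allow_scale=cfg.allow_scale, seed=cfg.seed,
    )
    result.consensus = consensus
    result.transform = consensus.transform
    result.stages["prosac"] = [m for m, f in zip(geo, consensus.inlier_flags) if f]
    if not result.stages["prosac"]:
        result.termination_stage = "prosac"

    _assert_stage_subsets(result, cfg)
    for name in STAGES:
        if name in result.stages:
            log.info("stage %-13s %4d matches", name, len(result.stages[name]))
    return result


def _bidirectional_stage(matches, desc_a, desc_b, t) -> list[MatchCandidate]:
    """Bidirectional ratio test over the keypoints still in play.

    Candidate sets are restricted to keypoints appearing in the incoming
    matches; surviving pairs are intersected with the incoming list so the
    stage-subset invariant holds.
    """
    ia = sorted({m.query_idx for m in matches})
    ib = sorted({m.train_idx for m in matches})
    bid = rough_select.bidirectional_ratio_match(desc_a[ia], desc_b[ib], t=t)
    pairs = {(ia[m.query_idx], ib[m.train_idx]) for m in bid}
    return [m for m in matches if (m.query_idx, m.train_idx) in pairs]


def _geometric_stage(basis, kps_a, kps_b, cfg: RegistrationConfig) -> list[MatchCandidate]:
    """Distance-profile matching over the keypoints of the basis matches.

    The same physical feature is often detected on several pyramid levels,
    yielding near-coincident level-0 points whose profiles are mutually
    indistinguishable (and would all fail the distinctiveness test), so each
    side is first clustered spatially and matching runs on the cluster
    representatives (highest Harris response).  A basis match survives iff its
    representative pair was matched geometrically, which keeps the output a
    subset of the basis.
    """
    rep_pairs, assign_a, assign_b = _rep_pair_match(
        {m.query_idx for m in basis}, {m.train_idx for m in basis}, kps_a, kps_b, cfg
    )
    out = []
    seen = set()
    for m in basis:
        key = (assign_a.get(m.query_idx), assign_b.get(m.train_idx))
        if key in rep_pairs and key not in seen:
            seen.add(key)
            out.append(
                MatchCandidate(
                    query_idx=m.query_idx, train_idx=m.train_idx,
                    hamming=m.hamming, scale_ratio=m.scale_ratio,
                    quality=rep_pairs[key],
                )
            )
    return out


def _geometric_repair(kps_a, kps_b, cfg: RegistrationConfig) -> list[MatchCandidate]:
    """Replace-mode geometric stage: pair the full described keypoint sets."""
    rep_pairs, _, _ = _rep_pair_match(
        range(len(kps_a)), range(len(kps_b)), kps_a, kps_b, cfg
    )
    return [
        MatchCandidate(query_idx=i, train_idx=j, quality=q)
        for (i, j), q in sorted(rep_pairs.items())
    ]


def _rep_pair_match(idx_a, idx_b, kps_a, kps_b, cfg: RegistrationConfig):
    """Cluster each side spatially and match the representative profiles."""
    reps_a, assign_a = _cluster_keypoints(
        idx_a, kps_a, cfg.geom_dedup_radius, cfg.geom_max_points
    )
    reps_b, assign_b = _cluster_keypoints(
        idx_b, kps_b, cfg.geom_dedup_radius, cfg.geom_max_points
    )
    if len(reps_a) < 2 or len(reps_b) < 2:
        return {}, assign_a, assign_b
    prof_a = geom_match.distance_profiles(
        np.array([kps_a[i].xy0 for i in reps_a]), normalize=cfg.normalize_profiles
    )
    prof_b = geom_match.distance_profiles(
        np.array([kps_b[j].xy0 for j in reps_b]), normalize=cfg.normalize_profiles
    )
    geo = geom_match.geometric_match(prof_a, prof_b, T=cfg.T, K=cfg.K, sigma=cfg.sigma)
    rep_pairs = {(reps_a[g.query_idx], reps_b[g.train_idx]): g.quality for g in geo}
    return rep_pairs, assign_a, assign_b


def _cluster_keypoints(indices, kps, radius: float, max_points: int):
    """Greedy spatial clustering at level-0 scale; strongest response first.

    Returns (representative indices, index -> representative mapping).
    """
    order = sorted(indices, key=lambda i: (-kps[i].response, i))
    reps: list[int] = []
    assign: dict[int, int] = {}
    r2 = radius * radius
    for i in order:
        x, y = kps[i].xy0
        for r in reps:
            rx, ry = kps[r].xy0
            if (x - rx) ** 2 + (y - ry) ** 2 <= r2:
                assign[i] = r
                break
        else:
            if len(reps) < max_points:
                reps.append(i)
                assign[i] = i
    return reps, assign


def _assert_stage_subsets(result: RegistrationResult, cfg: RegistrationConfig) -> None:
    """Pipeline invariant: stage match lists are nested subsets.

    With ``intersect_geom`` off the geometric matcher re-pairs the detected
    keypoint sets (replace mode), so nesting is checked within the two chains
    it breaks into: initial -> scale -> window -> bidirectional, and
    geometric -> prosac.
    """
    order = [s for s in STAGES if s in result.stages]
    for prev, cur in zip(order, order[1:]):
        if not cfg.intersect_geom and cur == "geometric":
            continue
        prev_pairs = {(m.query_idx, m.train_idx) for m in result.stages[prev]}
        assert all(
            (m.query_idx, m.train_idx) in prev_pairs for m in result.stages[cur]
        ), f"stage {cur} is not a subset of {prev}"


def evaluate_matches(
    src_pts, dst_pts, truth: SimilarityTransform, tol_px: float = 3.0,
    n_initial: int | None = None,
) -> MatchMetrics:
    """Score screened matches against a ground-truth transform.

    A match (p, p') counts as correct iff ||truth(p) - p'|| <= tol_px.
    """
    src = np.asarray(src_pts, dtype=np.float64).reshape(-1, 2)
    dst = np.asarray(dst_pts, dtype=np.float64).reshape(-1, 2)
    n_screened = len(src)
    if n_screened:
        err = np.linalg.norm(truth.apply(src) - dst, axis=1)
        n_mismatch = int((err > tol_px).sum())
    else:
        n_mismatch = 0
    return MatchMetrics(
        n_initial=n_initial if n_initial is not None else n_screened,
        n_screened=n_screened,
        n_mismatch=n_mismatch,
    )


def evaluate_result(
    result: RegistrationResult, truth: SimilarityTransform, tol_px: float = 3.0,
    stage: str = "prosac",
) -> MatchMetrics:
    """Table-style metrics for one pipeline run against fixture ground truth."""
    src, dst = result.stage_points(stage)
    return evaluate_matches(
        src, dst, truth, tol_px=tol_px,
        n_initial=len(result.stages.get("initial", [])),
    )


__all__ = [
    "MatchMetrics", "RegistrationResult", "matching_rate", "register",
    "detect_and_describe", "evaluate_matches", "evaluate_result",
    "ransac_baseline", "STAGES",
]
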