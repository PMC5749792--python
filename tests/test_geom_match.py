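"""Distance profiles, Gaussian coincidence cost, distinctiveness matching."""

import math

import numpy as np
import pytest

from georeg import (
    distance_profiles,
    geometric_cost,
    geometric_match,
    synth_correspondences,
)
from georeg.geom_match import DistanceProfile, cost_matrix
from georeg.errors import (
    DegenerateGeometryError,
    InsufficientPointsError,
    ParameterError,
)
from georeg.types import SimilarityTransform


class TestDistanceProfiles:
    def test_pythagorean_triangle(self):
        profs = distance_profiles([(0, 0), (3, 0), (0, 4)], normalize=False)
        got = [tuple(p.dists) for p in profs]
        assert got == [(3.0, 4.0), (3.0, 5.0), (4.0, 5.0)]

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        tf = SimilarityTransform(alpha=0.7, du=31.0, dv=-8.0)
        moved = tf.apply(pts)
        for a, b in zip(
            distance_profiles(pts, normalize=False),
            distance_profiles(moved, normalize=False),
        ):
            assert np.allclose(a.dists, b.dists)

    def test_uniform_scaling_cancels_with_normalization(self, rng):
        pts = rng.uniform(0, 100, (8, 2))
        for a, b in zip(distance_profiles(pts), distance_profiles(pts * 3.7)):
            assert np.allclose(a.dists, b.dists)
            assert b.norm_factor == pytest.approx(3.7 * a.norm_factor)

    def test_normalized_profiles_have_unit_mean(self, rng):
        for p in distance_profiles(rng.uniform(0, 50, (6, 2))):
            assert p.dists.mean() == pytest.approx(1.0)
            assert np.all(np.diff(p.dists) >= 0)  # ascending

    def test_degenerate_inputs(self):
        with pytest.raises(InsufficientPointsError):
            distance_profiles([(0, 0)])
        with pytest.raises(DegenerateGeometryError):
            distance_profiles([(0, 0), (1, 1), (0, 0)])


class TestGeometricCost:
    def test_four_term_example(self):
        p1 = DistanceProfile(0, np.array([1.0, 2.0]))
        p2 = DistanceProfile(0, np.array([1.0, 3.0]))
        got = geometric_cost(p1, p2, sigma=1.0).value
        expect = math.exp(0) + math.exp(-4) + math.exp(-1) + math.exp(-1)
        assert got == pytest.approx(expect, abs=1e-4)
        assert got == pytest.approx(1.7540, abs=1e-4)

    def test_sigma_default_is_one(self):
        p1 = DistanceProfile(0, np.array([1.0, 2.0]))
        p2 = DistanceProfile(0, np.array([1.0, 3.0]))
        assert geometric_cost(p1, p2).value == geometric_cost(p1, p2, sigma=1.0).value

    def test_identical_profiles_lower_bound(self, rng):
        d = np.sort(rng.uniform(0, 200, 9))
        p = DistanceProfile(0, d)
        assert geometric_cost(p, p).value >= len(d)

    def test_symmetry(self, rng):
        p1 = DistanceProfile(0, np.sort(rng.uniform(0, 100, 7)))
        p2 = DistanceProfile(1, np.sort(rng.uniform(0, 100, 5)))
        assert geometric_cost(p1, p2).value == pytest.approx(
            geometric_cost(p2, p1).value
        )

    def test_as_printed_mode_flips_exponent(self):
        p1 = DistanceProfile(0, np.array([1.0, 2.0]))
        p2 = DistanceProfile(0, np.array([1.0, 3.0]))
        got = geometric_cost(p1, p2, mode="as-printed").value
        expect = math.exp(0) + math.exp(4) + math.exp(1) + math.exp(1)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_parameter_errors(self):
        p = DistanceProfile(0, np.array([1.0]))
        with pytest.raises(ParameterError):
            geometric_cost(p, p, sigma=0.0)
        with pytest.raises(ParameterError):
            geometric_cost(p, p, mode="bogus")

    def test_moving_an_entry_away_decreases_cost(self):
        base = DistanceProfile(0, np.array([10.0, 50.0, 90.0]))
        prev = None
        for shift in (0.0, 0.5, 1.0, 2.0):
            other = DistanceProfile(1, np.array([10.0 + shift, 50.0, 90.0]))
            val = geometric_cost(base, other).value
            if prev is not None:
                assert val < prev
            prev = val

    def test_windowed_matrix_equals_dense_oracle(self, rng):
        profs_a = [
            DistanceProfile(i, np.sort(rng.uniform(0, 300, 12))) for i in range(4)
        ]
        profs_b = [
            DistanceProfile(j, np.sort(rng.uniform(0, 300, 9))) for j in range(5)
        ]
        F = cost_matrix(profs_a, profs_b, sigma=2.0)
        for i, pa in enumerate(profs_a):
            for j, pb in enumerate(profs_b):
                dense = np.exp(
                    -((pa.dists[:, None] - pb.dists[None, :]) / 2.0) ** 2
                ).sum()
                assert F[i, j] == pytest.approx(dense, rel=1e-12)


def brute_force_matcher(profs_a, profs_b, T=0.8, K=2, sigma=1.0):
    """Independent matcher: pairwise geometric_cost + explicit rule application."""
    F = np.array(
        [[geometric_cost(pa, pb, sigma=sigma).value for pb in profs_b] for pa in profs_a]
    )
    claims = {}
    for i in range(len(profs_a)):
        order = np.argsort(-F[i], kind="stable")
        j = int(order[0])
        if F[i, j] <= 0:
            continue
        if any(F[i, int(order[m])] / F[i, j] >= T for m in range(1, min(K, len(order)))):
            continue
        if j not in claims or F[i, j] > F[claims[j], j]:
            claims[j] = i
    return {(profs_a[i].owner_idx, profs_b[j].owner_idx) for j, i in claims.items()}


class TestGeometricMatch:
    @pytest.mark.parametrize("seed", range(20))
    def test_clean_constellations_recover_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        tf = SimilarityTransform(
            alpha=rng.uniform(-math.pi, math.pi),
            du=rng.uniform(-50, 50), dv=rng.uniform(-50, 50),
        )
        src, dst, _ = synth_correspondences(seed=seed, n=n, transform=tf)
        perm = rng.permutation(n)
        profs_a = distance_profiles(src, normalize=False)
        profs_b = distance_profiles(dst[perm], normalize=False)
        got = {(m.query_idx, m.train_idx) for m in geometric_match(profs_a, profs_b)}
        expect_perm = {(int(perm[k]), int(k)) for k in range(n)}
        assert got == expect_perm
        assert got == brute_force_matcher(profs_a, profs_b)

    def test_ambiguous_mirror_constellation_rejected(self):
        rng = np.random.default_rng(4)
        C = rng.uniform(0, 80, (6, 2))
        mirror = C.copy()
        mirror[:, 0] = 1000.0 - mirror[:, 0]  # reflection about x = 500
        b_pts = np.vstack([C, mirror])
        profs_a = distance_profiles(C, normalize=False)
        profs_b = distance_profiles(b_pts, normalize=False)
        # every a-profile scores identically against a point and its mirror
        assert geometric_match(profs_a, profs_b) == []

    def test_one_to_one_output(self, rng):
        src, dst, _ = synth_correspondences(seed=3, n=10, noise_sigma=2.0)
        profs_a = distance_profiles(src, normalize=False)
        profs_b = distance_profiles(dst, normalize=False)
        ms = geometric_match(profs_a, profs_b)
        assert len({m.query_idx for m in ms}) == len(ms)
        assert len({m.train_idx for m in ms}) == len(ms)

    def test_defaults_match_explicit_parameters(self):
        src, dst, _ = synth_correspondences(seed=5, n=8)
        profs_a = distance_profiles(src, normalize=False)
        profs_b = distance_profiles(dst, normalize=False)
        implicit = geometric_match(profs_a, profs_b)
        explicit = geometric_match(profs_a, profs_b, T=0.8, K=2, sigma=1.0)
        assert [(m.query_idx, m.train_idx) for m in implicit] == [
            (m.query_idx, m.train_idx) for m in explicit
        ]

    def test_parameter_validation(self):
        src, dst, _ = synth_correspondences(seed=1, n=5)
        pa = distance_profiles(src, normalize=False)
        pb = distance_profiles(dst, normalize=False)
        with pytest.raises(ParameterError):
            geometric_match(pa, pb, T=0.0)
        with pytest.raises(ParameterError):
            geometric_match(pa, pb, K=1)
        with pytest.raises(InsufficientPointsError):
            geometric_match([], pb)

    def test_normalized_profiles_match_under_scaling(self):
        # scale change: raw profiles fail to coincide, normalized ones (with
        # the sigma mapped through the norm factors) still match exactly
        rng = np.random.default_rng(11)
        src = rng.uniform(0, 200, (9, 2))
        tf = SimilarityTransform(alpha=0.5, du=10, dv=5, s=1.8)
        dst = tf.apply(src)
        profs_a = distance_profiles(src, normalize=True)
        profs_b = distance_profiles(dst, normalize=True)
        got = {(m.query_idx, m.train_idx) for m in geometric_match(profs_a, profs_b)}
        assert got == {(k, k) for k in range(9)}
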