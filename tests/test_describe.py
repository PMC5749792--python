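"""Descriptor: pattern generation/learning, steering, sub-window comparisons."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from georeg import (
    describe,
    generate_pattern,
    hamming_distance,
    learn_pattern_greedy,
    steer_pattern,
)
from georeg.describe import (
    SamplingPattern,
    box_sums,
    integral_image,
)
from georeg.detect import compute_orientation
from georeg.errors import BorderError, ParameterError
from georeg.types import KeyPoint


class TestGeneratePattern:
    def test_deterministic(self):
        a = generate_pattern(seed=7)
        b = generate_pattern(seed=7)
        assert np.array_equal(a.pairs, b.pairs)

    def test_seeds_differ(self):
        assert not np.array_equal(generate_pattern(0).pairs, generate_pattern(1).pairs)

    @pytest.mark.parametrize("seed", range(0, 200, 7))
    def test_coordinates_within_bounds(self, seed):
        p = generate_pattern(seed=seed, patch_half=15)
        assert np.all(np.abs(p.pairs) <= 13)
        # all-angle steering safety: points stay on the disc of radius 13
        assert np.all(np.linalg.norm(p.pairs, axis=-1) <= 13 + 1e-9)

    def test_patch_half_minimum(self):
        with pytest.raises(ParameterError):
            generate_pattern(seed=0, patch_half=7)


class TestSteerPattern:
    def test_zero_angle_is_identity(self, pattern):
        assert np.array_equal(steer_pattern(pattern, 0.0).pairs, pattern.pairs)

    def test_quarter_turn_exact(self, pattern):
        # rotation by +pi/2 in the image frame (y down): (x, y) -> (-y, x)
        steered = steer_pattern(pattern, math.pi / 2)
        expect = np.stack([-pattern.pairs[..., 1], pattern.pairs[..., 0]], axis=-1)
        assert np.array_equal(steered.pairs, expect)

    def test_arbitrary_angle_equals_matrix_product(self):
        p = generate_pattern(seed=7)
        alpha = 0.3
        c, s = math.cos(alpha), math.sin(alpha)
        R = np.array([[c, -s], [s, c]])
        expect = np.rint(np.einsum("ij,pqj->pqi", R, p.pairs))
        assert np.array_equal(steer_pattern(p, alpha).pairs, expect)


class TestBoxSums:
    def test_equals_naive_double_loop(self, rng):
        img = rng.uniform(0, 255, (40, 40))
        ii = integral_image(img)
        xs = rng.integers(3, 37, size=20)
        ys = rng.integers(3, 37, size=20)
        got = box_sums(ii, xs, ys, half=2)
        for k, (x, y) in enumerate(zip(xs, ys)):
            naive = sum(
                img[y + dy, x + dx] for dy in range(-2, 3) for dx in range(-2, 3)
            )
            assert got[k] == pytest.approx(naive, rel=1e-12)


class TestDescribe:
    def test_constant_image_all_zero_bits(self, pattern):
        img = np.full((64, 64), 50.0)
        d = describe(img, KeyPoint(x=32, y=32), pattern)
        assert d.bits.sum() == 0

    def test_intensity_inversion_complements_bits(self, pattern, rng):
        img = ndi.gaussian_filter(rng.uniform(0, 255, (64, 64)), 1.0)
        kp = KeyPoint(x=32, y=32, orientation=0.4)
        d = describe(img, kp, pattern)
        d_inv = describe(255.0 - img, kp, pattern)
        # verify the no-ties precondition of the complement identity
        from georeg.describe import _steered

        sp = _steered(pattern, kp.orientation, exact=False)
        ii = integral_image(img)
        pts = sp.pairs.astype(int)
        sums = box_sums(ii, 32 + pts[..., 0], 32 + pts[..., 1], 2)
        assert np.all(sums[:, 0] != sums[:, 1])
        assert np.array_equal(d.bits, 1 - d_inv.bits)

    def test_one_pair_changes_at_most_one_bit(self, pattern, rng):
        img = rng.uniform(0, 255, (64, 64))
        kp = KeyPoint(x=32, y=32)
        base = describe(img, kp, pattern).bits
        pairs = pattern.pairs.copy()
        pairs[100] = [[1, 2], [-3, 4]]
        mutated = describe(img, kp, SamplingPattern(pairs)).bits
        assert int(np.sum(base != mutated)) <= 1

    def test_rotation_covariance_small_hamming(self, pattern):
        rng = np.random.default_rng(3)
        img = ndi.gaussian_filter(rng.uniform(0, 255, (96, 96)), 1.5) * 1.4
        img = np.clip(img, 0, 255)
        kp = KeyPoint(x=48, y=48)
        compute_orientation(img, kp)
        d0 = describe(img, kp, pattern)
        phi = math.radians(30)
        rot = ndi.rotate(img, math.degrees(phi), reshape=False, order=1, mode="nearest")
        kp_r = KeyPoint(x=48, y=48)
        compute_orientation(rot, kp_r)
        d1 = describe(rot, kp_r, pattern)
        assert hamming_distance(d0, d1) <= 40

    def test_border_error_when_patch_leaves_image(self, pattern):
        with pytest.raises(BorderError):
            describe(np.zeros((64, 64)), KeyPoint(x=5, y=32), pattern)


def greedy_oracle(bits: np.ndarray, threshold: float, n_select: int) -> list[int]:
    """Straightforward greedy re-implementation on a bit matrix (rows=tests)."""
    means = np.abs(bits.mean(axis=1) - 0.5)
    order = sorted(range(len(bits)), key=lambda i: (means[i], i))
    chosen: list[int] = []
    thr = threshold
    while len(chosen) < n_select and thr <= 1.0 + 1e-9:
        for i in order:
            if i in chosen or len(chosen) == n_select:
                continue
            ok = True
            for j in chosen:
                a, b = bits[i], bits[j]
                if a.std() == 0 or b.std() == 0:
                    corr = 1.0 if np.array_equal(a, b) else 0.0
                else:
                    corr = abs(np.corrcoef(a, b)[0, 1])
                if corr >= thr:
                    ok = False
                    break
            if ok:
                chosen.append(i)
        thr += 0.05
    return chosen


class TestLearnPatternGreedy:
    def _patches(self, rng, n=100):
        return [ndi.gaussian_filter(rng.uniform(0, 255, (31, 31)), 1.0) for _ in range(n)]

    def test_small_candidate_set_matches_oracle(self, rng):
        patches = self._patches(rng)
        cands = rng.integers(-10, 11, size=(5, 2, 2)).astype(float)
        got = learn_pattern_greedy(
            cands, patches, corr_threshold=0.3, n_select=3
        )
        # independent greedy run on the same bit matrix
        bits = _bit_matrix(cands, patches)
        expect = greedy_oracle(bits, 0.3, 3)
        assert np.array_equal(got.pairs, cands[expect])

    def test_duplicate_test_selected_at_most_once(self, rng):
        patches = self._patches(rng, 60)
        cands = rng.integers(-10, 11, size=(40, 2, 2)).astype(float)
        cands[1] = cands[0]  # exact duplicate: bit columns correlate 1.0
        got = learn_pattern_greedy(cands, patches, n_select=20)
        dup = [tuple(p.ravel()) for p in got.pairs].count(tuple(cands[0].ravel()))
        assert dup <= 1

    def test_requires_enough_candidates(self, rng):
        with pytest.raises(ParameterError):
            learn_pattern_greedy(
                rng.normal(size=(10, 2, 2)), self._patches(rng, 50), n_select=256
            )

    def test_full_selection_from_random_pool(self, rng):
        patches = self._patches(rng, 60)
        cands = np.rint(np.clip(rng.normal(0, 7, size=(300, 2, 2)), -13, 13))
        got = learn_pattern_greedy(cands, patches, n_select=256)
        assert got.pairs.shape == (256, 2, 2)
        assert len({tuple(p.ravel()) for p in got.pairs}) > 200  # mostly distinct


def _bit_matrix(cands, patches):
    bits = np.zeros((len(cands), len(patches)))
    for j, patch in enumerate(patches):
        ii = integral_image(patch)
        cy, cx = patch.shape[0] // 2, patch.shape[1] // 2
        pts = np.rint(cands).astype(int)
        xs = np.clip(cx + pts[..., 0], 2, patch.shape[1] - 3)
        ys = np.clip(cy + pts[..., 1], 2, patch.shape[0] - 3)
        s = box_sums(ii, xs, ys, 2)
        bits[:, j] = s[:, 0] < s[:, 1]
    return bits
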