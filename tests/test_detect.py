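"""Detector: segment test, Harris selection, intensity-centroid orientation."""

import math

import numpy as np
import pytest

from georeg import fast9_detect, harris_select, compute_orientation
from georeg.detect import harris_response_map, suppress_nonmax
from georeg.errors import BorderError, DimensionError, ParameterError
from georeg.fixtures import synth_texture_pair
from georeg.types import KeyPoint

from conftest import fast9_oracle


def white_square(size=64, lo=12, hi=32):
    img = np.zeros((size, size))
    img[lo:hi, lo:hi] = 255.0
    return img


class TestFast9:
    def test_constant_image_has_no_corners(self):
        assert fast9_detect(np.full((64, 64), 128.0), xi=40) == []

    def test_square_corners_match_brute_force(self):
        img = white_square()
        kps = fast9_detect(img, xi=40)
        got = {(kp.x, kp.y) for kp in kps}
        assert got == fast9_oracle(img, 40)
        corners = [(12, 12), (31, 12), (12, 31), (31, 31)]
        for x, y in got:
            assert min(math.dist((x, y), c) for c in corners) <= 3 * math.sqrt(2)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_textured_images(self, seed):
        img = synth_texture_pair(seed=seed, size=128).image_a.pixels
        got = {(kp.x, kp.y) for kp in fast9_detect(img, xi=30)}
        assert got == fast9_oracle(img, 30)

    def test_translation_equivariance(self):
        base = synth_texture_pair(seed=7, size=128).image_a.pixels
        dx, dy = 5, 3
        shifted = np.zeros_like(base)
        shifted[dy:, dx:] = base[:-dy, :-dx]
        det_base = {(kp.x, kp.y) for kp in fast9_detect(base, xi=40)}
        det_shift = {(kp.x, kp.y) for kp in fast9_detect(shifted, xi=40)}
        h, w = base.shape
        interior = {
            (x + dx, y + dy)
            for x, y in det_base
            if 3 <= x + dx < w - 3 and 3 <= y + dy < h - 3 and x >= 3 and y >= 3
        }
        # shifted detections must contain every translated interior detection
        assert interior <= det_shift

    def test_default_threshold_is_forty(self):
        img = synth_texture_pair(seed=3, size=128).image_a.pixels
        implicit = {(kp.x, kp.y) for kp in fast9_detect(img)}
        explicit = {(kp.x, kp.y) for kp in fast9_detect(img, xi=40.0)}
        assert implicit == explicit

    def test_rejects_bad_inputs(self):
        with pytest.raises(DimensionError):
            fast9_detect(np.zeros((16, 16)))
        with pytest.raises(ParameterError):
            fast9_detect(np.zeros((64, 64)), xi=0)
        with pytest.raises(ParameterError):
            fast9_detect(np.zeros((64, 64)), xi=255)

    def test_nonmax_suppression_keeps_local_peaks_only(self):
        img = white_square()
        kps, score = fast9_detect(img, xi=40, return_scores=True)
        kept = suppress_nonmax(kps, score)
        assert set(map(id, kept)) <= set(map(id, kps))
        for kp in kept:
            y, x = int(kp.y), int(kp.x)
            patch = score[y - 1 : y + 2, x - 1 : x + 2]
            assert score[y, x] >= patch.max()


class TestHarrisSelect:
    def test_single_candidate_returned_with_score(self):
        img = white_square()
        out = harris_select(img, [KeyPoint(x=12, y=12)], n_keep=10)
        assert len(out) == 1
        assert out[0].response != 0.0

    def test_corner_outranks_edge_midpoint(self):
        img = white_square(size=64, lo=10, hi=50)
        corner = KeyPoint(x=10, y=10)
        edge = KeyPoint(x=30, y=10)  # midpoint of the top edge
        out = harris_select(img, [edge, corner], n_keep=2)
        assert (out[0].x, out[0].y) == (10, 10)
        # independent check: structure-tensor eigenvalues at both sites
        for site, expect_two in [((10, 10), True), ((30, 10), False)]:
            lam = _structure_tensor_eigs(img, *site)
            if expect_two:
                assert lam.min() > 0.05 * lam.max()
            else:
                assert lam.min() < 0.05 * lam.max()

    def test_output_subset_sorted_truncated(self):
        img = synth_texture_pair(seed=1, size=128).image_a.pixels
        cands = fast9_detect(img, xi=30)
        out = harris_select(img, cands, n_keep=10)
        assert len(out) == 10
        resp = [kp.response for kp in out]
        assert resp == sorted(resp, reverse=True)
        in_pos = {(kp.x, kp.y) for kp in cands}
        assert {(kp.x, kp.y) for kp in out} <= in_pos

    def test_n_keep_zero_and_negative(self):
        img = white_square()
        assert harris_select(img, [KeyPoint(x=12, y=12)], n_keep=0) == []
        with pytest.raises(ParameterError):
            harris_select(img, [KeyPoint(x=12, y=12)], n_keep=-1)


def _structure_tensor_eigs(img, x, y, win=3):
    gx = np.gradient(img, axis=1)
    gy = np.gradient(img, axis=0)
    sl = np.s_[y - win : y + win + 1, x - win : x + win + 1]
    M = np.array(
        [
            [(gx[sl] ** 2).sum(), (gx[sl] * gy[sl]).sum()],
            [(gx[sl] * gy[sl]).sum(), (gy[sl] ** 2).sum()],
        ]
    )
    return np.linalg.eigvalsh(M)


class TestOrientation:
    def test_right_half_bright_points_along_x(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 255.0
        assert compute_orientation(img, KeyPoint(x=32, y=32), radius=15) == 0.0

    def test_point_symmetric_patch_defaults_to_zero(self):
        img = np.full((64, 64), 77.0)
        assert compute_orientation(img, KeyPoint(x=32, y=32), radius=15) == 0.0

    def test_quarter_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        from scipy import ndimage as ndi

        img = ndi.gaussian_filter(rng.uniform(0, 255, (65, 65)), 2.0)
        kp = KeyPoint(x=32, y=32)
        a0 = compute_orientation(img, kp, radius=15)
        # np.rot90 maps content offset (dx, dy) -> (dy, -dx): angle -pi/2
        rot = np.rot90(img)
        a1 = compute_orientation(rot, KeyPoint(x=32, y=32), radius=15)
        diff = (a1 - a0 + math.pi) % (2 * math.pi) - math.pi
        assert abs(abs(diff) - math.pi / 2) < 1e-9

    def test_continuous_rotation_equivariance(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(9)
        img = ndi.gaussian_filter(rng.uniform(0, 255, (81, 81)), 3.0)
        phi = math.radians(45)
        # ndi.rotate(angle=-deg) rotates content by +phi in the (x, y-down) frame
        rot = ndi.rotate(img, -math.degrees(phi), reshape=False, order=1, mode="nearest")
        a0 = compute_orientation(img, KeyPoint(x=40, y=40), radius=15)
        a1 = compute_orientation(rot, KeyPoint(x=40, y=40), radius=15)
        diff = (a1 - a0 - phi + math.pi) % (2 * math.pi) - math.pi
        assert abs(diff) < 0.05

    def test_border_error(self):
        with pytest.raises(BorderError):
            compute_orientation(np.zeros((64, 64)), KeyPoint(x=5, y=5), radius=15)
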