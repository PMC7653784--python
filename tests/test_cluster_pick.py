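"""Stage-1 segmentation and shape detection: clustering, components, contour
perimeter vs an independent boundary-walk oracle, Hough circles vs the
exhaustive accumulator, Feret calipers vs all-pairs projection."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from cryopick.cluster_pick import (clean_mask, contour_perimeter,
                                   detect_circles_cht, extract_particles,
                                   feret_diameters, fit_circle_cht, ibc_cluster,
                                   label_components, smooth_mask,
                                   superpixel_kmeans_cluster)
from cryopick.io_formats import BoundingBox
from cryopick.synthetic import SyntheticSpec, generate_with_clean

from oracles import allpairs_feret, angle_ordered_perimeter, brute_cht


def two_level_disc_image(n=120, centers=((30, 30), (80, 90)), radius=12):
    img = np.full((n, n), 0.2)
    mask = np.zeros((n, n), dtype=bool)
    for c in centers:
        rr, cc = draw_disk(c, radius, shape=img.shape)
        img[rr, cc] = 0.8
        mask[rr, cc] = True
    return img, mask


class TestIBC:
    def test_two_level_image_recovers_discs_exactly(self):
        img, truth = two_level_disc_image()
        _, mask = ibc_cluster(img, 2)
        assert np.array_equal(mask, truth)

    def test_assignment_is_intensity_only(self, rng):
        img = rng.uniform(0, 1, (40, 40))
        _, mask = ibc_cluster(img, 2)
        perm = rng.permutation(img.size)
        _, mask_perm = ibc_cluster(img.ravel()[perm].reshape(img.shape), 2)
        assert np.array_equal(mask.ravel()[perm], mask_perm.ravel())

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ibc_cluster(np.full((16, 16), 0.5), 2)

    def test_simulator_particle_pixels_recovered(self):
        # at SNR 0.3 the enhanced micrograph clusters into a mask covering the
        # particles (per-particle overlap with truth >= 0.7)
        from cryopick.preprocess import preprocess_chain
        spec = SyntheticSpec(target_snr=0.3, n_ice_blobs=0, seed=1)
        noisy, clean, truth = generate_with_clean(spec)
        _, mask = ibc_cluster(preprocess_chain(noisy.pixels), 2)
        mask = smooth_mask(mask)
        truth_mask = clean.pixels > spec.background_level + spec.particle_intensity / 2
        jaccards = []
        for b in truth.boxes:
            t = truth_mask[b.y:b.y + b.h, b.x:b.x + b.w]
            m = mask[b.y:b.y + b.h, b.x:b.x + b.w]
            jaccards.append((t & m).sum() / (t | m).sum())
        assert (mask & truth_mask).sum() / truth_mask.sum() >= 0.9
        assert min(jaccards) >= 0.7


class TestSuperpixel:
    def test_two_level_disc_recovered(self):
        img, truth = two_level_disc_image()
        mask = superpixel_kmeans_cluster(img, n_superpixels=150, k=2)
        for c, r in (((30, 30), 12), ((80, 90), 12)):
            rr, cc = draw_disk(c, r, shape=img.shape)
            t = np.zeros_like(truth)
            t[rr, cc] = True
            j = (mask & t).sum() / (mask | t)[t | (mask & t)].sum()
            assert (mask & t).sum() / (t.sum()) >= 0.7

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            superpixel_kmeans_cluster(np.full((64, 64), 0.5), 100, 2)

    def test_too_few_superpixels_rejected(self):
        with pytest.raises(ValueError, match="n_superpixels"):
            superpixel_kmeans_cluster(np.zeros((32, 32)), 1, 2)


class TestCleanMask:
    def test_small_speck_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5:8] = True
        assert not clean_mask(mask, min_area=10).any()

    def test_border_component_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:5, 8:12] = True
        assert not clean_mask(mask, min_area=0, border_margin=1).any()

    def test_zero_thresholds_identity(self, rng):
        mask = rng.random((30, 30)) > 0.7
        assert np.array_equal(clean_mask(mask, 0, 0), mask)

    def test_never_increases_component_count(self, rng):
        from skimage.measure import label
        for _ in range(5):
            mask = rng.random((40, 40)) > 0.6
            cleaned = clean_mask(mask, min_area=3, border_margin=2)
            assert label(cleaned, connectivity=2).max() <= label(mask, connectivity=2).max()


class TestComponents:
    def test_two_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:7, 2:7] = True
        mask[10:15, 10:15] = True
        comps = label_components(mask)
        assert len(comps) == 2
        assert all(c.area == 25 for c in comps)

    def test_empty_mask(self):
        assert label_components(np.zeros((8, 8), dtype=bool)) == []

    def test_areas_conserve_total(self, rng):
        mask = rng.random((50, 50)) > 0.7
        comps = label_components(mask)
        assert sum(c.area for c in comps) == mask.sum()

    def test_centroid_inside_bounding_box(self, rng):
        mask = rng.random((40, 40)) > 0.75
        for c in label_components(mask):
            b = c.bounding_box
            cx, cy = c.centroid
            assert b.x - 0.5 <= cx <= b.x + b.w and b.y - 0.5 <= cy <= b.y + b.h


class TestContourPerimeter:
    def test_square_is_four_sides(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        assert contour_perimeter(mask) == pytest.approx(36.0)

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert contour_perimeter(mask) == 1.0

    @pytest.mark.parametrize("radius", [6, 10, 15, 22])
    def test_disc_matches_angle_ordered_oracle(self, radius):
        mask = np.zeros((2 * radius + 10,) * 2, dtype=bool)
        rr, cc = draw_disk((radius + 5, radius + 5), radius)
        mask[rr, cc] = True
        assert contour_perimeter(mask) == pytest.approx(
            angle_ordered_perimeter(mask), abs=1e-9)

    def test_ellipse_matches_oracle(self):
        from skimage.draw import ellipse
        mask = np.zeros((40, 60), dtype=bool)
        rr, cc = ellipse(20, 30, 12, 22)
        mask[rr, cc] = True
        assert contour_perimeter(mask) == pytest.approx(
            angle_ordered_perimeter(mask), abs=1e-9)


class TestCHT:
    def test_single_disc_matches_brute_accumulator(self):
        mask = np.zeros((100, 100), dtype=bool)
        rr, cc = draw_disk((50, 48), 20)
        mask[rr, cc] = True
        circles = detect_circles_cht(mask, 12, 28)
        oracle = brute_cht(mask, 12, 28)
        assert len(circles) == 1 and len(oracle) >= 1
        cx, cy = circles[0].center
        assert abs(cx - 48) <= 1 and abs(cy - 50) <= 1
        assert abs(circles[0].radius - 20) <= 1
        ox, oy, orad, _ = oracle[0]
        assert abs(cx - ox) <= 1 and abs(cy - oy) <= 1 and abs(circles[0].radius - orad) <= 1

    def test_empty_mask_gives_no_circles(self):
        assert detect_circles_cht(np.zeros((50, 50), dtype=bool), 5, 10) == []

    def test_two_separated_discs(self):
        mask = np.zeros((100, 100), dtype=bool)
        for c in ((25, 25), (70, 72)):
            rr, cc = draw_disk(c, 15)
            mask[rr, cc] = True
        circles = detect_circles_cht(mask, 10, 20)
        oracle = brute_cht(mask, 10, 20)
        assert len(circles) == 2 == len(oracle)
        got = sorted((round(c.center[0]), round(c.center[1])) for c in circles)
        want = sorted((x, y) for x, y, _, _ in oracle)
        for (gx, gy), (wx, wy) in zip(got, want):
            assert abs(gx - wx) <= 1 and abs(gy - wy) <= 1

    def test_fit_returns_argmax_even_for_partial_circle(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = draw_disk((30, 30), 15)
        keep = rr <= 30  # half disc
        mask[rr[keep], cc[keep]] = True
        fit = fit_circle_cht(mask, 10, 20)
        assert fit is not None

    def test_invalid_radius_range_rejected(self):
        with pytest.raises(ValueError):
            detect_circles_cht(np.zeros((10, 10), dtype=bool), 5, 5)


def _component_from_mask(mask):
    comps = label_components(np.asarray(mask, dtype=bool))
    assert len(comps) == 1
    return comps[0]


class TestFeret:
    def test_square_diagonal_and_side(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:13, 3:13] = True
        f = feret_diameters(_component_from_mask(mask))
        assert f.max_diameter == pytest.approx(10 * np.sqrt(2), rel=0.03)
        assert f.min_diameter == pytest.approx(10, rel=0.03)

    def test_line(self):
        mask = np.zeros((5, 24), dtype=bool)
        mask[2, 2:22] = True
        f = feret_diameters(_component_from_mask(mask))
        assert f.max_diameter == pytest.approx(20, rel=0.02)
        assert f.min_diameter == pytest.approx(1, rel=0.02)

    def test_matches_allpairs_oracle(self, rng):
        from skimage.draw import ellipse
        mask = np.zeros((50, 50), dtype=bool)
        rr, cc = ellipse(25, 25, 10, 17, rotation=0.4)
        mask[rr, cc] = True
        f = feret_diameters(_component_from_mask(mask))
        omax, omin = allpairs_feret(mask)
        assert f.max_diameter == pytest.approx(omax, abs=1e-9)
        assert f.min_diameter == pytest.approx(omin, abs=1e-9)

    def test_rotation_changes_max_by_under_3pct(self):
        from scipy.ndimage import rotate
        mask = np.zeros((100, 100), dtype=bool)
        mask[38:62, 18:82] = True
        f0 = feret_diameters(_component_from_mask(mask))
        rot = rotate(mask.astype(float), 30, order=0, reshape=True) > 0.5
        f30 = feret_diameters(_component_from_mask(rot))
        assert abs(f30.max_diameter - f0.max_diameter) / f0.max_diameter <= 0.03

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        f = feret_diameters(_component_from_mask(mask))
        assert f.max_diameter == f.min_diameter == 1.0


class TestExtract:
    def test_centered_box_arithmetic(self):
        img = np.zeros((200, 200))
        from cryopick.cluster_pick import Circle
        crops = extract_particles(img, [Circle((100, 100), 10)], 50)
        assert crops[0][1] == BoundingBox(75, 75, 50, 50)
        assert crops[0][0].shape == (50, 50)

    def test_near_edge_detection_dropped(self):
        img = np.zeros((200, 200))
        crops = extract_particles(img, [(10, 100)], 50)
        assert crops == []

    def test_crop_count_bounded(self, rng):
        img = np.zeros((100, 100))
        dets = [tuple(p) for p in rng.uniform(0, 100, (20, 2))]
        assert len(extract_particles(img, dets, 40)) <= 20

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="patch_size"):
            extract_particles(np.zeros((30, 30)), [], 40)
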