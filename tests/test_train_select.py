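"""Good/bad selection rules (roundness, Feret, area/centering), rotation
augmentation, and the balanced 80/20/(80/20) split arithmetic."""

import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from cryopick.cluster_pick import Circle, label_components
from cryopick.io_formats import BoundingBox, Micrograph
from cryopick.train_select import (TrainingSample, augment_rotations,
                                   balance_and_split, circularity,
                                   circularity_value, harvest_negatives,
                                   make_perfect_circle_mask, select_good_irregular,
                                   select_good_sideview, select_good_topview)

from oracles import angle_ordered_perimeter


def disc_component(radius=14, pad=6, center=None, canvas=None):
    n = 2 * (radius + pad)
    mask = np.zeros((n, n), dtype=bool) if canvas is None else canvas
    c = (n // 2, n // 2) if center is None else center
    rr, cc = draw_disk(c, radius, shape=mask.shape)
    mask[rr, cc] = True
    return label_components(mask)[0]


class TestCircularity:
    def test_ideal_circle_is_one(self):
        r = 5.0
        assert circularity_value(2 * math.pi * r, math.pi * r * r) == pytest.approx(1.0)

    def test_ideal_square_is_4_over_pi(self):
        s = 7.0
        assert circularity_value(4 * s, s * s) == pytest.approx(4 / math.pi)

    def test_rasterized_disc_matches_boundary_walk_oracle(self):
        comp = disc_component(radius=30, pad=5)
        expected = angle_ordered_perimeter(comp.mask) ** 2 / (4 * math.pi * comp.area)
        assert circularity(comp) == pytest.approx(expected, abs=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            circularity_value(10.0, 0.0)


class TestPerfectCircleMask:
    @pytest.mark.parametrize("radius", [10, 15, 25])
    def test_area_close_to_analytic(self, radius):
        mask = make_perfect_circle_mask(Circle((40, 40), radius), (80, 80))
        assert mask.sum() == pytest.approx(math.pi * radius ** 2, rel=0.03)

    def test_radius_one_is_plus_shape(self):
        mask = make_perfect_circle_mask(Circle((2, 2), 1), (5, 5))
        assert mask.sum() == 5
        assert mask[2, 2] and mask[1, 2] and mask[3, 2] and mask[2, 1] and mask[2, 3]

    def test_quarter_turn_symmetric(self):
        mask = make_perfect_circle_mask(Circle((20, 20), 12), (41, 41))
        assert np.array_equal(mask, np.rot90(mask))

    def test_out_of_patch_rejected(self):
        with pytest.raises(ValueError):
            make_perfect_circle_mask(Circle((5, 5), 10), (12, 12))


class TestTopView:
    def test_clean_disc_batch_all_good(self):
        comps = [disc_component(radius=14) for _ in range(5)]
        circles = [Circle((c.centroid[0], c.centroid[1]), 14) for c in comps]
        good, bad = select_good_topview(comps, circles)
        assert len(good) == 5 and bad == []

    def test_half_disc_rejected_by_overlap(self):
        # a border-clipped circle overlaps its perfect circle at ~0.5 < 0.8
        n = 40
        mask = np.zeros((n, n), dtype=bool)
        rr, cc = draw_disk((0, 20), 14, shape=(n, n))
        mask[rr, cc] = True
        half = label_components(mask)[0]
        full = [disc_component(radius=14) for _ in range(4)]
        comps = full + [half]
        circles = [Circle((c.centroid[0], c.centroid[1]), 14) for c in full]
        circles.append(Circle((20.0, 0.0), 14))
        good, bad = select_good_topview(comps, circles)
        assert half in bad and all(c in good for c in full)

    def test_speck_blowing_up_perimeter_rejected_by_roundness(self):
        # disc plus a long thin tendril: perimeter inflated ~40%, circularity
        # far above the batch band while the mean stays near 1
        n = 60
        mask = np.zeros((n, n), dtype=bool)
        rr, cc = draw_disk((30, 26), 14)
        mask[rr, cc] = True
        mask[29:31, 40:58] = True  # tendril
        perturbed = label_components(mask)[0]
        clean = [disc_component(radius=14) for _ in range(6)]
        comps = clean + [perturbed]
        circles = [Circle((c.centroid[0], c.centroid[1]), 14) for c in clean]
        circles.append(Circle((26.0, 30.0), 14))
        assert circularity(perturbed) > 1.4 * circularity(clean[0])
        good, bad = select_good_topview(comps, circles)
        assert perturbed in bad

    def test_no_circle_means_bad(self):
        comps = [disc_component(radius=14) for _ in range(3)]
        circles = [Circle((comps[0].centroid[0], comps[0].centroid[1]), 14), None, None]
        good, bad = select_good_topview(comps, circles)
        assert len(good) == 1 and len(bad) == 2

    def test_partition_and_permutation_invariance(self):
        comps = [disc_component(radius=r) for r in (10, 12, 14, 16)]
        circles = [Circle((c.centroid[0], c.centroid[1]), r)
                   for c, r in zip(comps, (10, 12, 14, 16))]
        good, bad = select_good_topview(comps, circles)
        assert sorted(map(id, good + bad)) == sorted(map(id, comps))
        perm = [2, 0, 3, 1]
        good_p, bad_p = select_good_topview([comps[i] for i in perm],
                                            [circles[i] for i in perm])
        assert {id(c) for c in good_p} == {id(c) for c in good}

    def test_empty_input(self):
        assert select_good_topview([], []) == ([], [])


def square_component(side=20, pad=6):
    n = side + 2 * pad
    mask = np.zeros((n, n), dtype=bool)
    mask[pad:pad + side, pad:pad + side] = True
    return label_components(mask)[0]


class TestSideView:
    def test_identical_squares_all_good(self):
        comps = [square_component() for _ in range(6)]
        good, bad = select_good_sideview(comps)
        assert len(good) == 6 and bad == []

    def test_fused_double_square_removed(self):
        comps = [square_component() for _ in range(5)]
        n = 60
        fused = np.zeros((n, n), dtype=bool)
        fused[20:40, 8:48] = True  # two fused squares: double-length component
        comps.append(label_components(fused)[0])
        good, bad = select_good_sideview(comps)
        assert len(bad) == 1 and comps[-1] in bad

    def test_disc_among_squares_removed_by_ratio(self):
        comps = [square_component() for _ in range(5)]
        comps.append(disc_component(radius=12))
        good, bad = select_good_sideview(comps)
        assert comps[-1] in bad and len(good) == 5

    def test_good_masks_replaced_by_perfect_squares(self):
        comps = [square_component(side=20)]
        good, _ = select_good_sideview(comps)
        assert good[0].mask.all()
        assert good[0].mask.shape[0] == good[0].mask.shape[1]
        assert abs(good[0].mask.shape[0] - 20) <= 1


def blob_component(area_scale=1.0, canvas=48, at=None):
    mask = np.zeros((canvas, canvas), dtype=bool)
    c = (canvas // 2, canvas // 2) if at is None else at
    rr, cc = draw_disk(c, 10 * math.sqrt(area_scale), shape=mask.shape)
    mask[rr, cc] = True
    comp = label_components(mask, patch_shape=(canvas, canvas))[0]
    return comp


class TestIrregular:
    def test_equal_blobs_all_good(self):
        comps = [blob_component() for _ in range(10)]
        good, bad = select_good_irregular(comps)
        assert len(good) == 10 and bad == []

    def test_fragment_rejected_by_area(self):
        comps = [blob_component() for _ in range(6)] + [blob_component(area_scale=0.3)]
        good, bad = select_good_irregular(comps)
        assert len(bad) == 1 and comps[-1] in bad

    def test_corner_centroid_rejected(self):
        comps = [blob_component() for _ in range(6)]
        comps.append(blob_component(at=(5, 5)))
        good, bad = select_good_irregular(comps)
        assert comps[-1] in bad

    def test_empty_input(self):
        assert select_good_irregular([]) == ([], [])


class TestNegatives:
    def test_particle_free_micrograph_gives_n_crops(self, rng):
        m = Micrograph(rng.random((128, 128)))
        samples = harvest_negatives(m, [], n=6, patch_size=32, seed=0)
        assert len(samples) == 6
        assert all(s.label == "background" for s in samples)

    def test_crops_disjoint_from_particles(self, rng):
        m = Micrograph(rng.random((160, 160)))
        boxes = [BoundingBox(40, 40, 40, 40), BoundingBox(100, 100, 30, 30)]
        samples = harvest_negatives(m, boxes, n=10, patch_size=24, seed=1)
        for s in samples:
            x, y = map(int, s.source.split(":")[1].split(","))
            crop = BoundingBox(x, y, 24, 24)
            for b in boxes:
                overlap_x = min(crop.x + crop.w, b.x + b.w) - max(crop.x, b.x)
                overlap_y = min(crop.y + crop.h, b.y + b.h) - max(crop.y, b.y)
                assert overlap_x <= 0 or overlap_y <= 0

    def test_seeded_determinism(self, rng):
        m = Micrograph(rng.random((96, 96)))
        a = harvest_negatives(m, [], n=4, patch_size=16, seed=3)
        b = harvest_negatives(m, [], n=4, patch_size=16, seed=3)
        assert all(np.array_equal(x.patch, y.patch) for x, y in zip(a, b))


class TestRotations:
    def test_exactly_four_samples(self, rng):
        s = TrainingSample(rng.random((16, 16)), "top_view")
        out = augment_rotations(s)
        assert len(out) == 4
        assert [o.rotation for o in out] == [0, 90, 180, 270]
        assert all(o.label == "top_view" for o in out)

    def test_full_turn_recovers_original(self, rng):
        s = TrainingSample(rng.random((16, 16)), "irregular")
        out = augment_rotations(s)
        assert np.array_equal(np.rot90(out[3].patch), out[0].patch)

    def test_symmetric_patch_gives_identical_rotations(self):
        patch = np.zeros((9, 9))
        patch[4, 4] = 1.0
        out = augment_rotations(TrainingSample(patch, "background"))
        assert all(np.array_equal(o.patch, patch) for o in out)

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            augment_rotations(TrainingSample(rng.random((8, 10)), "background"))


def _samples(n, label, rng):
    return [TrainingSample(rng.random((8, 8)), label) for _ in range(n)]


class TestBalanceSplit:
    def test_published_counts_at_1500(self, rng):
        by_class = {c: _samples(400, c, rng)
                    for c in ("top_view", "side_view", "background")}
        split = balance_and_split(by_class, 1500, seed=0)
        per_class = 3
        assert len(split.train) == 960 * per_class
        assert len(split.validation) == 240 * per_class
        assert len(split.test) == 300 * per_class

    def test_small_target_conserves_counts(self, rng):
        by_class = {"top_view": _samples(10, "top_view", rng)}
        split = balance_and_split(by_class, 10, seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)

    def test_same_seed_same_membership(self, rng):
        by_class = {"top_view": _samples(30, "top_view", rng),
                    "background": _samples(30, "background", rng)}
        s1 = balance_and_split(by_class, 20, seed=5)
        s2 = balance_and_split(by_class, 20, seed=5)
        for a, b in zip(s1.train + s1.validation + s1.test,
                        s2.train + s2.validation + s2.test):
            assert a is b

    def test_augmentation_fills_shortfall(self, rng):
        by_class = {"top_view": _samples(30, "top_view", rng)}
        split = balance_and_split(by_class, 100, seed=0)
        assert len(split.train) + len(split.validation) + len(split.test) == 100

    def test_insufficient_class_named_in_error(self, rng):
        by_class = {"side_view": _samples(3, "side_view", rng)}
        with pytest.raises(ValueError, match="side_view"):
            balance_and_split(by_class, 100, seed=0)
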