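"""The eight collagen features: worked examples and limit properties."""

import warnings

import numpy as np
import pytest

import collagenscore as cs
from collagenscore.features import (FeatureVector, aggregate_patient,
                                    area_fraction, compute_feature_vector,
                                    crosslink_density,
                                    crosslink_spacing_mean, fiber_count,
                                    fiber_length_mean,
                                    fiber_straightness_mean,
                                    fiber_width_mean, orientation_index)
from collagenscore.network import Fiber, FiberNetwork, skeletonize_mask, \
    extract_fiber_network
from conftest import network_from_pixels


def make_fiber(vertices, path_length=None, width=1.0):
    v = np.asarray(vertices, dtype=int)
    if path_length is None:
        path_length = float(
            np.sqrt((np.diff(v, axis=0) ** 2).sum(axis=1)).sum())
    return Fiber(vertices=v, path_length=path_length, mean_width=width)


class TestAreaFraction:
    def test_extremes_and_quarter(self):
        assert area_fraction(np.ones((16, 16), bool)) == 1.0
        assert area_fraction(np.zeros((16, 16), bool)) == 0.0
        mask = np.zeros((512, 512), bool)
        mask[:256, :256] = True  # 65536 px
        assert area_fraction(mask) == 0.25


class TestCounts:
    def test_empty_network(self):
        assert fiber_count(FiberNetwork([])) == 0
        assert np.isnan(fiber_length_mean(FiberNetwork([])))

    def test_ground_truth_count(self, clean_scene, clean_network):
        spec, _, _ = clean_scene
        net, _ = clean_network
        assert fiber_count(net) == spec.n_fibers

    def test_x_passthrough_counts_two(self, x_network):
        assert fiber_count(x_network) == 2


class TestLengthWidthStraightness:
    def test_length_mean_is_arithmetic_mean(self):
        f1 = make_fiber([(0, c) for c in range(51)])   # 50
        f2 = make_fiber([(5, c) for c in range(151)])  # 150
        assert fiber_length_mean(FiberNetwork([f1, f2])) == 100.0

    def test_length_recovery_on_straight_fibers(self, clean_scene,
                                                clean_network):
        _, _, truth = clean_scene
        net, _ = clean_network
        true_mean = np.mean([np.sqrt((np.diff(c, axis=0) ** 2)
                                     .sum(axis=1)).sum()
                             for c in truth.fiber_centerlines])
        assert fiber_length_mean(net) == pytest.approx(true_mean, rel=0.05)

    def test_width_from_rectangles(self):
        mask = np.zeros((64, 200), bool)
        mask[30:35, 20:180] = True  # 5 px tall
        skel = skeletonize_mask(mask)
        net = extract_fiber_network(skel)
        w = fiber_width_mean(net, skel)
        assert 4.0 <= w <= 6.0

        mask2 = np.zeros((64, 200), bool)
        mask2[10:14, 20:180] = True   # 4 px
        mask2[40:48, 20:180] = True   # 8 px
        skel2 = skeletonize_mask(mask2)
        net2 = extract_fiber_network(skel2)
        assert 5.0 <= fiber_width_mean(net2, skel2) <= 7.0

    def test_width_recovery_on_synthetic_fibers(self):
        spec = cs.FiberSpec(n_fibers=10, width_mean=6, width_sd=0,
                            crossing_allowed=False, noise_sd=0, waviness=0,
                            seed=6, shape=(256, 256))
        _, truth = cs.generate_fiber_image(spec)
        net, skel = cs.extract_network(truth.true_mask)
        assert fiber_width_mean(net, skel) == pytest.approx(6.0, abs=1.0)

    def test_straightness_examples(self):
        straight = make_fiber([(0, c) for c in range(101)])
        assert straight.straightness() == 1.0
        # L-path, legs 30 and 40 at unit steps: 50 / 70
        legs = [(0, c) for c in range(31)] + [(r, 30) for r in range(1, 41)]
        lpath = make_fiber(legs, path_length=70.0)
        assert fiber_straightness_mean(FiberNetwork([lpath])) == \
            pytest.approx(50 / 70, abs=1e-9)

    def test_straight_synthetic_fibers_near_one(self, clean_network):
        net, _ = clean_network
        assert fiber_straightness_mean(net) >= 0.98

    def test_closed_loop_excluded_with_warning(self):
        ring = np.zeros((32, 32), bool)
        rr = [(5, c) for c in range(5, 25)] + [(r, 24) for r in range(6, 25)]
        rr += [(24, c) for c in range(23, 4, -1)] + \
              [(r, 5) for r in range(23, 5, -1)]
        loop = make_fiber(rr + [rr[0]])
        straight = make_fiber([(0, c) for c in range(30)])
        with pytest.warns(RuntimeWarning, match="closed-loop"):
            val = fiber_straightness_mean(FiberNetwork([loop, straight]))
        assert val == 1.0


class TestCrosslinkFeatures:
    def test_density_examples(self, x_network, grid_network):
        parallel = network_from_pixels(
            [(10, c) for c in range(5, 45)] + [(20, c) for c in range(5, 45)])
        assert crosslink_density(parallel) == 0.0
        assert crosslink_density(x_network) == 0.5
        assert crosslink_density(grid_network) == pytest.approx(1.5)

    def test_spacing_hand_built(self):
        verts = [(10, c) for c in range(101)]
        fiber = make_fiber(verts)
        members = {(10, 10): 0, (10, 40): 1, (10, 100): 2}
        net = FiberNetwork([fiber], crosslinks=[(10, 10), (10, 40),
                                                (10, 100)],
                           crosslink_members=members)
        assert crosslink_spacing_mean(net) == pytest.approx(45.0)

    def test_single_crosslink_is_missing(self):
        fiber = make_fiber([(10, c) for c in range(50)])
        net = FiberNetwork([fiber], crosslinks=[(10, 20)],
                           crosslink_members={(10, 20): 0})
        assert np.isnan(crosslink_spacing_mean(net))

    def test_grid_spacing_matches_construction(self):
        pix = {(r, c) for r in (100, 200, 300) for c in range(50, 351)} | \
              {(r, c) for c in (100, 200, 300) for r in range(50, 351)}
        net = network_from_pixels(sorted(pix), shape=(400, 400))
        assert crosslink_spacing_mean(net) == pytest.approx(100.0, rel=0.02)


class TestOrientationIndex:
    def test_parallel_stripes_highly_aligned(self):
        img = np.zeros((256, 256))
        img[:, ::8] = 1.0
        assert orientation_index(img) >= 0.9

    def test_isotropic_scene_low(self):
        vals = []
        for seed in range(10):
            _, truth = cs.generate_fiber_image(cs.FiberSpec(
                n_fibers=40, orientation_kappa=0, seed=seed, noise_sd=0,
                shape=(256, 256)))
            vals.append(orientation_index(truth.true_mask.astype(float)))
        assert np.mean(vals) <= 0.2

    def test_rotation_invariance(self):
        _, truth = cs.generate_fiber_image(cs.FiberSpec(
            n_fibers=20, orientation_kappa=8, seed=3, noise_sd=0,
            shape=(256, 256)))
        a = orientation_index(truth.true_mask.astype(float))
        b = orientation_index(np.rot90(truth.true_mask).astype(float))
        assert abs(a - b) <= 0.02

    def test_constant_input_missing(self):
        assert np.isnan(orientation_index(np.zeros((64, 64))))

    def test_alignment_increases_with_kappa(self):
        means = []
        for kappa in (0.0, 4.0, 32.0):
            vals = []
            for s in range(5):
                _, truth = cs.generate_fiber_image(cs.FiberSpec(
                    n_fibers=25, orientation_kappa=kappa, waviness=0.0,
                    seed=s, noise_sd=0, shape=(256, 256)))
                vals.append(orientation_index(truth.true_mask.astype(float)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestAssemblyAndAggregation:
    def test_empty_mask_feature_vector(self):
        mask = np.zeros((64, 64), bool)
        skel = skeletonize_mask(mask)
        net = extract_fiber_network(skel)
        fv = compute_feature_vector(mask.astype(np.uint16), mask, net, skel)
        assert fv.fea1 == 0.0 and fv.fea2 == 0.0
        assert all(np.isnan(getattr(fv, f"fea{i}")) for i in range(3, 9))

    def test_straight_aligned_scene_limits(self):
        spec = cs.FiberSpec(n_fibers=12, waviness=0.0,
                            orientation_kappa=np.inf, orientation_mean=40,
                            crossing_allowed=False, noise_sd=0, seed=2,
                            shape=(256, 256))
        img, truth = cs.generate_fiber_image(spec)
        net, skel = cs.extract_network(truth.true_mask)
        fv = compute_feature_vector(img, truth.true_mask, net, skel)
        assert fv.fea5 >= 0.98
        assert fv.fea8 >= 0.9
        fv.validate()

    def test_straightness_decreases_with_waviness(self):
        means = []
        for wav in (0.0, 0.2, 0.5):
            vals = []
            for s in range(5):
                _, truth = cs.generate_fiber_image(cs.FiberSpec(
                    n_fibers=10, waviness=wav, crossing_allowed=False,
                    noise_sd=0, seed=s, shape=(256, 256)))
                net, _ = cs.extract_network(truth.true_mask)
                vals.append(fiber_straightness_mean(net))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_aggregate_identity_mean_and_missing_skip(self):
        a = FeatureVector(fea1=0.2, fea2=3, fea3=50, fea4=4, fea5=0.9,
                          fea6=0.5, fea7=np.nan, fea8=0.3)
        b = FeatureVector(fea1=0.4, fea2=5, fea3=70, fea4=6, fea5=1.0,
                          fea6=0.7, fea7=80.0, fea8=0.5)
        single = aggregate_patient([a], patient_id="p")
        assert np.allclose(single.aggregate.to_array(), a.to_array(),
                           equal_nan=True)
        agg = aggregate_patient([a, b]).aggregate
        assert agg.fea1 == pytest.approx(0.3)
        assert agg.fea7 == 80.0  # missing skipped, not zero-filled

    def test_aggregate_empty_roi_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([])
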