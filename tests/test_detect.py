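import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanolabel.core_io import Contrast, DetectionParams, VolumeGrid
from nanolabel.detect import (
    component_centroid,
    detect_gold,
    high_intensity_mask,
    label_components,
    lattice_voxel_count,
    normalize_unit_interval,
    pixel_span,
    remove_singletons,
    size_gate,
    slab_average,
    theoretical_voxel_count,
)
from nanolabel.simulate import simulate_tomogram


class TestSlabAverage:
    def test_width_one_identity(self, bright_volume_factory, rng):
        vol = bright_volume_factory(rng.normal(size=(5, 4, 3)))
        out = slab_average(vol, 1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_constant_unchanged(self, bright_volume_factory):
        vol = bright_volume_factory(np.full((6, 2, 2), 3.5))
        for width in (1, 3, 6):
            np.testing.assert_allclose(slab_average(vol, width).data, vol.data)

    def test_hand_arithmetic_column(self, bright_volume_factory):
        # window [z, z+1] for width 2; the last window shrinks to one slice
        vol = bright_volume_factory(np.array([0.0, 0.0, 4.0, 0.0]).reshape(4, 1, 1))
        out = slab_average(vol, 2)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 2.0, 2.0, 0.0])

    def test_dimensions_preserved(self, bright_volume_factory, rng):
        vol = bright_volume_factory(rng.normal(size=(10, 3, 3)))
        assert slab_average(vol, 10).shape == vol.shape

    def test_width_bounds(self, bright_volume_factory):
        vol = bright_volume_factory(np.zeros((4, 2, 2)))
        with pytest.raises(ValueError):
            slab_average(vol, 0)
        with pytest.raises(ValueError):
            slab_average(vol, 5)


class TestNormalize:
    def test_two_values(self, bright_volume_factory):
        vol = bright_volume_factory(np.array([0.0, 2.0]).reshape(1, 1, 2))
        np.testing.assert_allclose(normalize_unit_interval(vol).data.ravel(), [0, 1])

    def test_three_values(self, bright_volume_factory):
        vol = bright_volume_factory(np.array([-1.0, 0.0, 1.0]).reshape(1, 1, 3))
        np.testing.assert_allclose(normalize_unit_interval(vol).data.ravel(),
                                   [0.0, 0.5, 1.0])

    def test_idempotent_on_normalized(self, bright_volume_factory, rng):
        data = rng.uniform(size=(3, 3, 3))
        data.flat[0], data.flat[-1] = 0.0, 1.0
        vol = bright_volume_factory(data)
        np.testing.assert_allclose(normalize_unit_interval(vol).data, data,
                                   atol=1e-7)

    def test_constant_rejected(self, bright_volume_factory):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_unit_interval(bright_volume_factory(np.ones((2, 2, 2))))


class TestHighIntensityMask:
    def test_single_hot_voxel(self, bright_volume_factory):
        # mean = 1/27, SD (ddof=0) ~ 0.190, threshold ~ 0.66 < 1
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 1.0
        mask = high_intensity_mask(bright_volume_factory(data), 3.3)
        expected = np.zeros((3, 3, 3), dtype=bool)
        expected[1, 1, 1] = True
        np.testing.assert_array_equal(mask, expected)

    def test_all_equal_rejected(self, bright_volume_factory):
        with pytest.raises(ValueError, match="SD is zero"):
            high_intensity_mask(bright_volume_factory(np.ones((2, 2, 2))), 3.3)

    def test_huge_k_empty_mask(self, bright_volume_factory, rng):
        vol = bright_volume_factory(rng.normal(size=(4, 4, 4)))
        assert not high_intensity_mask(vol, 1e9).any()

    def test_density_dark_rejected(self, rng):
        vol = VolumeGrid(rng.normal(size=(4, 4, 4)), 3.0,
                         contrast=Contrast.DENSITY_DARK)
        with pytest.raises(ValueError, match="density_bright"):
            high_intensity_mask(vol, 3.3)


class TestComponents:
    def test_corner_sharing_connectivity(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert len(label_components(mask, connectivity=26)) == 1
        assert len(label_components(mask, connectivity=6)) == 2

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        comps = label_components(mask)
        assert len(comps) == 1 and len(comps[0]) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_full_block(self, connectivity):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        comps = label_components(mask, connectivity)
        assert len(comps) == 1 and len(comps[0]) == 8

    def test_empty_mask(self):
        assert label_components(np.zeros((2, 2, 2), dtype=bool)) == []

    def test_ordering_by_min_linear_index(self):
        mask = np.zeros((1, 1, 9), dtype=bool)
        mask[0, 0, [6, 7]] = True
        mask[0, 0, [0, 1]] = True
        comps = label_components(mask, connectivity=6)
        assert [c[0, 2] for c in comps] == [0, 6]

    def test_remove_singletons(self):
        sizes = [1, 5, 1, 44]
        comps = [np.zeros((s, 3), dtype=int) for s in sizes]
        assert [len(c) for c in remove_singletons(comps)] == [5, 44]
        assert remove_singletons([]) == []

    def test_size_gate_paper_bounds(self):
        comps = [np.zeros((s, 3), dtype=int) for s in (39, 40, 53, 55, 56)]
        kept = size_gate(comps, 40, 55)
        assert [len(c) for c in kept] == [40, 53, 55]
        assert size_gate(comps, 1, 10**9) == comps
        assert size_gate([], 40, 55) == []

    def test_gate_singleton_commutes_when_min_ge_2(self, rng):
        for _ in range(10):
            sizes = rng.integers(1, 60, size=12)
            comps = [np.zeros((s, 3), dtype=int) for s in sizes]
            a = size_gate(remove_singletons(comps), 5, 40)
            b = remove_singletons(size_gate(comps, 5, 40))
            assert [len(c) for c in a] == [len(c) for c in b]


class TestVoxelCounts:
    def test_paper_value_53(self):
        assert theoretical_voxel_count(7.0, 3.0) == 53

    def test_lattice_oracle_disambiguates(self):
        # center-in-sphere counting gives 57, not the reported 53 -> the
        # definition must be the volume ratio
        assert lattice_voxel_count(7.0, 3.0) == 57

    def test_zero_radius(self):
        assert theoretical_voxel_count(0.0, 3.0) == 0

    def test_unit_ratio(self):
        assert theoretical_voxel_count(7.0, 7.0) == 4  # (4/3)pi ~ 4.19

    def test_invalid_voxel(self):
        with pytest.raises(ValueError):
            theoretical_voxel_count(7.0, 0.0)


class TestCentroid:
    def test_single_voxel_center_convention(self):
        c = component_centroid(np.array([[1, 1, 1]]), 3.0)
        np.testing.assert_allclose(c, [4.5, 4.5, 4.5])

    def test_symmetric_pair_midpoint(self):
        comp = np.array([[0, 0, 0], [0, 0, 2]])
        np.testing.assert_allclose(component_centroid(comp, 1.0), [1.5, 0.5, 0.5])

    def test_block_center(self):
        zz, yy, xx = np.meshgrid(range(2), range(2), range(2), indexing="ij")
        comp = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        np.testing.assert_allclose(component_centroid(comp, 2.0), [2.0, 2.0, 2.0])


class TestPixelSpan:
    def test_paper_value(self):
        assert pixel_span(14.0, 1.068) == 13

    def test_unity(self):
        assert pixel_span(14.0, 14.0) == 1

    def test_arithmetic(self):
        assert pixel_span(50.0, 3.0) == 17


class TestDetectGold:
    def test_noiseless_oracle(self, oracle_sim_config, oracle_detection_params):
        vol, truth = simulate_tomogram(oracle_sim_config(seed=1))
        detections = detect_gold(vol, oracle_detection_params)
        assert len(detections) == len(truth.gold_positions)
        centroids = np.array([d.centroid for d in detections])
        for gold in truth.gold_positions:
            err = np.linalg.norm(centroids - gold, axis=1).min()
            assert err <= vol.voxel_size

    def test_oversize_blob_gated_out(self, bright_volume_factory, rng):
        data = rng.normal(0, 1e-3, size=(20, 20, 20))
        data[4:12, 4:12, 4:12] = 1.0  # 512-voxel blob: "gallium, ice or membrane"
        vol = bright_volume_factory(data)
        params = DetectionParams(slab_width=1, min_voxels=40, max_voxels=55)
        assert detect_gold(vol, params) == []

    def test_noise_only_volume_no_detections(self, bright_volume_factory):
        data = np.random.default_rng(0).normal(size=(64, 64, 64))
        vol = bright_volume_factory(data)
        assert detect_gold(vol, DetectionParams()) == []

    def test_affine_intensity_invariance(self, oracle_sim_config,
                                         oracle_detection_params):
        vol, _ = simulate_tomogram(oracle_sim_config(seed=2, noise_sd=0.1))
        base = detect_gold(vol, oracle_detection_params)
        scaled = vol.with_data(vol.data * 7.5 - 2.0)
        again = detect_gold(scaled, oracle_detection_params)
        assert len(base) == len(again)
        np.testing.assert_allclose(
            np.array([d.centroid for d in base]),
            np.array([d.centroid for d in again]),
            atol=1e-6,
        )

    def test_k_sd_monotonicity(self, oracle_sim_config):
        vol, _ = simulate_tomogram(oracle_sim_config(seed=3, noise_sd=0.2))
        counts = []
        for k in (2.0, 3.3, 5.0, 8.0):
            params = DetectionParams(k_sd=k, slab_width=1, min_voxels=2,
                                     max_voxels=10**6)
            counts.append(len(detect_gold(vol, params)))
        assert counts == sorted(counts, reverse=True)

    def test_resampling_to_working_grid(self, oracle_sim_config,
                                        oracle_detection_params):
        # render at 1.5 A and detect on the 3 A working grid (block mean x2)
        cfg = oracle_sim_config(seed=4)
        cfg.voxel_size = 1.5
        cfg.dims = (256, 256, 256)
        vol, truth = simulate_tomogram(cfg)
        detections = detect_gold(vol, oracle_detection_params)
        assert len(detections) == len(truth.gold_positions)
        centroids = np.array([d.centroid for d in detections])
        for gold in truth.gold_positions:
            assert np.linalg.norm(centroids - gold, axis=1).min() <= 3.0

    def test_non_integer_ratio_rejected(self, bright_volume_factory):
        vol = VolumeGrid(np.zeros((8, 8, 8)), 1.3, contrast=Contrast.DENSITY_BRIGHT)
        with pytest.raises(ValueError, match="integer"):
            detect_gold(vol, DetectionParams(working_pixel_size=3.0))

    def test_density_dark_rejected(self):
        vol = VolumeGrid(np.zeros((8, 8, 8)), 3.0)
        with pytest.raises(ValueError, match="density_bright"):
            detect_gold(vol, DetectionParams())


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
def test_mask_affine_invariance_property(scale, shift):
    data = np.random.default_rng(99).normal(size=(6, 6, 6))
    vol = VolumeGrid(data, 3.0, contrast=Contrast.DENSITY_BRIGHT)
    transformed = vol.with_data(data * scale + shift)
    np.testing.assert_array_equal(
        high_intensity_mask(vol, 3.3),
        high_intensity_mask(transformed, 3.3),
    )
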