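"""Segmentation: thresholding, 3D labeling vs a flood-fill oracle,
measurement arithmetic, the minimum-volume filter, and ground-truth
recovery on a rendered scene."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coloc3d import (
    VoxelGrid,
    filter_min_volume,
    label_components,
    measure_objects,
    segment_channel,
    smooth_and_threshold,
)
from coloc3d.segmentation import equivalent_radius


def _grid(array, spacing=(1.0, 1.0, 1.0), channel="reference"):
    return VoxelGrid(
        data=np.asarray(array, dtype=float)[None], spacing=spacing, channels=(channel,)
    )


class TestSmoothAndThreshold:
    def test_zero_channel_fixed_threshold(self):
        mask = smooth_and_threshold(
            _grid(np.zeros((4, 5, 6))), "reference", sigma_um=0, threshold=10
        )
        assert not mask.any()

    def test_fixed_threshold_recovers_blobs_exactly(self):
        vol = np.zeros((6, 10, 10))
        vol[1:3, 1:4, 1:4] = 100
        vol[4:6, 6:9, 6:9] = 100
        mask = smooth_and_threshold(_grid(vol), "reference", sigma_um=0, threshold=50)
        assert np.array_equal(mask, vol > 50)

    def test_auto_threshold_separates_bimodal(self, rng):
        background = rng.normal(10, 2, size=4000)
        foreground = rng.normal(100, 5, size=1000)
        vol = np.concatenate([background, foreground]).reshape(5, 10, 100)
        thr_mask = smooth_and_threshold(_grid(vol), "reference", sigma_um=0)
        # between-class-variance oracle: exhaustive scan over every possible
        # cut position (prefix sums make the full scan cheap)
        values = np.sort(vol.ravel())
        n = values.size
        csum = np.cumsum(values)
        k = np.arange(1, n)  # cut after the k-th smallest value
        mean_lo = csum[:-1] / k
        mean_hi = (csum[-1] - csum[:-1]) / (n - k)
        w = k / n
        between_var = w * (1 - w) * (mean_lo - mean_hi) ** 2
        best_cut = values[int(between_var.argmax())]
        # the chosen threshold must lie strictly between the two modes,
        # like the exhaustive maximizer does
        assert 10 < best_cut < 100
        # both the oracle cut and the automatic threshold fall in the gap
        # between modes, so they induce the identical mask
        assert np.array_equal(thr_mask, vol > best_cut)
        assert int(thr_mask.sum()) == foreground.size

    def test_auto_threshold_constant_image_errors(self):
        with pytest.raises(ValueError, match="constant"):
            smooth_and_threshold(_grid(np.full((3, 3, 3), 7.0)), "reference")

    def test_anisotropic_smoothing_sigma(self):
        # a point source smoothed at 0.3 μm on (0.3, 0.1, 0.1) voxels must
        # spread 3x as far (in voxels) along y/x as along z
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1000.0
        g = _grid(vol, spacing=(0.3, 0.1, 0.1))
        mask = smooth_and_threshold(g, "reference", sigma_um=0.3, threshold=1e-3)
        zs, ys, xs = np.nonzero(mask)
        assert (ys.max() - ys.min()) > (zs.max() - zs.min())


class TestLabelComponents:
    def test_two_blobs_two_labels(self):
        mask = np.zeros((4, 8, 8), dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        mask[2:4, 5:8, 5:8] = True
        labels = label_components(mask)
        assert labels.max() == 2

    def test_corner_touch_connectivity(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # touching only at a corner
        assert label_components(mask, connectivity=26).max() == 1
        assert label_components(mask, connectivity=6).max() == 2

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_components(np.zeros((2, 2, 2), dtype=bool), connectivity=8)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        mask = rng.random((8, 10, 10)) < 0.25
        labels = label_components(mask, connectivity=connectivity)
        assert _partition(labels) == _flood_fill_partition(mask, connectivity)


def _offsets(connectivity):
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                out.append((dz, dy, dx))
    return out


def _flood_fill_partition(mask, connectivity):
    """Independent BFS flood fill; returns the set of component voxel-sets."""
    offsets = _offsets(connectivity)
    seen = np.zeros_like(mask, dtype=bool)
    components = set()
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if any(c < 0 or c >= s for c, s in zip(w, mask.shape)):
                    continue
                if mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.add(frozenset(comp))
    return components


def _partition(labels):
    return {
        frozenset(zip(*np.nonzero(labels == k))) for k in range(1, labels.max() + 1)
    }


class TestMeasureObjects:
    def test_single_voxel(self):
        labels = np.zeros((5, 6, 7), dtype=int)
        labels[2, 3, 4] = 1
        t = measure_objects(labels, spacing=(0.3, 0.06, 0.06))
        row = t.iloc[0]
        assert row.voxel_count == 1
        assert row.volume_um3 == pytest.approx(0.3 * 0.06 * 0.06)
        assert (row.x_um, row.y_um, row.z_um) == pytest.approx((0.27, 0.21, 0.75))

    def test_block_centroid_and_volume(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[2:4, 2:4, 2:4] = 1
        t = measure_objects(labels, spacing=(0.5, 0.5, 0.5))
        row = t.iloc[0]
        assert row.voxel_count == 8
        assert row.volume_um3 == pytest.approx(8 * 0.125)
        assert (row.x_um, row.y_um, row.z_um) == pytest.approx((1.5, 1.5, 1.5))

    def test_equivalent_radius_value(self):
        # numerically evaluated (3V/4π)^(1/3) at V = 0.0185 μm³
        assert equivalent_radius(0.0185) == pytest.approx(0.16407, abs=1e-4)

    @given(
        st.integers(min_value=1, max_value=500),
        st.tuples(
            st.floats(0.05, 1.0), st.floats(0.05, 1.0), st.floats(0.05, 1.0)
        ),
    )
    @settings(max_examples=30, deadline=None)
    def test_volume_radius_consistency(self, n_vox, spacing):
        labels = np.zeros((8, 8, 8), dtype=int)
        flat = labels.reshape(-1)
        flat[:n_vox] = 1
        t = measure_objects(labels, spacing=spacing)
        r = t.iloc[0]
        assert abs(r.radius_um - (3 * r.volume_um3 / (4 * np.pi)) ** (1 / 3)) < 1e-9


class TestFilterMinVolume:
    def test_retains_at_and_above_threshold(self):
        t = pd.DataFrame(
            {
                "object_id": range(5),
                "voxel_count": [3, 14, 15, 20, 100],
                "volume_um3": np.array([3, 14, 15, 20, 100]) * 0.001,
            }
        )
        out = filter_min_volume(t, min_voxels=15)
        assert list(out.voxel_count) == [15, 20, 100]
        assert list(out.object_id) == [2, 3, 4]

    def test_empty_and_all_below(self):
        t = pd.DataFrame({"object_id": [], "voxel_count": [], "volume_um3": []})
        assert len(filter_min_volume(t, min_voxels=15)) == 0
        t2 = pd.DataFrame(
            {"object_id": [1, 2], "voxel_count": [1, 2], "volume_um3": [0.1, 0.2]}
        )
        assert len(filter_min_volume(t2, min_voxels=15)) == 0

    def test_volume_mode(self):
        t = pd.DataFrame(
            {"object_id": [1, 2], "voxel_count": [10, 20], "volume_um3": [0.01, 0.02]}
        )
        out = filter_min_volume(t, min_voxels=None, min_volume_um3=0.0185)
        assert list(out.object_id) == [2]

    def test_exactly_one_mode_required(self):
        t = pd.DataFrame({"object_id": [1], "voxel_count": [10], "volume_um3": [0.01]})
        with pytest.raises(ValueError):
            filter_min_volume(t, min_voxels=15, min_volume_um3=0.0185)


class TestGroundTruthRecovery:
    def test_noiseless_scene_recovered_exactly(self, small_scene, small_grid):
        spacing = np.array(small_grid.spacing)
        diag = float(np.linalg.norm(spacing))
        for channel in ("candidate", "reference"):
            table = segment_channel(
                small_grid, channel, sigma_um=0.0, threshold=50.0, min_voxels=1
            )
            truth = small_scene.channel_objects(channel)
            assert len(table) == len(truth)
            got = table[["x_um", "y_um", "z_um"]].to_numpy()
            for o in truth:
                d = np.linalg.norm(got - o.center, axis=1).min()
                assert d < diag  # centroid within one voxel diagonal
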