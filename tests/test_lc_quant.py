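"""LC quantification: normalization, brightest-contiguous selection, QC."""

import itertools

import numpy as np
import pytest

from coeruleus import (
    MaskSet,
    PhantomSpec,
    VolumeGrid,
    compute_lc_ri,
    generate_phantom,
    mask_overlap_qc,
    quantify,
    select_lc_voxels,
    slicewise_normalize,
)
from coeruleus.lc_quant import (
    DataError,
    QuantificationError,
    SliceCoverageError,
    _neighbor_offsets,
)


def toy_volume(data):
    return VolumeGrid(np.asarray(data, dtype=float))


def single_slice_setup(ref_values, lc_value):
    """1-slice toy: a 1x3x1 grid — two reference voxels and one LC voxel."""
    data = np.zeros((3, 2, 1))
    data[0, 0, 0], data[1, 0, 0] = ref_values
    data[2, 0, 0] = lc_value
    ref = np.zeros((3, 2, 1), bool)
    ref[0, 0, 0] = ref[1, 0, 0] = True
    left = np.zeros((3, 2, 1), bool)
    left[2, 0, 0] = True
    right = np.zeros((3, 2, 1), bool)
    right[2, 1, 0] = True
    data[2, 1, 0] = 1.0
    return toy_volume(data), MaskSet(left, right, ref)


class TestSlicewiseNormalize:
    def test_reference_mean_is_100_on_every_covered_slice(self):
        spec = PhantomSpec(noise_sd=20.0, slice_drift_range=(0.8, 1.2), seed=1)
        vol, masks, _ = generate_phantom(spec)
        norm = slicewise_normalize(vol, masks)
        for z in range(norm.n_slices):
            ref_z = masks.reference[:, :, z]
            if ref_z.any():
                assert norm.data[:, :, z][ref_z].mean() == pytest.approx(100.0, abs=1e-9)

    def test_slice_already_at_100_is_unchanged(self):
        vol, masks = single_slice_setup((50.0, 150.0), 240.0)
        norm = slicewise_normalize(vol, masks)
        assert np.allclose(norm.data, vol.data)

    @pytest.mark.parametrize(
        "ref_values,lc_value,expected",
        [((50.0, 150.0), 240.0, 240.0), ((40.0, 60.0), 90.0, 180.0)],
    )
    def test_hand_computed_single_slice_factors(self, ref_values, lc_value, expected):
        vol, masks = single_slice_setup(ref_values, lc_value)
        norm = slicewise_normalize(vol, masks)
        assert norm.data[2, 0, 0] == pytest.approx(expected)

    def test_idempotence(self):
        spec = PhantomSpec(noise_sd=15.0, slice_drift_range=(0.85, 1.15), seed=2)
        vol, masks, _ = generate_phantom(spec)
        once = slicewise_normalize(vol, masks)
        twice = slicewise_normalize(once, masks)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_nonpositive_reference_mean_is_data_error(self):
        vol, masks = single_slice_setup((-60.0, 40.0), 90.0)
        with pytest.raises(DataError, match="slice 0"):
            slicewise_normalize(vol, masks)

    def test_search_voxels_without_reference_coverage_is_qc_error(self):
        data = np.ones((3, 2, 2))
        ref = np.zeros((3, 2, 2), bool)
        ref[0, :, 0] = True  # reference only on slice 0
        left = np.zeros((3, 2, 2), bool)
        left[1, 0, 1] = True  # LC candidate on uncovered slice 1
        right = np.zeros((3, 2, 2), bool)
        right[2, 0, 0] = True
        with pytest.raises(SliceCoverageError, match="slice 1"):
            slicewise_normalize(toy_volume(data), MaskSet(left, right, ref))

    def test_uncovered_noncandidate_slices_are_excluded(self):
        spec = PhantomSpec(noise_sd=0.0, slice_drift_range=(1.0, 1.0))
        vol, masks, _ = generate_phantom(spec)
        norm = slicewise_normalize(vol, masks)
        uncovered = [z for z in range(vol.n_slices) if not masks.reference[:, :, z].any()]
        assert uncovered  # the default geometry leaves edge slices uncovered
        for z in uncovered:
            assert np.allclose(norm.data[:, :, z], 0.0)


def brute_force_best_connected(values, space, k, connectivity=26):
    """Exhaustive maximum-total connected k-subset (oracle for tiny grids)."""
    offsets = _neighbor_offsets(connectivity)
    cand = [tuple(v) for v in np.argwhere(space)]

    def connected(subset):
        subset = set(subset)
        seen = {next(iter(subset))}
        frontier = list(seen)
        while frontier:
            v = frontier.pop()
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if nb in subset and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        return len(seen) == len(subset)

    best, best_total = None, -np.inf
    for subset in itertools.combinations(cand, k):
        if not connected(subset):
            continue
        total = sum(values[v] for v in subset)
        if total > best_total:
            best, best_total = subset, total
    return best, best_total


class TestSelection:
    def test_k1_reduces_to_argmax(self, rng):
        values = rng.random((5, 5, 3))
        vol = toy_volume(values)
        space = np.ones((5, 5, 3), bool)
        sel = select_lc_voxels(vol, space, k=1)
        assert tuple(sel[0]) == tuple(np.unravel_index(np.argmax(values), values.shape))

    def test_greedy_close_to_exhaustive_optimum_on_seeded_grids(self):
        """20 random 4x4x1 grids, k=3: greedy >= 95% of the brute-force
        optimum, with equality whenever the top-3 voxels are mutually
        contiguous."""
        offsets = _neighbor_offsets(26)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = rng.random((4, 4, 1))
            vol = toy_volume(values)
            space = np.ones((4, 4, 1), bool)
            sel = select_lc_voxels(vol, space, k=3)
            greedy_total = values[tuple(sel.T)].sum()
            _, opt_total = brute_force_best_connected(values, space, 3)
            assert greedy_total >= 0.95 * opt_total
            flat = np.argsort(values.ravel())[::-1][:3]
            top3 = [tuple(v) for v in np.array(np.unravel_index(flat, values.shape)).T]
            mutually_contiguous = all(
                any(
                    tuple(np.add(a, off)) == b
                    for off in offsets
                )
                for a, b in itertools.combinations(top3, 2)
            )
            if mutually_contiguous:
                assert greedy_total == pytest.approx(opt_total)

    def test_selection_lands_inside_planted_blob(self, noiseless_phantom):
        vol, masks, truth = noiseless_phantom
        norm = slicewise_normalize(vol, masks)
        sel = select_lc_voxels(norm, masks.lc_search_left, k=10)
        assert len(sel) == 10
        assert all(truth.lc_blob_left[tuple(v)] for v in sel)

    def test_selected_region_is_connected(self, rng):
        values = rng.random((8, 8, 4))
        vol = toy_volume(values)
        space = np.ones((8, 8, 4), bool)
        sel = select_lc_voxels(vol, space, k=10)
        _, total = brute_force_best_connected(
            values, np.zeros((8, 8, 4), bool), 0
        ) if False else (None, None)
        subset = {tuple(v) for v in sel}
        # BFS connectivity check under 26-adjacency
        offsets = _neighbor_offsets(26)
        seen = {next(iter(subset))}
        frontier = list(seen)
        while frontier:
            v = frontier.pop()
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if nb in subset and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        assert seen == subset

    def test_too_small_search_space_is_quantification_error(self, rng):
        vol = toy_volume(rng.random((3, 3, 1)))
        space = np.zeros((3, 3, 1), bool)
        space[0, 0, 0] = True
        with pytest.raises(QuantificationError):
            select_lc_voxels(vol, space, k=10)

    def test_deterministic_under_ties(self):
        vol = toy_volume(np.ones((4, 4, 1)))
        space = np.ones((4, 4, 1), bool)
        a = select_lc_voxels(vol, space, k=5)
        b = select_lc_voxels(vol, space, k=5)
        assert np.array_equal(a, b)


class TestLCRI:
    def test_noiseless_phantom_measures_exactly_120(self, noiseless_phantom):
        vol, masks, _ = noiseless_phantom
        m = quantify(vol, masks)
        assert m.lc_ri_left == pytest.approx(120.0, abs=1e-9)
        assert m.lc_ri_right == pytest.approx(120.0, abs=1e-9)
        assert m.lc_ri_mean == pytest.approx(120.0, abs=1e-9)

    def test_mean_is_average_of_sides(self, noiseless_phantom):
        vol, masks, truth = noiseless_phantom
        norm = slicewise_normalize(vol, masks)
        norm.data[truth.lc_blob_left] = 130.0
        norm.data[truth.lc_blob_right] = 110.0
        m = compute_lc_ri(norm, masks)
        assert (m.lc_ri_left, m.lc_ri_right) == (130.0, 110.0)
        assert m.lc_ri_mean == pytest.approx(120.0)

    def test_global_rescaling_invariance(self):
        spec = PhantomSpec(noise_sd=10.0, slice_drift_range=(0.9, 1.1), seed=6)
        vol, masks, _ = generate_phantom(spec)
        m1 = quantify(vol, masks)
        scaled = VolumeGrid(vol.data * 3.7, vol.voxel_size)
        m2 = quantify(scaled, masks)
        assert m1.lc_ri_mean == pytest.approx(m2.lc_ri_mean, abs=1e-9)
        assert np.array_equal(m1.lc_mask_left, m2.lc_mask_left)

    def test_masks_have_exactly_k_voxels(self, noiseless_phantom):
        vol, masks, _ = noiseless_phantom
        for k in (5, 10):
            m = quantify(vol, masks, k=k)
            assert len(m.lc_mask_left) == k and len(m.lc_mask_right) == k

    def test_json_roundtrip(self, noiseless_phantom, tmp_path):
        from coeruleus import LCMeasurement

        vol, masks, _ = noiseless_phantom
        m = quantify(vol, masks, subject_id="s1", session_id="0")
        path = tmp_path / "m.json"
        m.to_json(path)
        back = LCMeasurement.from_json(path)
        assert back.lc_ri_mean == m.lc_ri_mean
        assert np.array_equal(back.lc_mask_left, m.lc_mask_left)


class TestOverlapQC:
    def _measurement(self, voxels, shape=(8, 8, 4)):
        import coeruleus

        arr = np.array(sorted(voxels), dtype=int)
        return coeruleus.LCMeasurement(
            lc_ri_left=110.0,
            lc_ri_right=110.0,
            lc_ri_mean=110.0,
            lc_mask_left=arr,
            lc_mask_right=arr,
            grid_shape=shape,
            voxel_size=(0.7, 0.7, 1.8),
        )

    def test_identical_masks(self):
        vox = [(i, 0, 0) for i in range(8)] + [(0, 1, 0), (1, 1, 0)]
        m = self._measurement(vox)
        rep = mask_overlap_qc(m, m)
        assert rep.dice_left == 1.0 and rep.displacement_left_mm == 0.0
        assert not rep.flagged

    def test_disjoint_masks(self):
        a = self._measurement([(i, 0, 0) for i in range(8)] + [(0, 1, 0), (1, 1, 0)])
        b = self._measurement([(i, 4, 2) for i in range(8)] + [(0, 5, 2), (1, 5, 2)])
        rep = mask_overlap_qc(a, b)
        assert rep.dice_left == 0.0
        assert rep.flagged

    def test_half_overlap_is_dice_half(self):
        base = [(i, 0, 0) for i in range(5)]
        a = self._measurement(base + [(i, 1, 0) for i in range(5)])
        b = self._measurement(base + [(i, 2, 0) for i in range(5)])
        rep = mask_overlap_qc(a, b)
        assert rep.dice_left == pytest.approx(0.5)

    def test_displacement_in_millimetres(self):
        a = self._measurement([(i, 0, 0) for i in range(10)])
        b = self._measurement([(i, 0, 1) for i in range(10)])  # one slice down
        rep = mask_overlap_qc(a, b)
        assert rep.displacement_left_mm == pytest.approx(1.8)

    def test_grid_mismatch_is_usage_error(self):
        a = self._measurement([(i, 0, 0) for i in range(10)], shape=(8, 8, 4))
        b = self._measurement([(i, 0, 0) for i in range(10)], shape=(9, 8, 4))
        with pytest.raises(ValueError, match="same grid"):
            mask_overlap_qc(a, b)
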