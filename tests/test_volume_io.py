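import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsurv.volume_io import (
    AlignmentError,
    EmptyMaskError,
    SegmentationMask,
    TumorVOI,
    VolumeGrid,
    check_alignment,
    discretize,
    discretize_values,
    extract_voi,
    read_volume,
    resample_isotropic,
    write_volume,
)


class TestReadWrite:
    def test_round_trip_preserves_values_and_spacing(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = VolumeGrid(rng.normal(size=(10, 10, 10)), spacing=(0.5, 0.5, 3.0))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)

    def test_unit_spacing_round_trip(self, tmp_path):
        vol = VolumeGrid(np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        write_volume(vol, tmp_path / "v.nii")
        back = read_volume(tmp_path / "v.nii")
        assert back.shape == (10, 10, 10)
        assert back.spacing == (1.0, 1.0, 1.0)

    def test_zero_byte_file_raises_io_error(self, tmp_path):
        p = tmp_path / "empty.nii"
        p.write_bytes(b"")
        with pytest.raises(IOError):
            read_volume(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_volume(tmp_path / "nope.nii")

    def test_4d_image_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4))
        nib.save(img, tmp_path / "fourd.nii")
        with pytest.raises(ValueError, match="3D"):
            read_volume(tmp_path / "fourd.nii")

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            VolumeGrid(np.zeros((2, 2, 2)), spacing=(1, 0, 1))

    def test_nan_values_rejected(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            VolumeGrid(vals)


class TestAlignment:
    def test_identical_grids_pass(self):
        vol = VolumeGrid(np.zeros((10, 10, 10)))
        mask = SegmentationMask(np.ones((10, 10, 10)))
        assert check_alignment(vol, mask) == (vol, mask)

    def test_shape_mismatch_names_shape(self):
        vol = VolumeGrid(np.zeros((10, 10, 10)))
        mask = SegmentationMask(np.ones((10, 10, 9)))
        with pytest.raises(AlignmentError, match="shape"):
            check_alignment(vol, mask)

    def test_spacing_within_tolerance_passes(self):
        vol = VolumeGrid(np.zeros((5, 5, 5)), spacing=(1, 1, 1))
        mask = SegmentationMask(np.ones((5, 5, 5)), spacing=(1 + 1e-5, 1, 1))
        check_alignment(vol, mask)

    def test_spacing_beyond_tolerance_fails(self):
        vol = VolumeGrid(np.zeros((5, 5, 5)), spacing=(1, 1, 1))
        mask = SegmentationMask(np.ones((5, 5, 5)), spacing=(1.01, 1, 1))
        with pytest.raises(AlignmentError, match="spacing"):
            check_alignment(vol, mask)


class TestResample:
    def test_constant_volume_stays_constant(self):
        vol = VolumeGrid(np.full((10, 10, 10), 42.0), spacing=(1, 2, 0.7))
        out = resample_isotropic(vol, 1.5)
        np.testing.assert_allclose(out.values, 42.0)
        assert out.spacing == (1.5, 1.5, 1.5)

    def test_downsample_halves_shape(self):
        vol = VolumeGrid(np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        assert resample_isotropic(vol, 2.0).shape == (5, 5, 5)

    def test_linear_ramp_interpolates_exactly(self):
        # ramp along x; 2x finer grid must hit the half-step values
        x = np.arange(8, dtype=float)
        vol = VolumeGrid(np.broadcast_to(x[:, None, None], (8, 8, 8)).copy())
        out = resample_isotropic(vol, 0.5, method="linear")
        expect = np.arange(out.shape[0]) * 0.5
        expect = np.minimum(expect, 7.0)  # beyond the last sample: edge value
        np.testing.assert_allclose(out.values[:, 4, 4], expect, atol=1e-9)

    def test_mask_resampling_is_nearest_and_binary(self):
        mask = SegmentationMask(
            np.pad(np.ones((4, 4, 4)), 3).astype(bool), spacing=(1, 1, 1)
        )
        out = resample_isotropic(mask, 0.5)
        assert out.values.dtype == bool
        assert out.n_foreground == 8 ** 3

    def test_bad_spacing_rejected(self):
        vol = VolumeGrid(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.0)


class TestVOI:
    def test_voi_counts_foreground(self):
        vals = np.arange(27, dtype=float).reshape(3, 3, 3)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask.ravel()[[0, 3, 5, 9, 13, 20, 26]] = True
        voi = extract_voi(VolumeGrid(vals), SegmentationMask(mask))
        assert voi.n_voxels == 7
        np.testing.assert_array_equal(voi.intensities, [0, 3, 5, 9, 13, 20, 26])

    def test_full_mask_gives_flattened_volume(self):
        vals = np.arange(8, dtype=float).reshape(2, 2, 2)
        voi = extract_voi(VolumeGrid(vals), SegmentationMask(np.ones((2, 2, 2))))
        np.testing.assert_array_equal(voi.intensities, vals.ravel())

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_voi(
                VolumeGrid(np.zeros((3, 3, 3))),
                SegmentationMask(np.zeros((3, 3, 3))),
            )


class TestDiscretize:
    def test_two_bins_splits_at_midpoint(self):
        voi = TumorVOI(np.array([0.0, 1.0, 2.0, 3.0]), None, (1, 1, 1), (4, 1, 1))
        np.testing.assert_array_equal(
            discretize(voi, 2).foreground_levels, [1, 1, 2, 2]
        )

    def test_constant_voi_maps_to_level_one(self):
        voi = TumorVOI(np.full(5, 3.3), None, (1, 1, 1), (5, 1, 1))
        np.testing.assert_array_equal(discretize(voi, 64).foreground_levels, 1)

    def test_identity_binning_at_matching_bin_count(self):
        voi = TumorVOI(np.arange(32, dtype=float), None, (1, 1, 1), (32, 1, 1))
        np.testing.assert_array_equal(
            discretize(voi, 32).foreground_levels, np.arange(1, 33)
        )

    def test_fewer_than_two_bins_rejected(self):
        with pytest.raises(ValueError):
            discretize_values(np.arange(4.0), 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=50
        ),
        st.sampled_from([2, 32, 64, 128]),
    )
    def test_monotone_and_bounded(self, values, n_bins):
        x = np.asarray(values)
        g = discretize_values(x, n_bins)
        assert g.min() >= 1 and g.max() <= n_bins
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(g[order]) >= 0)
        assert len(np.unique(g)) <= n_bins
        # extremes pin to the first and last level
        if x.max() > x.min():
            assert g[np.argmin(x)] == 1 and g[np.argmax(x)] == n_bins
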