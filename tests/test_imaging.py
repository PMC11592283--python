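"""Volume model, HU windowing, coordinate mapping, NIfTI/DICOM round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedplan.errors import InputError, ValidationError
from pedplan.imaging import (
    LabelMap,
    Volume,
    read_labelmap,
    read_volume,
    resample_to,
    to_physical,
    to_voxel,
    window_hu,
    write_labelmap,
    write_volume,
)


def make_volume(shape=(4, 5, 6), spacing=(1, 1, 2), origin=(5, 5, 5)):
    data = np.arange(np.prod(shape), dtype=np.float32).reshape(shape)
    return Volume(data, spacing, origin)


class TestWindowing:
    @pytest.mark.parametrize(
        "hu,expected",
        [(150.0, 0.5), (-600.0, 0.0), (900.0, 1.0), (-1000.0, 0.0), (525.0, 0.75)],
    )
    def test_default_window_maps_hu_linearly_with_clamp(self, hu, expected):
        v = Volume(np.full((1, 1, 1), hu, dtype=np.float32))
        assert window_hu(v).data[0, 0, 0] == pytest.approx(expected, abs=1e-6)

    def test_windowing_is_monotone_in_hu(self, rng):
        hu = np.sort(rng.uniform(-2000, 2000, 100)).astype(np.float32)
        out = window_hu(Volume(hu.reshape(1, 1, -1))).data.ravel()
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0 and out.max() <= 1

    def test_unit_window_is_identity_on_windowed_data(self, rng):
        v = window_hu(Volume(rng.uniform(-2000, 2000, (3, 3, 3)).astype(np.float32)))
        again = window_hu(v, center=0.5, width=1.0)
        np.testing.assert_allclose(again.data, v.data, atol=1e-6)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            window_hu(make_volume(), width=0.0)


class TestCoordinates:
    def test_origin_is_first_voxel_center(self):
        v = make_volume()
        np.testing.assert_allclose(to_physical((0, 0, 0), v), (5, 5, 5))

    def test_unit_step_in_x(self):
        v = make_volume(spacing=(1, 1, 1))
        idx = to_voxel((6, 5, 5), v)
        assert tuple(idx) == (1, 0, 0) and idx.inside

    def test_out_of_grid_point_is_flagged_not_raised(self):
        v = make_volume()
        idx = to_voxel((1000, 0, 0), v)
        assert not idx.inside

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 3), st.integers(0, 4), st.integers(0, 5))
    def test_round_trip_identity_on_grid(self, i, j, k):
        v = make_volume()
        back = to_voxel(to_physical((i, j, k), v), v)
        assert tuple(back) == (i, j, k) and back.inside


class TestNiftiIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        v = Volume(rng.random((3, 4, 5)).astype(np.float32), (1, 1, 2), (1, 2, 3))
        p = tmp_path / "v.nii.gz"
        write_volume(v, p)
        v2 = read_volume(p)
        np.testing.assert_array_equal(v2.data, v.data)
        assert v2.spacing == v.spacing and v2.origin == v.origin

    def test_lps_volume_reoriented_to_ras(self, tmp_path, rng):
        import nibabel as nib

        data = rng.random((3, 4, 5)).astype(np.float32)
        # write in LPS orientation: flip x and y axes and affine signs
        aff = np.diag([-1.0, -1.0, 2.0, 1.0])
        aff[:3, 3] = [2.0, 3.0, 3.0]
        nib.save(nib.Nifti1Image(data[::-1, ::-1, :], aff), str(tmp_path / "lps.nii.gz"))
        v = read_volume(tmp_path / "lps.nii.gz")
        np.testing.assert_allclose(v.data, data, atol=1e-6)

    def test_labelmap_round_trip(self, tmp_path):
        lm = LabelMap(
            np.array([[[0, 2], [21, 0]]], dtype=np.int16),
            (1, 1, 1), (0, 0, 0), {2: "L2", 21: "L2_left_pedicle"},
        )
        write_labelmap(lm, tmp_path / "l.nii.gz")
        lm2 = read_labelmap(tmp_path / "l.nii.gz")
        np.testing.assert_array_equal(lm2.data, lm.data)

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_corrupt_file_is_input_error(self, tmp_path):
        p = tmp_path / "bad.nii"
        p.write_bytes(b"this is not a nifti file")
        with pytest.raises(InputError):
            read_volume(p)


def _write_dicom_slice(path, z, rows=8, cols=8, skip_uid=False):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SeriesInstanceUID = "1.2.3.4"
    ds.SOPInstanceUID = pydicom.uid.generate_uid()
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [1.0, 1.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.SliceThickness = 1.0
    ds.RescaleSlope, ds.RescaleIntercept = 1.0, -1024.0
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    arr = np.full((rows, cols), 1024 + int(z), dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicom:
    def test_series_read_with_rescale_to_hu(self, tmp_path):
        for z in range(4):
            _write_dicom_slice(tmp_path / f"s{z}.dcm", z)
        v = read_volume(tmp_path, format="dicom_dir")
        assert v.shape == (8, 8, 4)
        assert v.spacing == (1.0, 1.0, 1.0)
        # HU = stored + intercept; slice z stores 1024 + z
        np.testing.assert_allclose(np.unique(v.data[:, :, 0]), [0.0])
        np.testing.assert_allclose(np.unique(v.data[:, :, 3]), [3.0])

    def test_missing_intermediate_slice_rejected(self, tmp_path):
        for z in (0, 1, 3):  # gap at z=2
            _write_dicom_slice(tmp_path / f"s{z}.dcm", z)
        with pytest.raises(ValidationError):
            read_volume(tmp_path, format="dicom_dir")


class TestResample:
    def test_identity_resample_preserves_data(self, rng):
        v = Volume(rng.random((4, 4, 4)).astype(np.float32))
        out = resample_to(v, v)
        np.testing.assert_allclose(out.data, v.data, atol=1e-6)

    def test_labels_use_nearest_neighbor(self):
        lm = LabelMap(np.array([[[2, 6]]], dtype=np.int16), label_scheme={2: "a", 6: "b"})
        fine = Volume(np.zeros((1, 1, 4), dtype=np.float32), (1, 1, 0.5), (0, 0, 0))
        out = resample_to(lm, fine)
        assert set(np.unique(out.data)) <= {0, 2, 6}  # no interpolated label values


class TestValidation:
    def test_labels_must_appear_in_scheme(self):
        with pytest.raises(ValidationError):
            LabelMap(np.array([[[7]]], dtype=np.int16), label_scheme={2: "L2"})

    def test_volume_needs_positive_spacing(self):
        with pytest.raises(ValidationError):
            Volume(np.zeros((2, 2, 2), dtype=np.float32), spacing=(1, 0, 1))
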