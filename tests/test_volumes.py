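"""Volume IO, Hounsfield-window segmentation, reference sampling, brushes."""

import numpy as np
import pydicom
import pytest
from hypothesis import given, settings, strategies as st
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

import voxflap as vf
from voxflap.errors import EmptyROIError, UnsupportedInputError, VolumeFormatError


def _flat_volume(values, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(values, dtype=np.float32).reshape(-1, 1, 1)
    return vf.ScalarVolume(data=data, spacing=spacing)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def test_nifti_roundtrip_preserves_data_and_geometry(tmp_path, small_phantom):
    vol, _ = small_phantom
    path = str(tmp_path / "vol.nii.gz")
    vf.write_nifti(vol, path)
    back = vf.read_volume(path)
    np.testing.assert_array_equal(back.data, vol.data)
    assert back.spacing == vol.spacing
    assert back.origin == vol.origin


def _write_dicom_slice(path, z, pixel_value, orientation=(1, 0, 0, 0, 1, 0), frame_uid="1.2.3"):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.FrameOfReferenceUID = frame_uid
    ds.ImageOrientationPatient = list(orientation)
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.PixelSpacing = [0.8, 0.6]  # [row (y), col (x)]
    ds.SliceThickness = 1.0
    ds.Rows = 4
    ds.Columns = 4
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    arr = np.full((4, 4), pixel_value, dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def test_dicom_series_applies_rescale(tmp_path):
    # stored value 1224 with intercept -1024 -> 200 HU
    d = tmp_path / "series"
    d.mkdir()
    _write_dicom_slice(d / "s0.dcm", 0.0, 1224)
    _write_dicom_slice(d / "s1.dcm", 1.0, 1224)
    vol = vf.read_volume(str(d))
    assert vol.shape == (4, 4, 2)
    np.testing.assert_allclose(vol.data, 200.0)
    assert vol.spacing == (0.6, 0.8, 1.0)  # (x=col, y=row, z=slice)


def test_dicom_inconsistent_orientation_is_a_format_error(tmp_path):
    d = tmp_path / "series"
    d.mkdir()
    _write_dicom_slice(d / "s0.dcm", 0.0, 100)
    _write_dicom_slice(d / "s1.dcm", 1.0, 100, orientation=(0, 1, 0, 1, 0, 0))
    with pytest.raises(VolumeFormatError):
        vf.read_volume(str(d))


def test_read_volume_rejects_4d(tmp_path):
    import nibabel as nib

    path = str(tmp_path / "vol4d.nii.gz")
    nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4)), path)
    with pytest.raises(UnsupportedInputError):
        vf.read_volume(path)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def test_threshold_window_is_inclusive_muscle_window():
    vol = _flat_volume([-80, 205, 950, 1200, 180, 230])
    mask = vf.threshold_segment(vol, vf.SegmentationParams(180, 230))
    np.testing.assert_array_equal(mask.data.ravel(), [0, 1, 0, 0, 1, 1])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    values=st.lists(st.integers(-1100, 1300), min_size=1, max_size=60),
    lo=st.integers(-500, 900),
    width=st.integers(1, 600),
)
def test_threshold_equals_per_voxel_predicate(values, lo, width):
    """With smoothing off and no size filter, the mask is exactly the
    per-voxel predicate hu_lo <= v <= hu_hi."""
    hi = lo + width
    vol = _flat_volume(values)
    mask = vf.threshold_segment(vol, vf.SegmentationParams(lo, hi))
    expected = [1 if lo <= v <= hi else 0 for v in values]
    assert mask.data.ravel().tolist() == expected


def test_threshold_component_filter_removes_small_islands():
    data = np.zeros((12, 3, 3), dtype=np.float32)
    data[1:6, 1, 1] = 200.0  # 5-voxel blob
    data[9:11, 1, 1] = 200.0  # 2-voxel island
    vol = vf.ScalarVolume(data=data)
    mask = vf.threshold_segment(vol, vf.SegmentationParams(180, 230, min_component_voxels=3))
    assert mask.data[1:6, 1, 1].sum() == 5
    assert mask.data[9:11, 1, 1].sum() == 0


def test_threshold_size_filter_is_idempotent():
    rng = np.random.default_rng(7)
    data = (rng.random((20, 20, 20)) < 0.2).astype(np.float32) * 200.0
    vol = vf.ScalarVolume(data=data)
    params = vf.SegmentationParams(180, 230, min_component_voxels=4)
    once = vf.threshold_segment(vol, params)
    again = vf.threshold_segment(
        vf.ScalarVolume(data=once.data.astype(np.float32) * 200.0), params
    )
    np.testing.assert_array_equal(once.data, again.data)


def test_invalid_window_rejected():
    with pytest.raises(UnsupportedInputError):
        vf.SegmentationParams(230, 180)


# ---------------------------------------------------------------------------
# Reference-range sampling
# ---------------------------------------------------------------------------


def test_reference_sample_reproduces_vessel_window():
    """A 1000 HU aortic-style sample with the default half-width yields the
    standard 900-1100 HU contrast window."""
    vol = vf.ScalarVolume(data=np.full((10, 10, 10), 1000.0, dtype=np.float32))
    mean, params = vf.sample_reference_range(vol, (5, 5, 5), 3.0)
    assert mean == 1000.0
    assert (params.hu_lo, params.hu_hi) == (900.0, 1100.0)


def test_reference_sample_custom_half_width():
    vol = vf.ScalarVolume(data=np.zeros((8, 8, 8), dtype=np.float32))
    _, params = vf.sample_reference_range(vol, (4, 4, 4), 2.0, half_width=50.0)
    assert (params.hu_lo, params.hu_hi) == (-50.0, 50.0)


def test_reference_sample_outside_volume_raises():
    vol = vf.ScalarVolume(data=np.zeros((8, 8, 8), dtype=np.float32))
    with pytest.raises(EmptyROIError):
        vf.sample_reference_range(vol, (100, 100, 100), 2.0)


# ---------------------------------------------------------------------------
# Brush edits
# ---------------------------------------------------------------------------


def _tube_mask_with_gap():
    data = np.zeros((20, 5, 5), dtype=np.uint8)
    data[2:9, 2, 2] = 1
    data[11:18, 2, 2] = 1  # 2-voxel gap at x = 9, 10
    return vf.LabelMask(data=data, spacing=(1, 1, 1), origin=(0, 0, 0), name="vessels")


def test_fill_stroke_bridges_gap_to_connected_tube():
    from scipy import ndimage

    mask = _tube_mask_with_gap()
    _, n_before = ndimage.label(mask.data)
    assert n_before == 2
    stroke = vf.BrushStroke(mode="fill", centers=((8, 2, 2), (12, 2, 2)), radius=1.0)
    out = vf.apply_brush(mask, stroke)
    _, n_after = ndimage.label(out.data)  # default structure = 6-connectivity
    assert n_after == 1


def test_erase_stroke_covering_everything_empties_mask():
    mask = _tube_mask_with_gap()
    stroke = vf.BrushStroke(mode="erase", centers=((0, 2, 2), (19, 2, 2)), radius=10.0)
    assert vf.apply_brush(mask, stroke).count() == 0


def test_fill_then_erase_over_empty_region_restores_mask():
    mask = _tube_mask_with_gap()
    centers = ((2, 4, 4), (18, 4, 4))  # disjoint from the tube support
    filled = vf.apply_brush(mask, vf.BrushStroke("fill", centers, 0.9))
    restored = vf.apply_brush(filled, vf.BrushStroke("erase", centers, 0.9))
    np.testing.assert_array_equal(restored.data, mask.data)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    cx=st.floats(0, 19), cy=st.floats(0, 4), cz=st.floats(0, 4),
    radius=st.floats(0.2, 6.0),
)
def test_brush_monotonicity(cx, cy, cz, radius):
    """Fill never shrinks a mask; erase never grows it."""
    mask = _tube_mask_with_gap()
    filled = vf.apply_brush(mask, vf.BrushStroke("fill", ((cx, cy, cz),), radius))
    erased = vf.apply_brush(mask, vf.BrushStroke("erase", ((cx, cy, cz),), radius))
    assert np.all(filled.data >= mask.data)
    assert np.all(erased.data <= mask.data)


def test_dice_of_identical_masks_is_one(small_phantom):
    _, truth = small_phantom
    assert vf.dice(truth.muscle, truth.muscle) == 1.0
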