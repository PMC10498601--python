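"""CT-like scalar volumes and Hounsfield-range segmentation.

The imaging front end of the pipeline: read a CT(A) volume from a DICOM series
or NIfTI file, segment each anatomical structure by an inclusive Hounsfield
window (muscle is typically found around 180-230 HU, contrast-filled vessels
around 900-1100 HU depending on contrast saturation), derive the vessel window
by sampling a reference region in the descending aorta, and apply scripted
fill/erase brush strokes to repair segmentation gaps reproducibly.

Conventions: world units are millimetres everywhere; the world coordinate of
voxel index (i, j, k) is ``origin + index * spacing`` (voxel-center
convention); Hounsfield windows are inclusive at both ends.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Literal

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from ._raster import polyline_mask
from .errors import (
    EmptyROIError,
    UnsupportedInputError,
    VolumeFormatError,
)

logger = logging.getLogger("voxflap")

_GEOM_TOL = 1e-5


@dataclass
class ScalarVolume:
    """A 3-D scalar image in Hounsfield units with physical geometry.

    Parameters
    ----------
    data
        3-D array of HU values, indexed ``[x, y, z]``.
    spacing
        Voxel size (sx, sy, sz) in mm; strictly positive.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    axes
        Free-text axis convention label (kept for provenance only).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "xyz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise UnsupportedInputError(
                f"volume data must be 3-D with positive dimensions, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise UnsupportedInputError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center world coordinates (mm)."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.data.shape[i])
            for i in range(3)
        )

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, float) * np.asarray(self.spacing)

    def same_geometry(self, other: "ScalarVolume | LabelMask", tol: float = _GEOM_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelMask:
    """Binary mask of one structure, sharing a source volume's geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    name: str = "other"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise UnsupportedInputError(f"mask must be 3-D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise UnsupportedInputError(f"mask values must be 0/1, found {vals[:5]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @classmethod
    def from_volume(cls, vol: ScalarVolume, data: np.ndarray, name: str = "other") -> "LabelMask":
        if data.shape != vol.shape:
            raise UnsupportedInputError(
                f"mask shape {data.shape} does not match volume shape {vol.shape}"
            )
        return cls(data=data, spacing=vol.spacing, origin=vol.origin, name=name)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.data.shape[i]) for i in range(3)
        )

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))

    def centroid(self) -> np.ndarray:
        """World centroid (mm) of the mask's voxel centers."""
        if not self.data.any():
            raise EmptyROIError(f"mask '{self.name}' is empty; no centroid")
        idx = np.argwhere(self.data > 0).mean(axis=0)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class SegmentationParams:
    """Inclusive Hounsfield window plus optional mask post-processing.

    ``smoothing_sigma`` is the Gaussian kernel width in mm applied to the
    binary mask (re-binarized at 0.5); ``min_component_voxels`` removes
    connected components (6-connectivity) below that size.
    """

    hu_lo: float
    hu_hi: float
    smoothing_sigma: float = 0.0
    min_component_voxels: int = 0

    def __post_init__(self) -> None:
        if not self.hu_lo < self.hu_hi:
            raise UnsupportedInputError(
                f"hu_lo ({self.hu_lo}) must be < hu_hi ({self.hu_hi})"
            )
        if self.smoothing_sigma < 0:
            raise UnsupportedInputError("smoothing_sigma must be >= 0")
        if self.min_component_voxels < 0:
            raise UnsupportedInputError("min_component_voxels must be >= 0")


@dataclass(frozen=True)
class BrushStroke:
    """A scripted fill/erase stroke: a capsule swept along a polyline.

    A reproducible stand-in for interactive freeform brush edits; strokes are
    recorded in the pipeline config so every mask edit is replayable.
    """

    mode: Literal["fill", "erase"]
    centers: tuple[tuple[float, float, float], ...]
    radius: float

    def __post_init__(self) -> None:
        if self.mode not in ("fill", "erase"):
            raise UnsupportedInputError(f"brush mode must be fill|erase, got {self.mode!r}")
        if len(self.centers) < 1:
            raise UnsupportedInputError("brush stroke needs at least one center")
        if self.radius <= 0:
            raise UnsupportedInputError("brush radius must be > 0")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_volume(path: str, format: str | None = None) -> ScalarVolume:
    """Read a CT-like scalar volume from a DICOM series directory or NIfTI file.

    DICOM rescale slope/intercept is applied so values are in HU. The format is
    inferred from the path when not given: a directory is read as a DICOM
    series, a ``.nii``/``.nii.gz`` file as NIfTI.
    """
    if format is None:
        if os.path.isdir(path):
            format = "dicom_series"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise UnsupportedInputError(f"cannot infer volume format from path {path!r}")
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise UnsupportedInputError(f"unknown format {format!r}")


def _read_nifti(path: str) -> ScalarVolume:
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise UnsupportedInputError(f"expected a 3-D scalar image, got {img.ndim}-D")
    aff = np.asarray(img.affine, float)
    rot = aff[:3, :3]
    diag = np.diag(rot)
    if np.abs(rot - np.diag(diag)).max() > 1e-4 * max(1.0, np.abs(diag).max()):
        raise UnsupportedInputError(
            "only axis-aligned (diagonal affine) NIfTI volumes are supported"
        )
    if np.any(diag <= 0):
        raise UnsupportedInputError(
            "only positively oriented NIfTI volumes are supported (negative axis scale)"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    return ScalarVolume(data=data, spacing=tuple(diag), origin=tuple(aff[:3, 3]))


def write_nifti(obj: ScalarVolume | LabelMask, path: str) -> None:
    """Write a volume or mask as NIfTI with a diagonal mm affine."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(obj.spacing)
    aff[:3, 3] = obj.origin
    data = obj.data
    if isinstance(obj, LabelMask):
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, aff), path)


def _read_dicom_series(path: str) -> ScalarVolume:
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no DICOM image slices found under {path}")

    frames = {getattr(ds, "FrameOfReferenceUID", None) for ds in slices}
    if len(frames) > 1:
        raise VolumeFormatError("DICOM series mixes multiple frames of reference")

    iop0 = np.asarray(slices[0].ImageOrientationPatient, float)
    for ds in slices[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop0, atol=1e-4):
            raise VolumeFormatError("DICOM series has inconsistent slice orientations")
    if not (np.allclose(iop0[:3], (1, 0, 0), atol=1e-3) and np.allclose(iop0[3:], (0, 1, 0), atol=1e-3)):
        raise UnsupportedInputError(
            "only axis-aligned axial DICOM series are supported "
            f"(ImageOrientationPatient={iop0.tolist()})"
        )

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0 or (dz.max() - dz.min()) > 1e-3:
            raise VolumeFormatError("DICOM slice positions are not uniformly spaced")
        slice_spacing = float(dz.mean())
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    ps = [np.asarray(ds.PixelSpacing, float) for ds in slices]
    if any(not np.allclose(p, ps[0], atol=1e-6) for p in ps[1:]):
        raise VolumeFormatError("DICOM series has inconsistent pixel spacing")
    row_sp, col_sp = float(ps[0][0]), float(ps[0][1])

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        inter = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(slope * arr + inter)  # pixel_array is (rows=y, cols=x)
    data = np.stack([p.T for p in planes], axis=2)  # -> (x, y, z)
    ipp0 = np.asarray(slices[0].ImagePositionPatient, float)
    return ScalarVolume(
        data=data,
        spacing=(col_sp, row_sp, slice_spacing),
        origin=tuple(ipp0),
    )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def threshold_segment(
    vol: ScalarVolume, params: SegmentationParams, name: str = "other"
) -> LabelMask:
    """Segment by inclusive HU window with optional smoothing and size filter.

    The mask is 1 exactly where ``hu_lo <= HU <= hu_hi``; with
    ``smoothing_sigma > 0`` the binary mask is Gaussian-smoothed (sigma in mm,
    converted per axis to voxels) and re-binarized at 0.5; components smaller
    than ``min_component_voxels`` are then removed.
    """
    mask = (vol.data >= params.hu_lo) & (vol.data <= params.hu_hi)
    if params.smoothing_sigma > 0:
        sigma_vox = [params.smoothing_sigma / s for s in vol.spacing]
        smoothed = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma_vox)
        mask = smoothed >= 0.5
    if params.min_component_voxels > 0:
        mask = _remove_small_components(mask, params.min_component_voxels)
    if not mask.any():
        logger.warning(
            "threshold_segment(%s): window [%g, %g] produced an empty mask",
            name,
            params.hu_lo,
            params.hu_hi,
        )
    return LabelMask.from_volume(vol, mask, name=name)


def _remove_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    # 6-connectivity; components of exactly min_voxels are kept.
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labels]


def sample_reference_range(
    vol: ScalarVolume,
    roi_center,
    roi_radius: float,
    half_width: float = 100.0,
) -> tuple[float, SegmentationParams]:
    """Derive a HU window from a spherical reference ROI.

    Emulates sampling the descending aorta for its average contrast
    attenuation: the returned window is ``[mean - half_width, mean +
    half_width]``; the default half-width of 100 HU turns a 1000 HU aortic
    sample into the standard 900-1100 HU vessel window.
    """
    roi_center = np.asarray(roi_center, float)
    xs, ys, zs = vol.axis_centers()
    d2 = (
        (xs[:, None, None] - roi_center[0]) ** 2
        + (ys[None, :, None] - roi_center[1]) ** 2
        + (zs[None, None, :] - roi_center[2]) ** 2
    )
    sel = d2 <= roi_radius**2
    if not sel.any():
        raise EmptyROIError(
            f"spherical ROI at {roi_center.tolist()} (r={roi_radius} mm) contains no voxels"
        )
    mean = float(vol.data[sel].mean())
    return mean, SegmentationParams(hu_lo=mean - half_width, hu_hi=mean + half_width)


def apply_brush(mask: LabelMask, stroke: BrushStroke) -> LabelMask:
    """Apply one scripted fill/erase capsule stroke; geometry is unchanged."""
    out = mask.data.astype(bool).copy()
    xs, ys, zs = mask.axis_centers()
    polyline_mask(xs, ys, zs, stroke.centers, stroke.radius, out, stroke.mode == "fill")
    return LabelMask(data=out, spacing=mask.spacing, origin=mask.origin, name=mask.name)


def dice(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks (1.0 = identical)."""
    da = (a.data if isinstance(a, LabelMask) else np.asarray(a)) > 0
    db = (b.data if isinstance(b, LabelMask) else np.asarray(b)) > 0
    na, nb = int(da.sum()), int(db.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((da & db).sum()) / (na + nb)
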