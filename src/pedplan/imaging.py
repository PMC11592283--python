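"""Volume/label data model, coordinate mapping, NIfTI/DICOM I/O, HU windowing.

Conventions used throughout the package:

* the voxel array is indexed ``data[i, j, k]`` with ``i`` increasing to the
  patient's right (R), ``j`` to anterior (A) and ``k`` to superior (S) —
  RAS+ with axis-aligned grids;
* voxel indices are 0-based; a voxel's physical position is the position of
  its *center*: ``point = origin + index * spacing`` (mm);
* Hounsfield-unit volumes are mapped to ``[0, 1]`` by linear window/level
  clamping before any network sees them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

from pedplan.errors import InputError, ValidationError

__all__ = [
    "Volume",
    "LabelMap",
    "VoxelIndex",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "window_hu",
    "to_physical",
    "to_voxel",
    "resample_to",
]


@dataclasses.dataclass(frozen=True)
class Volume:
    """A 3D scalar image on an axis-aligned RAS+ grid.

    Parameters
    ----------
    data
        3D array of intensities; HU before windowing, unitless in [0, 1]
        after.
    spacing
        Voxel size (sx, sy, sz) in mm; all components positive.
    origin
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValidationError(
                f"volume data must be 3D with positive extents, got shape {data.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValidationError(f"origin must have 3 components, got {self.origin}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, spacing=self.spacing, origin=self.origin)

    def same_grid(self, other: "Volume | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclasses.dataclass(frozen=True)
class LabelMap:
    """Integer labels on the same grid as a :class:`Volume`.

    ``label_scheme`` maps every non-zero integer present in ``data`` to a
    semantic name (0 is always background).  The conventional scheme used by
    the phantom generator and the segmenter is: 2..6 = L2..S1 vertebra
    (body + posterior elements), ``10*v + 1/2`` = left/right pedicle of
    vertebra ``v``, ``10*v + 3/4`` = left/right superior facet region.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_scheme: Mapping[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValidationError(f"label data must be 3D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValidationError(f"label data must be integer, got dtype {data.dtype}")
        if data.min() < 0:
            raise ValidationError("labels must be non-negative")
        present = set(np.unique(data).tolist()) - {0}
        missing = present - set(int(k) for k in self.label_scheme)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from label_scheme")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "label_scheme", dict(self.label_scheme))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, labels) -> np.ndarray:
        """Binary mask of the union of the given label ids."""
        return np.isin(self.data, np.asarray(list(labels)))

    def geometry(self) -> Volume:
        """A zero Volume on this grid (geometry carrier)."""
        return Volume(np.zeros(self.shape, dtype=np.float32), self.spacing, self.origin)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

class VoxelIndex(tuple):
    """Integer voxel index triple with an ``inside`` flag.

    Behaves as a plain ``(i, j, k)`` tuple; ``inside`` records whether the
    physical point fell within the grid (out-of-grid lookups are flagged,
    never raised).
    """

    inside: bool

    def __new__(cls, idx, inside: bool = True):
        self = super().__new__(cls, tuple(int(i) for i in idx))
        self.inside = bool(inside)
        return self


def to_physical(idx, v: Volume) -> np.ndarray:
    """Physical position (mm) of the center of voxel ``idx`` (0-based)."""
    idx = np.asarray(idx, dtype=float)
    return np.asarray(v.origin) + idx * np.asarray(v.spacing)


def to_voxel(p, v: Volume) -> VoxelIndex:
    """Nearest voxel index containing physical point ``p`` (mm).

    Out-of-grid points return a flagged result (``result.inside`` is False)
    with the index clipped to the grid, rather than raising.
    """
    cont = (np.asarray(p, dtype=float) - np.asarray(v.origin)) / np.asarray(v.spacing)
    idx = np.rint(cont).astype(int)
    shape = np.asarray(v.shape)
    inside = bool(np.all(idx >= 0) and np.all(idx < shape))
    return VoxelIndex(np.clip(idx, 0, shape - 1), inside=inside)


def continuous_index(p, v: Volume) -> np.ndarray:
    """Fractional voxel coordinates of physical point ``p`` (mm)."""
    return (np.asarray(p, dtype=float) - np.asarray(v.origin)) / np.asarray(v.spacing)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def window_hu(v: Volume, center: float = 150.0, width: float = 1500.0) -> Volume:
    """Map HU to [0, 1] by linear window/level clamping.

    ``out = clip((hu - (center - width/2)) / width, 0, 1)``.  The default
    window (center 150 HU, width 1500 HU) spans [-600, 900] HU, placing soft
    tissue low and trabecular/cortical bone high in the unit range.
    """
    if width <= 0:
        raise ValidationError(f"window width must be > 0, got {width}")
    lo = center - width / 2.0
    out = np.clip((v.data.astype(np.float32) - lo) / width, 0.0, 1.0)
    return v.with_data(out)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _ras_affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _from_nifti(img) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.as_closest_canonical(img)  # reorient to RAS+
    aff = img.affine
    # after canonicalization the affine is axis-aligned up to tiny shears
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-4):
        raise ValidationError("oblique NIfTI grids are not supported; resample first")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(s) for s in np.diag(rot))
    origin = tuple(float(o) for o in aff[:3, 3])
    return data, spacing, origin


def read_volume(path, format: str | None = None) -> Volume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    The result is always RAS+ oriented regardless of on-disk orientation;
    spacing and origin come from the headers.  ``format`` may be ``"nifti"``
    or ``"dicom_dir"``; by default it is inferred from the path.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such input: {path}")
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as e:  # nibabel raises various types on corrupt files
            raise InputError(f"cannot read NIfTI volume {path}: {e}") from e
        data, spacing, origin = _from_nifti(img)
        return Volume(data.astype(np.float32), spacing, origin)
    if format == "dicom_dir":
        return _read_dicom_series(path)
    raise ValidationError(f"unknown format {format!r}")


def write_volume(v: Volume, path) -> None:
    """Write a Volume as NIfTI (.nii or .nii.gz) with an RAS+ affine."""
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _ras_affine(v.spacing, v.origin))
    nib.save(img, str(path))


def read_labelmap(path, label_scheme: Mapping[int, str] | None = None) -> LabelMap:
    """Read an integer label map from NIfTI; labels round to nearest int."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such input: {path}")
    try:
        img = nib.load(str(path))
    except Exception as e:
        raise InputError(f"cannot read NIfTI labels {path}: {e}") from e
    data, spacing, origin = _from_nifti(img)
    labels = np.rint(data).astype(np.int32)
    if label_scheme is None:
        label_scheme = {int(v): f"label_{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelMap(labels, spacing, origin, label_scheme)


def write_labelmap(lm: LabelMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(lm.data, dtype=np.int16), _ras_affine(lm.spacing, lm.origin))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(dirpath: Path) -> Volume:
    import pydicom

    files = sorted(p for p in dirpath.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise InputError(f"no readable DICOM slices in {dirpath}")
    uids = {getattr(ds, "SeriesInstanceUID", "") for ds in slices}
    if len(uids) > 1:
        raise InputError(f"ambiguous DICOM directory {dirpath}: {len(uids)} series found")

    first = slices[0]
    orient = np.asarray(getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    row, col = orient[:3], orient[3:]
    normal = np.cross(row, col)
    slices.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))

    zs = [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)) for ds in slices]
    dzs = np.diff(zs)
    if len(dzs) and (np.ptp(dzs) > 1e-3):
        raise ValidationError(
            f"inconsistent DICOM slice spacing in {dirpath}: steps range "
            f"{dzs.min():.4f}..{dzs.max():.4f} mm"
        )
    dz = float(dzs[0]) if len(dzs) else float(getattr(first, "SliceThickness", 1.0))

    rows_sp, cols_sp = (float(s) for s in first.PixelSpacing)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    stack = np.stack([ds.pixel_array.astype(np.float32) for ds in slices], axis=0)
    stack = stack * slope + intercept  # to HU

    # pixel_array is (row, col) = (y, x) in the patient frame given by
    # orient; support the standard axial identity orientation (LPS axes).
    if not (np.allclose(row, [1, 0, 0], atol=1e-3) and np.allclose(col, [0, 1, 0], atol=1e-3)):
        raise ValidationError(f"unsupported DICOM orientation {orient.tolist()} in {dirpath}")
    # stack axes (z, row=y, col=x) -> (x, y, z)
    data = np.transpose(stack, (2, 1, 0))
    pos0 = np.asarray(slices[0].ImagePositionPatient, float)  # LPS
    # LPS -> RAS: flip x and y axes of the array and negate origin components
    data = data[::-1, ::-1, :].copy()
    ox = -(pos0[0] + (data.shape[0] - 1) * cols_sp)
    oy = -(pos0[1] + (data.shape[1] - 1) * rows_sp)
    oz = pos0[2]
    return Volume(data, (cols_sp, rows_sp, dz), (float(ox), float(oy), float(oz)))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to(src: Volume | LabelMap, target: Volume) -> Volume | LabelMap:
    """Resample ``src`` onto the grid of ``target``.

    Intensities are interpolated trilinearly; label maps use nearest-neighbor
    so that label identities are preserved.
    """
    ti, tj, tk = np.meshgrid(
        np.arange(target.shape[0]), np.arange(target.shape[1]), np.arange(target.shape[2]),
        indexing="ij",
    )
    pts = np.stack([ti, tj, tk], axis=-1) * np.asarray(target.spacing) + np.asarray(target.origin)
    cont = (pts - np.asarray(src.origin)) / np.asarray(src.spacing)
    coords = np.moveaxis(cont, -1, 0)
    if isinstance(src, LabelMap):
        out = ndimage.map_coordinates(src.data, coords, order=0, mode="constant", cval=0)
        return LabelMap(out.astype(src.data.dtype), target.spacing, target.origin, src.label_scheme)
    out = ndimage.map_coordinates(src.data, coords, order=1, mode="constant", cval=float(src.data.min()))
    return Volume(out.astype(np.float32), target.spacing, target.origin)
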