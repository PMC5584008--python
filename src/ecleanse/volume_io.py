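"""Volumetric I/O and the grid/orientation contract.

Every module in the package consumes volumes in a fixed canonical axis order
``(slice, down, right)``: axis 0 walks through axial slices, axis 1 points
*toward the scanner table* (gravity; the table sits at the bottom of each
axial image) and axis 2 is the in-slice left-right axis.  The ``down_axis``
of an :class:`HUVolume` names the in-slice axis along which index increase
means "toward the table"; for the canonical order this is axis 1.

Converters between on-disk layouts (DICOM series, NIfTI-1) and the canonical
order live only here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HUVolume",
    "LabelMap",
    "FormatError",
    "OrderingError",
    "load_volume",
    "save_volume",
    "save_labelmap",
    "load_labelmap",
]


class FormatError(ValueError):
    """Raised for unreadable or inconsistent on-disk volumes."""


class OrderingError(FormatError):
    """Raised when DICOM slice positions are not strictly monotone."""


@dataclass
class HUVolume:
    """A 3-D grid of CT attenuations in Hounsfield units.

    Parameters
    ----------
    data:
        3-D float array in canonical ``(slice, down, right)`` order.
    spacing:
        Voxel spacing ``(dz, dy, dx)`` in millimetres, matching the axis
        order of ``data``.
    down_axis:
        In-slice axis index (1 or 2) along which increasing index points
        toward the scanner table.  The default canonical order puts the
        table at high row indices, i.e. axis 1.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    down_axis: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU volume contains non-finite values")
        if self.down_axis not in (1, 2):
            raise ValueError("down_axis must be an in-slice axis (1 or 2)")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "HUVolume":
        return replace(self, data=self.data.copy())


@dataclass
class LabelMap:
    """Integer label grid aligned with a source :class:`HUVolume`.

    Label 0 is background.  ``legend`` maps label values to names.
    """

    data: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.int32)
            else:
                raise ValueError("label maps must hold integers")
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D label map, got shape {self.data.shape}")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask for one label, or for all non-background voxels."""
        if label is None:
            return self.data > 0
        return self.data == label


# ---------------------------------------------------------------------------
# NIfTI
#
# On disk NIfTI data are stored (x, y, z) = (right, down, slice); we
# transpose to the canonical (slice, down, right) order on load and back on
# save, and carry the spacing in the affine diagonal.
# ---------------------------------------------------------------------------


def _nifti_to_canonical(arr: np.ndarray, zooms) -> tuple[np.ndarray, tuple[float, float, float]]:
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    dx, dy, dz = (float(z) for z in zooms[:3])
    return data, (dz, dy, dx)


def _canonical_to_nifti(data: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    dz, dy, dx = spacing
    affine = np.diag([dx, dy, dz, 1.0])
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0))), affine


def _load_nifti(path: str) -> HUVolume:
    import nibabel as nib

    img = nib.load(path)
    arr = np.asanyarray(img.dataobj).astype(np.float64)
    if arr.ndim != 3:
        raise FormatError(f"expected 3-D NIfTI, got shape {arr.shape}")
    data, spacing = _nifti_to_canonical(arr, img.header.get_zooms())
    return HUVolume(data=data, spacing=spacing, down_axis=1)


def _save_nifti(vol: HUVolume, path: str, dtype=np.float64) -> None:
    import nibabel as nib

    arr, affine = _canonical_to_nifti(np.asarray(vol.data, dtype=dtype), vol.spacing)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, path)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------


def _load_dicom_dir(path: str) -> HUVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:  # non-DICOM clutter in the directory
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM image slices found in {path!r}")

    series = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(series) > 1:
        raise FormatError(f"mixed DICOM series in {path!r}: {sorted(map(str, series))}")

    def z_of(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))

    slices.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in slices])
    if len(zs) > 1:
        dzs = np.diff(zs)
        if np.any(dzs <= 0):
            raise OrderingError("non-monotone DICOM slice positions")
        dz = float(np.median(dzs))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    ref = slices[0]
    rows, cols = int(ref.Rows), int(ref.Columns)
    ps = getattr(ref, "PixelSpacing", [1.0, 1.0])
    dy, dx = float(ps[0]), float(ps[1])
    for ds in slices:
        if int(ds.Rows) != rows or int(ds.Columns) != cols:
            raise FormatError("DICOM slices disagree on matrix size")

    data = np.empty((len(slices), rows, cols), dtype=np.float64)
    for i, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        data[i] = ds.pixel_array.astype(np.float64) * slope + intercept

    # DICOM rows run anterior->posterior for a supine axial acquisition, so
    # increasing row index points toward the table: canonical order already.
    return HUVolume(data=data, spacing=(dz, dy, dx), down_axis=1)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "dicom_dir"
    if path.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise FormatError(f"cannot infer volume format from {path!r}")


def load_volume(path: str, format: str | None = None, down_axis: int | None = None) -> HUVolume:
    """Read a CT volume in HU from a DICOM directory or a NIfTI file.

    DICOM rescale slope/intercept are applied so returned values are
    calibrated Hounsfield units.  ``down_axis`` overrides the orientation
    inferred from the file layout.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        vol = _load_nifti(path)
    elif fmt == "dicom_dir":
        vol = _load_dicom_dir(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if down_axis is not None:
        vol.down_axis = down_axis
        HUVolume.__post_init__(vol)
    return vol


def save_volume(vol: HUVolume, path: str, format: str = "nifti") -> None:
    """Write a volume so that :func:`load_volume` round-trips it exactly."""
    if format != "nifti":
        raise FormatError(f"unsupported output format {format!r}")
    _save_nifti(vol, path)


def save_labelmap(lab: LabelMap, spacing, path: str) -> None:
    """Write an integer label map as NIfTI (legend not serialized here)."""
    import nibabel as nib

    arr, affine = _canonical_to_nifti(lab.data.astype(np.int32), spacing)
    nib.save(nib.Nifti1Image(arr, affine), path)


def load_labelmap(path: str, legend: dict[int, str] | None = None) -> LabelMap:
    import nibabel as nib

    img = nib.load(path)
    arr = np.asanyarray(img.dataobj)
    data, _ = _nifti_to_canonical(arr, img.header.get_zooms())
    return LabelMap(data=np.rint(data).astype(np.int32), legend=legend or {})
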