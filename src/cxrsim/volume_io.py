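"""CT volume and radiograph I/O.

Volumes are held in a single canonical array orientation so that the
projector and the segmentation code never have to branch on axis roles:

* array axis 0 runs inferior -> superior (``IS``),
* array axis 1 runs anterior -> posterior (``AP``),
* array axis 2 runs right -> left (``RL``).

Readers permute whatever orientation the file header declares into this
order; only axis-aligned direction matrices (permutations and flips) are
supported.  Coordinates are 0-based voxel indices and physical positions are
voxel-center positions in mm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, ValidationError

#: Canonical anatomical axis labels, in array-axis order.
CANONICAL_AXES = ("IS", "AP", "RL")

_VALID_S = (1000, 1024)


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with per-axis spacing in mm.

    Parameters
    ----------
    voxels
        3D array of HU values in canonical ``(IS, AP, RL)`` order.
    spacing
        Physical voxel size in mm along each canonical array axis.
    axes
        Anatomical label of each array axis; a permutation of
        :data:`CANONICAL_AXES`.
    scale_factor_S
        Vendor HU scale factor, 1000 or 1024.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = CANONICAL_AXES
    scale_factor_S: int = 1000
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        if sorted(self.axes) != sorted(CANONICAL_AXES):
            raise ValidationError(f"axes must be a permutation of {CANONICAL_AXES}")
        if self.scale_factor_S not in _VALID_S:
            raise ValidationError(f"scale_factor_S must be one of {_VALID_S}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Radiograph:
    """A 2D projection image.

    ``kind`` distinguishes raw line integrals (dimensionless optical depth,
    nonnegative) from display-normalized images with values in [0, 1].
    ``pixel_spacing`` is mm per pixel along (row, column).
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    kind: str = "raw_line_integral"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("radiograph pixels must be 2D")
        if self.kind not in ("raw_line_integral", "display"):
            raise ValidationError(f"unknown radiograph kind {self.kind!r}")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("pixel_spacing must be positive")
        if np.all(np.isfinite(self.pixels)):
            if self.kind == "raw_line_integral" and self.pixels.min() < -1e-9:
                raise ValidationError("raw line integrals must be nonnegative")
            if self.kind == "display" and (
                self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9
            ):
                raise ValidationError("display pixels must lie in [0, 1]")


def with_axis_order(volume: CTVolume, axes: tuple[str, str, str]) -> CTVolume:
    """Return a copy of ``volume`` with array axes permuted to ``axes``."""
    if sorted(axes) != sorted(CANONICAL_AXES):
        raise ValidationError(f"axes must be a permutation of {CANONICAL_AXES}")
    perm = tuple(volume.axes.index(a) for a in axes)
    return replace(
        volume,
        voxels=np.transpose(volume.voxels, perm),
        spacing=tuple(volume.spacing[p] for p in perm),
        axes=tuple(axes),
    )


def _detect_format(path: str, format: str) -> str:
    if format != "auto":
        return format
    lower = str(path).lower()
    if lower.endswith((".mhd", ".mha")):
        return "metaimage"
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise FormatError(f"cannot infer volume format from path {path!r}")


def _canonicalize(array: np.ndarray, spacing_xyz, direction) -> tuple[np.ndarray, tuple]:
    """Permute/flip an (z, y, x)-indexed array into canonical orientation.

    SimpleITK reports direction cosines in physical LPS coordinates; physical
    axes map to canonical array axes as L->RL(2), P->AP(1), S->IS(0).
    """
    D = np.asarray(direction, dtype=float).reshape(3, 3)
    phys_for_canon = {0: 2, 1: 1, 2: 0}  # physical x->col 2, y->row 1, z->slice 0
    dest_axes = [-1, -1, -1]
    flips = []
    for img_axis in range(3):  # image index axes in sitk (x, y, z) order
        col = D[:, img_axis]
        phys = int(np.argmax(np.abs(col)))
        if abs(col[phys]) < 0.99 or np.sum(np.abs(col) > 0.01) > 1:
            raise FormatError("only axis-aligned direction matrices are supported")
        arr_axis = 2 - img_axis  # numpy array is indexed (z, y, x)
        dest_axes[arr_axis] = phys_for_canon[phys]
        if col[phys] < 0:
            flips.append(arr_axis)
    if sorted(dest_axes) != [0, 1, 2]:
        raise FormatError("direction matrix is not a permutation of the axes")
    if flips:
        array = np.flip(array, axis=tuple(flips))
    # dest_axes[a] is the canonical position of current array axis a
    perm = tuple(dest_axes.index(c) for c in range(3))
    array = np.transpose(array, perm)
    spacing_zyx = (spacing_xyz[2], spacing_xyz[1], spacing_xyz[0])
    spacing = tuple(float(spacing_zyx[p]) for p in perm)
    return np.ascontiguousarray(array), spacing


def read_volume(path, format: str = "auto", scale_factor_S: int = 1000) -> CTVolume:
    """Read a CT volume from MetaImage or NIfTI into canonical orientation.

    HU values are returned unmodified; spacing and axis roles come from the
    file header.
    """
    fmt = _detect_format(path, format)
    if not os.path.exists(str(path)) and not os.path.exists(str(path) + ".gz"):
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on malformed headers
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    array = sitk.GetArrayFromImage(img)
    if array.ndim != 3:
        raise FormatError(f"{path} is not a 3D volume")
    spacing_xyz = img.GetSpacing()
    if any(s <= 0 for s in spacing_xyz):
        raise ValidationError(f"{path}: non-positive voxel spacing {spacing_xyz}")
    voxels, spacing = _canonicalize(array.astype(np.float32), spacing_xyz, img.GetDirection())
    return CTVolume(
        voxels=voxels,
        spacing=spacing,
        scale_factor_S=scale_factor_S,
        volume_id=os.path.basename(str(path)),
    )


def write_volume(volume: CTVolume, path, format: str = "auto") -> None:
    """Write a volume to MetaImage or NIfTI; round-trips voxels and spacing."""
    fmt = _detect_format(path, format)
    vol = volume if volume.axes == CANONICAL_AXES else with_axis_order(volume, CANONICAL_AXES)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.astype(np.float32)))
    img.SetSpacing(tuple(vol.spacing[::-1]))  # sitk wants (x, y, z)
    try:
        sitk.WriteImage(img, str(path), useCompression=fmt == "nifti")
    except Exception as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def export_radiograph(image: Radiograph, path, format: str = "png16") -> None:
    """Export a radiograph as 16-bit grayscale PNG or full-precision CSV.

    ``png16`` linearly quantizes the display image (raw images are min-max
    normalized first); ``float_csv`` preserves raw values.
    """
    if not np.all(np.isfinite(image.pixels)):
        raise ValidationError("radiograph contains NaN or Inf pixels")
    if format == "png16":
        p = image.pixels
        if image.kind != "display":
            lo, hi = float(p.min()), float(p.max())
            p = (p - lo) / (hi - lo) if hi > lo else np.zeros_like(p)
        iio.imwrite(str(path), np.round(p * 65535).astype(np.uint16))
    elif format == "float_csv":
        np.savetxt(str(path), image.pixels, delimiter=",", fmt="%.17g")
    else:
        raise ValidationError(f"unknown radiograph export format {format!r}")


def import_radiograph_csv(path, pixel_spacing=(1.0, 1.0), kind="raw_line_integral") -> Radiograph:
    """Load a radiograph previously exported with ``float_csv``."""
    return Radiograph(np.loadtxt(str(path), delimiter=","), pixel_spacing, kind)


def export_mask(mask: np.ndarray, path) -> None:
    """Export a 2D binary mask as an 8-bit PNG with values 0/255."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2D")
    iio.imwrite(str(path), (mask.astype(bool) * np.uint8(255)))
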