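"""HU-to-attenuation conversion, patient-table removal and lung segmentation.

A CT stores Hounsfield units; a radiograph simulator needs linear attenuation
coefficients.  The conversion is the affine map

    mu_x = mu_water + (mu_water - mu_air) * HU_x / S

with the vendor scale factor S (1000 or 1024) and mu_water = 0.2059 cm^-1 for
a monochromatic beam.  Before projecting, the patient table — absent in real
radiographs — is removed by thresholding plus connected components (the
second-largest above-threshold object is the table), and the lungs are
segmented by thresholding a tissue mask and filling its holes slice-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume_io import CTVolume

#: Linear attenuation of water at the simulator's reference energy, cm^-1.
MU_WATER_CM = 0.2059

AIR_HU = -1000.0


@dataclass
class AttenuationModel:
    """Monochromatic HU -> linear attenuation conversion parameters.

    mu_water and mu_air are in cm^-1; S is the vendor HU scale factor.
    Air attenuation is ~3 orders of magnitude below water, so mu_air
    defaults to 0.
    """

    mu_water: float = MU_WATER_CM
    mu_air: float = 0.0
    S: int = 1000

    def __post_init__(self) -> None:
        if not self.mu_water > self.mu_air >= 0:
            raise ValidationError("require mu_water > mu_air >= 0")
        if self.S not in (1000, 1024):
            raise ValidationError("S must be 1000 or 1024")


@dataclass
class LungMask:
    """Boolean lung mask aligned to a source CT volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    empty: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValidationError("lung mask must be 3D")


def hu_to_mu(hu, model: AttenuationModel | None = None):
    """Convert HU values (scalar or array) to linear attenuation in cm^-1."""
    model = model or AttenuationModel()
    hu = np.asarray(hu, dtype=float)
    mu = model.mu_water + (model.mu_water - model.mu_air) * hu / model.S
    return float(mu) if mu.ndim == 0 else mu


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValidationError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def _ranked_components(labels: np.ndarray, n: int) -> list[int]:
    """Component labels sorted by size desc, ties by first voxel in scan order."""
    counts = np.bincount(labels.ravel())[1:]  # skip background
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.arange(flat.size)
    # first occurrence of each label in C scan order
    rev = idx[::-1]
    first_rev = np.full(n + 1, -1, dtype=np.int64)
    first_rev[flat[rev]] = rev
    first[1:] = first_rev[1:]
    return sorted(range(1, n + 1), key=lambda lab: (-counts[lab - 1], first[lab]))


def remove_table(
    volume: CTVolume, threshold_hu: float = -300.0, connectivity: int = 26
) -> CTVolume:
    """Remove the patient table from a CT volume.

    Voxels above ``threshold_hu`` are grouped into connected components; the
    second-largest component (the table, the body being the largest) is set
    to air (-1000 HU).  With fewer than two components the volume is returned
    unchanged with a warning.  Ties in component size are broken by the
    smaller first-voxel index in canonical scan order.
    """
    structure = _connectivity_structure(connectivity)
    fg = volume.voxels > threshold_hu
    labels, n = ndimage.label(fg, structure=structure)
    if n < 2:
        warnings.warn("fewer than two components above threshold; no table removed")
        return replace(volume, voxels=volume.voxels.copy())
    ranked = _ranked_components(labels, n)
    out = volume.voxels.copy()
    out[labels == ranked[1]] = AIR_HU
    return replace(volume, voxels=out)


def segment_lung(
    volume: CTVolume,
    tissue_threshold_hu: float = -400.0,
    min_component_cm3: float = 1.0,
) -> LungMask:
    """Segment the lungs of a (table-free) CT volume.

    A tissue mask is extracted by thresholding at ``tissue_threshold_hu``;
    its largest connected component is the body.  Holes in the body are
    filled per axial slice, and the lung is the low-density region inside the
    filled body, keeping only components of at least ``min_component_cm3``.
    The mask excludes air outside the patient by construction.
    """
    tissue = volume.voxels > tissue_threshold_hu
    labels, n = ndimage.label(tissue)
    if n == 0:
        warnings.warn("no tissue above threshold; empty lung mask")
        return LungMask(np.zeros(volume.shape, bool), volume.spacing, empty=True)
    body = labels == _ranked_components(labels, n)[0]
    filled = np.empty_like(body)
    for k in range(body.shape[0]):  # slice-wise hole filling along IS
        filled[k] = ndimage.binary_fill_holes(body[k])
    candidate = filled & ~tissue
    labels, n = ndimage.label(candidate)
    if n:
        voxel_cm3 = np.prod(volume.spacing) / 1000.0
        min_vox = min_component_cm3 / voxel_cm3
        counts = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(counts >= min_vox) + 1
        mask = np.isin(labels, keep)
    else:
        mask = candidate
    empty = not mask.any()
    if empty:
        warnings.warn("lung segmentation produced an empty mask")
    return LungMask(mask, volume.spacing, empty=empty)
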