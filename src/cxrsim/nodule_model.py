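"""3D lung-nodule shapes: synthesis, loading, augmentation and rasterization.

Study nodules are drawn from a pool of lumpy quasi-spherical shapes (a
seeded stand-in for a library of patient-derived segmentations, which cannot
be redistributed).  Each shape is a star-shaped region whose surface radius
is a smooth random perturbation of a base sphere; because the perturbation's
relative amplitude is bounded by the ``irregularity`` parameter the support
is always connected.

Augmentation mirrors the simulator's training regime: an in-plane (coronal)
rotation uniform in [0, 360) degrees and per-axis rescaling of the tight
bounding box into a configured extent range (default 8-20 mm); in study mode
a single isotropic diameter is used instead.  Occupancy values stay in
[0, 1] with the maximum renormalized to 1, and the rasterizer multiplies
occupancy by the soft-tissue attenuation coefficient.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .preprocess import AttenuationModel, hu_to_mu
from .volume_io import CTVolume, read_volume, write_volume

#: Typical soft-tissue HU used to set the nodule attenuation by default.
SOFT_TISSUE_HU = 50.0

DEFAULT_EXTENT_RANGE_MM = (8.0, 20.0)


@dataclass
class NoduleIntensityModel:
    """Attenuation assigned to full nodule occupancy, in cm^-1."""

    mu_soft: float = hu_to_mu(SOFT_TISSUE_HU, AttenuationModel())

    def __post_init__(self) -> None:
        if not self.mu_soft > 0:
            raise ValidationError("mu_soft must be positive")


@dataclass
class Nodule:
    """A 3D soft occupancy grid in [0, 1] with physical spacing in mm."""

    shape: np.ndarray
    grid_spacing: tuple[float, float, float]
    id: str = ""

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=float)
        if self.shape.ndim != 3:
            raise ValidationError("nodule shape must be a 3D grid")
        if isinstance(self.grid_spacing, (int, float)):
            self.grid_spacing = (float(self.grid_spacing),) * 3
        self.grid_spacing = tuple(float(s) for s in self.grid_spacing)
        if any(s <= 0 for s in self.grid_spacing):
            raise ValidationError("grid_spacing must be positive")
        mx = self.shape.max() if self.shape.size else 0.0
        if mx <= 0:
            raise ValidationError("nodule occupancy is empty")
        if self.shape.min() < 0 or mx > 1 + 1e-9:
            raise ValidationError("occupancy values must lie in [0, 1]")
        if abs(mx - 1.0) > 1e-9:
            raise ValidationError("occupancy maximum must be 1 after normalization")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Tight bounding-box size of the (>= 0.5) support, per axis in mm."""
        return _support_extent_mm(self.shape, self.grid_spacing)


def _support_bbox(occ: np.ndarray, level: float = 0.5):
    support = occ >= level
    if not support.any():
        support = occ > 0
    slices = ndimage.find_objects(support.astype(np.int8))[0]
    return slices


def _support_extent_mm(occ, spacing, level: float = 0.5):
    sl = _support_bbox(occ, level)
    return tuple((s.stop - s.start) * sp for s, sp in zip(sl, spacing))


def _smooth_sphere_field(rng: np.random.Generator, n_lobes: int = 12):
    """A smooth random function on the unit sphere with values in [-1, 1]."""
    dirs = rng.normal(size=(n_lobes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coef = rng.normal(size=n_lobes)

    def f(units: np.ndarray) -> np.ndarray:
        # odd powers keep the field smooth and sign-balanced
        return np.tensordot(units, dirs.T, axes=1) ** 3 @ coef

    return f


def generate_shape(
    seed: int,
    base_diameter_mm: float = 12.0,
    irregularity: float = 0.3,
    grid_spacing: float = 1.0,
) -> Nodule:
    """Generate a connected, lumpy quasi-spherical binary nodule shape.

    The surface radius is ``R * (1 + irregularity * f(u))`` for a smooth
    random field ``f`` with max |f| = 1, so the relative radial perturbation
    never exceeds ``irregularity`` and the region stays star-shaped (hence
    connected).  ``irregularity=0`` yields the discretized base sphere:
    exactly the voxels whose center lies within the base radius.
    Deterministic for a fixed seed.
    """
    if base_diameter_mm <= 0:
        raise ValidationError("base_diameter_mm must be positive")
    if not 0 <= irregularity <= 1:
        raise ValidationError("irregularity must lie in [0, 1]")
    if base_diameter_mm / grid_spacing < 3:
        raise ValidationError(
            f"grid spacing {grid_spacing} mm too coarse for a "
            f"{base_diameter_mm} mm nodule (< 3 voxels across)"
        )
    radius = base_diameter_mm / 2.0
    half = int(np.ceil(radius * (1 + irregularity) / grid_spacing)) + 1
    coords = (np.arange(-half, half + 1) * grid_spacing).astype(float)
    z, y, x = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(z * z + y * y + x * x)
    if irregularity == 0:
        occ = (r <= radius).astype(float)
    else:
        rng = np.random.default_rng(seed)
        f = _smooth_sphere_field(rng)
        with np.errstate(invalid="ignore"):
            units = np.stack([z, y, x], axis=-1) / np.where(r > 0, r, 1.0)[..., None]
        vals = f(units.reshape(-1, 3)).reshape(r.shape)
        peak = np.abs(vals).max()
        if peak > 0:
            vals = vals / peak
        occ = (r <= radius * (1.0 + irregularity * vals)).astype(float)
        occ[r == 0] = 1.0
    return Nodule(occ, (grid_spacing,) * 3, id=f"synthetic-{seed}")


def load_shape(path) -> Nodule:
    """Load a user-supplied 3D nodule mask (MetaImage/NIfTI).

    Scalar masks are renormalized so that the maximum occupancy is 1.
    """
    vol = read_volume(path)
    arr = np.asarray(vol.voxels, dtype=float)
    mx = arr.max() if arr.size else 0.0
    if mx <= 0:
        raise ValidationError(f"{path}: nodule mask is empty")
    arr = np.clip(arr, 0, None) / mx
    return Nodule(arr, vol.spacing, id=os.path.basename(str(path)))


def augment(
    nodule: Nodule,
    rotation_deg: float | None = None,
    target_extent_mm=None,
    rng: np.random.Generator | None = None,
    extent_range_mm: tuple[float, float] = DEFAULT_EXTENT_RANGE_MM,
    isotropic: bool = False,
) -> Nodule:
    """Rotate a nodule in the coronal plane and rescale its bounding box.

    ``rotation_deg`` and ``target_extent_mm`` may be given explicitly or
    drawn from ``rng``: rotation uniform in [0, 360) degrees, extents uniform
    in ``extent_range_mm`` (one shared draw when ``isotropic``, else one per
    axis).  The coronal plane is spanned by the IS and RL axes, so rotation
    is about the AP axis.  After rescaling, the tight bounding box matches
    the target extents to within one voxel.
    """
    if rotation_deg is None or target_extent_mm is None:
        if rng is None:
            raise ValidationError("an rng is required when rotation/extents are not given")
        if rotation_deg is None:
            rotation_deg = float(rng.uniform(0.0, 360.0))
        if target_extent_mm is None:
            lo, hi = extent_range_mm
            if isotropic:
                target_extent_mm = (float(rng.uniform(lo, hi)),) * 3
            else:
                target_extent_mm = tuple(rng.uniform(lo, hi, size=3))
    if isinstance(target_extent_mm, (int, float)):
        target_extent_mm = (float(target_extent_mm),) * 3
    target_extent_mm = tuple(float(t) for t in target_extent_mm)
    lo, hi = extent_range_mm
    for t in target_extent_mm:
        if not lo - 1e-9 <= t <= hi + 1e-9:
            raise ValidationError(
                f"target extent {t} mm outside configured range [{lo}, {hi}] mm"
            )
        if t < 2 * max(nodule.grid_spacing):
            raise ValidationError(f"target extent {t} mm below 2x grid spacing")

    occ = nodule.shape
    angle = float(rotation_deg) % 360.0
    if angle != 0.0:
        occ = ndimage.rotate(occ, angle, axes=(0, 2), reshape=True, order=1, prefilter=False)
        occ = np.clip(occ, 0.0, 1.0)
    current = _support_extent_mm(occ, nodule.grid_spacing)
    zoom = [t / c for t, c in zip(target_extent_mm, current)]
    if any(abs(f - 1.0) > 1e-12 for f in zoom):
        occ = np.clip(ndimage.zoom(occ, zoom, order=1, prefilter=False), 0.0, 1.0)
    mx = occ.max()
    if mx <= 0:
        raise ValidationError("augmentation produced an empty nodule")
    return Nodule(occ / mx, nodule.grid_spacing, id=nodule.id)


def rasterize_mu(
    nodule: Nodule,
    target_spacing,
    intensity: NoduleIntensityModel | None = None,
) -> np.ndarray:
    """Resample occupancy to ``target_spacing`` and scale by soft-tissue mu.

    The result is a 3D attenuation grid in cm^-1 with maximum ``mu_soft``;
    linear in ``mu_soft`` and approximately mass-preserving under the linear
    resampling.
    """
    intensity = intensity or NoduleIntensityModel()
    if isinstance(target_spacing, (int, float)):
        target_spacing = (float(target_spacing),) * 3
    if any(s <= 0 for s in target_spacing):
        raise ValidationError("target_spacing must be positive")
    zoom = [src / dst for src, dst in zip(nodule.grid_spacing, target_spacing)]
    occ = nodule.shape
    if any(abs(f - 1.0) > 1e-12 for f in zoom):
        occ = np.clip(ndimage.zoom(occ, zoom, order=1, prefilter=False), 0.0, 1.0)
    mx = occ.max()
    if mx > 0:
        occ = occ / mx
    return occ * intensity.mu_soft


@dataclass
class NodulePool:
    """A reusable pool of nodule shapes with their generation parameters."""

    nodules: list[Nodule]
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.nodules)

    def choose(self, rng: np.random.Generator) -> Nodule:
        """Draw one shape uniformly with replacement."""
        if not self.nodules:
            raise ValidationError("nodule pool is empty")
        return self.nodules[int(rng.integers(len(self.nodules)))]


def default_pool(
    n_shapes: int = 19,
    seed: int = 0,
    base_diameter_mm: float = 12.0,
    irregularity: float = 0.3,
    grid_spacing: float = 1.0,
) -> NodulePool:
    """Build the default pool of seeded synthetic shapes (19 by default)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_shapes) % (2**31)
    rows, nodules = [], []
    for i, s in enumerate(seeds):
        nod = generate_shape(int(s), base_diameter_mm, irregularity, grid_spacing)
        nod.id = f"pool-{i:02d}"
        nodules.append(nod)
        rows.append(
            dict(
                id=nod.id,
                seed=int(s),
                base_diameter_mm=base_diameter_mm,
                irregularity=irregularity,
            )
        )
    return NodulePool(nodules, pd.DataFrame(rows))


def save_pool(pool: NodulePool, directory) -> None:
    """Persist a pool as one volume per shape plus a manifest CSV."""
    os.makedirs(str(directory), exist_ok=True)
    pool.manifest.to_csv(os.path.join(str(directory), "manifest.csv"), index=False)
    for nod in pool.nodules:
        vol = CTVolume(nod.shape, nod.grid_spacing)
        write_volume(vol, os.path.join(str(directory), f"{nod.id}.mhd"))


def load_pool(directory) -> NodulePool:
    """Load a pool saved by :func:`save_pool`."""
    manifest = pd.read_csv(os.path.join(str(directory), "manifest.csv"))
    nodules = []
    for nid in manifest["id"]:
        nod = load_shape(os.path.join(str(directory), f"{nid}.mhd"))
        nod.id = str(nid)
        nodules.append(nod)
    return NodulePool(nodules, manifest)
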