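"""Synthetic thorax CT phantoms with exact ground-truth masks.

The phantom is deliberately simple — an elliptical body, two ellipsoidal
lungs, a mediastinal slab between them, an optional patient table behind
the body and optional embedded blobs — but every region's voxel set is
returned as a truth mask, so table removal, lung segmentation, nodule
placement and projection can all be tested end to end without any external
CT data.  Region HU values sit inside the preprocessing thresholds rather
than far from them, so the segmentation defaults are exercised, not
trivially satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .volume_io import CTVolume

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass
class Blob:
    """A sphere embedded in the phantom (e.g. a vessel-like structure)."""

    center_vox: tuple[float, float, float]
    radius_mm: float
    hu: float = 50.0


@dataclass
class PhantomSpec:
    """Geometry and intensity description of a synthetic thorax.

    All ellipsoid parameters are fractions of the grid's physical extent
    along the corresponding canonical axis (IS, AP, RL); ``seed`` drives a
    small jitter of the lung/body geometry so pools of distinct phantoms can
    be built from one spec.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_semiaxes: tuple[float, float, float] = (0.46, 0.30, 0.40)
    lung_semiaxes: tuple[float, float, float] = (0.26, 0.16, 0.11)
    lung_offset_rl: float = 0.17
    mediastinum_halfwidth_rl: float = 0.065
    table: bool = True
    table_ap_range: tuple[float, float] = (0.86, 0.94)
    table_halfwidth_rl: float = 0.30
    hu_air: float = -1000.0
    hu_body: float = 20.0
    hu_mediastinum: float = 40.0
    hu_lung: float = -800.0
    hu_table: float = 150.0
    blobs: list[Blob] = field(default_factory=list)
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.hu_air, self.hu_body, self.hu_mediastinum, self.hu_lung, self.hu_table):
            if not HU_MIN <= v <= HU_MAX:
                raise ValidationError(f"HU value {v} outside [{HU_MIN}, {HU_MAX}]")
        if isinstance(self.spacing, (int, float)):
            self.spacing = (float(self.spacing),) * 3


def _ellipsoid(grid, center, semiaxes):
    z, y, x = grid
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def generate_thorax_phantom(spec: PhantomSpec) -> tuple[CTVolume, dict]:
    """Build a thorax CT volume and its exact region truth masks.

    Returns the volume plus ``{"body", "lungs", "table"}`` boolean masks.
    Regions are painted back to front (air < body < mediastinum < lungs <
    blobs < table), deterministically for a fixed spec/seed.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    extent = np.array([nz * sz, ny * sy, nx * sx])
    coords = np.meshgrid(
        (np.arange(nz) + 0.5) * sz,
        (np.arange(ny) + 0.5) * sy,
        (np.arange(nx) + 0.5) * sx,
        indexing="ij",
    )

    def jit(scale=1.0):
        return 1.0 + spec.jitter * scale * rng.uniform(-1, 1)

    center = extent / 2.0
    body_center = center * np.array([1.0, jit(0.2), jit(0.2)])
    body_semi = extent * np.array(spec.body_semiaxes) * np.array([1.0, jit(), jit()])
    body = _ellipsoid(coords, body_center, body_semi)

    lungs = np.zeros(spec.shape, bool)
    for sign in (-1.0, 1.0):
        lc = body_center + np.array([0.0, 0.0, sign * spec.lung_offset_rl * extent[2] * jit(0.5)])
        lsemi = extent * np.array(spec.lung_semiaxes) * np.array([jit(), jit(), jit()])
        lungs |= _ellipsoid(coords, lc, lsemi)
    if (lungs & ~body).any():
        raise ValidationError("lungs extend outside the body; adjust the spec")

    medi = body & (np.abs(coords[2] - body_center[2]) <= spec.mediastinum_halfwidth_rl * extent[2])

    vox = np.full(spec.shape, spec.hu_air, dtype=np.float32)
    vox[body] = spec.hu_body
    vox[medi] = spec.hu_mediastinum
    vox[lungs] = spec.hu_lung

    for blob in spec.blobs:
        bc = (np.asarray(blob.center_vox) + 0.5) * np.array(spec.spacing)
        sphere = _ellipsoid(coords, bc, np.full(3, blob.radius_mm))
        vox[sphere] = blob.hu

    table = np.zeros(spec.shape, bool)
    if spec.table:
        y_mm = coords[1]
        lo, hi = spec.table_ap_range
        table = (
            (y_mm >= lo * extent[1])
            & (y_mm <= hi * extent[1])
            & (np.abs(coords[2] - center[2]) <= spec.table_halfwidth_rl * extent[2])
        )
        if (table & body).any():
            raise ValidationError("table overlaps the body; adjust the spec")
        vox[table] = spec.hu_table

    volume = CTVolume(vox, spec.spacing, volume_id=f"phantom-{spec.seed}")
    return volume, {"body": body, "lungs": lungs, "table": table}


def perturb_phantom(
    volume: CTVolume, noise_sd_hu: float, rng: np.random.Generator
) -> CTVolume:
    """Add Gaussian HU noise (clipped to the valid HU range)."""
    if noise_sd_hu < 0:
        raise ValidationError("noise_sd_hu must be nonnegative")
    if noise_sd_hu == 0:
        return CTVolume(
            volume.voxels.copy(), volume.spacing, volume.axes, volume.scale_factor_S,
            volume.volume_id,
        )
    noisy = volume.voxels + rng.normal(0.0, noise_sd_hu, size=volume.shape)
    noisy = np.clip(noisy, HU_MIN, HU_MAX).astype(np.float32)
    return CTVolume(noisy, volume.spacing, volume.axes, volume.scale_factor_S, volume.volume_id)


def phantom_pool(
    n_volumes: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    noise_sd_hu: float = 0.0,
    jitter: float = 0.04,
) -> list[tuple[CTVolume, dict]]:
    """Generate a pool of distinct phantoms by jittering one base spec."""
    base = base_spec or PhantomSpec()
    out = []
    seeds = np.random.SeedSequence(seed).generate_state(n_volumes) % (2**31)
    for i, s in enumerate(seeds):
        spec = PhantomSpec(
            shape=base.shape,
            spacing=base.spacing,
            body_semiaxes=base.body_semiaxes,
            lung_semiaxes=base.lung_semiaxes,
            lung_offset_rl=base.lung_offset_rl,
            mediastinum_halfwidth_rl=base.mediastinum_halfwidth_rl,
            table=base.table,
            blobs=list(base.blobs),
            jitter=jitter,
            seed=int(s),
        )
        vol, masks = generate_thorax_phantom(spec)
        if noise_sd_hu > 0:
            vol = perturb_phantom(vol, noise_sd_hu, np.random.default_rng(int(s) + 1))
        vol.volume_id = f"phantom-{i:02d}"
        out.append((vol, masks))
    return out
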