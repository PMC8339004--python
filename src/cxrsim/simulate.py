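"""Nodule placement, parallel-beam forward projection, and study generation.

A posteroanterior radiograph is simulated from a CT volume by converting HU
to linear attenuation and integrating along the anterior-posterior axis
(parallel-beam geometry): each pixel is the optical depth
``sum(mu * path length)`` with the per-voxel path length taken along the ray
direction (mm converted to cm).  Nodules are rasterized into an otherwise
empty volume; because projection is linear, the diseased radiograph is the
sum of the clean projection and the nodule-only projection, and each
nodule's individual projection yields a perfect ground-truth mask.  Images
and masks are resized to 512 x 512 and lesion centers of mass are recomputed
on the resized masks.

Study generation reproduces a reader-study layout: a configured number of
radiographs per lesion-count class, a configured multiset of lesion
diameters randomly permuted over the lesion slots, equal per-case lesion
weights summing to one, and at most one nodule-free radiograph per source
volume to avoid duplicate healthy images.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.transform import resize

from .errors import PlacementError, ValidationError
from .nodule_model import Nodule, NoduleIntensityModel, NodulePool, augment, rasterize_mu
from .preprocess import AttenuationModel, LungMask, hu_to_mu, remove_table, segment_lung
from .volume_io import CTVolume, Radiograph

_AXIS_INDEX = {"IS": 0, "AP": 1, "RL": 2}

#: Default reader-study composition: radiograph count per lesion-count class.
DEFAULT_COMPOSITION = {0: 20, 1: 53, 2: 67, 3: 61}
#: Default lesion-size histogram: lesion count per isotropic diameter (mm).
DEFAULT_SIZE_COUNTS = {8.0: 32, 10.0: 111, 15.0: 120, 20.0: 107}


@dataclass
class NoduleRecord:
    """Ground truth for one inserted lesion, in output-pixel coordinates."""

    case_id: str
    lesion_id: int
    com_xy: tuple[float, float]
    diameter_mm: float
    shape_id: str = ""


@dataclass
class SimulatedRadiograph:
    """A simulated radiograph with per-lesion ground truth.

    ``image`` holds the raw optical-depth projection, ``display`` the
    display-normalized image; ``gt_masks`` and ``records`` are index-aligned.
    """

    image: Radiograph
    display: Radiograph
    gt_masks: list[np.ndarray]
    records: list[NoduleRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gt_masks) != len(self.records):
            raise ValidationError("one ground-truth mask per lesion record required")
        for m in self.gt_masks:
            if m.shape != self.image.pixels.shape:
                raise ValidationError("ground-truth masks must match the image shape")
            if not m.any():
                raise ValidationError("empty ground-truth mask")

    @property
    def case_id(self) -> str:
        return str(self.provenance.get("case_id", ""))


@dataclass
class SimConfig:
    """Knobs of the radiograph simulator."""

    attenuation: AttenuationModel = field(default_factory=AttenuationModel)
    intensity: NoduleIntensityModel = field(default_factory=NoduleIntensityModel)
    output_size: int = 512
    projection_axis: str = "AP"
    case_id: str = ""


@dataclass
class StudyConfig:
    """Composition and rendering options of a generated study set."""

    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    size_counts: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_COUNTS))
    sim: SimConfig = field(default_factory=SimConfig)
    extent_range_mm: tuple[float, float] = (8.0, 20.0)
    unique_healthy_per_volume: bool = True
    max_tries: int = 200

    def validate(self) -> None:
        n_lesions = sum(int(c) * int(n) for c, n in self.composition.items())
        n_sizes = sum(int(n) for n in self.size_counts.values())
        if n_lesions != n_sizes:
            raise ValidationError(
                f"composition implies {n_lesions} lesion slots but the size "
                f"histogram lists {n_sizes} diameters"
            )

    @property
    def n_cases(self) -> int:
        return sum(int(n) for n in self.composition.values())


@dataclass
class StudyManifest:
    """Full description of a generated study set.

    ``cases`` has one row per radiograph (case_id, volume_id, n_lesions);
    ``lesions`` one row per inserted nodule (case_id, lesion_id, com_x,
    com_y, diameter_mm, shape_id, weight).  Per-case weights are equal and
    sum to one.
    """

    cases: pd.DataFrame
    lesions: pd.DataFrame
    seed: int = 0
    composition: dict = field(default_factory=dict)

    def to_dir(self, directory) -> None:
        os.makedirs(str(directory), exist_ok=True)
        self.cases.to_csv(os.path.join(str(directory), "cases.csv"), index=False)
        self.lesions.to_csv(os.path.join(str(directory), "lesions.csv"), index=False)
        with open(os.path.join(str(directory), "study.yaml"), "w") as fh:
            yaml.safe_dump(
                {"seed": int(self.seed),
                 "composition": {int(k): int(v) for k, v in self.composition.items()}},
                fh,
            )

    @classmethod
    def from_dir(cls, directory) -> "StudyManifest":
        cases = pd.read_csv(os.path.join(str(directory), "cases.csv"))
        lesions = pd.read_csv(os.path.join(str(directory), "lesions.csv"))
        meta_path = os.path.join(str(directory), "study.yaml")
        seed, comp = 0, {}
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = yaml.safe_load(fh) or {}
            seed = int(meta.get("seed", 0))
            comp = meta.get("composition", {})
        return cls(cases, lesions, seed, comp)


def config_hash(config) -> str:
    """Stable short hash of a config object for provenance records."""
    blob = json.dumps(repr(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def forward_project(mu_volume: np.ndarray, spacing, axis: str = "AP") -> Radiograph:
    """Parallel-beam projection of an attenuation grid along a body axis.

    Each output pixel is the optical depth along one ray: the sum of
    mu (cm^-1) times the voxel size along the ray converted to cm.  For the
    p.a. view (``axis="AP"``) the image rows run superior -> inferior and
    the columns right -> left.
    """
    mu_volume = np.asarray(mu_volume)
    if mu_volume.ndim != 3:
        raise ValidationError("mu_volume must be 3D")
    if spacing is None:
        raise ValidationError("voxel spacing is required for projection")
    if isinstance(spacing, (int, float)):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be three positive values, got {spacing}")
    try:
        ax = _AXIS_INDEX[axis]
    except KeyError:
        raise ValidationError(f"axis must be one of {sorted(_AXIS_INDEX)}") from None
    proj = mu_volume.sum(axis=ax) * (spacing[ax] / 10.0)  # mm -> cm path length
    remaining = [a for a in range(3) if a != ax]
    if 0 in remaining:  # display superior at the top row
        proj = np.flip(proj, axis=remaining.index(0))
    pixel_spacing = tuple(spacing[a] for a in remaining)
    return Radiograph(proj, pixel_spacing, kind="raw_line_integral")


def sample_positions(
    lung: LungMask,
    nodule_extents_mm,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[tuple[int, int, int]]:
    """Sample non-overlapping nodule center positions inside the lung.

    Each returned voxel position admits the nodule's full bounding box
    inside the lung mask (checked by a box-erosion of the mask), positions
    are drawn uniformly from the admissible voxels, and pairwise 3D bounding
    boxes do not overlap.
    """
    extents = [tuple(float(e) for e in (ext if np.iterable(ext) else (ext,) * 3))
               for ext in nodule_extents_mm]
    if not extents:
        return []
    if not lung.voxels.any():
        raise PlacementError("lung mask is empty")
    positions: list[tuple[int, int, int]] = []
    half_sizes: list[np.ndarray] = []
    admissible_cache: dict[tuple, np.ndarray] = {}
    for i, ext in enumerate(extents):
        box = tuple(
            max(1, int(np.ceil(e / s))) for e, s in zip(ext, lung.spacing)
        )
        if box not in admissible_cache:
            adm = ndimage.minimum_filter(lung.voxels, size=box, mode="constant", cval=False)
            admissible_cache[box] = np.argwhere(adm)
        candidates = admissible_cache[box]
        if candidates.shape[0] == 0:
            raise PlacementError(
                f"nodule {i} with extent {ext} mm does not fit inside the lung"
            )
        half = np.array([(b - 1) // 2 + 1 for b in box])
        placed = False
        for _ in range(max_tries):
            pos = candidates[int(rng.integers(candidates.shape[0]))]
            ok = True
            for p, h in zip(positions, half_sizes):
                if np.all(np.abs(pos - np.array(p)) < half + h):
                    ok = False
                    break
            if ok:
                positions.append(tuple(int(v) for v in pos))
                half_sizes.append(half)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nodule {i} (extent {ext} mm) without overlap "
                f"after {max_tries} tries"
            )
    return positions


def _insert_nodule_mu(
    target: np.ndarray, nodule: Nodule, position, spacing, intensity
) -> None:
    """Add a nodule's attenuation grid into ``target`` centered at ``position``."""
    grid = rasterize_mu(nodule, spacing, intensity)
    start = [int(p) - s // 2 for p, s in zip(position, grid.shape)]
    t_sl, g_sl = [], []
    for st, gsz, tsz in zip(start, grid.shape, target.shape):
        t0, t1 = max(st, 0), min(st + gsz, tsz)
        if t0 >= t1:
            return
        t_sl.append(slice(t0, t1))
        g_sl.append(slice(t0 - st, t1 - st))
    target[tuple(t_sl)] += grid[tuple(g_sl)]


def _pad_to_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    if h == w:
        return arr
    size = max(h, w)
    ph, pw = size - h, size - w
    return np.pad(arr, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))


def _display_transform(optical_depth: np.ndarray) -> np.ndarray:
    """Invert the transmitted intensity and min-max normalize to [0, 1]."""
    trans = np.exp(-optical_depth)
    lo, hi = float(trans.min()), float(trans.max())
    if hi <= lo:
        return np.zeros_like(trans)
    return (hi - trans) / (hi - lo)


def make_radiograph(
    volume: CTVolume,
    nodules,
    config: SimConfig | None = None,
) -> SimulatedRadiograph:
    """Simulate a diseased p.a. radiograph with perfect ground truth.

    ``nodules`` is a list of ``(Nodule, position)`` pairs with positions in
    voxel indices (from :func:`sample_positions`).  The clean volume and the
    nodule-only volume are projected separately and summed; each nodule's
    individual projection gives its ground-truth mask (any ray with nonzero
    nodule optical depth).  Image and masks are padded to square, resized to
    the configured output size, and lesion centers of mass are recomputed on
    the resized masks.
    """
    config = config or SimConfig()
    mu_clean = np.clip(hu_to_mu(volume.voxels, config.attenuation), 0.0, None)
    clean_proj = forward_project(mu_clean, volume.spacing, config.projection_axis)

    nodule_mu = np.zeros(volume.shape, dtype=float)
    gt_projections = []
    for nodule, position in nodules:
        single = np.zeros(volume.shape, dtype=float)
        _insert_nodule_mu(single, nodule, position, volume.spacing, config.intensity)
        nodule_mu += single
        gt_projections.append(
            forward_project(single, volume.spacing, config.projection_axis)
        )

    nodule_proj = forward_project(nodule_mu, volume.spacing, config.projection_axis)
    diseased = clean_proj.pixels + nodule_proj.pixels

    out = config.output_size
    padded = _pad_to_square(diseased)
    scale = padded.shape[0] / out
    same_size = padded.shape == (out, out)
    image = padded if same_size else resize(
        padded, (out, out), order=1, preserve_range=True, anti_aliasing=scale > 1
    )
    mean_spacing = float(np.mean(clean_proj.pixel_spacing))
    pixel_spacing = (mean_spacing * scale, mean_spacing * scale)

    masks, records = [], []
    for lesion_idx, ((nodule, _pos), gt) in enumerate(zip(nodules, gt_projections), start=1):
        mask = _pad_to_square((gt.pixels > 0).astype(float))
        mask = mask >= 0.5 if same_size else resize(
            mask, (out, out), order=1, preserve_range=True, anti_aliasing=scale > 1
        ) >= 0.5
        com = ndimage.center_of_mass(mask)
        masks.append(mask)
        records.append(
            NoduleRecord(
                case_id=config.case_id,
                lesion_id=lesion_idx,
                com_xy=(float(com[1]), float(com[0])),
                diameter_mm=float(max(nodule.extent_mm)),
                shape_id=nodule.id,
            )
        )

    raw = Radiograph(image, pixel_spacing, kind="raw_line_integral")
    display = Radiograph(_display_transform(image), pixel_spacing, kind="display")
    return SimulatedRadiograph(
        image=raw,
        display=display,
        gt_masks=masks,
        records=records,
        provenance={
            "case_id": config.case_id,
            "volume_id": volume.volume_id,
            "config_hash": config_hash(config),
        },
    )


def draw_nodule_count(rng: np.random.Generator) -> int:
    """Training-mode nodule count: uniform on {1, ..., 6}."""
    return int(rng.integers(1, 7))


def _prepare_volume(volume: CTVolume, lung: LungMask | None):
    """Remove the table and segment the lung unless a mask is supplied."""
    clean = remove_table(volume)
    return clean, (lung or segment_lung(clean))


def generate_training_case(
    volume: CTVolume,
    pool: NodulePool,
    rng: np.random.Generator,
    config: SimConfig | None = None,
    lung: LungMask | None = None,
    extent_range_mm: tuple[float, float] = (8.0, 20.0),
    max_tries: int = 200,
) -> SimulatedRadiograph:
    """Simulate one training radiograph: 1-6 nodules, anisotropic scaling.

    The nodule count is uniform on {1..6}, shapes are drawn uniformly with
    replacement from the pool, each is rotated uniformly in the coronal
    plane and rescaled to independent per-axis extents uniform in
    ``extent_range_mm``.
    """
    if len(pool) == 0:
        raise ValidationError("nodule pool is empty")
    config = config or SimConfig()
    clean, lung = _prepare_volume(volume, lung)
    n = draw_nodule_count(rng)
    nodules = [
        augment(pool.choose(rng), rng=rng, extent_range_mm=extent_range_mm, isotropic=False)
        for _ in range(n)
    ]
    positions = sample_positions(lung, [nod.extent_mm for nod in nodules], rng, max_tries)
    return make_radiograph(clean, list(zip(nodules, positions)), config)


def _study_plan(config: StudyConfig, n_volumes: int, rng: np.random.Generator):
    """Decide case order, lesion diameters and volume assignment up front."""
    counts = []
    for c, n in sorted(config.composition.items()):
        counts.extend([int(c)] * int(n))
    order = rng.permutation(len(counts))
    lesion_counts = [counts[i] for i in order]
    diameters = [float(d) for d, n in sorted(config.size_counts.items()) for _ in range(int(n))]
    diameters = list(rng.permutation(diameters))
    healthy_idx = [i for i, c in enumerate(lesion_counts) if c == 0]
    if config.unique_healthy_per_volume and len(healthy_idx) > n_volumes:
        raise ValidationError(
            f"{len(healthy_idx)} nodule-free cases requested but only "
            f"{n_volumes} source volumes available for unique healthy images"
        )
    vol_assign = [0] * len(lesion_counts)
    for j, i in enumerate(healthy_idx):
        vol_assign[i] = j % n_volumes
    diseased_idx = [i for i, c in enumerate(lesion_counts) if c > 0]
    for j, i in enumerate(diseased_idx):
        vol_assign[i] = j % n_volumes
    return lesion_counts, diameters, vol_assign


def generate_study(
    volumes,
    config: StudyConfig | None = None,
    rng: np.random.Generator | int = 0,
    pool: NodulePool | None = None,
    on_radiograph=None,
):
    """Generate a full study set of simulated radiographs.

    ``volumes`` is a list of CTVolume (cycled over diseased cases; healthy
    cases use each source volume at most once when
    ``unique_healthy_per_volume``).  Returns ``(manifest, radiographs)``;
    when an ``on_radiograph(sim)`` callback is given, radiographs are
    streamed to it instead of being collected (the second element is then
    ``None``).  The whole generation is a pure function of (inputs, seed,
    config).
    """
    from .nodule_model import default_pool

    config = config or StudyConfig()
    config.validate()
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    if not volumes:
        raise ValidationError("at least one source volume is required")
    pool = pool or default_pool(seed=abs(seed) if seed >= 0 else 0)

    lesion_counts, diameters, vol_assign = _study_plan(config, len(volumes), rng)

    prepared: dict[int, tuple[CTVolume, LungMask]] = {}
    case_rows, lesion_rows = [], []
    radiographs = [] if on_radiograph is None else None
    d_iter = iter(diameters)
    for case_idx, (n_lesions, vol_idx) in enumerate(zip(lesion_counts, vol_assign)):
        case_id = f"case{case_idx:04d}"
        if vol_idx not in prepared:
            prepared[vol_idx] = _prepare_volume(volumes[vol_idx], None)
        clean, lung = prepared[vol_idx]
        sim_cfg = SimConfig(
            attenuation=config.sim.attenuation,
            intensity=config.sim.intensity,
            output_size=config.sim.output_size,
            projection_axis=config.sim.projection_axis,
            case_id=case_id,
        )
        case_diams = [next(d_iter) for _ in range(n_lesions)]
        nodules = [
            augment(
                pool.choose(rng),
                rotation_deg=float(rng.uniform(0, 360)),
                target_extent_mm=(d, d, d),
                extent_range_mm=config.extent_range_mm,
            )
            for d in case_diams
        ]
        positions = sample_positions(
            lung, [(d, d, d) for d in case_diams], rng, config.max_tries
        )
        sim = make_radiograph(clean, list(zip(nodules, positions)), sim_cfg)
        case_rows.append(
            dict(case_id=case_id, volume_id=volumes[vol_idx].volume_id, n_lesions=n_lesions)
        )
        weight = 1.0 / n_lesions if n_lesions else 0.0
        for rec in sim.records:
            lesion_rows.append(
                dict(
                    case_id=rec.case_id,
                    lesion_id=rec.lesion_id,
                    com_x=rec.com_xy[0],
                    com_y=rec.com_xy[1],
                    diameter_mm=case_diams[rec.lesion_id - 1],
                    shape_id=rec.shape_id,
                    weight=weight,
                )
            )
        if on_radiograph is None:
            radiographs.append(sim)
        else:
            on_radiograph(sim)

    manifest = StudyManifest(
        cases=pd.DataFrame(case_rows),
        lesions=pd.DataFrame(
            lesion_rows,
            columns=["case_id", "lesion_id", "com_x", "com_y",
                     "diameter_mm", "shape_id", "weight"],
        ),
        seed=seed,
        composition=dict(config.composition),
    )
    return manifest, radiographs
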