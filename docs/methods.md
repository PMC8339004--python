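# Methods

## Radiograph formation model

The simulator is monochromatic and parallel-beam. A CT volume with
Hounsfield-unit voxels is mapped voxelwise to linear attenuation

    μ_x = μ_water + (μ_water − μ_air) · HU_x / S     [cm⁻¹]

with defaults μ_water = 0.2059 cm⁻¹, μ_air = 0 (air attenuation is roughly
three orders of magnitude below water; the constant is configurable) and
S = 1000 (the DICOM-common scale; 1024 is accepted for vendors that use it).
No reference energy is attached to μ_water — the model is monochromatic by
construction, and polychromatic spectra, scatter, noise and detector MTF are
out of scope. Negative attenuation arising from HU below −S (e.g. −1024
padding) is clipped to zero so that line integrals are nonnegative.

A posteroanterior radiograph is the optical-depth image
`p(u,v) = Σ_ray μ · Δl`, with Δl the voxel size along the anterior–posterior
ray converted from mm to cm. Projection is exactly linear, which the
pipeline exploits: clean volume and nodule-only volume are projected
separately and summed to the diseased image, and each nodule's individual
projection provides its ground-truth mask (any ray with nonzero nodule
optical depth). Images and masks are padded to square (centered,
zero optical depth) and resized to 512×512 — bilinear for images, linear
interpolation thresholded at 0.5 for masks — and lesion centers of mass are
recomputed on the resized masks. The display image is
`1 − exp(−optical depth)`, min-max normalized per image; the raw
optical-depth image is always retained alongside, since the display
transform used in reader studies is a presentation choice, not physics.

## Preprocessing

All volumes are permuted to one canonical array orientation
(inferior→superior, anterior→posterior, right→left); only axis-aligned
direction matrices are supported.

*Table removal.* Voxels above −300 HU are grouped by 26-connected
components; the second-largest component is the table and is set to −1000 HU.
Ranking is by voxel count with ties broken by the smaller first-voxel index
in canonical scan order, so the operation is deterministic. With fewer than
two components nothing is removed and a warning is issued.

*Lung segmentation.* The tissue mask is `HU > −400`; its largest component
(the body) is hole-filled per axial slice, and the lung is the low-density
region inside the filled body. Components below 1 cm³ are dropped to
suppress airway/noise fragments. The −300/−400 HU thresholds and the minimum
component size are package choices (config-exposed), selected to separate
tissue, table and air robustly; they are not physical constants.

## Nodule model

Study nodules are drawn from a pool of 19 seeded synthetic shapes — a
star-shaped region whose surface radius is `R·(1 + irregularity·f(u))` for a
smooth random field `f` on the sphere with max |f| = 1 (default base
diameter 12 mm, irregularity 0.3, 1 mm grid). Star-shapedness guarantees a
connected support. The generator emits binary occupancy; softness enters
through linear interpolation during rotation, rescaling and rasterization
(thresholding at 0.5 only where a binary support is required), which
preserves projected mass better than nearest-neighbour. User-supplied 3D
masks can replace the synthetic pool; they are renormalized to maximum
occupancy 1.

Augmentation rotates the shape in the coronal plane (about the
anterior–posterior axis) by an angle uniform in [0, 360)° and rescales the
tight bounding box per axis. Two scaling modes exist because training-style
augmentation and a sized study set need different semantics: *training mode*
draws independent per-axis extents uniform in [8, 20] mm; *study mode* uses
one isotropic diameter per lesion from the configured size histogram.
Occupancy is multiplied by the soft-tissue attenuation, by default
μ(50 HU) = 0.2162 cm⁻¹ under the active attenuation model — 50 HU is typical
soft tissue, and the value is config-exposed since lesion density varies.

## Placement and study composition

Candidate centers are the voxels where the nodule's bounding box (extent in
voxels, box erosion of the lung mask) lies entirely inside the lung;
positions are drawn uniformly from that admissible set, with rejection (200
tries) of 3D bounding-box overlaps between nodules of one case. 3D
non-overlap prevents degenerate double-density lesions; overlap of the *2D
projections* is permitted, as it is in real radiographs. An impossible
placement raises an error naming the offending nodule.

The default study composition is 201 radiographs from 21 source volumes:
20/53/67/61 cases with 0/1/2/3 nodules and 370 lesions with diameters
32×8 mm, 111×10 mm, 120×15 mm, 107×20 mm. The diameter multiset is randomly
permuted over the lesion slots in case order (the assignment rule is a
package decision; only the histogram is fixed). Diseased cases cycle over
the volume pool; nodule-free cases use each source volume at most once, so
no two healthy radiographs are identical. Composition consistency
(Σ class·count = Σ histogram) is validated before any rendering. Per-case
lesion weights are 1/L and sum to one. Generation is a pure function of
(volumes, config, seed).

## Evaluation

A mark matches a lesion when the Euclidean distance between mark and
ground-truth center of mass is strictly below 30 output pixels and, when a
threshold ζ is active, its score is ≥ ζ. Both comparisons are config-exposed
(the strict `>` convention is also used in practice for some detectors, and
boundary behaviour at exactly 30 px is a convention, not a derivable fact).
Matching is greedy one-to-one in order of descending score, ties by smaller
distance then lesion id — deterministic and standard in FROC tooling.
Unmatched marks are non-lesion localizations; unmatched lesions rate −∞.

FROC: `LLF(ζ) = #{z_kl ≥ ζ}/ΣL_k`, `NLF(ζ) = #{NL ≥ ζ}/(K_N+K_F)` (all
cases in the denominator). wAFROC: FPF uses nodule-free cases only — false
positives on diseased cases affect NLF but not FPF. The figure of merit is
defined as the ψ-kernel two-sample statistic (unambiguous under ties and
unmarked cases, with −∞/−∞ ties scoring ½) rather than as a curve area; the
trapezoidal area under the empirical curve extended to (1,1) is computed
independently and the two agree to 1e-12 on randomized instances, which the
test suite asserts. `wllf_at` interpolates the monotone envelope of the
curve linearly, anchored at (0,0) and (1,1). Rating tables in the
three-table Truth/NL/LL layout (CSV directory or xlsx) can be written and
loaded; weights must sum to one per case within 1e-6.

## Synthetic thorax phantom

The phantom composes air (−1000 HU), an elliptical body (+20), a mediastinal
slab (+40), two ellipsoidal lungs (−800), optional blobs and an optional
table slab (+150) — values deliberately inside the segmentation thresholds
so the preprocessing defaults are exercised rather than trivially satisfied.
Default grid is 128³ at 2.5 mm (a desk-scale size that keeps a full
201-image study under a minute; a finer grid is a spec parameter). Gaussian
HU noise (default 20 HU in study generation) and a small geometric jitter
across a seeded pool emulate inter-patient variation.

What the phantom does *not* emulate: ribs, vasculature, organ texture,
partial-volume boundaries, realistic nodule-background contrast variation,
arm positions, or any acquisition noise beyond additive Gaussian HU noise.
Passing tests therefore demonstrate the correctness of the geometry, the
projection arithmetic, the composition bookkeeping and the scoring — not
that segmentation thresholds or detection difficulty transfer to clinical
CT data.

## Numerical choices and degenerate inputs

- Linear (order-1) interpolation everywhere occupancy is resampled; masks
  binarized at 0.5 only at the end.
- Rotation by a multiple of 360° is skipped exactly; zoom factors equal to 1
  are skipped, making the identity augmentation bit-exact.
- Resize is skipped when the padded projection already has the output size.
- Component-size ties (table removal) break by scan order; equal-score marks
  break by distance then lesion id.
- Empty lung masks and missing tables warn rather than fail; empty nodule
  masks, inconsistent study compositions, unknown case ids and degenerate
  boxes raise validation errors before any output is produced.
- All randomness flows through `numpy.random.Generator` seeded from a single
  integer; derived seeds are reduced below 2³¹.

## Known limitations

Parallel-beam only (no cone-beam divergence or magnification); physical
anisotropy of voxel spacing is not corrected in the 2D resize beyond square
padding; the synthetic shape pool underrepresents real tumor shape variance;
no significance testing or FOM confidence intervals (the variance machinery
of observer-study toolkits is out of scope); lateral views are not
generated.
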