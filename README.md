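# cxrsim

Synthetic posteroanterior chest radiographs with perfect lung-nodule ground
truth, plus FROC/wAFROC evaluation of detection performance.

Annotating nodules on real chest radiographs is expensive and imperfect:
lesions get missed or delineated inconsistently, which caps how well a CAD
system or a reader study can be evaluated. `cxrsim` sidesteps the problem by
*building* the radiograph: 3D nodules are inserted at random positions inside
the segmented lung of a CT volume, and the volume is forward-projected with a
parallel-beam projector into a 512×512 p.a. radiograph. Because the nodules
are projected separately, every lesion comes with an exact 2D ground-truth
mask and center of mass — no annotation step, no annotation error. Any
detector's or reader's mark list (case, x, y, confidence) can then be scored
at lesion level.

## What it computes

**Simulation.** CT Hounsfield units are converted to linear attenuation with

    μ_x = μ_water + (μ_water − μ_air) · HU_x / S

(μ_water = 0.2059 cm⁻¹, monochromatic; S = 1000 or 1024). The patient table
is removed by thresholding + connected components (the second-largest
component), lungs are segmented by thresholding and slice-wise hole filling.
A pixel of the radiograph is the optical depth ∫μ dl along the
anterior–posterior ray, with the voxel size along the ray as path length.
Nodule shapes come from a seeded pool of lumpy quasi-spherical 3D shapes (or
user-supplied masks), normalized to [0,1], multiplied by the soft-tissue
attenuation, rotated in the coronal plane and rescaled to 8–20 mm before
insertion.

**Evaluation.** A mark is a lesion localization when its distance to a
ground-truth lesion center of mass is below 30 pixels (greedy one-to-one
matching by descending score). With per-case lesion weights W_kl equal and
summing to one, the package computes the FROC curve (LLF vs NLF), the wAFROC
curve

    wLLF(ζ) = (1/K_N) Σ_k Σ_l W_kl · I(z_kl ≥ ζ),
    FPF(ζ)  = (1/K_F) Σ_k I(FP_k ≥ ζ),

and the wAFROC figure of merit — the weighted two-sample statistic
FOM = (1/(K_N·K_F)) Σ_{k'} Σ_{k,l} W_kl · ψ(FP_{k'}, z_kl) with
ψ(a,b) = 1, ½, 0 for b > a, b = a, b < a — which equals the trapezoidal area
under the empirical wAFROC curve extended to (1,1).

A synthetic thorax phantom generator (body, two lungs, mediastinum, patient
table, optional blobs — all with exact truth masks) makes the entire pipeline
testable without any external CT data.

## Worked example

```python
import numpy as np
from cxrsim import (StudyConfig, SimConfig, Mark, default_pool, phantom_pool,
                    generate_study, match_marks, compute_froc, compute_wafroc,
                    wllf_at)

volumes = [v for v, _ in phantom_pool(4, seed=0, noise_sd_hu=20.0)]
cfg = StudyConfig(composition={0: 3, 1: 3, 2: 3, 3: 3},
                  size_counts={8.0: 4, 10.0: 5, 15.0: 5, 20.0: 4})
manifest, radiographs = generate_study(volumes, cfg, rng=1, pool=default_pool(seed=1))
print(f"{len(manifest.cases)} radiographs, {len(manifest.lesions)} lesions")

# a toy observer: hits 80% of lesions with jittered marks, some false positives
rng = np.random.default_rng(2)
marks = []
for _, les in manifest.lesions.iterrows():
    if rng.random() < 0.8:
        marks.append(Mark(les.case_id, les.com_x + rng.normal(0, 6),
                          les.com_y + rng.normal(0, 6), rng.uniform(0.5, 1.0)))
for _, case in manifest.cases.iterrows():
    if rng.random() < 0.25:
        marks.append(Mark(case.case_id, rng.uniform(0, 511), rng.uniform(0, 511),
                          rng.uniform(0.0, 0.7)))

ratings = match_marks(marks, manifest, radius_px=30.0)
froc, wafroc = compute_froc(ratings), compute_wafroc(ratings)
print(f"LLF at the loosest threshold: {froc.llf[-1]:.3f}")
print(f"wAFROC FOM: {wafroc.fom:.3f}")
print(f"wLLF at FPF = 0.2: {wllf_at(wafroc, 0.2):.3f}")
```

prints

```
12 radiographs, 18 lesions
LLF at the loosest threshold: 0.778
wAFROC FOM: 0.907
wLLF at FPF = 0.2: 0.852
```

The 12-case study contains 18 lesions; the toy observer localizes 77.8 % of
them at its loosest operating point, and its wAFROC figure of merit is 0.907
(1.0 would mean every lesion outscores every false positive on the
nodule-free cases). The wLLF at the FPF = 0.2 operating point summarizes
sensitivity at a fixed nodule-free false-positive fraction.

## Command line

```sh
cxrsim phantom --out vol.mhd --masks masks/ --seed 3     # synthetic thorax CT
cxrsim study --out study/ --seed 1                       # full default study set
cxrsim evaluate --manifest study/ --marks marks.csv --radius 30 --out report/
```

`cxrsim study` without `--config` uses the shipped defaults: 201 radiographs
from 21 source volumes — 20/53/67/61 cases with 0/1/2/3 nodules, 370 lesions
with diameters 32×8 mm, 111×10 mm, 120×15 mm, 107×20 mm — rendered at
512×512. Every generation command requires `--seed` and reproduces its
outputs byte for byte.

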