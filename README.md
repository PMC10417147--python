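# cbctsct — CBCT-based synthetic CTs and trigger monitoring for adaptive proton therapy

Head-and-neck proton patients change during a treatment course: targets
shrink, air cavities fill, shoulders sit differently from day to day. Because
proton range depends on the stopping power along every beam path, these
changes erode target coverage, and clinics must decide *when* a plan needs
review. Daily cone-beam CT (CBCT) sees the actual treatment-day anatomy and
setup, but its gray values are not calibrated CT numbers, so dose cannot be
recomputed on it directly.

`cbctsct` implements, end to end, the synthetic-CT image chain and the
D99-based plan-review trigger workflow that make CBCT-based dose monitoring
possible, and ships a synthetic head-and-neck phantom generator so that every
stage is testable without clinical data. It is aimed at medical-physics
researchers prototyping adaptive-monitoring pipelines.

## The image chain

From a planning CT (pCT), a same-day CBCT, and optionally a verification CT
(vfCT), three evaluation images are built:

* **corrCBCT** — the CBCT converted to CT numbers. A joint histogram of the
  deformably registered pCT and the CBCT is built inside the CBCT field of
  view retracted by 2 cm; tissue-class modes (air, soft tissue, bone, …)
  define junctions of a monotone piecewise-linear gray→HU conversion; a
  low-frequency artifact map — the low-pass-filtered (Gaussian, σ = 25 mm)
  difference against the deformed pCT — removes cupping and shading. The
  conversion and the artifact correction relax jointly until the corrected
  image changes by less than 2 HU on average. Outside the field of view the
  anatomy is extended with the deformed pCT through a 10 mm feathered band.
* **virtCT** — the pCT deformed to the CBCT, with a voxel overridden by the
  corrCBCT value wherever the two disagree in mass density by more than
  Δρ = 0.3 g/cm³ *and* the smaller density is below 0.6 g/cm³ (both strict).
  The low-density masking imports real air-cavity/fluid change without
  duplicating bone.
* **gtCT** — the vfCT deformed to the same-day CBCT: diagnostic-quality
  anatomy at the true treatment position, used as the dosimetric reference.

Doses are recomputed on each image with a simplified proton dose proxy
(per-ray spread-out-Bragg-peak depth dose in water-equivalent-path-length
coordinates, distal edge conformed per ray, no lateral scatter) and compared
through the target-coverage metric **D99** — the minimum dose received by the
best-covered 99 % of a CTV, in percent of the planned value. A case is
flagged for physician/physicist review when the D99 loss exceeds **3
percentage points on a high-risk CTV** or **5 points on a standard-risk CTV**.

## Worked example

```python
from cbctsct import *
from cbctsct.workflow import RunConfig, evaluate_case

pct, structures = generate_phantom(PhantomSpec(seed=1))
change = AnatomyChangeSpec(target_shrink_fraction=0.164,      # boost volume shrinks
                           shoulder_shift_mm=(0, 0, 6.0),     # setup difference
                           cavity_fill_fraction=0.4, seed=1)
vfct, vf_structs, true_field = apply_anatomy_change(pct, structures, change)
cbct, fov, true_inverse = simulate_cbct(vfct, CbctDegradationSpec(seed=1))

report = evaluate_case(pct, cbct, fov, structures, vfct=vfct,
                       config=RunConfig(seed=1), case_id="demo")
for kind, d in report.delta_d99.items():
    print(f"{kind:9s} dD99 high {d['CTV_HIGH']:+6.2f} pp   standard {d['CTV_STANDARD']:+6.2f} pp")
print("review needed:", report.trigger["review"],
      "| decision image:", report.trigger["decision_image"])
```

prints

```
CORRCBCT  dD99 high  +1.26 pp   standard +46.22 pp
VIRTCT    dD99 high  +1.01 pp   standard +40.45 pp
GTCT      dD99 high  +1.33 pp   standard +46.81 pp
VFCT      dD99 high  +0.62 pp   standard +43.67 pp
review needed: True | decision image: GTCT
```

The superior shoulder shift moves bone into the posterior-oblique beam paths
of the inferior (standard-risk) target: its worst-covered corner falls into
beam shadow and D99 collapses, while the superior high-risk target barely
changes — exactly the shoulder-setup failure mode that motivates daily
CBCT-based monitoring. Both CBCT-derived images (corrCBCT, virtCT) report
coverage changes close to the ground-truth CT, and the case is correctly
flagged for review.

A command-line interface mirrors the workflow:

```bash
cbctsct --seed 3 simulate -n 20 --out cohort/ --materialize 2
cbctsct evaluate-case cohort/case0000
cbctsct cohort-report cohort/
```

## Layout

| module | contents |
|---|---|
| `cbctsct.core_images` | volumes, structure sets, NIfTI/MetaImage I/O, resampling, FOV retraction |
| `cbctsct.phantoms` | synthetic pCT/vfCT/CBCT triplets, anatomy change, CBCT degradation, cohorts |
| `cbctsct.registration` | rigid alignment, focus-masked demons DIR, warping, contour mapping |
| `cbctsct.synthetic_ct` | joint histogram, conversion fit, artifact map, corrCBCT/virtCT/gtCT |
| `cbctsct.dose` | HU→SPR, WEPL ray tracing, dose proxy, DVH and D-metrics |
| `cbctsct.trigger` | ΔD99, review-trigger rules, cohort accuracy statistics, Wilcoxon test |
| `cbctsct.workflow`, `cbctsct.cli` | per-case pipeline, cohort reports, `cbctsct` command |

See `docs/methods.md` for the models, parameter choices and limitations.
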