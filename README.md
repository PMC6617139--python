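# octascreen

Quantitative OCT-angiography (OCTA) feature extraction and hierarchical
multi-task classification of retinopathies.

OCTA produces en-face maps of retinal blood flow, resolved into the
superficial (SCP) and deep (DCP) capillary plexus. Retinal diseases such
as diabetic retinopathy (DR) and sickle-cell retinopathy (SCR) distort
this vasculature in measurable ways — capillaries drop out, vessels grow
tortuous, the foveal avascular zone (FAZ) enlarges and its boundary
roughens. `octascreen` turns a pair of plexus images into six
quantitative features (13 scalars), selects the most diagnostic feature
combination per task by stepwise backward elimination, and runs a
hierarchy of linear SVMs: control vs. disease, then DR vs. SCR, then
severity staging — reporting sensitivity, specificity, accuracy, ROC
curves and AUC for each stage. It is aimed at researchers prototyping
OCTA-based screening and at anyone needing a tested reference
implementation of these vascular metrics.

## The features

For a skeleton branch with endpoints (x₁,y₁), (x₂,y₂):

* **BVT** — blood vessel tortuosity: mean over branches of
  geodesic/Euclidean length, `BVT = (1/n) Σᵢ Lᵢ(arc) / Lᵢ(chord)` (straight
  vessels → 1);
* **BVC** (µm) — blood vascular caliber: `vascular area / vascular length`
  (vessel map area over skeleton length);
* **VPI** — vessel perimeter index: `perimeter area / total image area`;
* **BVD** — blood vessel density: fraction of pixels whose local
  box-counting fractal dimension (normalized to [0,1]) is ≥ 0.7, measured
  in three circular regions of diameter 2/4/6 mm around the fovea (C1–C3)
  with the FAZ excluded;
* **FAZ-A** (µm²) — `pixel count × single-pixel area` of the segmented
  avascular zone (region-based active contour from a central seed);
* **FAZ-CI** — FAZ contour perimeter over the perimeter of the
  equal-area circle (circle → 1).

BVT/BVC/VPI come from the SCP; BVD (×3 regions), FAZ-A and FAZ-CI from
both layers. Feature selection screens univariately (logistic p < 0.15),
then backward-eliminates at a multivariate critical value of 0.10
(reported also against 0.05), with p-values Bonferroni-corrected and ties
broken by cross-validated single-feature accuracy.

No clinical images ship with the package; a phantom generator
(`octascreen.phantom`) produces angiogram-like images — radiating
sinusoid-perturbed vessels with analytic arc/chord lengths, a perturbed
FAZ with a parafoveal capillary ring, speckle and illumination bias —
with exact ground truth, plus six-group disease-staged cohorts. See
`docs/methods.md` for the model and its limits.

## Worked example

```python
import pandas as pd
from octascreen import (PhantomSpec, generate_phantom, extract_all_features,
                        generate_cohort)
from octascreen.selection import TASKS, univariate_screen, backward_eliminate
from octascreen.classify import train_task

# one synthetic eye: SCP/DCP pair with ground truth
scp, dcp, truth = generate_phantom(PhantomSpec(seed=7))
fv = extract_all_features(scp, dcp, subject_id="demo", eye="OD")
print(f"BVT={fv.bvt_s:.3f}  BVC={fv.bvc_s:.1f}um  "
      f"FAZ-A={fv.faz_a_s:.0f}um2  FAZ-CI={fv.faz_ci_s:.3f}")
```

prints

```
BVT=1.031  BVC=61.6um  FAZ-A=157765um2  FAZ-CI=1.007
```

— mildly tortuous vessels (3% longer than their chords), a ~62 µm mean
caliber, a 0.15 mm² FAZ and a nearly circular FAZ boundary, as expected
for a disease-free phantom. A full cohort run:

```python
records, _ = generate_cohort(n_per_group=20, seed=42)
rows = []
for subject, eye, label, scp, dcp, _ in records:
    row = extract_all_features(scp, dcp, subject_id=subject, eye=eye).as_dict()
    row["label"] = label
    rows.append(row)
cohort = pd.DataFrame(rows)

task = TASKS["control_vs_disease"]
trace = backward_eliminate(cohort, task, univariate_screen(cohort, task))
report = train_task(cohort, task, trace.retained, seed=42)
print(trace.retained, f"AUC={report.auc:.2f}  acc={report.accuracy:.1f}%")
```

```
['FAZ_CI_D'] AUC=1.00  acc=98.3%
```

— on this cohort the deep-layer FAZ contour irregularity alone separates
disease from control with cross-validated AUC 1.00.

The same pipeline is available from the shell:

```bash
octascreen phantom  --out run/phantoms --n-per-group 20 --seed 42
octascreen extract  --manifest run/phantoms/manifest.csv --out run/features
octascreen pipeline --features run/features/features.csv --out run/reports --seed 42
```

which writes elimination traces (JSON), per-feature accuracy and
per-task performance tables (CSV), and ROC curves per task.

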