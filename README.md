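# nodulecad

Two-stage pulmonary-nodule detection for low-dose chest CT, with
synthetic lung phantoms, end-to-end training at CPU scale, and
FROC/CPM evaluation.

Early lung-cancer screening produces large volumes of low-dose CT
scans in which radiologists must find nodules of 3–30 mm — spherical
lesions easily confused with vessels and airway walls. `nodulecad`
implements a complete CAD pipeline for this task:

* **preprocessing** — isotropic resampling, lung segmentation
  (−600 HU threshold, corner-seeded region growing, radius-6 spherical
  dilation), HU windowing [−1200, 600] → [0, 255] and mask filling;
* **MSFD-Net** — a 3D anchor-box detector on a multi-scale
  encoder–decoder backbone with squeeze-and-excitation residual
  blocks; anchors of diameter {5, 8, 11} voxels at stride 4 and
  {15, 21} at stride 8, offsets `r_i = (g_i − b_i)/b_d`,
  `r_d = ln(g_d/b_d)`; focal loss (α = 0.5, γ = 2) with online hard
  negative mining and smooth-L1 regression;
* **candidate suppression** — lung-mask suppression by mean sphere
  density (keep Cm ≥ 0.8) and 3D NMS;
* **CS-Net** — a lightweight patch scorer for false-positive
  reduction on 1×32×32×32 candidate patches;
* **evaluation** — FROC curves, the CPM (mean sensitivity at
  0.125–8 FPs/scan), CAD-performance summaries, size-stratified
  reporting, and paired t-tests on per-fold precision;
* **phantom** — a deterministic synthetic-chest generator (lungs,
  small-diameter-skewed nodules, vessel confounders, LUNA16-dialect
  CSVs) so the whole pipeline trains and evaluates without external
  data.

The networks run on a compact NumPy reverse-mode autodiff engine
(`nodulecad.nn`) — no GPU or deep-learning framework is required.

## Worked example

Generate phantoms, inspect them, and score a perfect-versus-noisy
candidate file:

```python
import numpy as np
from nodulecad.phantom import PhantomSpec, generate_phantom
from nodulecad.preprocessing import preprocess_scan
from nodulecad.evaluation import froc_curve, cpm
from nodulecad.core import Candidate

spec = PhantomSpec(volume_shape=(96, 96, 96), n_nodules=4,
                   diameter_range=(6.0, 14.0), seed=7)
vol, lung_truth, annotations = generate_phantom(spec)
pre, mask, offset = preprocess_scan(vol)
print(pre.shape, offset)
# (89, 73, 79) (4, 12, 9)

boxes = [np.r_[a.to_voxel(vol).center, a.diameter] - np.r_[offset, 0]
         for a in annotations]
cands = {spec.scan_id: [Candidate(center=tuple(b[:3]), diameter=b[3],
                                  probability=0.9) for b in boxes]}
curve = froc_curve(cands, {spec.scan_id: boxes})
print(f"CPM = {100 * curve.cpm:.2f}%")
# CPM = 100.00%
```

The seven-point CPM arithmetic matches published FROC tables; for
example the row (77.08, 84.90, 90.48, 94.04, 95.70, 95.97, 95.97)
averages to 90.59 %:

```python
from nodulecad.evaluation import cpm
print(round(cpm([77.08, 84.90, 90.48, 94.04, 95.70, 95.97, 95.97]), 2))
# 90.59
```

A complete CPU-scale experiment — train the width-halved detector and
the compact scorer on 30 phantoms, evaluate on 10 held-out ones — is
one call (takes on the order of 20 minutes on one core):

```python
from nodulecad.experiments import run_reduced_study
result = run_reduced_study(seed=0)
print("one-stage (FPs/scan, sensitivity, precision):", result.one_stage)
print("two-stage:", result.two_stage)
```

## Command line

```sh
nodulecad phantom --out-dir data --n 10 --seed 1        # synthetic dataset
nodulecad preprocess --in data/phantom-1.mhd --out-dir pre
nodulecad train-detector --data-dir data --out det.npz --epochs 20
nodulecad train-scorer --data-dir data --detector det.npz --out cs.npz
nodulecad detect --in data/phantom-1.mhd --detector det.npz \
                 --scorer cs.npz --out candidates.csv
nodulecad evaluate --candidates candidates.csv \
                   --annotations data/annotations.csv --out metrics.json
```

`detect` writes the LUNA16 submission dialect
(`seriesuid, coordX, coordY, coordZ, probability`); `evaluate` emits a
metrics JSON with the FROC seven-point readout and CPM.

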