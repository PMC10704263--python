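# polarlr

Mueller-matrix polarimetry feature extraction and patient-grouped machine
learning for prognosticating 5-year **local recurrence (LR)** from the
collagenous stroma of colorectal-cancer resection samples.

Transmission polarimetry of unstained tissue sections measures how a sample
transforms polarized light.  The transformation is a 4×4 **Mueller matrix**
`M` acting on Stokes vectors, `S_out = M S_in`.  Birefringent collagen fibers
imprint retardance, diattenuation and depolarization on `M`, so the
organization and maturity of peri-tumoral stroma — a known but
hard-to-quantify prognostic signal — becomes measurable per pixel.  This
package implements the full analysis chain:

1. **optics** — a polarization-state-generator/analyzer (PSG/PSA) forward
   model (`I_k = a_kᵀ M s_k`) and per-pixel least-squares reconstruction of
   `M` from a 24-frame acquisition protocol;
2. **decomposition** — the Lu–Chipman polar decomposition
   `M = M_Δ·M_R·M_D` (diattenuation `D`, polarizance `P`, depolarization
   power `Δ`, total retardance `R`, linear retardance `δ_L`, optical rotation
   `ψ`), the Mueller-matrix-transformation parameters `b, t1, A`, and the
   resulting 25-element feature vector (16 normalized elements + 9 derived
   parameters);
3. **roi** — aggregation of ~10²–10⁴ pixel matrices to one element-wise
   **median Mueller matrix** per region of interest (ROI), *then* feature
   extraction (the order matters and is tested);
4. **ml** — patient-grouped stratified five-fold cross-validation (no
   patient's ROIs ever straddle train and test), five standard learners
   (logistic regression, LDA, linear SVM, random forest, XGBoost),
   cross-model min-max-normalized feature-importance ranking, greedy
   leave-one-patient-out outlier elimination, and 50 %-threshold
   majority-vote patient calls with sensitivity/specificity/accuracy/AUROC
   reporting;
5. **synthetic** — a hierarchical (class → patient → ROI → pixel) two-class
   tissue cohort generator so the entire pipeline runs end-to-end with no
   external data.

## Worked example

Decompose a known composite sample (35 % depolarizer · 0.9 rad retarder at
25° · 0.12 diattenuator on the same axis):

```python
import numpy as np
from polarlr.optics import linear_retarder, isotropic_depolarizer, linear_diattenuator
from polarlr.decomposition import feature_vector

M = isotropic_depolarizer(0.35) @ linear_retarder(25, 0.9) @ linear_diattenuator(25, 0.12)
fv = feature_vector(M)
for n in ("D", "P_L", "Delta", "R", "delta_L", "b", "t1", "A"):
    print(f"{n:8s} {fv[n]: .4f}")
```

```
D         0.1200
P_L       0.0780
Delta     0.3500
R         0.9000
delta_L   0.9000
b         0.5256
t1        0.1244
A         0.4484
```

The decomposition recovers the generating diattenuation (0.12), depolarization
(0.35) and retardance (0.9 rad) exactly; `b`, `t1`, `A` summarize the central
anisotropy and are invariant to the fiber axis angle.

Run the classification workflow on a synthetic study-shaped cohort
(27 no-LR / 8 LR patients, 333 ROIs, 2500 pixels per ROI):

```python
from polarlr import synthetic, ml

cfg = synthetic.CohortConfig(roi_counts=synthetic.study_roi_counts(),
                             pixels_per_roi=2500, seed=1)
feats, pats, _ = synthetic.generate_cohort(cfg)
res = ml.run_full_workflow(feats, ["xgboost"], k=5, seed=1)
rep = res["top_features"]["xgboost"]
print(res["importance_table"].selected)
print("patient accuracy %.3f +/- %.3f" % (rep.patient["accuracy"]["mean"],
                                          rep.patient["accuracy"]["sd"]))
print("mean AUROC %.3f +/- %.3f" % (rep.auroc_mean, rep.auroc_sd))
```

```
['t1', 'm11', 'm33', 'P_L', 'R']
patient accuracy 0.971 +/- 0.057
mean AUROC 0.986 +/- 0.027
```

With the default synthetic class contrast the five selected features are
anisotropy/retardance/polarizance descriptors, and majority-vote patient
calls are correct for 34 of 35 patients on average across the five folds.

## Command line

```sh
polarlr simulate  --config cfg.yaml --seed 7 --out run/ --stacks
polarlr reconstruct --stacks run/stacks --out run/mm
polarlr features  --mueller run/mm --rois run/rois.csv --out run/features.csv
polarlr report    --features run/features.csv --patients run/patients.csv \
                  --config cfg.yaml --seed 7 --out run/report
```

Each stage is a pure function of its inputs and `--seed`; artifacts written
by one stage are read by the next (multi-page TIFF + JSON manifest, NPZ
Mueller images, CSV tables, JSON reports).

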