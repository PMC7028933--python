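# icbrad

Volumetric response assessment, 3D radiomics and response prediction for
preclinical glioma immunotherapy MRI.

Serial MRI of checkpoint-blockade-treated orthotopic mouse gliomas shows a
sharp dichotomy: some animals respond (often after a transient lesion
enlargement — pseudoprogression), others progress.  `icbrad` is the
analysis side of that experiment for imaging scientists and
immuno-oncology labs:

* **Response criteria** — a volumetric translation of the clinical
  RANO/iRANO rules for a three-scan design (baseline MRI1, on-therapy
  MRI2, post-therapy MRI3).  With %V_ab = 100·(V_a − V_b)/V_b:
  CR at %V31 = −100; PR at %V31 ≤ −65 or %V32 ≤ −65; PD at %V31 ≥ +40
  unless %V32 ≤ −30 (unconfirmed progression, rescued to SD);
  SD otherwise.  The ±65/+40 thresholds are the spherical-lesion
  conversion of the RANO −50%/+25% diameter-product rules,
  (1+a)^(3/2) − 1, rounded to the nearest 5%.  Growth patterns G1–G4
  classify the sign pair (%V21, %V32); G2 = pseudoprogression.
* **Radiomics** — a fixed 423-feature extractor (146 first-order,
  33 shape, 200 texture, 44 curvature) over an intensity volume plus
  lesion mask, with anisotropic spacing honored, plus absolute
  MRI1→MRI2 delta features and z-score normalization.
* **Prediction** — a from-scratch gradient-boosting machine on binomial
  log-loss, evaluated by two-times-repeated stratified 5-fold CV; pooled
  held-out accuracy with exact Clopper–Pearson CI, sensitivity,
  specificity, AUROC, and a one-sided exact binomial test against the
  no-information rate (NIR, the majority-class proportion).
* **Immunology scores** — geometric-mean gene-signature scores, the
  z-scored log2-fold-change immunogram, TCR top-clone share and
  productive clonality (1 − H/ln R), shared CDR3 motif detection
  (Hamming ≤ 1), and the LDH specific-lysis correction.
* **Synthetic cohorts** — seeded trajectory archetypes (direct response,
  pseudoprogression, progression, late progression), star-convex
  spherical-harmonic tumor phantoms with an injectable surface-roughness
  signal, expression tables and TCR repertoires; every stage of the
  pipeline is testable without any data download.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Classify a pseudoprogressing animal and run the imaging pipeline on a
simulated cohort:

```python
from icbrad import (VolumeTrajectory, classify_response, CohortSpec,
                    generate_cohort, ResponseModel, CVConfig)

call = classify_response(VolumeTrajectory("m01", v1=10.0, v2=20.0, v3=14.0))
print(call.category.value, call.responder, call.growth_pattern.value,
      call.pseudoprogression_rescued)
# SD True G2 True    <- doubled at MRI2, regressed 30%: rescued pseudoprogression

spec = CohortSpec(n_animals=40, grid_shape=(48, 48, 48),
                  spacing=(0.12, 0.12, 0.12), seed=7)
cohort = generate_cohort(spec, time_points=(1, 2), extract_features=True)
X = cohort.features.reset_index(drop=True)
y = (cohort.calls.set_index("animal_id")
     .loc[cohort.features.index, "responder"].astype(int).to_numpy())
report = ResponseModel(X, y).evaluate_cv(CVConfig(seed=7))
print(report.summary())
```

```
Response classifier evaluation (pooled held-out predictions)
============================================================
held-out predictions         80
accuracy                   98.8%   (95% CI 93.2-100.0%)
sensitivity (responder)    97.4%
specificity               100.0%
AUROC                     1.000
no-information rate        52.5%
P(accuracy > NIR)         3.01e-21
top features:
  shape.normalized_surface_to_volume.delta 0.290
  shape.solidity.delta                     0.158
  shape.spherical_disproportion.delta      0.156
  shape.sphericity.delta                   0.149
  shape.extent.delta                       0.139
```

Each of the 40 animals is held out twice (80 pooled predictions).  The
cohort injects its response signal into the MRI1→MRI2 change in surface
irregularity, and the classifier recovers exactly that: every top feature
is a shape-change (`.delta`) feature, and accuracy beats the 52.5% NIR
decisively.  On a signal-free cohort (`delta=0`) the same pipeline stays
at NIR.

The same steps are available from the shell:

```
icbrad simulate --n 40 --seed 7 --outdir sim/ --extract-features
icbrad classify --volumes sim/volumes.csv --out calls.csv
icbrad summarize --calls calls.csv --out summary.json
icbrad train-eval --features features.csv --labels labels.csv --out report.json
```

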