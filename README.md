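# petrad

A PET/CT radiomics pipeline for predicting tumor genotype — EGFR mutation
status in non-small-cell lung cancer — from quantitative imaging phenotypes.
It is aimed at imaging scientists who want a fully reproducible, testable
implementation of the classic radiomics workflow: lesion segmentation on
PET, conventional PET quantification, handcrafted texture features, feature
screening, and machine-learned signatures with honest cross-validation.

## What it computes

* **Segmentation.** The tumor volume of interest is the 26-connected
  relative isocontour {SUV ≥ 0.42·SUVmax}; the metabolic tumor region is
  the absolute superlevel set {SUV > 2.5} of the lesion (empty when
  SUVmax ≤ 2.5, in which case MTV = 0).
* **Conventional PET metrics.** SUVmax, SUVmean, SUVpeak (mean over a 1 cm³
  sphere at the hottest voxel), MTV (mL), and TLG = MTV × SUVmean of the
  metabolic region, with SUV = activity / (injected dose / body weight).
* **38 radiomic features per modality** on the lesion's analysis slice:
  morphology (area, perimeter, diameter, concavity = (A−B)/B against the
  convex hull), 9 grayscale statistics (moments, histogram energy/entropy,
  gray span), 6 GLCM features (ASM, contrast, correlation, entropy,
  homogeneity, dissimilarity; 16 gray levels, distance 1, averaged over
  0°/45°/90°/135°), 15 gray level–gradient co-occurrence (GGCM) statistics,
  and 4 gray-level difference statistics (GLDS) averaged over the
  displacements (0,1), (1,1), (1,0), (1,−1).
* **Statistics.** Wilcoxon rank-sum screening with Benjamini–Hochberg FDR
  at 10%, Spearman correlation against conventional metrics, Mann–Whitney
  AUC, and Noether's one-sided test of AUC > 0.5 with a DeLong variance.
* **Signatures.** LASSO-selected features feeding an AdaBoost classifier,
  evaluated by stratified 10-fold cross-validation repeated 10 times with
  all preprocessing inside the training folds, for PET-only, CT-only and
  PET/CT scopes, optionally augmented with clinical covariates (age,
  gender, smoking, stage, lesion location).
* **Phantoms.** A synthetic cohort generator (default 64 mutant / 51
  wild-type patients) producing paired PET/CT NIfTI volumes whose classes
  differ in lesion uptake, spatial heterogeneity and boundary irregularity,
  plus a matching clinical table — so the entire pipeline runs and is
  tested without any external data.

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

```python
from petrad.pipeline import RunConfig, run_pipeline, render_report

cfg = RunConfig(out_dir="demo_run", seed=7,
                phantom={"n_mutant": 30, "n_wild": 24},
                folds=6, repeats=3, scopes=("petct", "pet", "ct"),
                include_clinical=(False,), n_rounds=50)
run_pipeline(cfg)
print(render_report(cfg.out_dir).read_text())
```

prints (exactly reproducible for this seed):

```
PET/CT radiomic signature report
========================================
seed: 7
gray levels: 16; GLCM angles: [0, 45, 90, 135] at distance 1 px
CV: 6-fold x 3 repeats

features significant after BH-FDR: 23 / 81

signature performance (means over repeats):
scope     clinical  AUC     acc %    sens   spec
petct     False     0.871   82.10    0.833  0.806
pet       False     0.867   85.80    0.833  0.889
ct        False     0.604   66.67    0.633  0.708
```

Reading it: on this 54-patient phantom cohort, 23 of the 81 per-patient
quantities (5 conventional metrics + 2×38 radiomic features) separate the
classes after FDR correction; the cross-validated PET and PET/CT signatures
discriminate strongly (AUC ≈ 0.87, accuracy 82–86%) while the CT-only
signature is clearly weaker — the class contrast is deliberately placed
predominantly in the PET channel.  The bundle directory also contains
the full feature matrix, the per-feature Wilcoxon/ROC tables, the Spearman
grids and a `manifest.json` recording every applied parameter.

The same stages are available from the shell:

```bash
petrad phantom generate --out cohort/ --seed 3
petrad features extract --input cohort/ --out features.csv
petrad signature evaluate --features features.csv --cohort cohort/cohort.csv \
       --scope petct --seed 3
petrad pipeline run --out run/ --seed 3
```

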