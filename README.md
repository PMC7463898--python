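# rectomics

Radiomic texture and shape analysis of the rectal environment on
post-chemoradiation T2-weighted MRI.

## The problem

After neoadjuvant chemoradiation (nCRT), roughly half of rectal tumours
down-stage to ypT0–2 (disease confined within the rectal wall), and those
patients are candidates for less aggressive surgery. But expert restaging
on post-treatment T2w MRI is unreliable — fibrosis and residual tumour
look alike. This package implements a quantitative alternative: radiomic
descriptors of the *rectal environment* (the entire rectal wall `R^E`,
the lumen `R^L`, and the treated tumour sub-region `R^P`) that capture
the textural and morphologic signatures of tumour regression, and a
cross-validated discriminant model separating ypT0–2 from ypT3–4.

Per patient the pipeline computes:

- **764 texture features** — a 191-map bank (local histogram statistics,
  gradient/edge operators, grey-level co-occurrence (Haralick) statistics,
  Gabor wavelets, Laws energy kernels, and CoLlAGe gradient-orientation
  entropy) over a 3-section sub-volume of `R^P`, each map summarized by
  mean, variance, skewness and kurtosis;
- **198 shape features** — 25 3D morphometric descriptors for each of
  wall and lumen, 4 wall-minus-lumen diameter differences, and 72
  slice-series features per structure quantifying how wall/lumen shape
  fluctuates between consecutive sections.

Features are normalized to mean 0 / mean-absolute-deviation 1 (fit on
the discovery cohort only), pruned by Wilcoxon rank-sum significance and
|Pearson r| > 0.6 redundancy, ranked by mRMR, and assessed with repeated
stratified 3-fold cross-validation in which the *entire* selection is
re-run inside every training split — the guard against selection bias.
Final QDA models (class-conditional Gaussians, equal priors, Youden-J
threshold) are evaluated on a held-out multi-institution cohort with
AUC, MCC, sensitivity/specificity, per-institution and per-sex
breakdowns, field-strength and inter-annotator robustness statistics,
and consensus clustering of 3D t-SNE embeddings.

No patient images are distributed; a tested phantom generator produces
tube-like wall/lumen geometries with class-dependent wall thickness,
lumen eccentricity and directional intensity heterogeneity, matching the
study's cohort structure (52 discovery + 42 validation cases, 22/16
ypT0–2 respectively).

## Worked example

```bash
python analysis/03_run_pipeline.py
```

runs the whole chain on the default phantom conditions (seed 1) and
prints:

```
discovery CV / hold-out performance (positive class = ypT0-2):
  F^T   cv AUC 0.99 +- 0.02 | hold-out AUC 1.00  MCC 1.00  sens 1.00  spec 1.00
        top features: T.collage.contrast.ws3.kurtosis, T.collage.contrast.ws3.mean, T.haralick.sum_avg.ws5.kurtosis, T.laws.L3L3.skewness
  F^S   cv AUC 0.98 +- 0.04 | hold-out AUC 1.00  MCC 1.00  sens 1.00  spec 1.00
        top features: S.2d.area.variance.ERW, S.2d.eccentricity.variance.ERW, S.3d.roundness.ERW, S.3d.compactness.ERW
  F^TS  cv AUC 0.99 +- 0.02 | hold-out AUC 1.00  MCC 1.00  sens 1.00  spec 1.00
        top features: S.2d.area.variance.ERW, T.collage.contrast.ws3.kurtosis, T.collage.contrast.ws3.mean, T.haralick.sum_avg.ws5.kurtosis

unsupervised clustering accuracy (validation cohort):
  F^T   1.00
  F^S   0.62
  F^TS  1.00

field-strength comparisons significant at Bonferroni threshold: 0 of 12
wall DSC between annotation sets: 0.87
```

Reading this: the simulated class effects (thicker, more variable walls;
more eccentric lumens; stronger directional wall heterogeneity in
ypT3–4) surface in the descriptor families built to detect them —
co-occurrence/Laws texture of the wall signal and wall morphology
(section-area variability, compactness, roundness) — and the
combined texture+shape vector clusters the hold-out cohort best, while
the top features show no spurious association with scanner field
strength. Phantom classes separate more cleanly (AUC ≈ 1.0) than any
clinical cohort would; the calibrated evidence that the pipeline is
honest comes from the null and injection experiments
(`analysis/04_null_and_recovery.py`), where phantoms with identical
class parameters drive hold-out AUC to ≈ 0.5 and re-injecting d = 1.5
effects into 4 known features puts those features in the top-4
selection-frequency ranks with hold-out AUC ≈ 0.97.

`analysis/01…05` are thin narrative drivers over the library
(`src/rectomics/`): cohort simulation, feature extraction, the full
pipeline, null/recovery calibration, and the selection-bias contrast.
The `rectomics` CLI (`simulate`, `extract`, `select`, `run-all`) wraps
the same stages for shell use; outputs embed the config hash and seed,
and identical (config, seed) re-runs are byte-identical.

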