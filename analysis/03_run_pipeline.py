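#!/usr/bin/env python
"""Run the full analysis under the default study conditions.

Normalization (mean/MAD, fit on discovery only), per-block repeated
3-fold cross-validation with two-stage selection inside each training
split, frequency-based feature ranking, final QDA models with optimized
thresholds, hold-out evaluation with institution/sex breakdowns,
robustness statistics and consensus clustering of t-SNE embeddings.
All artifacts land in results/pipeline/.
"""

import json
from pathlib import Path

from rectomics.modeling import CVConfig
from rectomics.pipeline import RunConfig, run_all

OUT = Path(__file__).resolve().parents[1] / "results"

cfg = RunConfig(seed=1, cv=CVConfig(repeats=50, k=4, seed=1))
report = run_all(cfg, OUT / "pipeline")

print("discovery CV / hold-out performance (positive class = ypT0-2):")
for block, r in report["blocks"].items():
    o = r["holdout"]["overall"]
    print(f"  F^{block:<3} cv AUC {r['cv_auc_mean']:.2f} +- "
          f"{r['cv_auc_sd']:.2f} | hold-out AUC {o['auc']:.2f}  "
          f"MCC {o['mcc']:.2f}  sens {o['sensitivity']:.2f}  "
          f"spec {o['specificity']:.2f}")
    print(f"        top features: {', '.join(r['top_features'])}")
print("\nunsupervised clustering accuracy (validation cohort):")
for block, acc in report["clustering"].items():
    print(f"  F^{block:<3} {acc['overall']:.2f}")
print("\nfield-strength comparisons significant at Bonferroni threshold:",
      report["field_strength"]["n_significant"], "of 12")
print("wall DSC between annotation sets: "
      f"{report['annotation']['dsc']['ERW'][0]:.2f}")
print("\nfull report:", OUT / "pipeline" / "report.json")
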