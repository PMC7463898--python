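#!/usr/bin/env python
"""Null calibration and injected-effect parameter recovery.

Over 10 master seeds: (a) phantoms with identical class parameters must
leave the hold-out AUC near chance (any excess would indicate selection
bias leaking through the cross-validation design), and (b) after
shifting 4 known features by d = 1.5 pooled SDs, those features must
dominate the cross-validation selection-frequency ranking and restore
high hold-out AUC.  Writes per-seed results to results/.
"""

import json
from pathlib import Path

import pandas as pd

from rectomics.experiments import multi_seed_recovery

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rec = multi_seed_recovery(seeds=range(1, 11), repeats=10, k=6,
                          cache_dir=OUT)
runs = pd.DataFrame(rec["runs"])
runs.to_csv(OUT / "null_recovery_runs.csv", index=False)

print(runs[["seed", "null_holdout_auc", "injected_holdout_auc",
            "recovered"]].to_string(index=False))
print(f"\nnull hold-out AUC (mean over 10 seeds):      "
      f"{rec['mean_null_holdout_auc']:.3f}  (expect ~0.5)")
print(f"injected hold-out AUC (mean over 10 seeds):  "
      f"{rec['mean_injected_holdout_auc']:.3f}  (expect >0.85)")
print(f"seeds where the 4 injected features hold the top-4 "
      f"frequency ranks: {rec['n_recovered']}/10")
print(f"null Wilcoxon survivor fraction at p<=0.05:  "
      f"{rec['mean_null_survivor_fraction']:.3f}  (expect ~0.05)")
(OUT / "null_recovery_summary.json").write_text(
    json.dumps({k: v for k, v in rec.items() if k != "runs"}, indent=1))
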