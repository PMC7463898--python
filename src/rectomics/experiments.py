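"""Canned validation experiments on phantom cohorts.

These drive the package's own evidence that the analysis chain behaves
correctly: a null experiment (identical class parameters, so any apparent
discrimination is selection/training bias), an effect-injection
experiment (known ground-truth features shifted by a fixed Cohen's d,
checking that selection recovers them), and the full default-conditions
pipeline.  Tests, analysis scripts and the acceptance script all call
these entry points so the numbers they report come from one code path.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .features import apply_normalization, fit_normalization
from .modeling import (CVConfig, evaluate, fit_final_model,
                       optimize_threshold, rank_features_by_frequency,
                       run_repeated_cv)
from .phantom import EffectSpec, inject_feature_effects
from .pipeline import RunConfig, extract_stage
from .selection import SelectionConfig, ranksum_pvalues, select_combined

log = logging.getLogger(__name__)

#: ground-truth features for the injection experiment: two directional
#: gradient texture features and two wall-shape (thickness/irregularity)
#: features, mirroring the descriptor families the analysis is built to
#: find.
INJECTED_FEATURES = (
    "T.gradient.sobel_xy.mean",
    "T.gradient.dy.mean",
    "S.3d.compactness.ERW",
    "S.2d.convexity.variance.ERW",
)


def _split_normalized(table):
    disc_ids = table.meta.index[table.meta["cohort"] == "discovery"]
    val_ids = table.meta.index[table.meta["cohort"] == "validation"]
    params = fit_normalization(table.subset(disc_ids))
    disc = apply_normalization(table.subset(disc_ids), params)
    val = apply_normalization(table.subset(val_ids), params)
    return disc, val


def _cv_and_holdout(disc, val, seed: int, repeats: int, k: int):
    selector = lambda tr: select_combined(tr.block("T"), tr.block("S"), k=k)
    cv = run_repeated_cv(disc, CVConfig(repeats=repeats, k=k, seed=seed),
                         selector=selector)
    ranking = rank_features_by_frequency(cv)
    top = ranking["feature"].head(k).tolist()
    bundle = fit_final_model(disc, top)
    optimize_threshold(bundle, disc)
    metrics = evaluate(bundle, val)
    return cv, ranking, metrics


def null_injection_experiment(seed: int, repeats: int = 10, k: int = 6,
                              effect_size: float = 1.5,
                              cache_dir: str | Path | None = None) -> dict:
    """One master seed of the paired null / injected-effect experiment.

    Generates a 52+42 null phantom cohort (identical class parameters),
    then (a) runs the full selection+CV+hold-out chain on it as-is, and
    (b) repeats the chain after shifting the four ground-truth features by
    ``effect_size`` pooled-SD units for the ypT3-4 class.
    """
    cfg = RunConfig(seed=seed, null_phantoms=True)
    table = extract_stage(cfg, Path(cache_dir) if cache_dir else None)

    pos = (table.labels == "ypT0-2").to_numpy()
    pvals = ranksum_pvalues(table.data.to_numpy(float), pos)
    survivor_fraction = float((pvals <= 0.05).mean())

    disc, val = _split_normalized(table)
    cv_null, _, m_null = _cv_and_holdout(disc, val, seed, repeats, k)

    injected = inject_feature_effects(
        table, EffectSpec(INJECTED_FEATURES, effect_size, 0), seed=seed)
    disc_i, val_i = _split_normalized(injected)
    cv_inj, ranking, m_inj = _cv_and_holdout(disc_i, val_i, seed, repeats, k)
    top_k = ranking["feature"].head(len(INJECTED_FEATURES)).tolist()

    # unsupervised check on the injected ground truth: clustering the
    # hold-out embedding of combined top features should do at least as
    # well as shape-only top features (which carry half the signal)
    from .clustering import cluster_accuracy, consensus_cluster, tsne_3d
    from .selection import select_features

    def _cluster_acc(block):
        if block == "TS":
            feats = top_k
        else:
            sub = disc_i.block(block)
            cv_b = run_repeated_cv(
                sub, CVConfig(repeats=max(repeats // 2, 3), k=k,
                              seed=seed + 1),
                selector=lambda tr: select_features(tr, k=k))
            feats = (rank_features_by_frequency(cv_b)["feature"]
                     .head(k).tolist())
        X = val_i.data[feats].to_numpy(float)
        coords = tsne_3d(X, seed=seed)
        res = consensus_cluster(coords, iters=300, seed=seed)
        return cluster_accuracy(res.assignment,
                                val_i.labels.to_numpy())["overall"]

    clus_TS = _cluster_acc("TS")
    clus_S = _cluster_acc("S")

    return {
        "seed": seed,
        "null_cv_auc": cv_null.mean_auc,
        "null_holdout_auc": m_null["overall"]["auc"],
        "null_survivor_fraction": survivor_fraction,
        "injected_cv_auc": cv_inj.mean_auc,
        "injected_holdout_auc": m_inj["overall"]["auc"],
        "top_features": top_k,
        "recovered": set(top_k) == set(INJECTED_FEATURES),
        "clustering_acc_TS": clus_TS,
        "clustering_acc_S": clus_S,
    }


def multi_seed_recovery(seeds=range(1, 11), repeats: int = 10, k: int = 6,
                        cache_dir: str | Path | None = None) -> dict:
    """Aggregate the null/injection experiment over several master seeds."""
    runs = [null_injection_experiment(s, repeats=repeats, k=k,
                                      cache_dir=cache_dir) for s in seeds]
    return {
        "runs": runs,
        "n_seeds": len(runs),
        "n_recovered": int(sum(r["recovered"] for r in runs)),
        "mean_null_holdout_auc": float(np.mean(
            [r["null_holdout_auc"] for r in runs])),
        "mean_injected_holdout_auc": float(np.mean(
            [r["injected_holdout_auc"] for r in runs])),
        "mean_null_survivor_fraction": float(np.mean(
            [r["null_survivor_fraction"] for r in runs])),
        "mean_clustering_acc_TS": float(np.mean(
            [r["clustering_acc_TS"] for r in runs])),
        "mean_clustering_acc_S": float(np.mean(
            [r["clustering_acc_S"] for r in runs])),
    }


def selection_bias_contrast(seed: int = 1, repeats: int = 5, k: int = 4,
                            cache_dir: str | Path | None = None) -> dict:
    """Contrast honest (inside-fold) selection against selection performed
    once on the full table before CV, on null phantoms.

    The biased variant re-uses test cases during selection and therefore
    inflates apparent CV performance above chance — the failure mode the
    3-fold scheme exists to avoid.
    """
    cfg = RunConfig(seed=seed, null_phantoms=True)
    table = extract_stage(cfg, Path(cache_dir) if cache_dir else None)
    disc, _ = _split_normalized(table)

    honest_sel = lambda tr: select_combined(tr.block("T"), tr.block("S"), k=k)
    cv_honest = run_repeated_cv(disc, CVConfig(repeats=repeats, k=k, seed=seed),
                                selector=honest_sel)
    # biased: freeze the features chosen on the *entire* discovery table
    leaked = select_combined(disc.block("T"), disc.block("S"), k=k).selected
    from .selection import SelectionResult
    biased_sel = lambda tr: SelectionResult(
        selected=list(leaked), relevance={f: 0.0 for f in leaked},
        redundancy={f: 0.0 for f in leaked}, survivors=list(leaked))
    cv_biased = run_repeated_cv(disc, CVConfig(repeats=repeats, k=k, seed=seed),
                                selector=biased_sel)
    return {"honest_cv_auc": cv_honest.mean_auc,
            "biased_cv_auc": cv_biased.mean_auc}
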