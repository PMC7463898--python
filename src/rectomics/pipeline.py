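"""End-to-end orchestration: simulate -> extract -> normalize -> select ->
cross-validate -> final model -> hold-out evaluation -> robustness ->
embedding/clustering; with reproducibility metadata in every artifact.

Identical ``(config, seed)`` produce byte-identical numeric outputs.  The
extraction stage (the expensive one) is cached under ``<out>/cache`` keyed
by a content hash of the simulation/extraction configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, robustness
from .features import (FeatureTable, apply_normalization, assemble_table,
                       fit_normalization)
from .modeling import (CVConfig, ModelBundle, evaluate, fit_final_model,
                       optimize_threshold, rank_features_by_frequency,
                       run_repeated_cv)
from .phantom import PhantomParams, generate_cohorts
from .selection import SelectionConfig, select_combined, select_features

log = logging.getLogger(__name__)

BLOCKS = ("T", "S", "TS")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    n_discovery: int = 52
    n_validation: int = 42
    null_phantoms: bool = False     # identical class parameters (no effect)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    n_dual_annotation: int = 20     # cases re-annotated for agreement tests
    clustering_iters: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "phantom" in d:
            ph = d.pop("phantom")
            for key in ("n_sections", "section_shape", "spacing"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomParams(**ph)
        if "selection" in d:
            kwargs["selection"] = SelectionConfig(**d.pop("selection"))
        if "cv" in d:
            kwargs["cv"] = CVConfig(**d.pop("cv"))
        kwargs.update(d)
        return cls(**kwargs)


def demo_config(seed: int = 0) -> RunConfig:
    """Small 60-phantom demonstration configuration."""
    return RunConfig(n_discovery=36, n_validation=24,
                     cv=CVConfig(repeats=10, seed=seed),
                     n_dual_annotation=10, clustering_iters=500, seed=seed)


def _stamp(cfg: RunConfig) -> str:
    return f"config_hash={cfg.hash()} seed={cfg.seed}"


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    payload = {"config_hash": cfg.hash(), "seed": cfg.seed, "result": obj}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                               default=float))


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig,
               index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_stamp(cfg)}\n")
        df.to_csv(fh, index=index)


def simulate_stage(cfg: RunConfig):
    params = cfg.phantom.null() if cfg.null_phantoms else cfg.phantom
    return generate_cohorts(params, cfg.n_discovery, cfg.n_validation,
                            seed=cfg.seed)


def extract_stage(cfg: RunConfig, out: Path | None = None) -> FeatureTable:
    """Simulate and extract the full (discovery + validation) raw feature
    table, using the on-disk cache when available."""
    cache = None
    if out is not None:
        key_cfg = {"phantom": asdict(cfg.phantom),
                   "n_discovery": cfg.n_discovery,
                   "n_validation": cfg.n_validation,
                   "null": cfg.null_phantoms, "seed": cfg.seed}
        key = hashlib.sha256(json.dumps(key_cfg, sort_keys=True,
                                        default=str).encode()).hexdigest()[:12]
        cache = out / "cache" / f"features-{key}.csv"
        if cache.exists():
            log.info("extract stage: cache hit %s", cache.name)
            return FeatureTable.from_csv(cache)
    disc, val = simulate_stage(cfg)
    table = assemble_table(disc + val)
    if cache is not None:
        cache.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(cache, header_comment=_stamp(cfg))
    return table


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the run report (also written to
    ``<out_dir>/report.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.hash(), "seed": cfg.seed,
                    "stages": {}}
    t_start = time.time()

    def stage(name):
        report["stages"][name] = round(time.time() - t_start, 2)
        log.info("stage %s done at %.1fs", name, time.time() - t_start)

    # -- simulate + extract ------------------------------------------------
    table = extract_stage(cfg, out)
    table.to_csv(out / "features_raw.csv", header_comment=_stamp(cfg))
    stage("extract")

    # -- normalize on discovery, freeze for validation ---------------------
    disc_ids = table.meta.index[table.meta["cohort"] == "discovery"]
    val_ids = table.meta.index[table.meta["cohort"] == "validation"]
    disc_raw = table.subset(disc_ids)
    params = fit_normalization(disc_raw)
    disc = apply_normalization(disc_raw, params)
    val = apply_normalization(table.subset(val_ids), params)
    (out / "normalization.json").write_text(params.to_json())
    stage("normalize")

    # -- per-block repeated CV, ranking, final model, hold-out -------------
    results = {}
    for bi, block in enumerate(BLOCKS):
        tb = disc.block(block)
        if block == "TS":
            selector = lambda train: select_combined(
                train.block("T"), train.block("S"),
                k=cfg.cv.k, config=cfg.selection)
        else:
            selector = lambda train: select_features(
                train, k=cfg.cv.k, config=cfg.selection)
        cv_cfg = dataclasses.replace(cfg.cv, seed=cfg.seed * 10 + bi)
        cv = run_repeated_cv(tb, cv_cfg, cfg.selection, selector=selector)
        ranking = rank_features_by_frequency(cv)
        top = ranking["feature"].head(cfg.cv.k).tolist()
        bundle = fit_final_model(tb, top, cfg.cv.classifier, seed=cfg.seed)
        optimize_threshold(bundle, tb)
        metrics = evaluate(bundle, val.block(block),
                           by=("institution", "sex"))
        results[block] = {
            "cv_auc_mean": cv.mean_auc, "cv_auc_sd": cv.sd_auc,
            "cv_mcc_mean": cv.mean_mcc,
            "top_features": top, "threshold": bundle.threshold,
            "holdout": metrics,
        }
        _write_csv(cv.records.drop(columns="selected"),
                   out / f"cv_records_{block}.csv", cfg)
        _write_csv(ranking, out / f"ranking_{block}.csv", cfg)
        (out / f"model_{block}.json").write_text(bundle.to_json())
        _write_json(metrics, out / f"metrics_{block}.json", cfg)
        stage(f"model_{block}")
    report["blocks"] = results

    # -- robustness --------------------------------------------------------
    top12 = (pd.read_csv(out / "ranking_T.csv", comment="#")["feature"]
             .head(6).tolist() +
             pd.read_csv(out / "ranking_S.csv", comment="#")["feature"]
             .head(6).tolist())
    norm_all = FeatureTable(pd.concat([disc.data, val.data]),
                            pd.concat([disc.meta, val.meta]))
    field_cmp = robustness.compare_by_field_strength(norm_all, top12)
    _write_csv(field_cmp, out / "field_strength.csv", cfg)
    report["field_strength"] = {
        "threshold": float(field_cmp["threshold"].iloc[0]),
        "n_significant": int(field_cmp["significant"].sum()),
    }

    n_half = cfg.n_dual_annotation // 2
    disc_cases, val_cases = simulate_stage(cfg)
    dual = disc_cases[:n_half] + val_cases[:n_half]
    r1, r2, dsc = robustness.dual_annotation_features(dual, top12,
                                                      seed=cfg.seed)
    agree = robustness.annotation_sensitivity(r1, r2, dsc)
    _write_csv(agree.per_feature, out / "annotation_agreement.csv", cfg)
    _write_csv(agree.dsc, out / "annotation_dsc.csv", cfg)
    report["annotation"] = {
        "n_significant": int(agree.per_feature["significant"].sum()),
        "icc_below_0.5": int((agree.per_feature["icc"] < 0.5).sum()),
        "dsc": {row["structure"]: [row["mean"], row["sd"]]
                for _, row in agree.dsc.iterrows()},
    }
    stage("robustness")

    # -- unsupervised evaluation on the validation cohort ------------------
    clus = {}
    for block in BLOCKS:
        feats = results[block]["top_features"]
        X = val.data[feats].to_numpy(dtype=float)
        coords = clustering.tsne_3d(X, seed=cfg.seed)
        cons = clustering.consensus_cluster(
            coords, k=2, iters=cfg.clustering_iters, seed=cfg.seed)
        acc = clustering.cluster_accuracy(
            cons.assignment, val.labels.to_numpy())
        clus[block] = acc
    _write_json(clus, out / "clustering.json", cfg)
    report["clustering"] = clus
    stage("clustering")

    report["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float))
    return report
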