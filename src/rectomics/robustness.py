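"""Resilience analyses: field-strength comparisons, inter-annotator
feature agreement (Wilcoxon + ICC) and mask-overlap DSC summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable, extract_case_features
from .io import StudyCase, dice
from .phantom import perturb_annotations
from .selection import wilcoxon_ranksum

log = logging.getLogger(__name__)


def bonferroni_threshold(n_features: int, alpha: float = 0.05,
                         decimals: int = 3) -> float:
    """Corrected significance threshold for a family of feature tests,
    reported to the conventional 3 decimals (12 features -> 0.004)."""
    return round(alpha / n_features, decimals)


def compare_by_field_strength(t: FeatureTable,
                              features: list[str]) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of each top-ranked feature between
    1.5 T and 3.0 T scans, with the Bonferroni-corrected threshold."""
    grp = t.meta["field_T"].astype(float)
    low = t.data.loc[grp == 1.5]
    high = t.data.loc[grp == 3.0]
    if low.empty or high.empty:
        raise ValueError("both field-strength groups must be non-empty")
    thr = bonferroni_threshold(len(features))
    rows = []
    for f in features:
        stat, p = wilcoxon_ranksum(low[f].to_numpy(), high[f].to_numpy())
        rows.append({"feature": f, "statistic": stat, "p_value": p,
                     "threshold": thr, "significant": p <= thr})
    return pd.DataFrame(rows)


@dataclass
class AgreementReport:
    """Per-feature inter-annotator agreement plus per-structure DSC."""

    per_feature: pd.DataFrame      # feature, p_value, icc, significant
    dsc: pd.DataFrame              # structure, mean, sd, per-case values

    def to_csv(self, path) -> None:
        self.per_feature.to_csv(path, index=False)


def icc_2_1(values: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``values`` has shape (subjects, raters).  Returns NaN when the
    between-subject variance is zero (agreement is undefined).
    """
    import pingouin as pg

    n, k = values.shape
    if np.allclose(values.var(axis=1).sum() + values.mean(axis=1).var(), 0):
        return float("nan")
    long = pd.DataFrame({
        "targets": np.repeat(np.arange(n), k),
        "raters": np.tile(np.arange(k), n),
        "scores": values.ravel(),
    })
    try:
        res = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="scores")
    except AssertionError:
        return float("nan")
    # two-way random, absolute agreement, single rater: labelled ICC2 or
    # ICC(A,1) depending on the pingouin version
    row = res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"]
    return float(row.iloc[0])


def dual_annotation_features(cases: list[StudyCase], features: list[str],
                             seed: int = 0,
                             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Recompute features under a second (perturbed) set of wall/lumen
    annotations for each case.

    Returns ``(rater1 table, rater2 table, per-case DSC table)`` with one
    row per case; the second annotation is a deterministic jitter of the
    first (see :func:`rectomics.phantom.perturb_annotations`).
    """
    from .io import Mask

    r1, r2, dscs = [], [], []
    ids = []
    for i, case in enumerate(cases):
        wall2, lumen2 = perturb_annotations(case, seed=seed + i)
        primary2_vox = case.primary.voxels & wall2.voxels
        if primary2_vox.sum() < 10:
            primary2_vox = case.primary.voxels
        case2 = StudyCase(
            case_id=case.case_id + "_r2", volume=case.volume,
            wall=wall2, lumen=lumen2,
            primary=Mask(primary2_vox, "primary_tumor",
                         spacing=case.primary.spacing),
            ypT_group=case.ypT_group, institution=case.institution,
            field_T=case.field_T, sex=case.sex, cohort=case.cohort)
        f1 = extract_case_features(case)
        f2 = extract_case_features(case2)
        r1.append({f: f1[f] for f in features})
        r2.append({f: f2[f] for f in features})
        dscs.append({"case_id": case.case_id,
                     "dsc_ERW": dice(case.wall, wall2),
                     "dsc_Lumen": dice(case.lumen, lumen2)})
        ids.append(case.case_id)
    return (pd.DataFrame(r1, index=ids), pd.DataFrame(r2, index=ids),
            pd.DataFrame(dscs).set_index("case_id"))


def annotation_sensitivity(rater1: pd.DataFrame, rater2: pd.DataFrame,
                           dsc: pd.DataFrame | None = None,
                           alpha: float = 0.05) -> AgreementReport:
    """Pairwise Wilcoxon rank-sum and ICC(2,1) per feature between two
    annotation-derived feature sets (same cases, same features)."""
    if len(rater1) < 2:
        raise ValueError("need at least 2 dually-annotated cases")
    if list(rater1.columns) != list(rater2.columns):
        raise ValueError("rater tables must share feature columns")
    rows = []
    for f in rater1.columns:
        x = rater1[f].to_numpy(dtype=float)
        y = rater2[f].to_numpy(dtype=float)
        _, p = wilcoxon_ranksum(x, y)
        icc = icc_2_1(np.column_stack([x, y]))
        rows.append({"feature": f, "p_value": p, "icc": icc,
                     "significant": p <= alpha})
    per_feature = pd.DataFrame(rows)
    if dsc is None:
        dsc_summary = pd.DataFrame()
    else:
        dsc_summary = pd.DataFrame([
            {"structure": c.replace("dsc_", ""),
             "mean": float(dsc[c].mean()), "sd": float(dsc[c].std(ddof=1))}
            for c in dsc.columns])
    return AgreementReport(per_feature=per_feature, dsc=dsc_summary)
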