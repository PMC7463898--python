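"""Cohort feature tables and mean / mean-absolute-deviation normalization.

Texture features carry a ``T.`` prefix and shape features an ``S.``
prefix, so the texture block, the shape block and their concatenation can
be addressed by name.  Normalization subtracts the per-feature mean and
divides by the mean absolute deviation about the mean; parameters are fit
on the discovery cohort only and frozen when transforming hold-out data
(the alternative would leak hold-out information into the model).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import StudyCase
from .shape import DEFAULT_SHAPE_CONFIG, ShapeConfig, extract_shape_features
from .texture import DEFAULT_CONFIG, TextureBankConfig, extract_texture_features

log = logging.getLogger(__name__)

META_FIELDS = ("ypT_group", "institution", "field_T", "sex", "cohort")


@dataclass
class NormalizationParams:
    """Per-feature centre (mean) and scale (mean absolute deviation)."""

    center: pd.Series
    scale: pd.Series

    def to_json(self) -> str:
        return json.dumps({"center": self.center.to_dict(),
                           "scale": self.scale.to_dict()})

    @classmethod
    def from_json(cls, s: str) -> "NormalizationParams":
        d = json.loads(s)
        return cls(center=pd.Series(d["center"]), scale=pd.Series(d["scale"]))


@dataclass
class FeatureTable:
    """Cases x named features with per-case metadata.

    ``data`` is indexed by case id; ``meta`` shares the index and holds the
    label and acquisition metadata; ``normalization`` records whether the
    values are raw or normalized (and with which parameters).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    normalization: NormalizationParams | None = None

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate case id(s): {dupes}")
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the same case index")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()[:5]
            raise ValueError(f"missing values in features, e.g. {bad}")

    @property
    def labels(self) -> pd.Series:
        return self.meta["ypT_group"]

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def block(self, prefix: str) -> "FeatureTable":
        """Sub-table of one feature block: 'T', 'S' or 'TS'."""
        if prefix == "TS":
            return self
        cols = [c for c in self.data.columns if c.startswith(prefix + ".")]
        return FeatureTable(self.data[cols].copy(), self.meta.copy(),
                            self.normalization)

    def subset(self, case_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(case_ids)].copy(),
                            self.meta.loc[list(case_ids)].copy(),
                            self.normalization)

    def to_csv(self, path, header_comment: str | None = None) -> None:
        df = pd.concat(
            [self.meta.add_prefix("meta_"), self.data], axis=1)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index_label="case_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, comment="#", index_col="case_id")
        df.index.name = None
        meta_cols = [c for c in df.columns if c.startswith("meta_")]
        meta = df[meta_cols].rename(columns=lambda c: c[len("meta_"):])
        return cls(df.drop(columns=meta_cols), meta)


def extract_case_features(case: StudyCase,
                          texture_config: TextureBankConfig = DEFAULT_CONFIG,
                          shape_config: ShapeConfig = DEFAULT_SHAPE_CONFIG,
                          ) -> dict[str, float]:
    """Texture (T.) plus shape (S.) features of one case: 962 by default."""
    out = {f"T.{k}": v for k, v in
           extract_texture_features(case, texture_config).items()}
    out.update({f"S.{k}": v for k, v in
                extract_shape_features(case.wall, case.lumen,
                                       shape_config).items()})
    return out


def assemble_table(cases: Iterable[StudyCase],
                   texture_config: TextureBankConfig = DEFAULT_CONFIG,
                   shape_config: ShapeConfig = DEFAULT_SHAPE_CONFIG,
                   ) -> FeatureTable:
    """Extract and assemble the cohort feature table.

    Cases whose extraction fails are dropped with a logged reason; columns
    are sorted by name for a deterministic order.
    """
    rows, metas, ids = [], [], []
    for case in cases:
        try:
            rows.append(extract_case_features(case, texture_config, shape_config))
        except (ValueError, KeyError) as exc:
            log.warning("dropping case %s: %s", case.case_id, exc)
            continue
        ids.append(case.case_id)
        metas.append({"ypT_group": case.ypT_group,
                      "institution": case.institution,
                      "field_T": case.field_T, "sex": case.sex,
                      "cohort": case.cohort})
    data = pd.DataFrame(rows, index=ids).sort_index(axis=1)
    meta = pd.DataFrame(metas, index=ids)
    return FeatureTable(data, meta)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def fit_normalization(t: FeatureTable) -> NormalizationParams:
    """Fit per-feature centre (mean) and scale (mean absolute deviation
    about the mean); fit on the discovery cohort only.

    Zero-MAD (constant) features get NaN scale and are dropped when the
    parameters are applied.
    """
    if len(t.data) < 2:
        raise ValueError("need at least 2 cases to fit normalization")
    center = t.data.mean(axis=0)
    scale = (t.data - center).abs().mean(axis=0)
    n_zero = int((scale == 0).sum())
    if n_zero:
        log.warning("%d zero-MAD feature(s) will be dropped on apply", n_zero)
    scale = scale.replace(0.0, np.nan)
    return NormalizationParams(center=center, scale=scale)


def apply_normalization(t: FeatureTable, p: NormalizationParams) -> FeatureTable:
    """Normalize a table with previously fitted parameters; constant
    (zero-MAD) features are dropped."""
    keep = p.scale.dropna().index
    keep = [c for c in t.data.columns if c in set(keep)]
    data = (t.data[keep] - p.center[keep]) / p.scale[keep]
    return FeatureTable(data, t.meta.copy(),
                        NormalizationParams(p.center[keep], p.scale[keep]))
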