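"""Repeated cross-validated selection + classification, final model and
hold-out evaluation.

The discovery cohort is split into 3 stratified folds; two folds drive the
whole two-stage feature selection and classifier fit, the third is scored.
The scheme is repeated (50 times by default) with fresh random folds, and
features are ranked by how often they were selected across all folds — the
guard against selection bias that motivates doing selection *inside* the
resampling loop.  The positive class throughout is ypT0-2 (tumour
down-staging).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable, NormalizationParams
from .selection import POSITIVE_CLASS, SelectionConfig, select_features

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    folds: int = 3
    repeats: int = 50
    classifier: str = "qda"        # "qda" | "rfc"
    k: int = 4                     # features per model (4-6 in the study)
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("folds must be >= 2 and repeats >= 1")
        if self.classifier not in ("qda", "rfc"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class CVResult:
    """Per-fold records plus aggregate discrimination statistics."""

    records: pd.DataFrame          # repeat, fold, auc, mcc, selected (tuple)
    relevance_sums: dict           # feature -> summed mRMR relevance
    config: CVConfig

    @property
    def mean_auc(self) -> float:
        return float(self.records["auc"].mean())

    @property
    def sd_auc(self) -> float:
        return float(self.records["auc"].std(ddof=1))

    @property
    def mean_mcc(self) -> float:
        return float(self.records["mcc"].mean())

    def selection_counts(self) -> pd.Series:
        counts: dict[str, int] = {}
        for sel in self.records["selected"]:
            for f in sel:
                counts[f] = counts.get(f, 0) + 1
        return pd.Series(counts, dtype=int)


@dataclass
class Metrics:
    auc: float | None
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def mcc(self) -> float:
        return mcc_from_confusion(self.tp, self.fn, self.tn, self.fp)

    def to_dict(self) -> dict:
        return {"auc": self.auc, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "mcc": self.mcc,
                "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


@dataclass
class ModelBundle:
    """Fitted final classifier with its feature list and decision threshold."""

    classifier: str
    features: list[str]
    model: object
    threshold: float = 0.5
    normalization: NormalizationParams | None = None

    def scores(self, t: FeatureTable) -> np.ndarray:
        """Positive-class (ypT0-2) posterior scores."""
        X = t.data[self.features].to_numpy(dtype=float)
        idx = list(self.model.classes_).index(POSITIVE_CLASS)
        return self.model.predict_proba(X)[:, idx]

    def to_json(self) -> str:
        d = {"classifier": self.classifier, "features": self.features,
             "threshold": self.threshold}
        if self.classifier == "qda":
            m = self.model
            d["means"] = np.asarray(m.means_).tolist()
            d["classes"] = [str(c) for c in m.classes_]
            d["precisions"] = [p.tolist() for p in m._prec]
            d["logdets"] = list(m._logdet)
        if self.normalization is not None:
            d["normalization"] = json.loads(self.normalization.to_json())
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelBundle":
        """Rebuild a fitted QDA bundle from its JSON serialization.

        Random-forest bundles are not JSON-serializable; train and
        evaluate them within one process.
        """
        d = json.loads(s)
        if d["classifier"] != "qda":
            raise ValueError("only QDA bundles can be reloaded from JSON")
        m = GaussianQDA()
        m.classes_ = np.asarray(d["classes"])
        m.means_ = np.asarray(d["means"])
        m._prec = [np.asarray(p) for p in d["precisions"]]
        m._logdet = list(d["logdets"])
        norm = None
        if d.get("normalization") is not None:
            norm = NormalizationParams.from_json(
                json.dumps(d["normalization"]))
        return cls(classifier="qda", features=list(d["features"]), model=m,
                   threshold=float(d["threshold"]), normalization=norm)


def mcc_from_confusion(tp: int, fn: int, tn: int, fp: int) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal
    is empty (zero denominator)."""
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return num / np.sqrt(den) if den > 0 else 0.0


def confusion_from_rates(sensitivity: float, specificity: float,
                         n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Reconstruct integer confusion counts (tp, fn, tn, fp) from printed
    sensitivity/specificity percentages and the class sizes."""
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    return tp, n_pos - tp, tn, n_neg - tn


class GaussianQDA:
    """Quadratic discriminant analysis: class-conditional Gaussians with
    per-class covariance and equal priors.

    A ridge ``eps * I`` is added to any class covariance whose smallest
    eigenvalue falls below ``eps`` (logged), so small training folds with
    near-singular covariances stay usable.
    """

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_, self._prec, self._logdet = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            if Xc.shape[0] > 1:
                cov = np.cov(Xc, rowvar=False, ddof=1)
            else:
                cov = np.zeros((X.shape[1], X.shape[1]))
            cov = np.atleast_2d(cov)
            w = np.linalg.eigvalsh(cov)
            if w.min() < self.eps:
                log.debug("ridge-regularizing class %s covariance", c)
                cov = cov + self.eps * np.eye(cov.shape[0])
            self.means_.append(mu)
            self._prec.append(np.linalg.inv(cov))
            self._logdet.append(float(np.linalg.slogdet(cov)[1]))
        self.means_ = np.asarray(self.means_)
        return self

    def _log_likelihood(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ll = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            d = X - self.means_[i]
            maha = np.einsum("ij,jk,ik->i", d, self._prec[i], d)
            ll[:, i] = -0.5 * (maha + self._logdet[i])
        return ll  # equal priors: constant terms cancel

    def predict_proba(self, X):
        ll = self._log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


def _make_classifier(kind: str, seed: int):
    if kind == "qda":
        return GaussianQDA()
    return RandomForestClassifier(n_estimators=500, max_features="sqrt",
                                  random_state=seed)


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

def run_repeated_cv(t: FeatureTable, cfg: CVConfig = CVConfig(),
                    sel: SelectionConfig = SelectionConfig(),
                    selector=None) -> CVResult:
    """Randomized stratified k-fold CV with selection inside each training
    split; deterministic for a fixed ``cfg.seed``.

    ``selector`` maps a training :class:`FeatureTable` to a
    :class:`~rectomics.selection.SelectionResult`; the default runs the
    two-stage selection on all columns of the table.
    """
    if selector is None:
        selector = lambda train: select_features(train, k=cfg.k, config=sel)
    y = t.labels
    y_arr = y.to_numpy()
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 31337])
    rows = []
    relevance_sums: dict[str, float] = {}
    for rep in range(cfg.repeats):
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                                  random_state=int(rng.integers(0, 2**31)))
            splits = list(skf.split(np.zeros(len(y_arr)), y_arr))
            if all(len(np.unique(y_arr[tr])) == 2 for tr, _ in splits):
                break
            log.warning("refolding repeat %d: a fold lost a class", rep)
        for fold, (tr, te) in enumerate(splits):
            train = t.subset(t.data.index[tr])
            test = t.subset(t.data.index[te])
            res = selector(train)
            feats = res.selected
            for f in feats:
                relevance_sums[f] = relevance_sums.get(f, 0.0) + res.relevance[f]
            clf = _make_classifier(cfg.classifier,
                                   int(rng.integers(0, 2**31)))
            clf.fit(train.data[feats].to_numpy(dtype=float),
                    train.labels.to_numpy())
            idx = list(clf.classes_).index(POSITIVE_CLASS)
            s = clf.predict_proba(test.data[feats].to_numpy(dtype=float))[:, idx]
            yte = (test.labels == POSITIVE_CLASS).to_numpy()
            auc = roc_auc_score(yte, s) if len(np.unique(yte)) == 2 else np.nan
            pred = s >= 0.5
            m = Metrics(auc=None,
                        tp=int((pred & yte).sum()), fn=int((~pred & yte).sum()),
                        tn=int((~pred & ~yte).sum()), fp=int((pred & ~yte).sum()))
            rows.append({"repeat": rep, "fold": fold, "auc": auc,
                         "mcc": m.mcc, "selected": tuple(feats)})
    return CVResult(records=pd.DataFrame(rows),
                    relevance_sums=relevance_sums, config=cfg)


def rank_features_by_frequency(cv: CVResult) -> pd.DataFrame:
    """Features ordered by how often they were selected across all CV
    folds; ties break by summed mRMR relevance, then name."""
    counts = cv.selection_counts()
    df = pd.DataFrame({
        "feature": counts.index,
        "frequency": counts.to_numpy(),
        "relevance": [cv.relevance_sums.get(f, 0.0) for f in counts.index],
    })
    df = df.sort_values(["frequency", "relevance", "feature"],
                        ascending=[False, False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------

def fit_final_model(t: FeatureTable, features: list[str],
                    classifier: str = "qda", seed: int = 0) -> ModelBundle:
    missing = [f for f in features if f not in t.data.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    clf = _make_classifier(classifier, seed)
    clf.fit(t.data[features].to_numpy(dtype=float), t.labels.to_numpy())
    return ModelBundle(classifier=classifier, features=list(features),
                       model=clf, normalization=t.normalization)


def optimize_threshold(bundle: ModelBundle, t: FeatureTable) -> float:
    """Decision threshold maximizing Youden's J on the training cohort.

    Candidate thresholds are midpoints between adjacent distinct scores;
    ties resolve to the lowest such threshold.  Sets ``bundle.threshold``.
    """
    s = bundle.scores(t)
    ypos = (t.labels == POSITIVE_CLASS).to_numpy()
    uniq = np.unique(s)
    cands = np.concatenate([[0.0], (uniq[1:] + uniq[:-1]) / 2, [1.0]])
    best_j, best_t = -np.inf, 0.5
    for thr in cands:
        pred = s >= thr
        tpr = (pred & ypos).sum() / max(ypos.sum(), 1)
        fpr = (pred & ~ypos).sum() / max((~ypos).sum(), 1)
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, float(thr)
    bundle.threshold = min(max(best_t, 1e-9), 1 - 1e-9)
    return bundle.threshold


def evaluate(bundle: ModelBundle, t: FeatureTable,
             by: tuple[str, ...] = ()) -> dict:
    """Hold-out metrics (AUC by rank statistic, confusion at the bundle
    threshold) plus optional per-stratum breakdowns on metadata columns.

    A stratum containing a single class gets ``auc=None``.
    """
    def _metrics(sub: FeatureTable) -> Metrics:
        s = bundle.scores(sub)
        ypos = (sub.labels == POSITIVE_CLASS).to_numpy()
        auc = (float(roc_auc_score(ypos, s))
               if len(np.unique(ypos)) == 2 else None)
        pred = s >= bundle.threshold
        return Metrics(auc=auc,
                       tp=int((pred & ypos).sum()), fn=int((~pred & ypos).sum()),
                       tn=int((~pred & ~ypos).sum()), fp=int((pred & ~ypos).sum()))

    out = {"overall": _metrics(t).to_dict()}
    for col in by:
        strata = {}
        for val, idx in t.meta.groupby(col).groups.items():
            strata[str(val)] = _metrics(t.subset(list(idx))).to_dict()
        out[f"by_{col}"] = strata
    return out
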