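"""Two-stage feature selection: Wilcoxon/correlation pruning, then mRMR.

Stage 1 keeps features whose two-sided Wilcoxon rank-sum p-value between
the two pathologic-stage groups is at most the threshold, then scans the
survivors in ascending-p order and drops any feature correlated (|Pearson
r| above the threshold) with an already-kept feature — so the most
class-associated member of each correlated cluster survives.

Stage 2 ranks the survivors by greedy minimum-Redundancy Maximum-Relevance
forward selection with the mutual-information difference criterion:
``I(f; label) - mean_{s in selected} I(f; s)``, with features discretized
by equal-frequency binning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable

POSITIVE_CLASS = "ypT0-2"


@dataclass(frozen=True)
class SelectionConfig:
    p_threshold: float = 0.05
    corr_threshold: float = 0.6
    mi_bins: int = 10
    k: int = 6

    def __post_init__(self):
        if not (0 < self.p_threshold < 1) or not (0 < self.corr_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class SelectionResult:
    """Ordered mRMR selection with per-feature scores."""

    selected: list[str]
    relevance: dict[str, float]
    redundancy: dict[str, float]
    survivors: list[str]

    def to_json(self) -> str:
        return json.dumps({"selected": self.selected,
                           "relevance": self.relevance,
                           "redundancy": self.redundancy,
                           "survivors": self.survivors})


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, and the tie-corrected normal
    approximation otherwise.  Returns ``(rank-sum statistic of x,
    two-sided p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (no_ties and combined.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2  # U -> rank sum
    return w, float(min(res.pvalue, 1.0))


def ranksum_pvalues(X: np.ndarray, in_group1: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values (tie-corrected normal
    approximation with continuity correction) for every column of ``X``."""
    n1 = int(in_group1.sum())
    n2 = int((~in_group1).sum())
    n = n1 + n2
    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[in_group1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    # tie correction per column
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (np.abs(u1 - mu) - 0.5) / sigma
    z = np.maximum(z, 0.0)
    return np.minimum(2 * stats.norm.sf(z), 1.0)


# ---------------------------------------------------------------------------
# Stage 1: pruning
# ---------------------------------------------------------------------------

def prune(t: FeatureTable, labels: pd.Series | None = None,
          config: SelectionConfig = SelectionConfig(),
          min_keep: int = 0) -> tuple[list[str], pd.Series]:
    """Significance + correlation pruning.

    Returns ``(survivor names in ascending-p order, all p-values)``.  With
    ``min_keep > 0`` the significance cut-off is relaxed (never the
    correlation stage) so that at least that many features survive — used
    inside cross-validation folds where a hard cut could empty the pool.
    """
    labels = t.labels if labels is None else labels
    pos = (labels == POSITIVE_CLASS).to_numpy()
    if pos.sum() < 3 or (~pos).sum() < 3:
        raise ValueError("each class needs at least 3 cases for pruning")
    X = t.data.to_numpy(dtype=float)
    pvals = pd.Series(ranksum_pvalues(X, pos), index=t.data.columns)
    order = pvals.sort_values(kind="mergesort").index  # stable ties by name order
    # greedy correlation removal in ascending-p order; features past the
    # significance threshold are only admitted while below min_keep
    kept: list[str] = []
    kept_X: list[tuple[np.ndarray, float]] = []
    for f in order:
        if pvals[f] > config.p_threshold and len(kept) >= min_keep:
            break  # ascending order: nothing significant remains
        x = t.data[f].to_numpy(dtype=float)
        xc = x - x.mean()
        nx = float(np.sqrt((xc**2).sum()))
        if nx == 0:
            continue
        ok = True
        for yc, ny in kept_X:
            r = abs(float(xc @ yc) / (nx * ny))
            if r > config.corr_threshold:
                ok = False
                break
        if ok:
            kept.append(f)
            kept_X.append((xc, nx))
    return kept, pvals


# ---------------------------------------------------------------------------
# Stage 2: mRMR
# ---------------------------------------------------------------------------

def discretize_equal_frequency(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency integer codes (0..bins-1)."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two integer code vectors."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(t: FeatureTable, labels: pd.Series | None = None,
              k: int = 6, config: SelectionConfig = SelectionConfig(),
              candidates: list[str] | None = None) -> SelectionResult:
    """Greedy mRMR (mutual-information difference scheme) over candidate
    features; the first pick always maximizes marginal MI with the label."""
    labels = t.labels if labels is None else labels
    candidates = list(t.data.columns) if candidates is None else list(candidates)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidate features")
    y = (labels == POSITIVE_CLASS).to_numpy().astype(np.int64)
    codes = {f: discretize_equal_frequency(
        t.data[f].to_numpy(dtype=float), config.mi_bins) for f in candidates}
    relevance = {f: mutual_information(codes[f], y) for f in candidates}

    selected: list[str] = []
    redundancy: dict[str, float] = {}
    remaining = list(candidates)
    pair_mi: dict[tuple[str, str], float] = {}
    while len(selected) < k:
        best, best_score, best_red = None, -np.inf, 0.0
        for f in remaining:
            if selected:
                red = 0.0
                for s in selected:
                    key = (f, s)
                    if key not in pair_mi:
                        pair_mi[key] = mutual_information(codes[f], codes[s])
                    red += pair_mi[key]
                red /= len(selected)
            else:
                red = 0.0
            score = relevance[f] - red
            if score > best_score + 1e-15 or (
                    abs(score - best_score) <= 1e-15 and
                    (best is None or f < best)):
                best, best_score, best_red = f, score, red
        selected.append(best)
        redundancy[best] = best_red
        remaining.remove(best)
    return SelectionResult(selected=selected,
                           relevance={f: relevance[f] for f in selected},
                           redundancy=redundancy,
                           survivors=candidates)


def select_features(t: FeatureTable, labels: pd.Series | None = None,
                    k: int = 6, config: SelectionConfig = SelectionConfig(),
                    ) -> SelectionResult:
    """Full two-stage selection (prune, then mRMR) on one feature block."""
    survivors, _ = prune(t, labels, config, min_keep=k)
    sub = FeatureTable(t.data[survivors].copy(), t.meta.copy())
    return mrmr_rank(sub, labels, k=min(k, len(survivors)), config=config)


def select_combined(tT: FeatureTable, tS: FeatureTable,
                    labels: pd.Series | None = None, k: int = 6,
                    config: SelectionConfig = SelectionConfig(),
                    ) -> SelectionResult:
    """mRMR over the concatenation of pruned texture and shape survivors."""
    labels = tT.labels if labels is None else labels
    parts = []
    for blk in (tT, tS):
        if blk.data.shape[1] == 0:
            continue
        survivors, _ = prune(blk, labels, config, min_keep=k)
        parts.append(blk.data[survivors])
    if not parts:
        raise ValueError("both blocks are empty")
    data = pd.concat(parts, axis=1)
    merged = FeatureTable(data, tT.meta.copy())
    return mrmr_rank(merged, labels, k=min(k, data.shape[1]), config=config)
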