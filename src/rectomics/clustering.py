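"""Unsupervised evaluation: 3D t-SNE, resampled hierarchical consensus
clustering, and cluster-vs-label agreement.

Consensus clustering follows the standard resampling recipe: many rounds
of average-linkage hierarchical clustering (distance = 1 - Pearson
correlation between the 3D embedding coordinates) on random 80% patient
subsamples cut at k = 2; the consensus matrix records how often each pair
of patients co-clusters among the rounds where both were sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


def tsne_3d(X: np.ndarray, seed: int = 0, perplexity: float = 30.0,
            n_iter: int = 1000) -> np.ndarray:
    """3D t-SNE embedding (random init, Euclidean metric).

    The perplexity is reduced (with a log message) when the sample is too
    small for the requested neighbourhood size.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("t-SNE needs at least 5 samples")
    eff = min(perplexity, (n - 1) / 3)
    if eff < perplexity:
        log.info("perplexity reduced from %g to %g for n=%d",
                 perplexity, eff, n)
    # sklearn's automatic learning rate is floored at 50, which badly
    # overshoots for cohort-sized n (tens of samples) and leaves the
    # optimization unconverged; a floor of 10 converges reliably there
    lr = max(n / 12.0 / 4.0, 10.0)
    ts = TSNE(n_components=3, perplexity=eff, init="random",
              random_state=int(seed) & 0x7FFFFFFF, max_iter=n_iter,
              learning_rate=lr, metric="euclidean")
    return ts.fit_transform(X)


@dataclass
class ConsensusResult:
    consensus: np.ndarray          # n x n co-clustering frequency (NaN if never co-sampled)
    assignment: np.ndarray         # final cluster labels in {1, 2}
    n_iterations: int


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(
            "constant coordinate vector(s): Pearson distance undefined")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def consensus_cluster(coords: np.ndarray, k: int = 2, iters: int = 1000,
                      subsample: float = 0.8, seed: int = 0) -> ConsensusResult:
    """Resampled average-linkage consensus clustering of embedding rows."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for consensus clustering")
    D = _pearson_distance(coords)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 2707])
    m = int(np.ceil(subsample * n))
    co_assign = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(iters):
        idx = rng.choice(n, size=m, replace=False)
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        lab = fcluster(Z, t=k, criterion="maxclust")
        same = lab[:, None] == lab[None, :]
        co_sample[np.ix_(idx, idx)] += 1
        co_assign[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_assign / np.maximum(co_sample, 1),
                             np.nan)
    np.fill_diagonal(consensus, 1.0)
    # final assignment: average linkage on (1 - consensus)
    Dc = 1.0 - np.nan_to_num(consensus, nan=0.5)
    Dc = (Dc + Dc.T) / 2
    np.fill_diagonal(Dc, 0.0)
    Z = linkage(squareform(np.clip(Dc, 0, None), checks=False), method="average")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    return ConsensusResult(consensus=consensus, assignment=assignment,
                           n_iterations=iters)


def cluster_accuracy(assignment: np.ndarray, labels: np.ndarray | pd.Series,
                     ) -> dict:
    """Accuracy under the cluster-to-label matching that maximizes overall
    agreement; reports overall and per-class fractions."""
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    clusters = np.unique(assignment)
    if len(classes) != 2 or len(clusters) > 2:
        raise ValueError("expected a 2-class / 2-cluster problem")
    best = None
    for mapping in ([(clusters[0], classes[0]),
                     (clusters[-1], classes[-1])],
                    [(clusters[0], classes[-1]),
                     (clusters[-1], classes[0])]):
        pred = np.empty_like(labels)
        for cl, lab in mapping:
            pred[assignment == cl] = lab
        acc = float((pred == labels).mean())
        per_class = {str(c): float((pred[labels == c] == c).mean())
                     for c in classes}
        if best is None or acc > best["overall"]:
            best = {"overall": acc, "per_class": per_class}
    return best
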