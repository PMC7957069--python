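"""Sample and cell-type clustering with consensus-based K selection.

The pipeline clusters twice: cell types are grouped by average-linkage
hierarchical clustering on correlation distance, and samples are
partitioned by K-means at a K chosen by consensus clustering. Consensus
stability is summarized by the proportion of ambiguous clustering (PAC):
the mass of the consensus-entry CDF between 0.1 and 0.9, low when pairs
are either always or never co-clustered. K is the largest value whose PAC
is within a tolerance of the minimum — "group as detailed as possible"
among equally crisp solutions. The within-cluster SSE (elbow) curve is
reported for diagnostics only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger("tmescore")

PAC_LOWER = 0.1
PAC_UPPER = 0.9


@dataclass
class ConsensusResult:
    """Per-K consensus matrices, PAC values and final labels."""

    k_values: list[int]
    consensus_matrices: dict[int, np.ndarray]
    pac: dict[int, float]
    labels: dict[int, np.ndarray]
    sample_ids: list[str] | None = None


@dataclass
class SSECurve:
    """K -> total within-cluster sum of squares (best of restarts)."""

    sse: dict[int, float] = field(default_factory=dict)


def hierarchical_cluster_cells(fractions, n_clusters: int = 4) -> pd.Series:
    """Group cell types by similarity of their fraction profiles.

    Average-linkage agglomeration on distance ``1 - Pearson r`` between
    cell-type columns, cut into ``n_clusters`` groups labeled "A", "B", ...
    by decreasing size. A zero-variance cell type has undefined
    correlation; it is treated as distance 0 to everything (warning).
    """
    X = fractions.data.to_numpy(dtype=float)
    cell_types = fractions.cell_types
    if len(cell_types) < n_clusters:
        raise ValueError("more clusters requested than cell types")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    if np.isnan(r).any():
        logger.warning("hierarchical_cluster_cells: zero-variance cell type, "
                       "using zero-distance convention")
        r = np.nan_to_num(r, nan=1.0)
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel by decreasing cluster size; ties broken by first occurrence
    order = pd.Series(raw).value_counts(sort=True).index.tolist()
    letters = {cl: chr(ord("A") + i) for i, cl in enumerate(order)}
    return pd.Series([letters[c] for c in raw], index=cell_types, name="cell_cluster")


def kmeans(data, k: int, n_restarts: int = 25, seed: int = 0):
    """K-means (k-means++ init, Lloyd, best SSE over restarts).

    Returns ``(labels, sse)``.
    """
    X = np.asarray(data, dtype=float)
    if k > len(np.unique(X, axis=0)):
        raise ValueError(f"k={k} exceeds the number of distinct points")
    model = KMeans(n_clusters=k, n_init=n_restarts, max_iter=300,
                   random_state=seed % (2**32))
    labels = model.fit_predict(X)
    return labels, float(model.inertia_)


def sse_curve(data, k_values, n_restarts: int = 25, seed: int = 0) -> SSECurve:
    return SSECurve(
        {int(k): kmeans(data, int(k), n_restarts, seed)[1] for k in k_values}
    )


def pac_statistic(consensus: np.ndarray) -> float:
    """Proportion of ambiguous clustering: CDF(0.9) - CDF(0.1) of the
    off-diagonal consensus entries. 0 for a perfectly binary matrix, 1
    when every pair is ambiguous."""
    iu = np.triu_indices_from(consensus, k=1)
    entries = consensus[iu]
    return float(np.mean(entries <= PAC_UPPER) - np.mean(entries <= PAC_LOWER))


def consensus_cdf(consensus: np.ndarray):
    """Empirical CDF grid of the off-diagonal consensus entries."""
    iu = np.triu_indices_from(consensus, k=1)
    entries = np.sort(consensus[iu])
    return entries, np.arange(1, len(entries) + 1) / len(entries)


def consensus_cluster(
    data,
    k_range,
    n_reps: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    inner_restarts: int = 10,
    sample_ids=None,
) -> ConsensusResult:
    """Subsampled K-means consensus clustering over a range of K.

    For each K and repetition, a fraction ``subsample`` of samples is
    drawn without replacement and K-means-partitioned; the consensus
    matrix is the ratio of co-clustering to co-sampling counts. Final
    labels come from average-linkage clustering of ``1 - consensus`` cut
    at K.
    """
    X = np.asarray(data, dtype=float)
    n = len(X)
    if n_reps < 20:
        raise ValueError("n_reps must be at least 20")
    if not 0.5 <= subsample < 1.0:
        raise ValueError("subsample fraction must be in [0.5, 1)")
    rng = np.random.default_rng(seed)
    m = int(np.floor(subsample * n))
    k_values = [int(k) for k in k_range]

    result = ConsensusResult(k_values, {}, {}, {},
                             list(sample_ids) if sample_ids is not None else None)
    for k in k_values:
        co_cluster = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(n_reps):
            idx = rng.choice(n, size=m, replace=False)
            labels, _ = kmeans(X[idx], k, n_restarts=inner_restarts,
                               seed=int(rng.integers(2**31 - 1)))
            sampled = np.zeros(n, dtype=bool)
            sampled[idx] = True
            co_sampled += np.outer(sampled, sampled)
            for cl in range(k):
                members = idx[labels == cl]
                ind = np.zeros(n, dtype=bool)
                ind[members] = True
                co_cluster += np.outer(ind, ind)
        off = ~np.eye(n, dtype=bool)
        if (co_sampled[off] == 0).any():
            raise ValueError(
                "some sample pairs were never co-sampled; increase n_reps"
            )
        consensus = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        Z = linkage(squareform(np.clip(1.0 - consensus, 0.0, None), checks=False),
                    method="average")
        final = fcluster(Z, t=k, criterion="maxclust") - 1
        result.consensus_matrices[k] = consensus
        result.pac[k] = pac_statistic(consensus)
        result.labels[k] = final
    return result


def select_k(consensus: ConsensusResult, sse: SSECurve | None = None,
             pac_tol: float = 0.01) -> int:
    """Choose K by minimal PAC, breaking near-ties toward the LARGER K.

    Any K whose PAC is within ``pac_tol`` of the minimum is a candidate;
    the largest candidate wins (group as detailed as possible). The SSE
    curve is diagnostic only and does not enter the decision.
    """
    if len(consensus.pac) < 2:
        raise ValueError("need PAC for at least two K values")
    best = min(consensus.pac.values())
    candidates = [k for k, v in consensus.pac.items() if v <= best + pac_tol]
    return max(candidates)
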