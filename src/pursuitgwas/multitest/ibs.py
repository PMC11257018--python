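"""Identity-by-state distance and complete-linkage population clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import squareform

from ..gwas.matrix import GenotypeMatrix

__all__ = ["ClusterAssignment", "ibs_distance", "ibs_cluster"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray   # cluster id per sample, 0-based
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(np.unique(self.labels)) > self.n_clusters:
            raise ValueError("more distinct labels than n_clusters")


def ibs_distance(codes: np.ndarray, block: int = 64) -> np.ndarray:
    """Pairwise IBS distance matrix 1 - mean(shared alleles)/2.

    For two 0/1/2 genotypes the IBS share is ``2 - |g_i - g_j|``; the
    mean runs over SNPs non-missing in both samples.  Complete data goes
    through cdist; with missing data pairwise-complete means are
    computed in blocks to bound memory.
    """
    from scipy.spatial.distance import cdist

    G = np.asarray(codes, dtype=float)
    n, m = G.shape
    mask = ~np.isnan(G)
    if mask.all():
        dist = cdist(G, G, metric="cityblock") / (2.0 * m)
    else:
        Gz = np.where(mask, G, 0.0)
        maskf = mask.astype(float)
        dist = np.zeros((n, n))
        for s in range(0, n, block):
            e = min(s + block, n)
            diff = np.abs(Gz[s:e, None, :] - Gz[None, :, :])   # b x n x m
            both = mask[s:e, None, :] & mask[None, :, :]
            diff *= both
            cnt = maskf[s:e] @ maskf.T                          # pairwise complete counts
            with np.errstate(invalid="ignore", divide="ignore"):
                dist[s:e] = np.where(cnt > 0, diff.sum(axis=2) / cnt, 1.0) / 2.0
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def ibs_cluster(matrix: GenotypeMatrix, n_clusters: int) -> ClusterAssignment:
    """Complete-linkage agglomerative clustering on IBS distance.

    The tree is cut to exactly ``n_clusters`` groups; labels are
    renumbered deterministically by the lowest member sample index.
    """
    n = matrix.n_samples
    if n_clusters < 1 or n_clusters > n:
        raise ValueError("n_clusters must be in [1, n_samples]")
    if n_clusters == 1:
        return ClusterAssignment(labels=np.zeros(n, dtype=int), n_clusters=1)
    dist = ibs_distance(matrix.codes)
    Z = complete(squareform(dist, checks=False))
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # deterministic relabel: cluster containing the lowest sample index first
    order = {}
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in raw])
    return ClusterAssignment(labels=labels, n_clusters=int(labels.max()) + 1)
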