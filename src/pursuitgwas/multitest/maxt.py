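"""Within-cluster max-T permutation for familywise error control.

The observed per-SNP association statistics are compared with the
permutation distribution of the genome-wide extreme statistic:
phenotype (together with its covariate row, which travels with it) is
shuffled only within population clusters, the full per-SNP scan is
re-run, and the maximum |t| over SNPs is recorded per permutation.  The
corrected p-value of a SNP is

    (1 + #{permutations whose max |t| >= observed |t|}) / (n_perm + 1)

which is monotone in the raw p-value and never below 1/(n_perm + 1).

Permuting (phenotype, covariates) jointly against fixed genotypes is
algebraically identical to applying the inverse permutation to the
genotype rows against fixed (phenotype, covariates); the implementation
uses the latter so the covariate space can be orthonormalised once.
Missing genotypes are mean-imputed inside the permutation engine so the
observed and permuted statistics come from the same exchangeable
computation; the default ``refit`` mode recomputes the full regression
per permutation (the residualize-once alternative reuses the observed
covariate projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..gwas.matrix import GenotypeMatrix
from ..gwas.regress import _design
from .ibs import ClusterAssignment

__all__ = ["PermutationResult", "maxT_permutation"]


@dataclass
class PermutationResult:
    corrected_p: pd.DataFrame     # columns: id, p_raw, p_corrected
    n_permutations: int
    seed: int
    top_snp_id: str
    max_t_trace: np.ndarray | None = None


def _impute_mean(codes: np.ndarray) -> np.ndarray:
    G = codes.copy()
    if np.isnan(G).any():
        mu = np.nanmean(G, axis=0)
        inds = np.where(np.isnan(G))
        G[inds] = np.take(mu, inds[1])
    return G


def _within_cluster_permutation(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    perm = np.arange(len(labels))
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def maxT_permutation(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None,
    clusters: ClusterAssignment,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "refit",
    keep_trace: bool = False,
) -> PermutationResult:
    """Genome-wide corrected p-values by within-cluster max-T permutation."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("refit", "residualize_once"):
        raise ValueError("mode must be 'refit' or 'residualize_once'")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if matrix.n_samples != n or len(clusters.labels) != n:
        raise ValueError("matrix, phenotype and clusters must align")

    G = _impute_mean(matrix.codes)
    C = _design(covariates, n)
    Q, _ = np.linalg.qr(C)
    df = n - C.shape[1] - 1

    def t_stats(Gp: np.ndarray) -> np.ndarray:
        G_t = Gp - Q @ (Q.T @ Gp)
        gg = np.einsum("ij,ij->j", G_t, G_t)
        gy = G_t.T @ y_t
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            rss = yy - beta * gy
            se = np.sqrt(rss / df / gg)
            t = np.abs(beta / se)
        t[gg <= 1e-12] = 0.0
        return t

    y_t = y - Q @ (Q.T @ y)
    yy = float(y_t @ y_t)
    t_obs = t_stats(G)
    p_raw = 2.0 * stats.t.sf(t_obs, df)

    if mode == "residualize_once":
        # residualise genotypes once; per permutation only y is re-projected
        G_res = G - Q @ (Q.T @ G)

    rng = np.random.default_rng(seed)
    max_t = np.empty(n_perm)
    for b in range(n_perm):
        perm = _within_cluster_permutation(clusters.labels, rng)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(n)
        if mode == "refit":
            max_t[b] = float(np.max(t_stats(G[inv])))
        else:
            Gp = G_res[inv]
            gg = np.einsum("ij,ij->j", Gp, Gp)
            gy = Gp.T @ y_t
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = gy / gg
                rss = yy - beta * gy
                t = np.abs(beta / np.sqrt(rss / df / gg))
            t[gg <= 1e-12] = 0.0
            max_t[b] = float(np.max(t))

    max_t_sorted = np.sort(max_t)
    exceed = n_perm - np.searchsorted(max_t_sorted, t_obs, side="left")
    p_corr = (1.0 + exceed) / (n_perm + 1.0)
    out = pd.DataFrame({"id": matrix.snp_meta["id"].to_numpy(),
                        "p_raw": p_raw, "p_corrected": p_corr})
    top = out.loc[out["p_raw"].idxmin(), "id"]
    return PermutationResult(corrected_p=out, n_permutations=n_perm, seed=seed,
                             top_snp_id=str(top),
                             max_t_trace=max_t if keep_trace else None)
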