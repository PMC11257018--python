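"""Permutation test for a group difference in per-allele effect size.

The observed statistic is |beta_A - beta_B| at one SNP, where the betas
come from fitting the additive model separately in the two groups (the
real split, e.g. males vs females).  The null distribution re-splits the
cohort at random into groups of the same sizes; the p-value uses the
add-one estimator (r + 1) / (n_perm + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..gwas.matrix import GenotypeMatrix
from ..gwas.regress import fit_additive

__all__ = ["sex_effect_permutation"]


def _beta_diff(g, y, C, idx_a, idx_b) -> float:
    Ca = C[idx_a] if C is not None else None
    Cb = C[idx_b] if C is not None else None
    ba, *_ = fit_additive(g[idx_a], y[idx_a], Ca)
    bb, *_ = fit_additive(g[idx_b], y[idx_b], Cb)
    return abs(ba - bb)


def sex_effect_permutation(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None,
    group_a: np.ndarray,
    snp_id: str,
    n_perm: int = 10_000,
    seed: int = 0,
    max_redraws: int = 100,
) -> tuple[float, float, np.ndarray]:
    """p-value for |beta(group A) - beta(group B)| at one SNP.

    ``group_a`` is a boolean mask of the real split (e.g. female).
    Permutation draws that leave the SNP monomorphic in a group are
    redrawn (and counted); returns (p, observed statistic, null stats).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    n = len(y)
    if len(group_a) != n or matrix.n_samples != n:
        raise ValueError("inputs must align on samples")
    ids = matrix.snp_meta["id"].to_numpy()
    cols = np.flatnonzero(ids == snp_id)
    if cols.size == 0:
        raise KeyError(f"SNP {snp_id!r} not in matrix")
    g = matrix.codes[:, cols[0]]
    C = np.asarray(covariates, dtype=float) if covariates is not None else None
    if C is not None and C.ndim == 1:
        C = C[:, None]

    idx_a = np.flatnonzero(group_a)
    idx_b = np.flatnonzero(~group_a)
    g1 = len(idx_a)
    observed = _beta_diff(g, y, C, idx_a, idx_b)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_redrawn = 0
    for b in range(n_perm):
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            try:
                null[b] = _beta_diff(g, y, C, perm[:g1], perm[g1:])
                break
            except ValueError:
                n_redrawn += 1
        else:
            raise RuntimeError("could not draw a valid split; SNP nearly monomorphic")
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return float(p), float(observed), null
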