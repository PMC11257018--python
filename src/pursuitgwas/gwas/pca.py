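"""Principal components of genetic variation (stratification covariates)."""

from __future__ import annotations

import numpy as np

from .matrix import GenotypeMatrix

__all__ = ["genotype_pca"]


def genotype_pca(matrix: GenotypeMatrix, k: int = 3,
                 return_eigenvalues: bool = False):
    """Top-k sample scores of the standardised genotype matrix.

    Each SNP column is centred at 2*p_hat and scaled by
    sqrt(2*p_hat*(1-p_hat)); missing genotypes are mean-imputed for the
    decomposition only.  Scores are the left singular vectors scaled by
    their singular values, with a deterministic sign convention (the
    largest-|loading| entry of each right singular vector is positive).
    """
    n, m = matrix.codes.shape
    if k < 1 or k >= min(n, m):
        raise ValueError(f"k must be in [1, min(n_samples, n_snps) - 1], got {k}")
    X = matrix.codes.copy()
    p_hat = np.nanmean(X, axis=0) / 2.0
    mu = 2.0 * p_hat
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= mu
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    keep = scale > 0
    X = X[:, keep] / scale[keep]

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    scores = U * S
    if return_eigenvalues:
        eigvals = S**2 / (n - 1)
        return scores, eigvals
    return scores
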