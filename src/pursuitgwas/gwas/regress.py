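"""Per-SNP additive-model association by ordinary least squares.

Each SNP is tested by regressing the quantitative phenotype on the
0/1/2 minor-allele count together with the covariates and an intercept;
the reported p-value is two-sided from the t distribution with
``n_used - n_parameters`` degrees of freedom.  Samples with a missing
genotype at a SNP are dropped for that SNP only (complete-case per SNP,
as in PLINK).  SNP columns with no missing data are fitted in a single
vectorised pass through the Frisch-Waugh-Lovell decomposition; the two
routes are algebraically identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .hwe import hwe_exact_test
from .matrix import GenotypeMatrix

__all__ = ["fit_additive", "run_gwas", "batched_t_stats"]

P_FLOOR = 1e-300


def _design(covariates: np.ndarray | pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if len(C) != n:
        raise ValueError("covariate rows must match phenotype length")
    if np.isnan(C).any():
        raise ValueError("covariates must not contain missing values")
    return np.column_stack([np.ones(n), C])


def fit_additive(genotype: np.ndarray, phenotype: np.ndarray,
                 covariates: np.ndarray | pd.DataFrame | None = None,
                 ) -> tuple[float, float, float, float, int]:
    """OLS fit of phenotype on one genotype vector plus covariates.

    Returns (beta, se, t, p, n_used) for the genotype term.  Raises on
    monomorphic genotypes and collinear designs.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    C = _design(covariates, len(y))
    keep = ~np.isnan(g) & ~np.isnan(y)
    g, y, C = g[keep], y[keep], C[keep]
    n = len(y)
    k = C.shape[1] + 1
    if n < k + 2:
        raise ValueError(f"too few complete cases ({n}) for {k} parameters")
    if np.ptp(g) == 0:
        raise ValueError("monomorphic genotype: zero variance")
    X = np.column_stack([g, C])
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < X.shape[1]:
        raise ValueError("collinear design matrix")
    beta_all, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_all
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    beta = float(beta_all[0])
    se = float(np.sqrt(cov_beta[0, 0]))
    t = beta / se
    p = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)
    return beta, se, float(t), float(p), n


def batched_t_stats(G: np.ndarray, y: np.ndarray,
                    covariates: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorised per-SNP (beta, se, t) for a complete genotype block.

    ``G`` is n x m with no missing values.  Uses an orthonormal basis Q
    of the intercept-plus-covariate space: with g~ = g - Q Q'g and
    y~ = y - Q Q'y, beta = g~.y~ / g~.g~ and the residual df is
    n - n_covariates - 2.
    """
    n = len(y)
    C = _design(covariates, n)
    Q, _ = np.linalg.qr(C)
    y_t = y - Q @ (Q.T @ y)
    G_t = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", G_t, G_t)
    gy = G_t.T @ y_t
    yy = float(y_t @ y_t)
    df = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = yy - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    bad = gg <= 1e-12
    beta[bad] = np.nan
    se[bad] = np.nan
    t[bad] = np.nan
    return beta, se, t, df


def run_gwas(matrix: GenotypeMatrix, phenotype: np.ndarray | pd.Series,
             covariates: np.ndarray | pd.DataFrame | None = None,
             rank_transform: bool = False,
             compute_hwe: bool = True) -> pd.DataFrame:
    """Additive association at every SNP; returns a table sorted by p.

    Columns: chrom pos id a1 a2 maf n_used beta se t p hwe_p (plus
    ``error`` for SNPs whose fit failed, recorded rather than fatal).
    With ``rank_transform`` the phenotype is replaced by its average
    ranks (ties averaged) before regression.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != matrix.n_samples:
        raise ValueError("phenotype length must match sample count")
    if rank_transform:
        y = stats.rankdata(y, method="average")
    n, m = matrix.codes.shape

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tval = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    errors = np.array([""] * m, dtype=object)

    complete = ~np.isnan(matrix.codes).any(axis=0)
    mono = np.nanstd(matrix.codes, axis=0) == 0
    fast = complete & ~mono
    if fast.any():
        b, s, t, df = batched_t_stats(matrix.codes[:, fast], y, covariates)
        p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR)
        beta[fast], se[fast], tval[fast], pval[fast] = b, s, t, p
        n_used[fast] = n
    for j in np.where(~fast)[0]:
        try:
            beta[j], se[j], tval[j], pval[j], n_used[j] = fit_additive(
                matrix.codes[:, j], y, covariates)
        except ValueError as exc:
            errors[j] = str(exc)

    out = matrix.snp_meta.copy().reset_index(drop=True)
    out["maf"] = matrix.maf()
    out["n_used"] = n_used
    out["beta"] = beta
    out["se"] = se
    out["t"] = tval
    out["p"] = pval
    if compute_hwe:
        out["hwe_p"] = [hwe_exact_test(*matrix.genotype_counts(j)) if not mono[j] else 1.0
                        for j in range(m)]
    out["error"] = errors
    return out.sort_values("p", na_position="last").reset_index(drop=True)
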