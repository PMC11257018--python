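"""Composite linkage disequilibrium between genotype vectors."""

from __future__ import annotations

import numpy as np

__all__ = ["ld_r2", "ld_r2_with_index"]


def ld_r2(genotypes_i: np.ndarray, genotypes_j: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1/2 codes (pairwise complete).

    Invariant to allele-label flips of either SNP; raises on zero
    variance among the shared non-missing samples.
    """
    gi = np.asarray(genotypes_i, dtype=float)
    gj = np.asarray(genotypes_j, dtype=float)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have equal length")
    keep = ~np.isnan(gi) & ~np.isnan(gj)
    gi, gj = gi[keep], gj[keep]
    if len(gi) < 2 or np.ptp(gi) == 0 or np.ptp(gj) == 0:
        raise ValueError("LD undefined: zero genotype variance")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def ld_r2_with_index(codes: np.ndarray, index_col: int) -> np.ndarray:
    """r^2 of every SNP column with the index column (NaN where undefined)."""
    m = codes.shape[1]
    out = np.full(m, np.nan)
    gi = codes[:, index_col]
    for j in range(m):
        try:
            out[j] = ld_r2(gi, codes[:, j])
        except ValueError:
            continue
    return out
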