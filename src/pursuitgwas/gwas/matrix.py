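"""Genotype matrix container: n samples x m SNPs of minor-allele counts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

SNP_META_COLUMNS = ["chrom", "pos", "id", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Diploid genotypes coded as counts of allele 1 (0/1/2, NaN = missing).

    ``snp_meta`` has one row per SNP with columns chrom, pos (1-based bp),
    id, a1, a2.  After :meth:`orient_minor` allele 1 is the minor allele
    (frequency <= 0.5) at every SNP.
    """

    codes: np.ndarray                 # float array, n x m, values 0/1/2/NaN
    snp_meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array (samples x SNPs)")
        n, m = self.codes.shape
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta rows must match number of SNP columns")
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise ValueError(f"snp_meta missing columns: {missing_cols}")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids must match number of rows")
        ok = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def allele1_freq(self) -> np.ndarray:
        """Observed frequency of allele 1 per SNP (ignoring missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele1_freq()
        return np.minimum(f, 1.0 - f)

    def snp_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.codes), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.codes), axis=1)

    def orient_minor(self) -> tuple["GenotypeMatrix", np.ndarray]:
        """Flip SNPs so allele 1 is the minor allele; returns (matrix, flipped mask)."""
        f = self.allele1_freq()
        flip = f > 0.5
        codes = self.codes.copy()
        codes[:, flip] = 2.0 - codes[:, flip]
        meta = self.snp_meta.copy().reset_index(drop=True)
        a1 = meta["a1"].to_numpy().copy()
        a2 = meta["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
        meta["a1"], meta["a2"] = a1, a2
        return GenotypeMatrix(codes, meta, list(self.sample_ids)), flip

    def subset(self, samples: np.ndarray | None = None,
               snps: np.ndarray | None = None) -> "GenotypeMatrix":
        codes = self.codes
        sample_ids = list(self.sample_ids)
        meta = self.snp_meta.reset_index(drop=True)
        if samples is not None:
            codes = codes[samples, :]
            sample_ids = [sid for sid, keep in zip(sample_ids, np.asarray(samples))
                          if keep] if np.asarray(samples).dtype == bool else \
                         [sample_ids[i] for i in np.asarray(samples)]
        if snps is not None:
            codes = codes[:, snps]
            meta = meta.loc[np.asarray(snps)].reset_index(drop=True) \
                if np.asarray(snps).dtype != bool else meta.loc[snps].reset_index(drop=True)
        return GenotypeMatrix(codes.copy(), meta, sample_ids)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_11, n_12, n_22): hom allele1, het, hom allele2 at SNP j."""
        g = self.codes[:, j]
        g = g[~np.isnan(g)]
        return int(np.sum(g == 2)), int(np.sum(g == 1)), int(np.sum(g == 0))
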