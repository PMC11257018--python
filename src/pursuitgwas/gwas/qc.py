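"""Genotype quality control.

Filters are applied in a fixed order: (1) drop samples with genotyping
call rate below the sample threshold; (2) drop SNPs whose missing
fraction among retained samples exceeds the missingness threshold;
(3) drop SNPs with minor allele frequency (computed after the sample
exclusions) below the MAF threshold.  HWE is computed and reported per
SNP but used as a filter only if a threshold is explicitly supplied.
Optionally, population outliers (extreme PC scores) and one member of
each near-duplicate pair (high IBS similarity) are removed first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .hwe import hwe_exact_test
from .matrix import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "run_qc"]


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate: float = 0.97
    snp_missing_rate: float = 0.02
    maf: float = 0.01
    hwe_p: float | None = None          # report-only unless set
    pc_outlier_sd: float | None = None  # |PC score| > k SD on top PCs
    ibs_duplicate: float | None = None  # pairwise IBS similarity cutoff


@dataclass
class QCReport:
    n_samples_in: int = 0
    n_snps_in: int = 0
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_snps: dict[str, int] = field(default_factory=dict)
    n_samples_out: int = 0
    n_snps_out: int = 0
    n_flipped_to_minor: int = 0
    per_snp: dict = field(default_factory=dict)  # id -> {maf, missing_rate, hwe_p}

    def to_dict(self) -> dict:
        return asdict(self)


def _duplicate_exclusions(matrix: GenotypeMatrix, cutoff: float) -> list[int]:
    from ..multitest.ibs import ibs_distance
    sim = 1.0 - ibs_distance(matrix.codes)
    np.fill_diagonal(sim, 0.0)
    drop: set[int] = set()
    for i, j in zip(*np.where(np.triu(sim, 1) > cutoff)):
        if i not in drop and j not in drop:
            drop.add(int(max(i, j)))  # keep the lower index of the pair
    return sorted(drop)


def run_qc(matrix: GenotypeMatrix,
           thresholds: QCThresholds = QCThresholds()) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC filter cascade; returns the filtered matrix and a report.

    The surviving matrix is minor-allele oriented (allele 1 frequency
    <= 0.5 at every SNP).  Raises ValueError if nothing survives.
    """
    report = QCReport(n_samples_in=matrix.n_samples, n_snps_in=matrix.n_snps)
    work = matrix

    # optional relatedness / outlier exclusions first (as in array QC)
    if thresholds.ibs_duplicate is not None and work.n_samples > 1:
        dup = _duplicate_exclusions(work, thresholds.ibs_duplicate)
        if dup:
            keep = np.ones(work.n_samples, dtype=bool)
            keep[dup] = False
            for i in dup:
                report.excluded_samples.append((work.sample_ids[i], "duplicate_or_related"))
            work = work.subset(samples=keep)
    if thresholds.pc_outlier_sd is not None and work.n_samples > 3:
        from .pca import genotype_pca
        scores = genotype_pca(work, k=min(3, work.n_samples - 1))
        z = (scores - scores.mean(axis=0)) / scores.std(axis=0)
        out = np.where(np.any(np.abs(z) > thresholds.pc_outlier_sd, axis=1))[0]
        if out.size:
            keep = np.ones(work.n_samples, dtype=bool)
            keep[out] = False
            for i in out:
                report.excluded_samples.append((work.sample_ids[i], "population_outlier"))
            work = work.subset(samples=keep)

    # 1) sample call rate
    cr = work.sample_call_rate()
    low = cr < thresholds.sample_call_rate
    if low.any():
        for i in np.where(low)[0]:
            report.excluded_samples.append((work.sample_ids[i], "low_call_rate"))
        work = work.subset(samples=~low)
    if work.n_samples == 0:
        raise ValueError("QC removed every sample")

    # 2) SNP missingness (recomputed on retained samples)
    miss = work.snp_missing_rate()
    drop_miss = miss > thresholds.snp_missing_rate
    report.excluded_snps["missingness"] = int(drop_miss.sum())
    work = work.subset(snps=~drop_miss)

    # 3) MAF, computed post sample QC
    maf = work.maf()
    drop_maf = maf < thresholds.maf
    report.excluded_snps["maf"] = int(drop_maf.sum())
    work = work.subset(snps=~drop_maf)
    if work.n_snps == 0:
        raise ValueError("QC removed every SNP")

    work, flipped = work.orient_minor()
    report.n_flipped_to_minor = int(flipped.sum())

    maf = work.maf()
    miss = work.snp_missing_rate()
    hwe_p = np.array([hwe_exact_test(*work.genotype_counts(j)) for j in range(work.n_snps)])
    if thresholds.hwe_p is not None:
        drop_hwe = hwe_p < thresholds.hwe_p
        report.excluded_snps["hwe"] = int(drop_hwe.sum())
        work = work.subset(snps=~drop_hwe)
        maf, miss, hwe_p = maf[~drop_hwe], miss[~drop_hwe], hwe_p[~drop_hwe]

    report.per_snp = {
        sid: {"maf": float(m), "missing_rate": float(mi), "hwe_p": float(h)}
        for sid, m, mi, h in zip(work.snp_meta["id"], maf, miss, hwe_p)
    }
    report.n_samples_out = work.n_samples
    report.n_snps_out = work.n_snps
    return work, report
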