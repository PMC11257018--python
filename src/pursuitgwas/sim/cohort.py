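"""Simulate genotype/phenotype cohorts with known ground truth.

Genotypes are drawn under Hardy-Weinberg equilibrium within each
population cluster.  Cluster allele frequencies follow a
Balding-Nichols draw around the ancestral frequency with dispersion
controlled by an Fst-like divergence parameter.  The quantitative
phenotype is built on a standardised scale:

    y = beta * g_causal + sex_sd * z_sex + cluster_sd * z_cluster + e

with the residual variance chosen so the total variance is 1, so
``beta`` is directly the per-minor-allele effect in phenotype SD units
and the causal SNP explains ``beta^2 * 2 p (1-p)`` of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..gwas.matrix import GenotypeMatrix

__all__ = ["CausalSpec", "SimCohortConfig", "CohortTruth", "simulate_cohort",
           "simulate_ld_block_cohort"]


@dataclass(frozen=True)
class CausalSpec:
    maf: float = 0.49
    beta_sd_per_allele: float = 0.29


@dataclass(frozen=True)
class SimCohortConfig:
    n_individuals: int = 980
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snp: CausalSpec | None = CausalSpec()
    sex_effect_sd: float = 0.1
    n_clusters: int = 1
    cluster_divergence: float = 0.0
    cluster_effect_sd: float = 0.0
    missing_rate: float = 0.0
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1 or self.n_clusters < 1:
            raise ValueError("n_individuals, n_snps, n_clusters must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.causal_snp is not None and not (0.0 < self.causal_snp.maf <= 0.5):
            raise ValueError("causal maf must be in (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.cluster_divergence < 0:
            raise ValueError("cluster_divergence must be >= 0")


@dataclass
class CohortTruth:
    causal_index: int | None
    genotype_of_causal: np.ndarray | None
    phenotype_components: pd.DataFrame   # columns: genetic, covariate, residual
    cluster_labels: np.ndarray
    sex: np.ndarray                      # 1 = female
    ancestral_freqs: np.ndarray
    beta_true: float = 0.0


def _balding_nichols(p: np.ndarray, fst: float, n_clusters: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Cluster-specific allele frequencies, shape (n_clusters, m)."""
    if fst <= 0 or n_clusters == 1:
        return np.tile(p, (n_clusters, 1))
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    freqs = rng.beta(np.tile(a, (n_clusters, 1)), np.tile(b, (n_clusters, 1)))
    return np.clip(freqs, 1e-3, 1.0 - 1e-3)


def simulate_cohort(config: SimCohortConfig) -> tuple[GenotypeMatrix, pd.DataFrame, CohortTruth]:
    """Draw a cohort; returns (genotypes, phenotype table, truth).

    The phenotype table has columns sample_id, phenotype, sex.  The
    causal SNP sits at column ``n_snps // 2``; missingness is applied
    completely at random at ``missing_rate`` (never to the truth log).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    causal_idx = None
    beta = 0.0
    if config.causal_snp is not None:
        causal_idx = m // 2
        p[causal_idx] = config.causal_snp.maf
        beta = config.causal_snp.beta_sd_per_allele

    clusters = rng.integers(0, config.n_clusters, size=n)
    freqs = _balding_nichols(p, config.cluster_divergence, config.n_clusters, rng)
    genotypes = rng.binomial(2, freqs[clusters, :]).astype(float)

    sex = (rng.random(n) < config.female_fraction).astype(float)
    g_causal = genotypes[:, causal_idx].copy() if causal_idx is not None else None

    genetic = np.zeros(n)
    if causal_idx is not None and beta != 0.0:
        genetic = beta * (g_causal - g_causal.mean())
    z_sex = sex - sex.mean()
    sd_sex = z_sex.std()
    cov = config.sex_effect_sd * (z_sex / sd_sex if sd_sex > 0 else z_sex)
    if config.cluster_effect_sd > 0 and config.n_clusters > 1:
        c_eff = rng.normal(0.0, 1.0, config.n_clusters)[clusters]
        c_eff = (c_eff - c_eff.mean()) / max(c_eff.std(), 1e-12)
        cov = cov + config.cluster_effect_sd * c_eff

    var_explained = float(np.var(genetic) + np.var(cov))
    resid_var = 1.0 - var_explained
    if resid_var <= 0:
        raise ValueError("effect sizes leave no residual variance: "
                         f"explained {var_explained:.3f} >= 1")
    residual = rng.normal(0.0, np.sqrt(resid_var), n)
    residual -= residual.mean()
    y = genetic + cov + residual
    y = y / y.std()   # unit total variance on the realized sample

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = np.nan

    sample_ids = [f"S{i:05d}" for i in range(n)]
    meta = pd.DataFrame({
        "chrom": "1",
        "pos": 50_000 * (np.arange(m) + 1),
        "id": [f"snp{j:05d}" for j in range(m)],
        "a1": "A",
        "a2": "G",
    })
    matrix = GenotypeMatrix(genotypes, meta, sample_ids)
    pheno = pd.DataFrame({"sample_id": sample_ids, "phenotype": y, "sex": sex.astype(int)})
    truth = CohortTruth(
        causal_index=causal_idx,
        genotype_of_causal=g_causal,
        phenotype_components=pd.DataFrame(
            {"genetic": genetic, "covariate": cov, "residual": residual}),
        cluster_labels=clusters,
        sex=sex.astype(int),
        ancestral_freqs=p,
        beta_true=beta,
    )
    return matrix, pheno, truth


def simulate_ld_block_cohort(
    n_individuals: int = 500,
    n_null_snps: int = 500,
    block_size: int = 10,
    block_maf: float = 0.3,
    copy_fidelity: float = 0.92,
    beta: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Cohort with one LD block around a causal SNP plus independent null SNPs.

    Block SNPs copy the causal SNP's haplotype alleles with probability
    ``copy_fidelity`` (else an independent Bernoulli draw), giving
    pairwise haplotype correlation ~fidelity^2 between block members and
    ~fidelity with the causal SNP.  The block occupies a contiguous
    physical window in the middle of the map.
    """
    rng = np.random.default_rng(seed)
    n = n_individuals
    m = n_null_snps + block_size
    p_null = rng.uniform(0.05, 0.5, size=m)

    # haplotype-level simulation for the block
    hap_causal = (rng.random((n, 2)) < block_maf).astype(float)
    block = np.empty((n, 2, block_size))
    for j in range(block_size):
        keep = rng.random((n, 2)) < copy_fidelity
        indep = (rng.random((n, 2)) < block_maf).astype(float)
        block[:, :, j] = np.where(keep, hap_causal, indep)
    block_geno = block.sum(axis=1)
    g_causal = hap_causal.sum(axis=1)

    genotypes = rng.binomial(2, p_null, size=(n, m)).astype(float)
    start = n_null_snps // 2
    causal_col = start + block_size // 2
    genotypes[:, start : start + block_size] = block_geno
    genotypes[:, causal_col] = g_causal

    y = beta * (g_causal - g_causal.mean())
    y = y + rng.normal(0.0, np.sqrt(max(1.0 - y.var(), 0.1)), n)

    pos = 50_000 * (np.arange(m) + 1)
    # compress the block into a 200 kb physical window
    pos[start : start + block_size] = pos[start] + 20_000 * np.arange(block_size)
    pos[start + block_size :] = pos[start] + 20_000 * block_size + \
        50_000 * (np.arange(m - start - block_size) + 1)
    meta = pd.DataFrame({"chrom": "1", "pos": pos,
                         "id": [f"snp{j:05d}" for j in range(m)],
                         "a1": "A", "a2": "G"})
    sample_ids = [f"S{i:05d}" for i in range(n)]
    matrix = GenotypeMatrix(genotypes, meta, sample_ids)
    pheno = pd.DataFrame({"sample_id": sample_ids, "phenotype": y,
                          "sex": rng.integers(0, 2, n)})
    truth = {"causal_index": int(causal_col),
             "causal_id": meta.loc[causal_col, "id"],
             "causal_pos": int(meta.loc[causal_col, "pos"]),
             "block_indices": list(range(start, start + block_size))}
    return matrix, pheno, truth
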