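"""Simulate a quantitative-trait cohort and run the association scan.

The cohort mirrors the study's operating point: 980 individuals, a
causal SNP at minor allele frequency 0.49 whose each additional minor
allele shifts the standardized phenotype by 0.29 SD (variance explained
~0.043), plus a small sex effect.  The scan regresses the phenotype on
each SNP's 0/1/2 minor-allele count with sex and three genotype
principal components as covariates.
"""

import numpy as np

from pursuitgwas.gwas import QCThresholds, genomic_inflation, genotype_pca, run_gwas, run_qc
from pursuitgwas.sim import CausalSpec, SimCohortConfig, simulate_cohort

config = SimCohortConfig(n_individuals=980, n_snps=2000,
                         causal_snp=CausalSpec(maf=0.49, beta_sd_per_allele=0.29),
                         missing_rate=0.01, seed=1)
matrix, pheno, truth = simulate_cohort(config)

matrix_qc, report = run_qc(matrix, QCThresholds())
print(f"QC: {report.n_samples_in} -> {report.n_samples_out} samples, "
      f"{report.n_snps_in} -> {report.n_snps_out} SNPs "
      f"(missingness {report.excluded_snps['missingness']}, "
      f"MAF {report.excluded_snps['maf']})")

pcs = genotype_pca(matrix_qc, k=3)
covars = np.column_stack([pheno["sex"].to_numpy(dtype=float), pcs])
results = run_gwas(matrix_qc, pheno["phenotype"].to_numpy(), covars)

top = results.iloc[0]
causal_id = f"snp{truth.causal_index:05d}"
print(f"top SNP: {top['id']}  beta={top['beta']:.3f}  se={top['se']:.3f}  "
      f"p={top['p']:.2e}  maf={top['maf']:.2f}  hwe_p={top['hwe_p']:.2f}")
print(f"causal SNP was {causal_id}; recovered: {top['id'] == causal_id}")
print(f"genomic inflation lambda = {genomic_inflation(results['p'].dropna()):.3f}")
print()
print("beta is the change in the standardized phenotype per additional")
print("minor allele (truth: -0.29 or +0.29 depending on orientation);")
print("lambda near 1.00 indicates no residual stratification confounding.")
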