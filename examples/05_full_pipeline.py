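"""Run the whole pipeline end to end from one config.

simulate (cohort + sessions) -> phenotype -> gwas -> clump -> power,
all under pipeline_demo/, with a manifest recording per-stage row counts,
wall time and output checksums.  Re-running with the same config and
seed reproduces identical checksums.
"""

import json

from pursuitgwas.config import RunConfig
from pursuitgwas.pipeline import run_pipeline

config = RunConfig(out_dir="pipeline_demo", seed=7,
                   n_individuals=200, n_snps=500, n_sessions=2,
                   run_permtest=True, n_perm=200)
manifest = run_pipeline(config)

print(json.dumps({name: stage["rows"] for name, stage in manifest.stages.items()},
                 indent=2))
print()
print("outputs under pipeline_demo/: genotypes.tsv, phenotypes.tsv,")
print("oculo_phenotypes.tsv, assoc.tsv, permtest.tsv, clumps.tsv,")
print("power.json, qc_report.json, manifest.json.")
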