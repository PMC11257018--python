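"""Pipeline orchestrator: simulate -> phenotype -> gwas -> permtest -> clump -> power.

Each enabled stage writes its outputs before the next begins; a manifest
(JSON) with the tool version, config hash, input checksums, per-stage
row counts and wall time is written last.  A stage failure aborts the
run with a manifest marking the failed stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .fileio import (read_genotypes, read_traces, read_table, write_matrix_tsv,
                     write_session, write_table)
from .gwas import (QCThresholds, genomic_inflation, genotype_pca, run_gwas, run_qc)
from .multitest import (ClumpParams, PowerParams, clump, ibs_cluster,
                        maxT_permutation, power_ncf)
from .pursuit import summarize_session
from .sim import (CausalSpec, SimCohortConfig, SimTraceConfig, simulate_cohort,
                  simulate_session)

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("pursuitgwas")


@dataclass
class RunManifest:
    version: str = __version__
    config_hash: str = ""
    input_checksums: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)   # name -> {rows, seconds, outputs}
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    cfg_path = out / "run_config.txt"
    save_config(config, cfg_path)
    manifest = RunManifest(config_hash=_sha256(cfg_path))
    manifest_path = out / "manifest.json"

    def finish_stage(name: str, t0: float, rows: int, outputs: list[Path]) -> None:
        manifest.stages[name] = {
            "rows": rows,
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        log.info("stage %s: %d rows", name, rows)

    def write_manifest() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2)

    geno_path = out / "genotypes.tsv"
    pheno_path = out / "phenotypes.tsv"
    traces_dir = out / "traces"
    assoc_path = out / "assoc.tsv"

    stage = None
    try:
        if config.run_simulate:
            stage = "simulate"
            t0 = time.perf_counter()
            cohort_cfg = SimCohortConfig(
                n_individuals=config.n_individuals, n_snps=config.n_snps,
                maf_range=(config.maf_min, config.maf_max),
                causal_snp=CausalSpec(config.causal_maf, config.causal_beta),
                sex_effect_sd=config.sex_effect_sd, n_clusters=config.n_clusters,
                cluster_divergence=config.cluster_divergence,
                cluster_effect_sd=config.cluster_effect_sd,
                missing_rate=config.missing_rate, seed=config.seed)
            matrix, pheno, truth = simulate_cohort(cohort_cfg)
            write_matrix_tsv(matrix, geno_path)
            write_table(pheno, pheno_path)
            truth_obj = {"causal_index": truth.causal_index,
                         "beta_true": truth.beta_true,
                         "cluster_labels": truth.cluster_labels.tolist()}
            (out / "cohort_truth.json").write_text(json.dumps(truth_obj))
            for k in range(config.n_sessions):
                trace_cfg = SimTraceConfig(pursuit_gain_true=config.pursuit_gain_true,
                                           seed=config.seed + 1000 + k)
                trials, cals, _ = simulate_session(None, trace_cfg)
                write_session(trials, cals, traces_dir, f"P{k:03d}")
            finish_stage("simulate", t0, matrix.n_snps,
                         [geno_path, pheno_path, out / "cohort_truth.json"])

        if config.run_phenotype:
            stage = "phenotype"
            t0 = time.perf_counter()
            rows = []
            event_tables = []
            for pid, (trials, cals) in read_traces(traces_dir).items():
                ph, events = summarize_session(trials, cals, return_events=True)
                rows.append({"participant_id": pid, "rmse": ph.rmse_deg,
                             "gain": ph.gain, "catchup_per_s": ph.catchup_per_s,
                             "anticipatory_per_s": ph.anticipatory_per_s,
                             "n_trials_used": ph.n_trials_used})
                events.insert(0, "participant_id", pid)
                event_tables.append(events)
            oculo = pd.DataFrame(rows)
            write_table(oculo, out / "oculo_phenotypes.tsv")
            write_table(pd.concat(event_tables, ignore_index=True),
                        out / "oculo_saccades.tsv")
            finish_stage("phenotype", t0, len(oculo),
                         [out / "oculo_phenotypes.tsv", out / "oculo_saccades.tsv"])

        if config.run_gwas:
            stage = "gwas"
            t0 = time.perf_counter()
            matrix = read_genotypes(geno_path, "matrix_tsv")
            pheno = read_table(pheno_path)
            matrix_qc, qc_report = run_qc(matrix, QCThresholds(
                sample_call_rate=config.qc_sample_call_rate,
                snp_missing_rate=config.qc_snp_missing, maf=config.qc_maf))
            keep = pheno["sample_id"].isin(matrix_qc.sample_ids).to_numpy()
            pheno_qc = pheno.loc[keep].set_index("sample_id").loc[matrix_qc.sample_ids]
            pcs = genotype_pca(matrix_qc, k=config.n_pcs)
            covars = np.column_stack([pheno_qc["sex"].to_numpy(dtype=float), pcs])
            assoc = run_gwas(matrix_qc, pheno_qc["phenotype"].to_numpy(),
                             covars, rank_transform=config.rank_transform)
            write_table(assoc.drop(columns=["error"]), assoc_path)
            (out / "qc_report.json").write_text(
                json.dumps({k: v for k, v in qc_report.to_dict().items()
                            if k != "per_snp"}, indent=2))
            lam = genomic_inflation(assoc["p"].dropna().to_numpy()) \
                if assoc["p"].notna().sum() >= 100 else float("nan")
            (out / "gwas_summary.json").write_text(json.dumps(
                {"lambda_gc": lam, "top_snp": str(assoc.iloc[0]["id"]),
                 "top_p": float(assoc.iloc[0]["p"])}))
            finish_stage("gwas", t0, len(assoc),
                         [assoc_path, out / "qc_report.json", out / "gwas_summary.json"])
            gwas_state = (matrix_qc, pheno_qc, covars)

        if config.run_permtest:
            stage = "permtest"
            t0 = time.perf_counter()
            matrix_qc, pheno_qc, covars = gwas_state
            clusters = ibs_cluster(matrix_qc, config.perm_clusters)
            perm = maxT_permutation(matrix_qc, pheno_qc["phenotype"].to_numpy(),
                                    covars, clusters, n_perm=config.n_perm,
                                    seed=config.seed)
            write_table(perm.corrected_p, out / "permtest.tsv")
            finish_stage("permtest", t0, len(perm.corrected_p), [out / "permtest.tsv"])

        if config.run_clump:
            stage = "clump"
            t0 = time.perf_counter()
            matrix_qc = gwas_state[0]
            assoc = read_table(assoc_path)
            report = clump(assoc, matrix_qc, ClumpParams(
                p1=config.clump_p1, p2=config.clump_p2,
                r2=config.clump_r2, kb=config.clump_kb))
            frame = report.to_frame()
            write_table(frame, out / "clumps.tsv")
            finish_stage("clump", t0, len(frame), [out / "clumps.tsv"])

        if config.run_power:
            stage = "power"
            t0 = time.perf_counter()
            pw = power_ncf(PowerParams(r_squared=config.power_r2,
                                       nu1=config.power_nu1, nu2=config.power_nu2,
                                       alpha=config.power_alpha))
            (out / "power.json").write_text(json.dumps(
                {"r_squared": config.power_r2, "power": pw}))
            finish_stage("power", t0, 1, [out / "power.json"])
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.stages[f"{stage}_error"] = f"{type(exc).__name__}: {exc}"
        write_manifest()
        raise

    manifest.input_checksums = {"run_config.txt": manifest.config_hash}
    write_manifest()
    return manifest
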