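"""Flat key=value run configuration.

Every pipeline parameter lives in one flat namespace so a saved config
file reproduces a run bit-identically.  Values are parsed back to bool /
int / float / str by shape; '#' starts a comment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # stage toggles
    run_simulate: bool = True
    run_phenotype: bool = True
    run_gwas: bool = True
    run_permtest: bool = False
    run_clump: bool = True
    run_power: bool = True
    # global
    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    # cohort simulation
    n_individuals: int = 200
    n_snps: int = 500
    maf_min: float = 0.05
    maf_max: float = 0.5
    causal_maf: float = 0.49
    causal_beta: float = 0.29
    sex_effect_sd: float = 0.1
    n_clusters: int = 2
    cluster_divergence: float = 0.02
    cluster_effect_sd: float = 0.0
    missing_rate: float = 0.01
    # session simulation (oculomotor chain)
    n_sessions: int = 3
    pursuit_gain_true: float = 0.9
    # QC
    qc_sample_call_rate: float = 0.97
    qc_snp_missing: float = 0.02
    qc_maf: float = 0.01
    # association
    n_pcs: int = 3
    rank_transform: bool = False
    # permutation
    n_perm: int = 200
    perm_clusters: int = 2
    # clumping
    clump_p1: float = 1e-5
    clump_p2: float = 0.01
    clump_r2: float = 0.1
    clump_kb: float = 1250.0
    # power
    power_r2: float = 0.043
    power_nu1: int = 1
    power_nu2: int = 977
    power_alpha: float = 5e-7

    def validate(self) -> None:
        if self.run_permtest and not self.run_gwas:
            raise ValueError("permtest requires the gwas stage (dependency check)")
        if self.run_clump and not self.run_gwas:
            raise ValueError("clump requires the gwas stage (dependency check)")
        if self.run_phenotype and not self.run_simulate:
            raise ValueError("phenotype stage needs simulated traces in this pipeline")


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key}={value}\n")


def _parse(value: str):
    if value in ("True", "False"):
        return value == "True"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def load_config(path: str | Path) -> RunConfig:
    known = {f.name for f in fields(RunConfig)}
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line {lineno}: {line!r}")
            key, value = line.split("=", 1)
            key = key.strip()
            if key not in known:
                raise ValueError(f"unknown config key {key!r} (line {lineno})")
            kwargs[key] = _parse(value.strip())
    return RunConfig(**kwargs)
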