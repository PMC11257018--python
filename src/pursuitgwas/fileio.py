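"""Readers and writers for the pipeline's text formats.

Genotypes come in as VCF (GT field, diploid), a PED/MAP text dialect, or
the package's canonical matrix TSV (rows = SNPs: ``chrom pos id a1 a2``
followed by one 0/1/2/NA column per individual).  The matrix TSV is the
only writable genotype format because PED/MAP loses the minor-allele
orientation.  Eye traces and calibrations are plain TSVs; phenotype,
covariate and association tables round-trip through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas.matrix import GenotypeMatrix
from .pursuit.trace import EyeTrace, RawCalibration, SessionTrial
from .sim.targets import TargetSpec, TargetTrajectory

__all__ = [
    "read_genotypes", "write_matrix_tsv", "read_matrix_tsv",
    "read_vcf", "read_ped_map",
    "write_trace_tsv", "read_trace_tsv", "write_calibration_tsv",
    "read_calibration_tsv", "write_session", "read_traces",
    "write_table", "read_table", "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"   # 10 significant digits: reproducible diffs


# --------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format: 'vcf', 'matrix_tsv' or 'ped_map' (by suffix if None)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "matrix_tsv", ".tsv": "matrix_tsv", ".txt": "matrix_tsv",
                  ".vcf": "vcf", ".ped": "ped_map", ".map": "ped_map"}.get(suffix)
        if format is None and path.name.endswith(".vcf.gz"):
            format = "vcf"
        if format is None:
            raise ValueError(f"cannot infer genotype format from {path.name!r}")
    if format == "vcf":
        return read_vcf(path)
    if format == "matrix_tsv":
        return read_matrix_tsv(path)
    if format == "ped_map":
        return read_ped_map(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tid\ta1\ta2\t" + "\t".join(matrix.sample_ids) + "\n")
        for j in range(matrix.n_snps):
            meta = matrix.snp_meta.iloc[j]
            row = matrix.codes[:, j]
            codes = "\t".join("NA" if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{meta['chrom']}\t{int(meta['pos'])}\t{meta['id']}\t"
                     f"{meta['a1']}\t{meta['a2']}\t{codes}\n")


def read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "id", "a1", "a2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"matrix TSV missing columns {missing} in {path}")
    sample_ids = [c for c in df.columns if c not in required]
    codes = df[sample_ids].to_numpy(dtype=float).T  # -> samples x SNPs
    bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"invalid genotype code at line {j + 2} of {path}")
    meta = df[required].copy()
    return GenotypeMatrix(codes, meta, sample_ids)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT records; ALT is coded as allele 1, then the matrix
    is minor-allele oriented (flips logged on the returned object are
    visible through snp_meta)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, meta_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"only biallelic SNPs supported: {var.ID} at {var.POS}")
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        if np.any(gts > 1):
            raise ValueError(f"non-diploid or multiallelic GT at {var.ID}")
        gts[gts < 0] = np.nan
        rows.append(gts.sum(axis=1))
        meta_rows.append({"chrom": str(var.CHROM), "pos": int(var.POS),
                          "id": var.ID or f"{var.CHROM}:{var.POS}",
                          "a1": var.ALT[0], "a2": var.REF})
    codes = np.asarray(rows).T
    matrix = GenotypeMatrix(codes, pd.DataFrame(meta_rows), sample_ids)
    oriented, _ = matrix.orient_minor()
    return oriented


def read_ped_map(path: str | Path) -> GenotypeMatrix:
    """PED/MAP pair; ``path`` may point at either file. '0 0' is missing."""
    path = Path(path)
    ped = path.with_suffix(".ped")
    map_ = path.with_suffix(".map")
    snps = pd.read_csv(map_, sep=r"\s+", header=None,
                       names=["chrom", "id", "cm", "pos"], dtype={"chrom": str})
    sample_ids, geno_rows = [], []
    with open(ped) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(snps):
                raise ValueError(f"malformed PED line {lineno}: "
                                 f"{len(parts)} fields, expected {6 + 2 * len(snps)}")
            sample_ids.append(parts[1])
            geno_rows.append(parts[6:])
    alleles = np.asarray(geno_rows).reshape(len(sample_ids), len(snps), 2)
    codes = np.full((len(sample_ids), len(snps)), np.nan)
    a1_list, a2_list = [], []
    for j in range(len(snps)):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq = sorted(np.unique(obs)) if obs.size else ["A", "B"]
        if len(uniq) == 1:
            uniq.append("0?")
        counts = [np.sum(obs == a) for a in uniq[:2]]
        minor, major = (uniq[0], uniq[1]) if counts[0] <= counts[1] else (uniq[1], uniq[0])
        miss = (col == "0").any(axis=1)
        codes[~miss, j] = (col[~miss] == minor).sum(axis=1)
        a1_list.append(minor)
        a2_list.append(major)
    meta = pd.DataFrame({"chrom": snps["chrom"], "pos": snps["pos"],
                         "id": snps["id"], "a1": a1_list, "a2": a2_list})
    return GenotypeMatrix(codes, meta, sample_ids)


# --------------------------------------------------------------------------
# traces and calibrations

def write_trace_tsv(trial: SessionTrial, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_ms": trial.eye.time_ms,
        "eye_deg": trial.eye.position_deg,
        "valid": trial.eye.valid.astype(int),
        "target_deg": trial.target.position_deg,
    })
    header = (f"# trial={trial.index} fs={trial.eye.sample_rate_hz} "
              f"fixation_ms={trial.target.fixation_ms} "
              f"speed={trial.target.spec.speed_deg_s} "
              f"amplitude={trial.target.spec.amplitude_deg}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_trace_tsv(path: str | Path) -> SessionTrial:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"missing metadata header line in {path}")
    meta = dict(kv.split("=") for kv in first[1:].split())
    df = pd.read_csv(path, sep="\t", skiprows=1)
    for col in ("time_ms", "eye_deg", "valid"):
        if col not in df.columns:
            raise ValueError(f"trace file {path} missing column {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"non-monotone time series in {path}")
    fs = int(meta.get("fs", 1000))
    eye = EyeTrace(time_ms=t, position_deg=df["eye_deg"].to_numpy(dtype=float),
                   valid=df["valid"].to_numpy(dtype=bool), sample_rate_hz=fs)
    fix_ms = int(meta.get("fixation_ms", 0))
    target = TargetTrajectory(
        time_ms=t, position_deg=df["target_deg"].to_numpy(dtype=float),
        sample_rate_hz=fs, fixation_ms=fix_ms,
        spec=TargetSpec(speed_deg_s=float(meta.get("speed", 20)),
                        amplitude_deg=float(meta.get("amplitude", 15))))
    return SessionTrial(eye=eye, target=target, index=int(meta.get("trial", 0)))


def write_calibration_tsv(cal: RawCalibration, path: str | Path) -> None:
    df = pd.DataFrame({"time_ms": cal.time_ms, "signal": cal.signal,
                       "target_deg": cal.target_deg})
    with open(path, "w") as fh:
        fh.write(f"# before_trial={cal.before_trial}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_calibration_tsv(path: str | Path) -> RawCalibration:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"missing metadata header line in {path}")
    meta = dict(kv.split("=") for kv in first[1:].split())
    df = pd.read_csv(path, sep="\t", skiprows=1)
    return RawCalibration(time_ms=df["time_ms"].to_numpy(dtype=float),
                          signal=df["signal"].to_numpy(dtype=float),
                          target_deg=df["target_deg"].to_numpy(dtype=float),
                          before_trial=int(meta.get("before_trial", 0)))


def write_session(trials: list[SessionTrial], calibrations: list[RawCalibration],
                  directory: str | Path, participant: str) -> None:
    """One file per trial/calibration under ``directory``, prefixed by id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        write_trace_tsv(trial, directory / f"{participant}_trial{trial.index:03d}.tsv")
    for k, cal in enumerate(calibrations):
        write_calibration_tsv(cal, directory / f"{participant}_cal{k:03d}.tsv")


def read_traces(directory: str | Path) -> dict[str, tuple[list[SessionTrial], list[RawCalibration]]]:
    """Load all sessions in a directory, keyed by participant id.

    Files follow the ``<participant>_trialNNN.tsv`` / ``<participant>_calNNN.tsv``
    convention of :func:`write_session`.  An empty directory gives an
    empty mapping.
    """
    directory = Path(directory)
    sessions: dict[str, tuple[list, list]] = {}
    for f in sorted(directory.glob("*_trial*.tsv")):
        pid = f.name.rsplit("_trial", 1)[0]
        sessions.setdefault(pid, ([], []))[0].append(read_trace_tsv(f))
    for f in sorted(directory.glob("*_cal*.tsv")):
        pid = f.name.rsplit("_cal", 1)[0]
        if pid in sessions:
            sessions[pid][1].append(read_calibration_tsv(f))
    for pid, (trials, cals) in sessions.items():
        trials.sort(key=lambda t: t.index)
        cals.sort(key=lambda c: c.before_trial)
    return sessions


# --------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
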