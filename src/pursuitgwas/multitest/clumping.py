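"""Greedy LD clumping of association results around index SNPs.

The PLINK-style procedure: repeatedly take the unclumped SNP with the
smallest p-value at or below the index threshold ``p1`` as an index SNP,
then assign to its clump every still-unclumped SNP with p <= ``p2`` on
the same chromosome within ``kb`` kilobases whose LD with the index is
r^2 >= ``r2``.  Ties in p are broken by SNP id.  Clumps partition the
assigned SNPs: a SNP belongs to at most one clump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..gwas.matrix import GenotypeMatrix
from .ld import ld_r2

__all__ = ["ClumpParams", "Clump", "ClumpReport", "clump"]


@dataclass(frozen=True)
class ClumpParams:
    p1: float = 1e-5
    p2: float = 0.01
    r2: float = 0.1
    kb: float = 1250.0


@dataclass
class Clump:
    index_id: str
    index_p: float
    chrom: str
    bp_min: int
    bp_max: int
    members: pd.DataFrame   # columns: id, p, r2_with_index, pos


@dataclass
class ClumpReport:
    clumps: list[Clump] = field(default_factory=list)
    params: ClumpParams = ClumpParams()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clumps:
            rows.append({"index_id": c.index_id, "index_p": c.index_p,
                         "chrom": c.chrom, "bp_min": c.bp_min, "bp_max": c.bp_max,
                         "n_members": len(c.members),
                         "member_ids": ",".join(c.members["id"])})
        return pd.DataFrame(rows)


def clump(results: pd.DataFrame, matrix: GenotypeMatrix,
          params: ClumpParams = ClumpParams()) -> ClumpReport:
    """Greedy clumping of an association table joined to genotypes.

    ``results`` needs columns id, chrom, pos, p.  SNPs absent from the
    genotype matrix cannot be clumped and are ignored as members.  An
    empty report (no SNP below p1) is not an error.
    """
    res = results.loc[:, ["id", "chrom", "pos", "p"]].dropna(subset=["p"]).copy()
    res = res.sort_values(["p", "id"], kind="mergesort").reset_index(drop=True)
    col_of = {sid: j for j, sid in enumerate(matrix.snp_meta["id"])}

    unclumped = dict.fromkeys(res["id"])  # insertion-ordered set
    by_id = res.set_index("id")
    report = ClumpReport(params=params)

    while unclumped:
        index_id = next(iter(unclumped))
        row = by_id.loc[index_id]
        if row["p"] > params.p1:
            break  # remaining SNPs all exceed the index threshold
        del unclumped[index_id]
        if index_id not in col_of:
            continue
        g_index = matrix.codes[:, col_of[index_id]]

        cand = [sid for sid in unclumped
                if by_id.loc[sid, "p"] <= params.p2
                and by_id.loc[sid, "chrom"] == row["chrom"]
                and abs(by_id.loc[sid, "pos"] - row["pos"]) <= params.kb * 1000.0
                and sid in col_of]
        member_rows = [{"id": index_id, "p": float(row["p"]),
                        "r2_with_index": 1.0, "pos": int(row["pos"])}]
        for sid in cand:
            try:
                r2 = ld_r2(g_index, matrix.codes[:, col_of[sid]])
            except ValueError:
                continue
            if r2 >= params.r2:
                member_rows.append({"id": sid, "p": float(by_id.loc[sid, "p"]),
                                    "r2_with_index": float(r2),
                                    "pos": int(by_id.loc[sid, "pos"])})
                del unclumped[sid]
        members = pd.DataFrame(member_rows)
        report.clumps.append(Clump(
            index_id=index_id, index_p=float(row["p"]), chrom=str(row["chrom"]),
            bp_min=int(members["pos"].min()), bp_max=int(members["pos"].max()),
            members=members))
    return report
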