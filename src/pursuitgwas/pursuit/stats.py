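"""Rank correlations between phenotypes and test-retest reliability."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["correlate_phenotypes", "PHENOTYPE_MEASURES"]

PHENOTYPE_MEASURES = ["rmse", "gain", "catchup_per_s", "anticipatory_per_s"]


def correlate_phenotypes(table: pd.DataFrame,
                         retest: pd.DataFrame | None = None,
                         measures: list[str] | None = None,
                         ) -> tuple[pd.DataFrame, pd.Series | None]:
    """Spearman correlations between measures, plus test-retest reliability.

    ``table`` (and optional ``retest``) are indexed or keyed by
    ``participant_id``.  Returns (measure x measure rank-correlation
    matrix on the full table, per-measure session-1 vs session-2 rank
    correlation over participants present in both tables, or None).
    Ties get average ranks (scipy default); fewer than 3 complete pairs
    raises.
    """
    measures = measures or PHENOTYPE_MEASURES
    t1 = table.set_index("participant_id") if "participant_id" in table.columns else table
    missing = [m for m in measures if m not in t1.columns]
    if missing:
        raise ValueError(f"missing measures: {missing}")
    sub = t1[measures].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete rows for correlations")
    rho = stats.spearmanr(sub.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    corr = pd.DataFrame(rho, index=measures, columns=measures)

    reliability = None
    if retest is not None:
        t2 = retest.set_index("participant_id") if "participant_id" in retest.columns else retest
        shared = t1.index.intersection(t2.index)
        if len(shared) < 3:
            raise ValueError("need >= 3 matched participants for reliability")
        vals = {}
        for m in measures:
            a = t1.loc[shared, m].to_numpy(dtype=float)
            b = t2.loc[shared, m].to_numpy(dtype=float)
            keep = ~np.isnan(a) & ~np.isnan(b)
            if keep.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for {m}")
            vals[m] = float(stats.spearmanr(a[keep], b[keep]).statistic)
        reliability = pd.Series(vals)
    return corr, reliability
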