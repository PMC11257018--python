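"""Genomic-control inflation factor and Q-Q diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["genomic_inflation", "qq_coordinates", "CHI2_MEDIAN_1DF"]

CHI2_MEDIAN_1DF = 0.4549364231195724  # median of chi-square with 1 df


def genomic_inflation(p_values: np.ndarray) -> float:
    """Median-based genomic inflation factor lambda.

    p-values are converted to 1-df chi-square quantiles; lambda is the
    median observed chi-square divided by the 1-df null median 0.4549.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def qq_coordinates(p_values: np.ndarray, band: float = 0.95) -> pd.DataFrame:
    """-log10 expected vs observed quantiles with an order-statistic band.

    The i-th smallest of m uniform p-values is Beta(i, m - i + 1); the
    band columns give the pointwise ``band`` envelope on that scale.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    m = len(p)
    i = np.arange(1, m + 1)
    expected = (i - 0.5) / m
    alpha = (1.0 - band) / 2.0
    lo = stats.beta.ppf(alpha, i, m - i + 1)
    hi = stats.beta.ppf(1.0 - alpha, i, m - i + 1)
    return pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.maximum(p, 1e-300)),
        "band_lo_neglog10": -np.log10(hi),
        "band_hi_neglog10": -np.log10(lo),
    })
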