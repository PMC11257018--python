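"""Exact test for Hardy-Weinberg equilibrium.

Two-sided exact test of the observed heterozygote count conditional on
the allele counts, after Wigginton, Cutler & Abecasis (2005): the
p-value sums the conditional probabilities of all heterozygote counts
no more probable than the observed one.  Probabilities are built with
the stable ratio recurrence

    P(h + 2) / P(h) = 4 * n_hom1 * n_hom2 / ((h + 2) * (h + 1))

walking out from the mode, so counts into the thousands are exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hwe_exact_test", "hwe_het_distribution"]


def hwe_het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploid individuals and ``n_a`` copies of the rarer
    allele, returns (attainable het counts, their probabilities).
    """
    n_b = 2 * n - n_a
    if n_a > n_b:
        n_a, n_b = n_b, n_a
    h_min = n_a % 2
    hets = np.arange(h_min, n_a + 1, 2)
    # start the recurrence at the (approximate) mode for stability
    mode = int(round(n_a * n_b / (2.0 * n)))
    if (mode - h_min) % 2:
        mode += 1
    mode = min(max(mode, h_min), n_a)
    probs = {mode: 1.0}
    h = mode
    while h + 2 <= n_a:
        hom1 = (n_a - h) // 2
        hom2 = (n_b - h) // 2
        probs[h + 2] = probs[h] * 4.0 * hom1 * hom2 / ((h + 2.0) * (h + 1.0))
        h += 2
    h = mode
    while h - 2 >= h_min:
        # inverse step: P(h-2)/P(h) = h (h-1) / (4 hom1(h-2) hom2(h-2))
        hom1 = (n_a - h) // 2 + 1
        hom2 = (n_b - h) // 2 + 1
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * hom1 * hom2)
        h -= 2
    pvec = np.array([probs[h] for h in hets])
    return hets, pvec / pvec.sum()


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int, *, midp: bool = False) -> float:
    """Two-sided exact HWE p-value for genotype counts (hom1, het, hom2).

    ``midp`` subtracts half the observed configuration's probability
    (off by default).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_a = 2 * n_aa + n_ab
    n_a = min(n_a, 2 * n - n_a)
    hets, probs = hwe_het_distribution(n, n_a)
    p_obs = probs[hets == n_ab][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    if midp:
        p -= 0.5 * p_obs
    return float(min(p, 1.0))
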