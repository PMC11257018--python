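"""Analytic power for a single-SNP F test via the noncentral F distribution."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerParams", "power_ncf"]


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the noncentral-F power computation.

    r_squared : coefficient of determination attributable to the tested
        term (variance explained), in [0, 1).
    nu1, nu2 : numerator / denominator degrees of freedom.
    alpha : test size.
    """

    r_squared: float
    nu1: int = 1
    nu2: int = 977
    alpha: float = 5e-7

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared < 1.0):
            raise ValueError("r_squared must be in [0, 1)")
        if self.nu1 < 1 or self.nu2 < 1:
            raise ValueError("degrees of freedom must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def noncentrality(self) -> float:
        """lambda = [r^2 / (1 - r^2)] * nu2."""
        return self.r_squared / (1.0 - self.r_squared) * self.nu2


def power_ncf(params: PowerParams) -> float:
    """power = 1 - F_ncf(Fcrit | nu1, nu2, lambda).

    Fcrit is the (1 - alpha) quantile of the central F(nu1, nu2); at
    r^2 = 0 the noncentral F collapses to the central one and the power
    equals alpha exactly.
    """
    fcrit = stats.f.isf(params.alpha, params.nu1, params.nu2)
    if params.r_squared == 0.0:
        return float(params.alpha)
    return float(stats.ncf.sf(fcrit, params.nu1, params.nu2, params.noncentrality))
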