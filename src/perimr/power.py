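"""Statistical power for MR with a binary outcome.

Non-centrality calculation for a two-sided Wald test of the causal odds
ratio, following the published calculation behind the mRnd calculator
(Brion et al.): the odds ratio is reparameterized as the risk difference

    b01 = K * ( OR / (1 + K*(OR - 1)) - 1 )

for case fraction K, the variance of the causal estimate is approximated by

    v = ( K*(1-K) - b01^2 ) / (N * R^2)

with outcome GWAS size N and instrument-explained exposure variance R^2,
and the power at significance level alpha is

    power = Phi( -z_{1-alpha/2} + |b01| / sqrt(v) ).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import AnalysisError, ConfigurationError


@dataclass(frozen=True)
class PowerInput:
    """Inputs of the binary-outcome power calculation.

    n_total: outcome GWAS size N; case_fraction: K in (0,1); odds_ratio:
    causal OR per exposure unit (> 0); r_squared: variance in the exposure
    explained by the instruments, in (0,1); alpha: significance level.
    """

    n_total: int
    case_fraction: float
    odds_ratio: float
    r_squared: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ConfigurationError("n_total must be >= 1")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError("case_fraction must be in (0,1)")
        if not self.odds_ratio > 0.0:
            raise ConfigurationError("odds_ratio must be > 0")
        if not 0.0 < self.r_squared < 1.0:
            raise ConfigurationError("r_squared must be in (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0,1)")


@dataclass(frozen=True)
class PowerResult:
    b01: float  # risk-difference reparameterization of the OR
    variance_term: float  # approximate variance of the causal estimate
    ncp: float  # |b01| / sqrt(v)
    power: float


def binary_outcome_power(inp: PowerInput) -> PowerResult:
    """Power of the two-sided causal test for a binary outcome."""
    k, or_ = inp.case_fraction, inp.odds_ratio
    b01 = k * (or_ / (1.0 + k * (or_ - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b01**2) / (inp.n_total * inp.r_squared)
    if v <= 0.0:
        raise AnalysisError("R^2 and N imply degenerate variance")
    ncp = abs(b01) / v**0.5
    z_crit = stats.norm.ppf(1.0 - inp.alpha / 2.0)
    power = float(stats.norm.cdf(-z_crit + ncp))
    return PowerResult(b01=float(b01), variance_term=float(v), ncp=float(ncp), power=power)
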