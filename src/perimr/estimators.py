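"""Causal-effect estimators and diagnostics for summary-data MR.

Given J harmonized instrument pairs (beta_Xj, se_Xj, beta_Yj, se_Yj), each
instrument yields a Wald ratio

    theta_j = beta_Yj / beta_Xj,    se_j = se_Yj / |beta_Xj|

(first-order delta method), and the pipeline pools them four ways:

* IVW fixed effects:  theta_IVW = sum(w_j theta_j) / sum(w_j) with
  w_j = 1/se_j^2 and SE_fixed = (sum w_j)^{-1/2}; algebraically identical to
  weighted least squares of beta_Y on beta_X through the origin.
* IVW multiplicative random effects: same point estimate, SE scaled by
  sqrt(Q/(J-1)) where Q is Cochran's Q about the IVW estimate. The scale
  factor is deliberately NOT floored at 1, so underdispersed instrument
  sets (Q/(J-1) < 1) report a random-effects SE below the fixed-effects
  SE; a ``floor_dispersion`` flag restores the floored convention.
* Simple and weighted median: the 50% point of the cumulative weight
  distribution over ordered ratios, with equal or inverse-variance weights;
  SE by parametric bootstrap.
* MR-Egger: weighted regression of beta_Y on beta_X with a free intercept
  (instruments oriented so beta_X >= 0); the intercept tests directional
  pleiotropy, the slope is a pleiotropy-robust causal estimate.

Heterogeneity is quantified by Cochran's Q about the IVW estimate (df J-1)
and by the Egger residual Q (df J-2). All pooled p-values are two-sided
normal; Q p-values are chi-square upper tails. Estimates on the log-odds
scale are reported with exp-transformed odds ratios and Wald CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import AnalysisError
from .harmonize import HarmonizedDataset

log = logging.getLogger(__name__)

IVW_FIXED = "ivw_fixed"
IVW_RANDOM = "ivw_random"
SIMPLE_MEDIAN = "simple_median"
WEIGHTED_MEDIAN = "weighted_median"
EGGER_SLOPE = "egger_slope"


@dataclass(frozen=True)
class RatioEstimate:
    """Per-instrument Wald ratio with its first-order SE and IVW weight."""

    variant_id: str
    theta: float
    se: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


@dataclass(frozen=True)
class MREstimate:
    """One method's pooled causal estimate on the log-odds scale."""

    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    degenerate: bool = False


@dataclass(frozen=True)
class DiagnosticResult:
    """Egger intercept (pleiotropy) test and Cochran's Q heterogeneity."""

    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    q_ivw: float
    df_ivw: int
    p_q_ivw: float
    q_egger: float
    df_egger: int
    p_q_egger: float


def ztest_p(beta: float, se: float) -> float:
    """Two-sided normal p-value, p = 2 * (1 - Phi(|beta/se|))."""
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into (OR, CI low, CI high)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
    )


def _finish(method: str, n_snp: int, beta: float, se: float, level: float,
            degenerate: bool = False) -> MREstimate:
    if se == 0.0:
        # Exact fit (e.g. noise-free Egger fixture): the estimate is a point mass.
        or_ = float(np.exp(beta))
        return MREstimate(
            method=method, n_snp=n_snp, beta=float(beta), se=0.0,
            pvalue=1.0 if beta == 0.0 else 0.0,
            or_=or_, ci_low=or_, ci_high=or_, level=level, degenerate=True,
        )
    or_, lo, hi = to_odds_ratio(beta, se, level)
    return MREstimate(
        method=method,
        n_snp=n_snp,
        beta=float(beta),
        se=float(se),
        pvalue=ztest_p(beta, se),
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        level=level,
        degenerate=degenerate,
    )


def wald_ratios(data: HarmonizedDataset) -> list[RatioEstimate]:
    """Per-instrument ratio estimates; pairs with beta_x = 0 are dropped."""
    ratios = []
    for pair in data.pairs:
        if pair.beta_x == 0.0:
            log.info("dropped %s: zero exposure effect", pair.variant_id)
            continue
        ratios.append(
            RatioEstimate(
                variant_id=pair.variant_id,
                theta=pair.beta_y / pair.beta_x,
                se=pair.se_y / abs(pair.beta_x),
            )
        )
    return ratios


def cochran_q(
    ratios: list[RatioEstimate], reference: float, df: int | None = None
) -> tuple[float, int, float]:
    """Cochran's Q about ``reference``: Q = sum w_j (theta_j - reference)^2.

    ``df`` defaults to J-1 (the IVW convention); pass J-2 for an Egger
    residual Q computed on regression residuals.
    """
    if df is None:
        df = len(ratios) - 1
    if df < 1:
        raise AnalysisError(f"Cochran's Q needs df >= 1, got {df}")
    q = float(sum(r.weight * (r.theta - reference) ** 2 for r in ratios))
    return q, df, float(stats.chi2.sf(q, df))


def ivw(
    ratios: list[RatioEstimate],
    model: str = "random",
    level: float = 0.95,
    floor_dispersion: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted pooled estimate.

    ``model="fixed"`` gives SE = (sum w_j)^{-1/2}; ``model="random"`` is the
    multiplicative random-effects variant with SE_fixed * sqrt(Q/(J-1)),
    unfloored unless ``floor_dispersion``. A single ratio is returned as-is
    with the ``degenerate`` flag set.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    if not ratios:
        raise AnalysisError("IVW requires at least one ratio estimate")
    method = IVW_FIXED if model == "fixed" else IVW_RANDOM
    if len(ratios) == 1:
        r = ratios[0]
        return _finish(method, 1, r.theta, r.se, level, degenerate=True)
    w = np.array([r.weight for r in ratios])
    th = np.array([r.theta for r in ratios])
    beta = float(np.sum(w * th) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if model == "fixed":
        return _finish(method, len(ratios), beta, se_fixed, level)
    q, df, _ = cochran_q(ratios, beta)
    scale = q / df
    if floor_dispersion:
        scale = max(scale, 1.0)
    return _finish(method, len(ratios), beta, se_fixed * np.sqrt(scale), level)


def _interpolated_weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Linear interpolation of ordered ratios against standardized
    cumulative-weight midpoints, evaluated at 1/2."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = weights[order].astype(float)
    # scale by the max first so equal weights reduce bit-exactly to 1/J each
    w = w / w.max()
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, th))


def median_estimate(
    ratios: list[RatioEstimate],
    weighted: bool,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> MREstimate:
    """Simple or weighted median of the Wald ratios.

    The weighted variant uses inverse-variance weights; the simple variant
    equal weights (and therefore reduces to the ordinary median for odd J).
    The SE is the standard deviation of the estimate over ``n_boot``
    parametric-bootstrap replicates in which each theta_j is redrawn from
    Normal(theta_j, se_j^2) with weights held fixed.
    """
    if len(ratios) < 3:
        raise AnalysisError(f"median estimator requires >= 3 ratios, got {len(ratios)}")
    th = np.array([r.theta for r in ratios])
    se = np.array([r.se for r in ratios])
    w = 1.0 / se**2 if weighted else np.ones_like(th)
    beta = _interpolated_weighted_median(th, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=th, scale=se, size=(n_boot, len(ratios)))
    boot = np.array([_interpolated_weighted_median(row, w) for row in draws])
    se_boot = float(boot.std(ddof=1))
    method = WEIGHTED_MEDIAN if weighted else SIMPLE_MEDIAN
    return _finish(method, len(ratios), beta, se_boot, level)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope estimate plus intercept (pleiotropy) test and
    residual heterogeneity."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    q: float
    df: int
    p_q: float


def egger(
    data: HarmonizedDataset,
    level: float = 0.95,
    floor_dispersion: bool = False,
) -> EggerResult:
    """MR-Egger weighted regression with a free intercept.

    Pairs are oriented so beta_x >= 0 (both betas negated otherwise);
    weights are 1/se_y^2. Coefficient SEs carry the multiplicative residual
    scale Q_egger/(J-2) without a floor at 1, matching the IVW
    random-effects convention; ``floor_dispersion`` restores the floor.
    """
    pairs = [p for p in data.pairs if p.beta_x != 0.0]
    if len(pairs) < 3:
        raise AnalysisError(f"MR-Egger requires >= 3 instruments, got {len(pairs)}")
    bx = np.array([p.beta_x for p in pairs])
    by = np.array([p.beta_y for p in pairs])
    sy = np.array([p.se_y for p in pairs])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    weights = 1.0 / sy**2

    fit = sm.WLS(by, sm.add_constant(bx), weights=weights).fit()
    # statsmodels' WLS scale is the weighted residual SS over (J-2): exactly
    # the unfloored multiplicative dispersion factor.
    q = float(fit.ssr)
    df = len(pairs) - 2
    intercept, slope = (float(v) for v in fit.params)
    se_intercept, se_slope = (float(v) for v in fit.bse)
    if floor_dispersion and fit.scale < 1.0:
        correction = float(fit.scale) ** -0.5
        se_intercept *= correction
        se_slope *= correction
    if se_intercept == 0.0:
        intercept_p = 1.0 if intercept == 0.0 else 0.0
    else:
        intercept_p = ztest_p(intercept, se_intercept)
    return EggerResult(
        slope=_finish(EGGER_SLOPE, len(pairs), slope, se_slope, level),
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_p=intercept_p,
        q=q,
        df=df,
        p_q=float(stats.chi2.sf(q, df)),
    )


def run_all_methods(
    data: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    floor_dispersion: bool = False,
) -> tuple[list[MREstimate], DiagnosticResult]:
    """All pooled estimates plus diagnostics for one harmonized dataset.

    Returns the four headline estimators (IVW random, IVW fixed, simple
    median, weighted median) followed by the Egger slope, and a
    DiagnosticResult bundling the Egger intercept test with both Cochran Q
    statistics.
    """
    ratios = wald_ratios(data)
    if not ratios:
        raise AnalysisError("no usable ratio estimates")
    est_random = ivw(ratios, "random", level, floor_dispersion)
    est_fixed = ivw(ratios, "fixed", level)
    est_simple = median_estimate(ratios, weighted=False, n_boot=n_boot, seed=seed, level=level)
    est_weighted = median_estimate(ratios, weighted=True, n_boot=n_boot, seed=seed + 1, level=level)
    egg = egger(data, level=level, floor_dispersion=floor_dispersion)
    q_ivw, df_ivw, p_q_ivw = cochran_q(ratios, est_fixed.beta)
    diagnostics = DiagnosticResult(
        egger_intercept=egg.intercept,
        egger_intercept_se=egg.intercept_se,
        egger_intercept_p=egg.intercept_p,
        q_ivw=q_ivw,
        df_ivw=df_ivw,
        p_q_ivw=p_q_ivw,
        q_egger=egg.q,
        df_egger=egg.df,
        p_q_egger=egg.p_q,
    )
    estimates = [est_random, est_fixed, est_simple, est_weighted, egg.slope]
    return estimates, diagnostics
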