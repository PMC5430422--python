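"""Two-sample Mendelian-randomization estimators and instrument diagnostics.

Per-SNP causal effects are Wald ratios: the variant-outcome effect divided
by the variant-exposure effect. With summary statistics from two
non-overlapping samples, K ratios are pooled by the fixed-effect
inverse-variance-weighted (IVW) estimator

    beta_IVW = sum_k E_k D_k / sigma_Dk^2  /  sum_k E_k^2 / sigma_Dk^2
    SE(beta_IVW) = sqrt( 1 / sum_k E_k^2 / sigma_Dk^2 )

where E_k is the per-allele effect on the exposure, D_k the per-allele
effect on the outcome and sigma_Dk its standard error. This is the slope of
a weighted least-squares regression of D on E through the origin with
weights sigma_Dk^-2, i.e. a fixed-effect meta-analysis of the Wald ratios
weighted by the outcome-side variance only.

Instrument strength is summarized by the variance in the exposure explained
per variant, R^2_k = beta_k^2 * 2 f_k (1 - f_k) with f_k the effect-allele
frequency (this assumes the exposure has unit variance; pass a phenotype SD
to rescale), and by the joint first-stage F-statistic

    F = (R^2 / K) / ((1 - R^2) / (n - K - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .sumstats import LOG_ODDS, ExposureAssociation, HarmonizedPair, Scale


class EstimationError(ValueError):
    """The requested estimate is undefined for the given inputs."""


@dataclass(frozen=True)
class WaldEstimate:
    """Single-variant causal estimate: outcome units per kg of handgrip."""

    snp_id: str
    ratio: float
    se: float
    outcome_scale: Scale

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: Wald SE must be positive")


@dataclass(frozen=True)
class IVWResult:
    """Fixed-effect IVW pooled causal estimate per 1-kg increase in handgrip.

    ``beta`` is on the outcome's analysis scale (log-odds for binary
    outcomes); ``or_point``/``or_ci`` carry the exponentiated presentation
    when the scale is log-odds, and are ``None`` otherwise.
    """

    beta: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    k_snps: int
    outcome_scale: Scale
    level: float = 0.95
    or_point: float | None = None
    or_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.k_snps < 1:
            raise ValueError("k_snps must be >= 1")
        if not self.ci_lower < self.beta < self.ci_upper:
            raise ValueError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class InstrumentStrength:
    """Variance explained and first-stage F for a set of instruments.

    ``per_snp_r2`` and ``f_stat`` apply the textbook formulas literally,
    which treats the exposure as having unit variance. When the phenotype's
    residual standard deviation is known, ``phenotype_sd`` rescales the
    variance fractions (``r2_total_adjusted = r2_total / sd^2``) and yields
    ``f_stat_adjusted``.
    """

    per_snp_r2: tuple[float, ...]
    r2_total: float
    k: int
    n: int
    f_stat: float
    phenotype_sd: float | None = None
    r2_total_adjusted: float | None = None
    f_stat_adjusted: float | None = None


def wald_ratio(pair: HarmonizedPair) -> WaldEstimate:
    """Per-SNP Wald estimate: outcome effect over exposure effect.

    The standard error is the first-order delta-method approximation
    ``sigma_Dk / |E_k|``, which ignores sampling error in the exposure
    effect; the IVW pooled SE does not depend on it.
    """
    if pair.exposure_beta == 0:
        raise EstimationError(f"{pair.snp_id}: exposure effect is 0; Wald ratio undefined")
    return WaldEstimate(
        snp_id=pair.snp_id,
        ratio=pair.outcome_beta / pair.exposure_beta,
        se=pair.outcome_se / abs(pair.exposure_beta),
        outcome_scale=pair.outcome_scale,
    )


def ci_and_p(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Normal-theory confidence interval and two-sided p-value."""
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    z = norm.ppf((1 + level) / 2)
    p = 2 * norm.sf(abs(beta) / se)
    return beta - z * se, beta + z * se, float(p)


def ivw_pool(pairs: Sequence[HarmonizedPair], level: float = 0.95) -> IVWResult:
    """Pool harmonized pairs with the fixed-effect IVW estimator.

    All pairs must share one outcome scale. For a single pair the result
    reduces algebraically to the Wald ratio. Log-odds results additionally
    carry the exponentiated odds-ratio presentation.
    """
    if len(pairs) == 0:
        raise ValueError("cannot pool an empty list of pairs")
    scales = {p.outcome_scale for p in pairs}
    if len(scales) > 1:
        raise ValueError(f"mixed outcome scales cannot be pooled: {sorted(scales)}")
    scale = pairs[0].outcome_scale

    E = np.array([p.exposure_beta for p in pairs], dtype=float)
    D = np.array([p.outcome_beta for p in pairs], dtype=float)
    s = np.array([p.outcome_se for p in pairs], dtype=float)
    if not np.all(s > 0):
        raise ValueError("all outcome standard errors must be positive")

    w = s**-2.0
    denom = float(np.sum(E * E * w))
    beta = float(np.sum(E * D * w)) / denom
    se = float(np.sqrt(1.0 / denom))
    lo, hi, p = ci_and_p(beta, se, level)

    or_point = or_ci = None
    if scale == LOG_ODDS:
        or_point = float(np.exp(beta))
        or_ci = (float(np.exp(lo)), float(np.exp(hi)))
    return IVWResult(
        beta=beta,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        k_snps=len(pairs),
        outcome_scale=scale,
        level=level,
        or_point=or_point,
        or_ci=or_ci,
    )


def snp_r2(beta: float, eaf: float) -> float:
    """Exposure variance explained by one variant: beta^2 * 2 f (1 - f).

    The formula is applied literally, with no rescaling by the phenotype
    variance; it is a variance *fraction* only if the exposure has unit
    variance. See :class:`InstrumentStrength` for the rescaled version.
    """
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must lie in (0, 1), got {eaf}")
    return float(beta * beta * (1 - eaf) * 2 * eaf)


def instrument_f(r2_total: float, k: int, n: int) -> float:
    """Joint first-stage F-statistic from total variance explained."""
    if not 0 <= r2_total < 1:
        raise ValueError(f"r2_total must lie in [0, 1), got {r2_total}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"n must exceed k + 1, got n={n}, k={k}")
    return float((r2_total / k) / ((1 - r2_total) / (n - k - 1)))


def instrument_strength(
    exposures: Sequence[ExposureAssociation],
    phenotype_sd: float | None = None,
) -> InstrumentStrength:
    """Per-SNP R-squared and joint F for a set of exposure associations.

    ``n`` is taken as the smallest first-stage sample size among the
    variants. If ``phenotype_sd`` (kg) is supplied, the literal R-squared
    values are divided by its square before the adjusted F is formed.
    """
    if len(exposures) == 0:
        raise ValueError("need at least one exposure association")
    if phenotype_sd is not None and not phenotype_sd > 0:
        raise ValueError("phenotype_sd must be positive")
    per = tuple(snp_r2(e.beta, e.eaf) for e in exposures)
    total = float(sum(per))
    k = len(exposures)
    n = min(e.n for e in exposures)
    f_lit = instrument_f(total, k, n)
    adj_total = adj_f = None
    if phenotype_sd is not None:
        adj_total = total / phenotype_sd**2
        adj_f = instrument_f(adj_total, k, n)
    return InstrumentStrength(
        per_snp_r2=per,
        r2_total=total,
        k=k,
        n=n,
        f_stat=f_lit,
        phenotype_sd=phenotype_sd,
        r2_total_adjusted=adj_total,
        f_stat_adjusted=adj_f,
    )
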