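"""GWAS summary-statistic records, parsing, unit conversion and allele harmonization.

This module holds the data model for per-SNP association statistics as
published by GWAS consortia: an exposure association (here, kg of handgrip
strength per copy of the effect allele) and an outcome association on a
declared scale (log-odds for binary disease endpoints, SD units or mmol/l
for continuous risk factors). Outcome effects published as odds ratios with
confidence intervals are converted to the log scale, with the standard
error back-calculated from the interval width. Harmonization re-orients an
outcome record to the exposure record's effect allele, flipping the sign of
the outcome effect when the reported allele is the exposure's other allele,
and resolving strand mismatches by base complementation when direct and
swapped matching both fail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Declared outcome scales.
LOG_ODDS = "log-odds"
SD_UNITS = "SD-units"
MMOL_L = "mmol/l"
SCALES = (LOG_ODDS, SD_UNITS, MMOL_L)

Scale = Literal["log-odds", "SD-units", "mmol/l"]
Derivation = Literal["reported-se", "ci-derived"]


class HarmonizationError(ValueError):
    """Exposure and outcome alleles cannot be reconciled."""


class ConfigurationError(ValueError):
    """A required column or file is missing or misconfigured."""


def _check_allele(a: str, label: str) -> str:
    a = str(a).strip().upper()
    if a not in VALID_BASES:
        raise ValueError(f"{label} must be a single IUPAC base (A/C/G/T), got {a!r}")
    return a


@dataclass(frozen=True)
class ExposureAssociation:
    """One SNP's per-allele effect on the exposure (kg of handgrip strength).

    Parameters
    ----------
    snp_id : str
        rsID of the variant.
    effect_allele, other_allele : str
        Single-base alleles; the reported effect refers to each additional
        copy of ``effect_allele``.
    beta : float
        Change in handgrip (kg) per copy of the effect allele.
    se : float
        Standard error of ``beta`` (kg); must be positive.
    eaf : float
        Effect-allele frequency, strictly inside (0, 1).
    p_value : float
        Association p-value in (0, 1].
    n : int
        First-stage sample size (>= 2).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"{self.snp_id}: p_value must lie in (0, 1], got {self.p_value}")
        if self.n < 2:
            raise ValueError(f"{self.snp_id}: n must be >= 2, got {self.n}")


@dataclass(frozen=True)
class OutcomeAssociation:
    """One SNP's per-allele effect on an outcome, on a declared scale.

    ``beta`` is always on the analysis scale (log-odds for binary outcomes);
    when the source published an odds ratio with a confidence interval,
    ``derivation`` is ``"ci-derived"`` and the original printed values are
    retained in ``source_or``/``source_ci_lower``/``source_ci_upper`` so the
    record can be serialized back without loss.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    scale: Scale = LOG_ODDS
    derivation: Derivation = "reported-se"
    ci_level: float = 0.95
    p_value: float | None = None
    source_or: float | None = None
    source_ci_lower: float | None = None
    source_ci_upper: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if self.scale not in SCALES:
            raise ValueError(f"{self.snp_id}: unknown scale {self.scale!r}")
        if self.derivation not in ("reported-se", "ci-derived"):
            raise ValueError(f"{self.snp_id}: unknown derivation {self.derivation!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"{self.snp_id}: ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class HarmonizedPair:
    """An exposure/outcome pair oriented to one common effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float
    outcome_se: float
    outcome_scale: Scale

    def __post_init__(self) -> None:
        if not self.exposure_se > 0 or not self.outcome_se > 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


def logor_from_or(odds_ratio: float) -> float:
    """Natural-log transform of a per-allele odds ratio.

    Raises
    ------
    ValueError
        If ``odds_ratio`` is not strictly positive.
    """
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return float(np.log(odds_ratio))


def se_from_or_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Back-calculate a log-scale standard error from an OR confidence interval.

    For a ``level`` interval (L, U) on the OR scale the log-scale SE is
    ``(ln U - ln L) / (2 z)`` with ``z`` the standard-normal quantile at
    ``(1 + level) / 2``. A zero-width interval returns 0 with a warning.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if not (lower > 0 and upper > 0):
        raise ValueError(f"CI bounds must be positive, got ({lower}, {upper})")
    if lower > upper:
        raise ValueError(f"CI lower bound exceeds upper bound: ({lower}, {upper})")
    if lower == upper:
        warnings.warn("degenerate zero-width confidence interval; SE is 0", stacklevel=2)
        return 0.0
    z = norm.ppf((1 + level) / 2)
    return float((np.log(upper) - np.log(lower)) / (2 * z))


def or_ci_from_logbeta(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Rebuild (OR, lower, upper) on the ratio scale from a log-scale estimate."""
    z = norm.ppf((1 + level) / 2)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


# --- parsing ---------------------------------------------------------------

#: Default header names; override any of them via ``column_map``.
DEFAULT_COLUMNS = {
    "snp_id": "snp_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "eaf": "eaf",
    "p_value": "p_value",
    "n": "n",
    "or": "or",
    "ci_lower": "ci_lower",
    "ci_upper": "ci_upper",
    "scale": "scale",
}


def read_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read a tab- or comma-delimited summary-statistic table with a header row."""
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, sep=None, engine="python", dtype=str, skipinitialspace=True)


def _num(value, label: str, row: int) -> float:
    """Parse a numeric cell, accepting thousands separators as printed in tables."""
    try:
        return float(str(value).replace(",", ""))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}: cannot parse {label}={value!r} as a number") from exc


def parse_summary_table(
    source: str | Path | pd.DataFrame,
    role: Literal["exposure", "outcome"],
    column_map: dict[str, str] | None = None,
    scale: Scale = LOG_ODDS,
    ci_level: float = 0.95,
) -> list[ExposureAssociation] | list[OutcomeAssociation]:
    """Parse a delimited summary-statistic table into association records.

    Outcome tables may report either ``(beta, se)`` directly or
    ``(or, ci_lower, ci_upper)``; OR-form rows are converted to the log
    scale and flagged ``derivation="ci-derived"``. A ``scale`` column in the
    table overrides the ``scale`` argument row-wise.
    """
    if role not in ("exposure", "outcome"):
        raise ValueError(f"role must be 'exposure' or 'outcome', got {role!r}")
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})
    df = read_table(source)

    def col(key: str, required: bool = True) -> str | None:
        name = cols[key]
        if name in df.columns:
            return name
        if required:
            raise ConfigurationError(
                f"required column {name!r} (for field {key!r}) not found; "
                f"table has columns {list(df.columns)}"
            )
        return None

    if df.empty:
        logger.warning("summary-statistic table %s has an empty body", source)
        return []

    snp_c = col("snp_id")
    ea_c = col("effect_allele")
    oa_c = col("other_allele")

    records: list = []
    if role == "exposure":
        beta_c, se_c, eaf_c, p_c, n_c = (col(k) for k in ("beta", "se", "eaf", "p_value", "n"))
        for i, row in df.iterrows():
            eaf = _num(row[eaf_c], "eaf", i)
            if not 0 < eaf < 1:
                raise ValueError(f"row {i}: eaf must lie in (0, 1), got {eaf}")
            records.append(
                ExposureAssociation(
                    snp_id=str(row[snp_c]).strip(),
                    effect_allele=row[ea_c],
                    other_allele=row[oa_c],
                    beta=_num(row[beta_c], "beta", i),
                    se=_num(row[se_c], "se", i),
                    eaf=eaf,
                    p_value=_num(row[p_c], "p_value", i),
                    n=int(round(_num(row[n_c], "n", i))),
                )
            )
        return records

    # outcome: prefer (beta, se); fall back to OR + CI
    has_beta = cols["beta"] in df.columns and cols["se"] in df.columns
    has_or = cols["or"] in df.columns
    if not has_beta and not has_or:
        raise ConfigurationError(
            f"outcome table needs either ({cols['beta']!r}, {cols['se']!r}) or "
            f"({cols['or']!r}, {cols['ci_lower']!r}, {cols['ci_upper']!r}) columns; "
            f"table has columns {list(df.columns)}"
        )
    scale_c = col("scale", required=False)
    p_c = cols["p_value"] if cols["p_value"] in df.columns else None
    for i, row in df.iterrows():
        row_scale = str(row[scale_c]).strip() if scale_c else scale
        p_val = _num(row[p_c], "p_value", i) if p_c is not None else None
        if has_beta:
            records.append(
                OutcomeAssociation(
                    snp_id=str(row[snp_c]).strip(),
                    effect_allele=row[ea_c],
                    other_allele=row[oa_c],
                    beta=_num(row[cols["beta"]], "beta", i),
                    se=_num(row[cols["se"]], "se", i),
                    scale=row_scale,
                    derivation="reported-se",
                    p_value=p_val,
                )
            )
        else:
            lo_c, hi_c = col("ci_lower"), col("ci_upper")
            or_val = _num(row[cols["or"]], "or", i)
            lo = _num(row[lo_c], "ci_lower", i)
            hi = _num(row[hi_c], "ci_upper", i)
            if not or_val > 0:
                raise ValueError(f"row {i}: odds ratio must be positive, got {or_val}")
            if not (lo > 0 and hi > 0):
                raise ValueError(f"row {i}: CI bounds must be positive, got ({lo}, {hi})")
            records.append(
                OutcomeAssociation(
                    snp_id=str(row[snp_c]).strip(),
                    effect_allele=row[ea_c],
                    other_allele=row[oa_c],
                    beta=logor_from_or(or_val),
                    se=se_from_or_ci(lo, hi, ci_level),
                    scale=row_scale,
                    derivation="ci-derived",
                    ci_level=ci_level,
                    p_value=p_val,
                    source_or=or_val,
                    source_ci_lower=lo,
                    source_ci_upper=hi,
                )
            )
    return records


def outcome_table(records: Sequence[OutcomeAssociation]) -> pd.DataFrame:
    """Serialize outcome records back to a delimited-ready table.

    CI-derived records are written in their original OR/CI form so that a
    parse -> serialize round trip preserves every source cell exactly.
    """
    rows = []
    for r in records:
        if r.derivation == "ci-derived":
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "or": r.source_or,
                    "ci_lower": r.source_ci_lower,
                    "ci_upper": r.source_ci_upper,
                    "p_value": r.p_value,
                    "scale": r.scale,
                }
            )
        else:
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "beta": r.beta,
                    "se": r.se,
                    "p_value": r.p_value,
                    "scale": r.scale,
                }
            )
    return pd.DataFrame(rows)


def exposure_table(records: Sequence[ExposureAssociation]) -> pd.DataFrame:
    """Serialize exposure records to a delimited-ready table."""
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p_value": [r.p_value for r in records],
            "eaf": [r.eaf for r in records],
            "n": [r.n for r in records],
        }
    )


def pairs_table(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Serialize harmonized pairs to a delimited-ready table."""
    return pd.DataFrame([vars(p) for p in pairs])


# --- harmonization ---------------------------------------------------------

def is_palindromic(allele_1: str, allele_2: str) -> bool:
    """A/T and C/G pairs: strand cannot be resolved from allele labels alone."""
    return COMPLEMENT.get(allele_1.upper()) == allele_2.upper()


def harmonize(
    exposure: ExposureAssociation,
    outcome: OutcomeAssociation,
    palindrome_policy: Literal["error", "drop"] = "error",
) -> HarmonizedPair | None:
    """Orient an outcome record to the exposure record's effect allele.

    Matching is attempted in order: same orientation (copy through), swapped
    alleles (negate the outcome effect), then — only if both fail — strand
    complementation of the outcome alleles followed by the same two rules.
    Palindromic variants (A/T or C/G) are ambiguous under complementation
    and are handled according to ``palindrome_policy``: ``"error"`` raises,
    ``"drop"`` returns ``None``.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(f"snp_id mismatch: {exposure.snp_id!r} vs {outcome.snp_id!r}")
    if is_palindromic(exposure.effect_allele, exposure.other_allele):
        if palindrome_policy == "drop":
            logger.warning("dropping palindromic SNP %s", exposure.snp_id)
            return None
        raise HarmonizationError(
            f"{exposure.snp_id} is palindromic ({exposure.effect_allele}/"
            f"{exposure.other_allele}); strand cannot be resolved from allele labels"
        )

    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    candidates = [(outcome.effect_allele, outcome.other_allele, False)]
    # strand flip is a fallback, attempted only if direct/swapped both fail
    candidates.append(
        (COMPLEMENT[outcome.effect_allele], COMPLEMENT[outcome.other_allele], True)
    )
    for o_ea, o_oa, flipped_strand in candidates:
        if (o_ea, o_oa) == (e_ea, e_oa):
            sign = 1.0
        elif (o_ea, o_oa) == (e_oa, e_ea):
            sign = -1.0
        else:
            continue
        if flipped_strand:
            logger.info("harmonize: %s matched after strand complementation", exposure.snp_id)
        return HarmonizedPair(
            snp_id=exposure.snp_id,
            effect_allele=e_ea,
            other_allele=e_oa,
            exposure_beta=exposure.beta,
            exposure_se=exposure.se,
            outcome_beta=sign * outcome.beta,
            outcome_se=outcome.se,
            outcome_scale=outcome.scale,
        )
    raise HarmonizationError(
        f"{exposure.snp_id}: irreconcilable allele sets "
        f"exposure {e_ea}/{e_oa} vs outcome "
        f"{outcome.effect_allele}/{outcome.other_allele}"
    )


def harmonize_tables(
    exposures: Sequence[ExposureAssociation],
    outcomes: Sequence[OutcomeAssociation],
    palindrome_policy: Literal["error", "drop"] = "error",
) -> list[HarmonizedPair]:
    """Harmonize every exposure SNP that also appears in the outcome table."""
    by_id = {o.snp_id: o for o in outcomes}
    pairs = []
    for exp in exposures:
        out = by_id.get(exp.snp_id)
        if out is None:
            logger.warning("SNP %s absent from outcome table; skipped", exp.snp_id)
            continue
        pair = harmonize(exp, out, palindrome_policy)
        if pair is not None:
            pairs.append(pair)
    return pairs


def flip_orientation(outcome: OutcomeAssociation) -> OutcomeAssociation:
    """Re-express an outcome record relative to its other allele (sign flip)."""
    return replace(
        outcome,
        effect_allele=outcome.other_allele,
        other_allele=outcome.effect_allele,
        beta=-outcome.beta,
        source_or=None if outcome.source_or is None else 1 / outcome.source_or,
        source_ci_lower=None if outcome.source_ci_upper is None else 1 / outcome.source_ci_upper,
        source_ci_upper=None if outcome.source_ci_lower is None else 1 / outcome.source_ci_lower,
    )
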