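"""Two-sample MR estimation from summary associations.

The causal effect of the exposure on the outcome is estimated by
inverse-variance weighting (IVW) with multiplicative random effects: the
point estimate is the slope of the zero-intercept weighted least-squares fit
of outcome betas on exposure betas with weights 1/se_outcome^2,

    beta_IVW = sum(bx * by / sy^2) / sum(bx^2 / sy^2),

identical to the fixed-effect IVW point estimate; the standard error is the
fixed-effect standard error inflated by the square root of the residual mean
square of the weighted fit, floored at 1 so that underdispersion never
shrinks the interval.  Confidence intervals use the normal approximation.

For file-based inputs the exposure and outcome records are first harmonized
to a common effect allele: outcome betas are sign-flipped when the allele
labels are swapped, strand flips are resolved by complementing, and
palindromic variants (A/T or C/G) are aligned by allele-frequency proximity
or dropped when the frequencies are uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NonEstimableError
from .gwas import InstrumentSet, SummaryAssociation, select_instruments, select_instruments_by_pvalue

__all__ = [
    "COMBINATIONS",
    "HarmonizedData",
    "MRResult",
    "CombinationResult",
    "wald_ratio",
    "ivw_fit",
    "ivw_mre",
    "harmonize",
    "run_four_combinations",
]

logger = logging.getLogger(__name__)

#: the four exposure/outcome covariable-adjustment combinations
COMBINATIONS = (
    "unadjusted",
    "exposure_adjusted",
    "outcome_adjusted",
    "both_adjusted",
)

#: 97.5% normal quantile for the 95% confidence interval
_Z95 = 1.959963984540054

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: palindromic variants with an effect-allele frequency this close to 0.5 on
#: either side cannot be aligned by frequency and are dropped
PALINDROMIC_AMBIGUITY_ZONE = (0.42, 0.58)


@dataclass(frozen=True)
class MRResult:
    """A causal-effect estimate in outcome units per exposure unit."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_instruments: int
    residual_scale: float
    method: str = "IVW-MRE"

    def covers(self, value: float) -> bool:
        """Whether the confidence interval contains ``value``."""
        return self.ci_low <= value <= self.ci_high


@dataclass
class HarmonizedData:
    """Exposure/outcome summary pairs aligned to a common effect allele.

    ``table`` has one row per retained variant with columns ``variant_id``,
    ``beta_exposure``, ``se_exposure``, ``beta_outcome``, ``se_outcome``,
    ``eaf_exposure``, ``eaf_outcome`` and ``flipped``; ``dropped`` records
    ``(variant_id, reason)`` for the variants that could not be aligned.
    """

    table: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)
    exposure_adjusted: str | None = None
    outcome_adjusted: str | None = None

    @property
    def n_variants(self) -> int:
        return len(self.table)


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
) -> tuple[float, float]:
    """Single-variant causal-effect estimate and first-order standard error.

    The estimate is ``beta_outcome / beta_exposure``; the standard error is
    the leading-order delta-method term ``|se_outcome / beta_exposure|``,
    which ignores the (second-order) uncertainty of the exposure association.
    """
    if beta_exposure == 0:
        raise ValueError("Wald ratio undefined: exposure association is zero")
    return beta_outcome / beta_exposure, abs(se_outcome / beta_exposure)


def ivw_fit(
    beta_exposure: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
) -> MRResult:
    """Multiplicative random-effects IVW over aligned summary pairs."""
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    if not bx.shape == by.shape == sy.shape:
        raise ValueError("beta/se arrays must share a common length")
    k = bx.size
    if k == 0:
        raise NonEstimableError("no instruments: causal effect is not estimable")
    if np.any(sy <= 0):
        raise ValueError("all outcome standard errors must be positive")
    if k == 1:
        logger.info("single instrument: falling back to the Wald ratio")
        est, se = wald_ratio(bx[0], np.nan, by[0], sy[0])
        return MRResult(
            estimate=est,
            se=se,
            ci_low=est - _Z95 * se,
            ci_high=est + _Z95 * se,
            n_instruments=1,
            residual_scale=1.0,
            method="Wald ratio",
        )
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    if sxx == 0:
        raise NonEstimableError("all exposure associations are zero")
    est = np.sum(w * bx * by) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    resid = by - est * bx
    dispersion = np.sum(w * resid**2) / (k - 1)
    residual_scale = max(1.0, float(np.sqrt(dispersion)))
    se = se_fixed * residual_scale
    return MRResult(
        estimate=float(est),
        se=float(se),
        ci_low=float(est - _Z95 * se),
        ci_high=float(est + _Z95 * se),
        n_instruments=k,
        residual_scale=residual_scale,
    )


def ivw_mre(harmonized: HarmonizedData) -> MRResult:
    """IVW with multiplicative random effects on a harmonized dataset."""
    t = harmonized.table
    return ivw_fit(
        t["beta_exposure"].to_numpy(),
        t["beta_outcome"].to_numpy(),
        t["se_outcome"].to_numpy(),
    )


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _ambiguous_eaf(eaf: float | None) -> bool:
    lo, hi = PALINDROMIC_AMBIGUITY_ZONE
    return eaf is None or not np.isfinite(eaf) or lo <= eaf <= hi


def harmonize(
    exposure_records: pd.DataFrame,
    outcome_records: pd.DataFrame,
    *,
    exposure_adjusted: str | None = None,
    outcome_adjusted: str | None = None,
) -> HarmonizedData:
    """Align outcome records to the exposure's effect alleles.

    Inner-joins on variant id, then per variant: identical alleles pass
    through; swapped effect/other alleles flip the outcome beta sign (and
    its frequency); strand differences are resolved by complementing the
    outcome alleles first.  Palindromic variants are aligned by comparing
    which side of 0.5 each frequency falls on, and dropped when either
    frequency is missing or inside the ambiguity zone.  Variants whose
    allele sets cannot be reconciled are dropped with a logged reason.
    """
    exp = exposure_records.set_index("variant_id", drop=False)
    out = outcome_records.set_index("variant_id", drop=False)
    if exp.index.has_duplicates or out.index.has_duplicates:
        raise ValueError("duplicate variant ids in summary records")
    shared = [v for v in exp.index if v in out.index]
    rows = []
    dropped: list[tuple[str, str]] = []
    for vid in shared:
        ex, ou = exp.loc[vid], out.loc[vid]
        ea_x = str(ex["effect_allele"]).upper()
        oa_x = str(ex["other_allele"]).upper()
        ea_y = str(ou["effect_allele"]).upper()
        oa_y = str(ou["other_allele"]).upper()
        eaf_x = ex.get("eaf")
        eaf_y = ou.get("eaf")
        beta_y = float(ou["beta"])

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                dropped.append((vid, "allele_mismatch"))
                continue
            if _ambiguous_eaf(eaf_x) or _ambiguous_eaf(eaf_y):
                dropped.append((vid, "palindromic_ambiguous"))
                continue
            flipped = (eaf_x < 0.5) != (eaf_y < 0.5)
        else:
            if {ea_y, oa_y} == {ea_x, oa_x}:
                flipped = ea_y != ea_x
            elif {_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)} == {ea_x, oa_x}:
                flipped = _COMPLEMENT[ea_y] != ea_x
            else:
                dropped.append((vid, "allele_mismatch"))
                continue
        if flipped:
            beta_y = -beta_y
            if eaf_y is not None and np.isfinite(eaf_y):
                eaf_y = 1.0 - eaf_y
        rows.append(
            {
                "variant_id": vid,
                "beta_exposure": float(ex["beta"]),
                "se_exposure": float(ex["se"]),
                "beta_outcome": beta_y,
                "se_outcome": float(ou["se"]),
                "eaf_exposure": eaf_x,
                "eaf_outcome": eaf_y,
                "flipped": bool(flipped),
            }
        )
    for vid, reason in dropped:
        logger.info("harmonization dropped %s (%s)", vid, reason)
    if not rows:
        raise NonEstimableError(
            "no variants could be harmonized between exposure and outcome records"
        )
    table = pd.DataFrame(rows)
    return HarmonizedData(
        table=table,
        dropped=dropped,
        exposure_adjusted=exposure_adjusted,
        outcome_adjusted=outcome_adjusted,
    )


@dataclass(frozen=True)
class CombinationResult:
    """MR output for one exposure/outcome adjustment combination.

    ``result`` is None when no instrument passed selection for this
    combination (the non-estimable marker); the other combinations of the
    same run are unaffected.
    """

    combination: str
    instruments: InstrumentSet
    result: MRResult | None
    mean_f_stat: float

    @property
    def estimable(self) -> bool:
        return self.result is not None


def _combine(
    combination: str,
    exposure_gwas: list[SummaryAssociation],
    outcome_gwas: list[SummaryAssociation],
    f_threshold: float | None,
    p_threshold: float | None,
) -> CombinationResult:
    if p_threshold is not None:
        instruments = select_instruments_by_pvalue(exposure_gwas, p_threshold)
    else:
        instruments = select_instruments(exposure_gwas, f_threshold or 10.0)
    exp_by_id = {a.variant_id: a for a in exposure_gwas}
    out_by_id = {a.variant_id: a for a in outcome_gwas}
    missing = [v for v in instruments if v not in out_by_id]
    if missing:
        raise ValueError(
            f"instruments absent from the outcome GWAS: {', '.join(missing)}"
        )
    selected = [exp_by_id[v] for v in instruments]
    mean_f = float(np.mean([a.f_stat for a in selected])) if selected else np.nan
    if not selected:
        return CombinationResult(combination, instruments, None, mean_f)
    bx = np.array([a.beta for a in selected])
    by = np.array([out_by_id[a.variant_id].beta for a in selected])
    sy = np.array([out_by_id[a.variant_id].se for a in selected])
    return CombinationResult(combination, instruments, ivw_fit(bx, by, sy), mean_f)


def run_four_combinations(
    exposure_gwas_unadj: list[SummaryAssociation],
    exposure_gwas_adj: list[SummaryAssociation],
    outcome_gwas_unadj: list[SummaryAssociation],
    outcome_gwas_adj: list[SummaryAssociation],
    f_threshold: float | None = 10.0,
    p_threshold: float | None = None,
) -> dict[str, CombinationResult]:
    """IVW under the four exposure/outcome adjustment combinations.

    Instruments are re-selected per combination from the matching exposure
    GWAS: combinations using W-adjusted exposure associations select on the
    adjusted F (or p) statistics, unadjusted combinations on the unadjusted
    ones.  Records are joined by variant id, so both GWAS must share the
    variant coding (as within one simulated cohort); for independently
    sourced files, harmonize first and use :func:`ivw_mre`.

    A combination with zero selected instruments yields a non-estimable
    marker rather than an error.
    """
    plan = {
        "unadjusted": (exposure_gwas_unadj, outcome_gwas_unadj),
        "exposure_adjusted": (exposure_gwas_adj, outcome_gwas_unadj),
        "outcome_adjusted": (exposure_gwas_unadj, outcome_gwas_adj),
        "both_adjusted": (exposure_gwas_adj, outcome_gwas_adj),
    }
    return {
        name: _combine(name, exp, out, f_threshold, p_threshold)
        for name, (exp, out) in plan.items()
    }
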