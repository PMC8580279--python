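"""File-based MR workflows: selection, harmonization and IVW on summary tables.

These drivers operate on DataFrames in the summary-statistics dialect (see
:mod:`mrcovadj.io`), as produced by GWAS consortia dumps or by the
simulation writer, and run the same four-combination analysis as the
Monte-Carlo study: instruments are re-selected from whichever exposure GWAS
(adjusted or unadjusted) a combination uses, harmonized against the outcome
records, and combined by multiplicative random-effects IVW.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import NonEstimableError
from .gwas import InstrumentSet, filter_by_covariable_association, select_instruments, select_instruments_by_pvalue
from .io import frame_to_associations
from .mr import CombinationResult, harmonize, ivw_mre

__all__ = ["mr_from_tables", "four_combinations_from_tables"]

logger = logging.getLogger(__name__)


def mr_from_tables(
    exposure_df: pd.DataFrame,
    outcome_df: pd.DataFrame,
    *,
    combination: str = "unadjusted",
    exposure_adjusted: str | None = None,
    outcome_adjusted: str | None = None,
    p_threshold: float | None = 5e-8,
    f_threshold: float | None = None,
    covariable_df: pd.DataFrame | None = None,
    exclude_p: float = 0.05,
) -> tuple[CombinationResult, dict]:
    """One MR analysis from exposure and outcome summary tables.

    Instruments are selected from the exposure records at genome-wide
    significance (``p_threshold``, strict) or by instrument strength
    (``f_threshold``, inclusive) when given; optionally, instruments
    associated with the covariable at ``p < exclude_p`` in ``covariable_df``
    are excluded.  Selected exposure rows are harmonized against the outcome
    records before IVW.  Variant independence (LD clumping) is the caller's
    responsibility.

    Returns the combination result (non-estimable marker when no variant
    survives) and a diagnostics dict with selection/harmonization counts.
    """
    records = frame_to_associations(
        exposure_df, trait="exposure", adjusted_for=exposure_adjusted
    )
    if f_threshold is not None:
        instruments = select_instruments(records, f_threshold)
    else:
        instruments = select_instruments_by_pvalue(records, p_threshold or 5e-8)
    if covariable_df is not None:
        covar_records = frame_to_associations(covariable_df, trait="covariable")
        instruments = filter_by_covariable_association(
            instruments, covar_records, exclude_p
        )
    selected = [r for r in records if r.variant_id in instruments]
    mean_f = float(np.mean([r.f_stat for r in selected])) if selected else np.nan
    diagnostics = {
        "n_exposure_records": len(records),
        "n_selected": len(selected),
        "n_harmonized": 0,
        "n_dropped": 0,
    }
    if not selected:
        return CombinationResult(combination, instruments, None, mean_f), diagnostics
    subset = exposure_df[exposure_df["variant_id"].isin(set(instruments))]
    try:
        harmonized = harmonize(
            subset,
            outcome_df,
            exposure_adjusted=exposure_adjusted,
            outcome_adjusted=outcome_adjusted,
        )
    except NonEstimableError:
        diagnostics["n_dropped"] = len(selected)
        return CombinationResult(combination, instruments, None, mean_f), diagnostics
    diagnostics["n_harmonized"] = harmonized.n_variants
    diagnostics["n_dropped"] = len(harmonized.dropped) + (
        len(selected) - harmonized.n_variants - len(harmonized.dropped)
    )
    result = ivw_mre(harmonized)
    retained = InstrumentSet(
        variant_ids=tuple(harmonized.table["variant_id"]),
        basis=instruments.basis,
        f_threshold=instruments.f_threshold,
        p_threshold=instruments.p_threshold,
    )
    logger.info(
        "%s: %d exposure records, %d selected, %d harmonized, %d dropped",
        combination,
        len(records),
        len(selected),
        diagnostics["n_harmonized"],
        diagnostics["n_dropped"],
    )
    return CombinationResult(combination, retained, result, mean_f), diagnostics


def four_combinations_from_tables(
    exposure_unadj: pd.DataFrame,
    exposure_adj: pd.DataFrame,
    outcome_unadj: pd.DataFrame,
    outcome_adj: pd.DataFrame,
    *,
    p_threshold: float | None = 5e-8,
    f_threshold: float | None = None,
    covariable_df: pd.DataFrame | None = None,
    exclude_p: float = 0.05,
) -> tuple[dict[str, CombinationResult], dict[str, dict]]:
    """The four adjustment combinations on file-based summary tables.

    Combinations using adjusted exposure associations select instruments
    from the adjusted exposure GWAS (and vice versa), mirroring that the set
    of instruments legitimately differs between adjusted and unadjusted
    analyses.
    """
    plan = {
        "unadjusted": (exposure_unadj, None, outcome_unadj, None),
        "exposure_adjusted": (exposure_adj, "W", outcome_unadj, None),
        "outcome_adjusted": (exposure_unadj, None, outcome_adj, "W"),
        "both_adjusted": (exposure_adj, "W", outcome_adj, "W"),
    }
    results: dict[str, CombinationResult] = {}
    diagnostics: dict[str, dict] = {}
    for name, (exp, exp_label, out, out_label) in plan.items():
        results[name], diagnostics[name] = mr_from_tables(
            exp,
            out,
            combination=name,
            exposure_adjusted=exp_label,
            outcome_adjusted=out_label,
            p_threshold=p_threshold,
            f_threshold=f_threshold,
            covariable_df=covariable_df,
            exclude_p=exclude_p,
        )
    return results, diagnostics
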