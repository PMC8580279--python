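"""File dialects and result serialization.

GWAS summary statistics travel as one flat tab-delimited dialect with
columns ``variant_id effect_allele other_allele eaf beta se pval n``
(case-insensitive, order-free; common consortium aliases such as ``SNP``,
``A1``/``A2`` or ``P`` are accepted on input).  MR results are written as a
deterministic tab-delimited report with one row per adjustment combination.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .gwas import SummaryAssociation
from .mr import CombinationResult
from .scenarios import ScenarioConfig

__all__ = [
    "SUMMARY_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "associations_to_frame",
    "frame_to_associations",
    "write_report",
    "load_scenario_config",
    "save_scenario_config",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se")

_ALIASES = {
    "snp": "variant_id",
    "rsid": "variant_id",
    "markername": "variant_id",
    "id": "variant_id",
    "ea": "effect_allele",
    "a1": "effect_allele",
    "allele1": "effect_allele",
    "nea": "other_allele",
    "oa": "other_allele",
    "a2": "other_allele",
    "allele2": "other_allele",
    "freq": "eaf",
    "eaf": "eaf",
    "effect_allele_frequency": "eaf",
    "b": "beta",
    "effect": "beta",
    "stderr": "se",
    "standard_error": "se",
    "p": "pval",
    "p_value": "pval",
    "pvalue": "pval",
    "samplesize": "n",
    "n_samples": "n",
}


def _canonical_columns(columns: list[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        canon = _ALIASES.get(key, key)
        if canon in SUMMARY_COLUMNS:
            mapping[col] = canon
    return mapping


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file into a typed DataFrame.

    Rows with non-numeric or non-positive standard errors, or non-numeric
    betas, are skipped; the number of skipped rows is logged and stored in
    ``df.attrs['n_rows_skipped']``.  A missing mandatory column raises
    :class:`FormatError` naming it.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse {path} as tab-delimited text: {exc}") from exc
    raw = raw.rename(columns=_canonical_columns(list(raw.columns)))
    for col in _MANDATORY:
        if col not in raw.columns:
            raise FormatError(f"{path} is missing the mandatory column {col!r}")
    df = raw.loc[:, [c for c in SUMMARY_COLUMNS if c in raw.columns]].copy()

    def _to_float(value):
        # float() is correctly rounded, so written values round-trip exactly
        try:
            return float(value)
        except (TypeError, ValueError):
            return np.nan

    for col in ("eaf", "beta", "se", "pval", "n"):
        if col in df.columns:
            df[col] = df[col].map(_to_float)
    ok = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning(
            "%s: skipped %d row(s) with missing/invalid beta or se", path, n_skipped
        )
    df = df.loc[ok].reset_index(drop=True)
    df.attrs["n_rows_skipped"] = n_skipped
    return df


def associations_to_frame(records: list[SummaryAssociation]) -> pd.DataFrame:
    """Summary associations as a DataFrame in the dialect's column order."""
    return pd.DataFrame(
        {
            "variant_id": [a.variant_id for a in records],
            "effect_allele": [a.effect_allele for a in records],
            "other_allele": [a.other_allele for a in records],
            "eaf": [np.nan if a.eaf is None else a.eaf for a in records],
            "beta": [a.beta for a in records],
            "se": [a.se for a in records],
            "pval": [a.p_value for a in records],
            "n": [a.n for a in records],
        }
    )


def frame_to_associations(
    df: pd.DataFrame, trait: str = "trait", adjusted_for: str | None = None
) -> list[SummaryAssociation]:
    """Typed records from a dialect DataFrame, with the Wald F recomputed."""
    records = []
    for row in df.itertuples(index=False):
        beta = float(row.beta)
        se = float(row.se)
        records.append(
            SummaryAssociation(
                variant_id=str(row.variant_id),
                trait=trait,
                beta=beta,
                se=se,
                n=int(row.n) if hasattr(row, "n") and np.isfinite(row.n) else 0,
                p_value=float(row.pval) if hasattr(row, "pval") else np.nan,
                f_stat=(beta / se) ** 2,
                adjusted_for=adjusted_for,
                eaf=float(row.eaf)
                if hasattr(row, "eaf") and np.isfinite(row.eaf)
                else None,
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
            )
        )
    return records


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited write with floats at full precision (exact round-trip)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_summary_stats(
    records: list[SummaryAssociation] | pd.DataFrame, path: str | Path
) -> None:
    """Write records in the tab-delimited dialect (full float precision)."""
    df = records if isinstance(records, pd.DataFrame) else associations_to_frame(records)
    write_table(df, path)


_REPORT_COLUMNS = (
    "combination",
    "status",
    "method",
    "n_instruments",
    "mean_f_stat",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "residual_scale",
    "n_harmonized",
    "n_dropped",
)


def write_report(
    results: dict[str, CombinationResult],
    path: str | Path,
    diagnostics: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Write one tab-delimited row per combination; returns the table.

    Non-estimable combinations appear as marker rows (``status =
    non_estimable``) with empty numeric fields.  ``diagnostics`` may carry
    per-combination harmonization audit counts (``n_harmonized``,
    ``n_dropped``).
    """
    if not results:
        raise ValueError("no combination results to report")
    rows = []
    for name, combo in results.items():
        diag = (diagnostics or {}).get(name, {})
        row = {
            "combination": name,
            "status": "ok" if combo.estimable else "non_estimable",
            "method": combo.result.method if combo.estimable else "",
            "n_instruments": len(combo.instruments),
            "mean_f_stat": combo.mean_f_stat,
            "estimate": combo.result.estimate if combo.estimable else np.nan,
            "se": combo.result.se if combo.estimable else np.nan,
            "ci_low": combo.result.ci_low if combo.estimable else np.nan,
            "ci_high": combo.result.ci_high if combo.estimable else np.nan,
            "residual_scale": combo.result.residual_scale if combo.estimable else np.nan,
            "n_harmonized": diag.get("n_harmonized", np.nan),
            "n_dropped": diag.get("n_dropped", np.nan),
        }
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(_REPORT_COLUMNS))
    write_table(table, path)
    return table


def save_scenario_config(config: ScenarioConfig, path: str | Path) -> None:
    """Serialize a scenario configuration as YAML."""
    payload = {
        "structure": config.structure,
        "confounding": config.confounding,
        "variant_mode": config.variant_mode,
        "beta_xy_null": config.beta_xy_null,
        "n_individuals": config.n_individuals,
        "n_variants": config.n_variants,
        "score_variance_fraction": config.score_variance_fraction,
        "direct_effect_variance_fraction": config.direct_effect_variance_fraction,
        "allele_freq_range": list(config.allele_freq_range),
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Parse a YAML scenario configuration (inverse of :func:`save_scenario_config`)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise FormatError(f"{path} does not contain a configuration mapping")
    if "allele_freq_range" in payload:
        payload["allele_freq_range"] = tuple(payload["allele_freq_range"])
    try:
        return ScenarioConfig(**payload)
    except TypeError as exc:
        raise FormatError(f"{path}: {exc}") from exc
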