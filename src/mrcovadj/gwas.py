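"""Per-variant summary associations and instrument selection.

Associations are ordinary least squares of a trait on each variant's allele
count, optionally adjusting for the heritable covariable W.  The instrument
strength F statistic is the squared Wald t of the genotype coefficient; in
adjusted models this is the partial F for the genotype term, which is what
two-sample MR practice reports per variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "SummaryAssociation",
    "InstrumentSet",
    "estimate_association",
    "run_gwas",
    "select_instruments",
    "select_instruments_by_pvalue",
    "filter_by_covariable_association",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryAssociation:
    """One variant's estimated association with one trait.

    ``beta`` is per effect-allele copy in trait units.  ``f_stat`` equals
    ``(beta/se)**2``.  A variant whose genotype column is constant in the
    sample carries NaN ``beta``/``se``/``f_stat`` and is excluded by the
    selection step.
    """

    variant_id: str
    trait: str
    beta: float
    se: float
    n: int
    p_value: float
    f_stat: float
    adjusted_for: str | None = None
    eaf: float | None = None
    effect_allele: str = "A"
    other_allele: str = "G"

    @property
    def is_defined(self) -> bool:
        return np.isfinite(self.beta) and np.isfinite(self.se) and self.se > 0


@dataclass(frozen=True)
class InstrumentSet:
    """Ordered, duplicate-free set of selected instrument variant ids."""

    variant_ids: tuple[str, ...]
    basis: str
    f_threshold: float | None = None
    p_threshold: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("instrument set contains duplicate variant ids")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __iter__(self):
        return iter(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.variant_ids


def _ols_scan(
    genotypes: np.ndarray,
    trait: np.ndarray,
    covariable: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized per-column OLS of trait on genotype (+ intercept, + covariable).

    Uses Frisch-Waugh-Lovell: residualize trait and genotype columns on the
    nuisance design (intercept, optionally W), then each variant's
    coefficient and standard error follow from a simple regression on the
    residualized column with the correct residual degrees of freedom.
    Identical to column-by-column multiple OLS.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = y.shape[0]
    if G.shape[0] != n:
        raise ValueError(
            f"genotypes and trait have mismatched lengths ({G.shape[0]} vs {n})"
        )
    y = y - y.mean()
    G = G - G.mean(axis=0)
    n_params = 2
    if covariable is not None:
        w = np.asarray(covariable, dtype=float)
        if w.shape[0] != n:
            raise ValueError(
                f"covariable length {w.shape[0]} does not match trait length {n}"
            )
        w = w - w.mean()
        ww = w @ w
        if ww > 0:
            y = y - (y @ w) / ww * w
            G = G - np.outer(w, (w @ G) / ww)
        n_params = 3
    df = n - n_params
    if df <= 0:
        raise ValueError(f"not enough observations (n={n}) for {n_params} parameters")
    if y @ y == 0:
        raise ValueError("trait has zero variance")
    sxx = np.einsum("ij,ij->j", G, G)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (y @ G) / sxx
        rss = np.maximum(y @ y - beta**2 * sxx, 0.0)
        se = np.sqrt(rss / df / sxx)
    constant = sxx == 0
    beta[constant] = np.nan
    se[constant] = np.nan
    return beta, se, df


def _wald_stats(beta: np.ndarray, se: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (beta / se) ** 2
    p = stats.f.sf(f_stat, 1, df)
    # perfect fits: se == 0 -> infinite F, p = 0
    exact = np.isfinite(beta) & (se == 0)
    f_stat = np.where(exact, np.inf, f_stat)
    p = np.where(exact, 0.0, p)
    return f_stat, p


def run_gwas(
    genotypes: np.ndarray,
    trait_values: np.ndarray,
    covariable_values: np.ndarray | None = None,
    *,
    variant_ids: tuple[str, ...] | None = None,
    trait: str = "trait",
    adjusted_for: str | None = None,
    eafs: np.ndarray | None = None,
) -> list[SummaryAssociation]:
    """One :class:`SummaryAssociation` per genotype column, order preserved.

    When ``covariable_values`` is supplied, every record carries the
    covariable label (default ``'W'``) in ``adjusted_for``.
    """
    G = np.asarray(genotypes)
    n, m = G.shape
    if variant_ids is None:
        variant_ids = tuple(f"rs{i + 1}" for i in range(m))
    if len(variant_ids) != m:
        raise ValueError("variant_ids length does not match the genotype matrix")
    if covariable_values is not None and adjusted_for is None:
        adjusted_for = "W"
    beta, se, df = _ols_scan(G, trait_values, covariable_values)
    f_stat, p = _wald_stats(beta, se, df)
    n_constant = int(np.sum(~np.isfinite(beta)))
    if n_constant:
        logger.warning(
            "%d of %d genotype columns are constant; their associations are "
            "undefined and will be excluded from instrument selection",
            n_constant,
            m,
        )
    return [
        SummaryAssociation(
            variant_id=variant_ids[j],
            trait=trait,
            beta=float(beta[j]),
            se=float(se[j]),
            n=n,
            p_value=float(p[j]) if np.isfinite(beta[j]) else np.nan,
            f_stat=float(f_stat[j]),
            adjusted_for=adjusted_for,
            eaf=None if eafs is None else float(eafs[j]),
        )
        for j in range(m)
    ]


def estimate_association(
    genotype_column: np.ndarray,
    trait_values: np.ndarray,
    covariable_values: np.ndarray | None = None,
    *,
    variant_id: str = "rs1",
    trait: str = "trait",
    adjusted_for: str | None = None,
    eaf: float | None = None,
) -> SummaryAssociation:
    """OLS association of one variant with one trait (optionally W-adjusted)."""
    g = np.asarray(genotype_column, dtype=float).reshape(-1, 1)
    records = run_gwas(
        g,
        trait_values,
        covariable_values,
        variant_ids=(variant_id,),
        trait=trait,
        adjusted_for=adjusted_for,
        eafs=None,
    )
    return replace(records[0], eaf=eaf)


def select_instruments(
    exposure_associations: list[SummaryAssociation],
    f_threshold: float = 10.0,
) -> InstrumentSet:
    """Variants whose exposure F statistic meets the strength threshold.

    The boundary is inclusive (an F of exactly 10 passes).  Undefined
    associations (constant genotype columns) never pass.  An empty result is
    valid: downstream estimation must then report non-estimability.
    """
    if f_threshold <= 0:
        raise ValueError(f"f_threshold must be positive; got {f_threshold}")
    # NaN F statistics (constant columns) compare False and are excluded
    ids = tuple(
        a.variant_id for a in exposure_associations if a.f_stat >= f_threshold
    )
    basis = "adjusted" if any(a.adjusted_for for a in exposure_associations) else "unadjusted"
    return InstrumentSet(variant_ids=ids, basis=basis, f_threshold=f_threshold)


def select_instruments_by_pvalue(
    exposure_associations: list[SummaryAssociation],
    p_threshold: float = 5e-8,
) -> InstrumentSet:
    """Genome-wide-significance selection (p strictly below the threshold)."""
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must lie in (0, 1); got {p_threshold}")
    ids = tuple(
        a.variant_id
        for a in exposure_associations
        if np.isfinite(a.p_value) and a.p_value < p_threshold
    )
    basis = "adjusted" if any(a.adjusted_for for a in exposure_associations) else "unadjusted"
    return InstrumentSet(variant_ids=ids, basis=basis, p_threshold=p_threshold)


def filter_by_covariable_association(
    instruments: InstrumentSet,
    covariable_associations: list[SummaryAssociation],
    p_threshold: float = 0.05,
) -> InstrumentSet:
    """Drop instruments associated with the covariable at p below the threshold.

    Retention is ``p >= p_threshold`` (variants associated at ``p <
    p_threshold`` are excluded).  Every instrument must appear in the
    covariable association list.
    """
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must lie in (0, 1); got {p_threshold}")
    p_by_id = {a.variant_id: a.p_value for a in covariable_associations}
    missing = [v for v in instruments if v not in p_by_id]
    if missing:
        raise ValueError(
            "instruments missing from the covariable association list: "
            + ", ".join(missing)
        )
    kept = tuple(v for v in instruments if p_by_id[v] >= p_threshold)
    return replace(instruments, variant_ids=kept)
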