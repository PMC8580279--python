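"""Synthetic individual-level cohorts for studying covariable-adjustment bias in MR.

The generator produces genotypes and continuous phenotypes under a family of
causal structures linking a set of independent biallelic variants (Z), an
exposure (X), a heritable covariable (W), an optional shared intermediate (R)
and an outcome (Y):

* ``A`` — W fully mediates the effect of Z on X (Z -> W -> X).
* ``B`` — Z affects X and W independently.
* ``C`` — X fully mediates the effect of Z on W (Z -> X -> W).
* ``D`` — Z affects an intermediate R which is a common cause of X and W.
* ``E`` — as B, but W additionally has a direct effect on Y (horizontal
  pleiotropy; instrument strength independent of the pleiotropic effects).
* ``F`` — as D, but W has a direct effect on Y (pleiotropy with the
  instrument-strength independence assumption violated).

Each structure is crossed with five confounding settings: none (1), an
unmeasured common cause of X and W (2), of W and Y (3), of X and Y (4), or
all three at once (5).

Effect sizes are parameterized as fractions of the child phenotype's
variance: the additive allele score built from all variants with direct
effects on a phenotype accounts for 10% of its variance by default, and each
phenotypic or unmeasured direct cause accounts for 20%.  All direct effects
are positive.  Residual noise tops each phenotype up to (approximately) unit
variance, so "fraction of variance explained" is well defined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "STRUCTURES",
    "CONFOUNDING_SETTINGS",
    "VARIANT_MODES",
    "ScenarioConfig",
    "VariantGroupAssignment",
    "Cohort",
    "draw_genotypes",
    "assign_variant_groups",
    "build_allele_score",
    "simulate_cohort",
    "split_samples",
]

STRUCTURES = ("A", "B", "C", "D", "E", "F")
CONFOUNDING_SETTINGS = (1, 2, 3, 4, 5)
VARIANT_MODES = ("homogeneous", "heterogeneous")

#: variant groups, named by the traits a group's variants directly affect
GROUP_X_ONLY = "X_only"
GROUP_W_ONLY = "W_only"
GROUP_X_AND_W = "X_and_W"
GROUP_R_ONLY = "R_only"
GROUP_NULL = "null"

# In homogeneous mode every variant shares one causal role, dictated by the
# structure: all on W in A, all on X and W in B/E, all on X in C, all on the
# shared intermediate R in D/F.
_HOMOGENEOUS_GROUP = {
    "A": GROUP_W_ONLY,
    "B": GROUP_X_AND_W,
    "C": GROUP_X_ONLY,
    "D": GROUP_R_ONLY,
    "E": GROUP_X_AND_W,
    "F": GROUP_R_ONLY,
}

_CONFOUNDERS = {
    1: (),
    2: ("U_XW",),
    3: ("U_WY",),
    4: ("U_XY",),
    5: ("U_XW", "U_WY", "U_XY"),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one simulation cell.

    Parameters
    ----------
    structure : {'A','B','C','D','E','F'}
        Causal layout among Z, X, W, R and Y (see module docstring).
    confounding : {1,2,3,4,5}
        Which unmeasured confounders exist (1 = none, 2 = U_XW, 3 = U_WY,
        4 = U_XY, 5 = all three).
    variant_mode : {'homogeneous','heterogeneous'}
        Whether all variants share a single causal role or are split into
        non-overlapping subgroups with different roles.
    beta_xy_null : bool
        If True the causal effect of X on Y is exactly zero; otherwise X has
        a direct effect accounting for ``direct_effect_variance_fraction`` of
        the variance of Y.
    n_individuals : int
        Total cohort size before the two-sample split (must be even).
    n_variants : int
        Number of independent biallelic candidate instruments.
    score_variance_fraction : float
        Fraction of a phenotype's variance explained by its allele score.
    direct_effect_variance_fraction : float
        Fraction of the child phenotype's variance contributed by each
        phenotypic or unmeasured direct cause.
    allele_freq_range : (float, float)
        Bounds for the per-variant effect-allele frequency draws.
    seed : int or None
        Seed for all randomness when no generator is supplied explicitly.
    """

    structure: str
    confounding: int
    variant_mode: str = "homogeneous"
    beta_xy_null: bool = False
    n_individuals: int = 100_000
    n_variants: int = 40
    score_variance_fraction: float = 0.10
    direct_effect_variance_fraction: float = 0.20
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ConfigurationError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )
        if self.confounding not in CONFOUNDING_SETTINGS:
            raise ConfigurationError(
                f"unknown confounding setting {self.confounding!r}; "
                f"expected one of {CONFOUNDING_SETTINGS}"
            )
        if self.variant_mode not in VARIANT_MODES:
            raise ConfigurationError(
                f"unknown variant_mode {self.variant_mode!r}; "
                f"expected one of {VARIANT_MODES}"
            )
        if self.n_individuals <= 0 or self.n_individuals % 2:
            raise ConfigurationError(
                "n_individuals must be positive and even (the cohort is split "
                f"into exact halves); got {self.n_individuals}"
            )
        if self.n_variants <= 0:
            raise ConfigurationError("n_variants must be positive")
        for name in ("score_variance_fraction", "direct_effect_variance_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1); got {v}")
        lo, hi = self.allele_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigurationError(
                f"allele_freq_range must satisfy 0 < lower <= upper < 1; got {lo}, {hi}"
            )
        self._check_variance_budget()

    def _check_variance_budget(self) -> None:
        """Every phenotype's nominal systematic variance must stay below 1."""
        for child, causes in self.direct_causes().items():
            total = sum(v for _, v in causes)
            if total >= 1.0:
                listing = ", ".join(f"{name} ({v:.2f})" for name, v in causes)
                raise ConfigurationError(
                    f"systematic variance budget for {child} is {total:.2f} >= 1 "
                    f"(contributing causes: {listing})"
                )

    # -- derived structure -------------------------------------------------

    @property
    def scenario_id(self) -> str:
        """Compact cell label, e.g. ``'B3'``."""
        return f"{self.structure}{self.confounding}"

    @property
    def has_r(self) -> bool:
        return self.structure in ("D", "F")

    @property
    def w_affects_y(self) -> bool:
        return self.structure in ("E", "F")

    @property
    def confounders_present(self) -> tuple[str, ...]:
        return _CONFOUNDERS[self.confounding]

    def direct_causes(self) -> dict[str, list[tuple[str, float]]]:
        """Map each generated phenotype to its ``(cause, variance_fraction)`` list.

        Used both by the generator (to build phenotypes in topological order)
        and by the variance-budget validity check.
        """
        sv = self.score_variance_fraction
        dv = self.direct_effect_variance_fraction
        hetero = self.variant_mode == "heterogeneous"
        causes: dict[str, list[tuple[str, float]]] = {}

        if self.has_r:
            causes["R"] = [("score_R", sv)]

        x: list[tuple[str, float]] = []
        if hetero or _HOMOGENEOUS_GROUP[self.structure] in (GROUP_X_ONLY, GROUP_X_AND_W):
            x.append(("score_X", sv))
        if self.structure == "A":
            x.append(("W", dv))
        if self.has_r:
            x.append(("R", dv))
        if "U_XW" in self.confounders_present:
            x.append(("U_XW", dv))
        if "U_XY" in self.confounders_present:
            x.append(("U_XY", dv))
        causes["X"] = x

        w: list[tuple[str, float]] = []
        if hetero or _HOMOGENEOUS_GROUP[self.structure] in (GROUP_W_ONLY, GROUP_X_AND_W):
            w.append(("score_W", sv))
        if self.structure == "C":
            w.append(("X", dv))
        if self.has_r:
            w.append(("R", dv))
        if "U_XW" in self.confounders_present:
            w.append(("U_XW", dv))
        if "U_WY" in self.confounders_present:
            w.append(("U_WY", dv))
        causes["W"] = w

        y: list[tuple[str, float]] = []
        if not self.beta_xy_null:
            y.append(("X", dv))
        if self.w_affects_y:
            y.append(("W", dv))
        if "U_XY" in self.confounders_present:
            y.append(("U_XY", dv))
        if "U_WY" in self.confounders_present:
            y.append(("U_WY", dv))
        causes["Y"] = y
        return causes


@dataclass(frozen=True)
class VariantGroupAssignment:
    """Partition of the candidate variants into non-overlapping causal groups."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        valid = {GROUP_X_ONLY, GROUP_W_ONLY, GROUP_X_AND_W, GROUP_R_ONLY, GROUP_NULL}
        bad = set(self.labels) - valid
        if bad:
            raise ValueError(f"unknown variant group labels: {sorted(bad)}")

    @property
    def n_variants(self) -> int:
        return len(self.labels)

    def indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == group)

    def affecting(self, trait: str) -> np.ndarray:
        """Indices of variants with a direct effect on ``trait`` ('X','W','R')."""
        if trait == "X":
            groups = {GROUP_X_ONLY, GROUP_X_AND_W}
        elif trait == "W":
            groups = {GROUP_W_ONLY, GROUP_X_AND_W}
        elif trait == "R":
            groups = {GROUP_R_ONLY}
        else:
            raise ValueError(f"no variant group affects trait {trait!r}")
        mask = np.array([lab in groups for lab in self.labels])
        return np.flatnonzero(mask)


@dataclass
class Cohort:
    """Individual-level data for one simulated sample.

    Arrays are aligned by individual; ``R`` and entries of ``confounders``
    are present only when the scenario includes them.  ``beta_xy_true`` is
    the generating coefficient of X in the structural equation for Y on the
    (approximately) standardized scale — exactly the estimand of the
    downstream MR analysis.
    """

    config: ScenarioConfig
    genotypes: np.ndarray
    allele_freqs: np.ndarray
    groups: VariantGroupAssignment
    X: np.ndarray
    Y: np.ndarray
    W: np.ndarray
    beta_xy_true: float
    R: np.ndarray | None = None
    confounders: dict[str, np.ndarray] = field(default_factory=dict)
    variant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.variant_ids:
            self.variant_ids = tuple(
                f"rs{i + 1}" for i in range(self.genotypes.shape[1])
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def take(self, indices: np.ndarray) -> "Cohort":
        """Row subset (e.g. one half of the two-sample split)."""
        idx = np.asarray(indices)
        return dataclasses.replace(
            self,
            genotypes=self.genotypes[idx],
            X=self.X[idx],
            Y=self.Y[idx],
            W=self.W[idx],
            R=None if self.R is None else self.R[idx],
            confounders={k: v[idx] for k, v in self.confounders.items()},
        )


def draw_genotypes(
    n_individuals: int,
    n_variants: int,
    allele_freq_range: tuple[float, float] = (0.1, 0.9),
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw independent biallelic genotypes under Hardy-Weinberg equilibrium.

    Each variant's effect-allele frequency is drawn uniformly from
    ``allele_freq_range`` unless ``freqs`` is supplied, and allele counts are
    Binomial(2, freq).  Returns ``(genotypes, freqs)`` with genotypes an
    ``(n_individuals, n_variants)`` int8 matrix of counts in {0, 1, 2}.
    """
    if n_individuals <= 0 or n_variants <= 0:
        raise ValueError(
            f"cohort dimensions must be positive; got n_individuals={n_individuals}, "
            f"n_variants={n_variants}"
        )
    rng = np.random.default_rng() if rng is None else rng
    if freqs is None:
        lo, hi = allele_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(
                f"allele_freq_range must satisfy 0 < lower <= upper < 1; got {lo}, {hi}"
            )
        freqs = rng.uniform(lo, hi, size=n_variants)
    else:
        freqs = np.broadcast_to(np.asarray(freqs, dtype=float), (n_variants,)).copy()
    genotypes = rng.binomial(2, freqs, size=(n_individuals, n_variants)).astype(np.int8)
    return genotypes, freqs


def assign_variant_groups(config: ScenarioConfig) -> VariantGroupAssignment:
    """Assign each candidate variant to a causal group, deterministically.

    Homogeneous mode: every variant takes the single role the structure
    dictates.  Heterogeneous mode: the variants are split into equal
    contiguous subgroups — direct effects on X only, on W only, on both X and
    W, and on R only when the structure includes R; structures without R keep
    the fourth subgroup as null variants with no effects, so the number of
    candidate instruments is the same in every cell.
    """
    if config.variant_mode == "homogeneous":
        return VariantGroupAssignment((_HOMOGENEOUS_GROUP[config.structure],) * config.n_variants)
    fourth = GROUP_R_ONLY if config.has_r else GROUP_NULL
    order = (GROUP_X_ONLY, GROUP_W_ONLY, GROUP_X_AND_W, fourth)
    labels: list[str] = []
    for block, group in zip(np.array_split(np.arange(config.n_variants), 4), order):
        labels.extend([group] * len(block))
    return VariantGroupAssignment(tuple(labels))


def build_allele_score(genotypes: np.ndarray, member_variants: np.ndarray) -> np.ndarray:
    """Unweighted additive allele score over the member variants, standardized.

    The score is the plain sum of allele counts across the member columns,
    centred and scaled to unit empirical variance.
    """
    idx = np.asarray(member_variants)
    if idx.size == 0:
        raise ValueError("allele score requires a non-empty set of member variants")
    raw = genotypes[:, idx].sum(axis=1).astype(float)
    sd = raw.std()
    if sd == 0:
        raise ValueError("allele score has zero variance (all member variants fixed)")
    return (raw - raw.mean()) / sd


def _compose_phenotype(
    causes: list[tuple[str, np.ndarray, float]],
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, float]]:
    """Sum of scaled direct causes plus residual noise topping variance to 1.

    Each cause enters with coefficient sqrt(v)/sd(cause) so that, were the
    causes uncorrelated, it would contribute exactly the fraction ``v`` of
    the child's unit variance.  The residual variance is 1 minus the
    empirical variance of the systematic part (floored at 0.01, since
    positively correlated causes can overshoot the nominal budget).
    """
    budget = sum(v for _, _, v in causes)
    if budget >= 1.0:
        listing = ", ".join(f"{name} ({v:.2f})" for name, _, v in causes)
        raise ConfigurationError(
            f"systematic variance {budget:.2f} >= 1; contributing causes: {listing}"
        )
    systematic = np.zeros(n)
    coefficients: dict[str, float] = {}
    for name, values, v in causes:
        sd = values.std()
        coef = np.sqrt(v) / sd
        coefficients[name] = coef
        systematic = systematic + coef * (values - values.mean())
    residual_var = max(1.0 - systematic.var(), 0.01)
    return systematic + rng.normal(0.0, np.sqrt(residual_var), n), coefficients


def simulate_cohort(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> Cohort:
    """Generate one cohort under the configured causal structure.

    Phenotypes are built in topological order of the structure's DAG:
    genotypes and allele scores first, then unmeasured confounders, the
    intermediate R where present, W before X in structure A (W mediates
    Z -> X), X before W in structure C (X mediates Z -> W), and Y last.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    genotypes, freqs = draw_genotypes(
        n, config.n_variants, config.allele_freq_range, rng
    )
    groups = assign_variant_groups(config)

    scores: dict[str, np.ndarray] = {}
    for trait in ("X", "W", "R"):
        idx = groups.affecting(trait)
        if idx.size:
            scores[f"score_{trait}"] = build_allele_score(genotypes, idx)

    confounders = {
        name: rng.standard_normal(n) for name in config.confounders_present
    }

    values: dict[str, np.ndarray] = {**scores, **confounders}
    causes = config.direct_causes()

    def build(child: str) -> np.ndarray:
        spec = [(name, values[name], v) for name, v in causes[child]]
        pheno, coefs = _compose_phenotype(spec, n, rng)
        values[child] = pheno
        build.coefficients[child] = coefs  # type: ignore[attr-defined]
        return pheno

    build.coefficients = {}  # type: ignore[attr-defined]

    R = build("R") if config.has_r else None
    if config.structure == "A":
        W = build("W")
        X = build("X")
    else:
        X = build("X")
        W = build("W")
    Y = build("Y")

    beta_xy_true = 0.0 if config.beta_xy_null else build.coefficients["Y"]["X"]  # type: ignore[attr-defined]

    return Cohort(
        config=config,
        genotypes=genotypes,
        allele_freqs=freqs,
        groups=groups,
        X=X,
        Y=Y,
        W=W,
        R=R,
        confounders=confounders,
        beta_xy_true=float(beta_xy_true),
    )


def split_samples(
    cohort: Cohort, rng: np.random.Generator | None = None
) -> tuple[Cohort, Cohort]:
    """Random disjoint halves for the two-sample design.

    The first half estimates instrument-exposure associations, the second
    instrument-outcome associations; no individual appears in both.
    """
    if cohort.n % 2:
        raise ValueError(f"cannot split an odd-sized cohort (n={cohort.n})")
    rng = np.random.default_rng() if rng is None else rng
    perm = rng.permutation(cohort.n)
    half = cohort.n // 2
    first = np.sort(perm[:half])
    second = np.sort(perm[half:])
    return cohort.take(first), cohort.take(second)
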