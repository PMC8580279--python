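"""Unit and property tests for the synthetic-cohort generator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrcovadj import (
    ConfigurationError,
    ScenarioConfig,
    assign_variant_groups,
    build_allele_score,
    draw_genotypes,
    simulate_cohort,
    split_samples,
)
from mrcovadj.scenarios import (
    CONFOUNDING_SETTINGS,
    GROUP_NULL,
    GROUP_R_ONLY,
    GROUP_W_ONLY,
    GROUP_X_AND_W,
    GROUP_X_ONLY,
    STRUCTURES,
    VARIANT_MODES,
)

from conftest import make_config


class TestScenarioConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"structure": "G"},
            {"confounding": 0},
            {"variant_mode": "mixed"},
            {"n_individuals": 99_999},
            {"n_individuals": -2},
            {"n_variants": 0},
            {"score_variance_fraction": 0.0},
            {"direct_effect_variance_fraction": 1.0},
            {"allele_freq_range": (0.0, 0.9)},
            {"allele_freq_range": (0.9, 0.1)},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        base = dict(structure="B", confounding=1)
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            ScenarioConfig(**base)

    @pytest.mark.parametrize("structure", STRUCTURES)
    @pytest.mark.parametrize("confounding", CONFOUNDING_SETTINGS)
    @pytest.mark.parametrize("variant_mode", VARIANT_MODES)
    @pytest.mark.parametrize("null", [True, False])
    def test_variance_budget_below_one_in_all_cells(
        self, structure, confounding, variant_mode, null
    ):
        """Summed variance fractions of every phenotype's direct causes < 1,
        enumerable over all 120 configuration cells."""
        config = ScenarioConfig(
            structure, confounding, variant_mode=variant_mode, beta_xy_null=null
        )
        for child, causes in config.direct_causes().items():
            assert sum(v for _, v in causes) < 1.0, child

    def test_oversized_variance_fraction_names_the_causes(self):
        with pytest.raises(ConfigurationError, match="U_XW"):
            ScenarioConfig("F", 5, direct_effect_variance_fraction=0.4)


class TestDrawGenotypes:
    def test_fixed_frequency_one_gives_all_homozygotes(self, rng):
        g, freqs = draw_genotypes(4, 1, rng=rng, freqs=1.0)
        assert np.all(g == 2)
        assert freqs[0] == 1.0

    def test_column_frequencies_within_sampling_error(self, rng):
        g, freqs = draw_genotypes(100_000, 40, (0.1, 0.9), rng)
        empirical = g.mean(axis=0) / 2
        assert np.all(empirical > 0.05) and np.all(empirical < 0.95)
        assert np.all(np.abs(empirical - freqs) < 0.01)
        assert set(np.unique(g)) <= {0, 1, 2}

    def test_seeded_determinism(self):
        g1, f1 = draw_genotypes(500, 10, rng=np.random.default_rng(9))
        g2, f2 = draw_genotypes(500, 10, rng=np.random.default_rng(9))
        assert np.array_equal(g1, g2) and np.array_equal(f1, f2)

    @pytest.mark.parametrize("n, m", [(0, 5), (5, 0), (-1, 5)])
    def test_non_positive_sizes_rejected(self, n, m, rng):
        with pytest.raises(ValueError):
            draw_genotypes(n, m, rng=rng)


class TestVariantGroups:
    @pytest.mark.parametrize(
        "structure, expected",
        [
            ("A", GROUP_W_ONLY),
            ("B", GROUP_X_AND_W),
            ("C", GROUP_X_ONLY),
            ("D", GROUP_R_ONLY),
            ("E", GROUP_X_AND_W),
            ("F", GROUP_R_ONLY),
        ],
    )
    def test_homogeneous_single_group_per_structure(self, structure, expected):
        groups = assign_variant_groups(make_config(structure))
        assert groups.labels == (expected,) * 40

    @pytest.mark.parametrize("structure", STRUCTURES)
    def test_heterogeneous_partition_covers_all_variants(self, structure):
        groups = assign_variant_groups(
            make_config(structure, variant_mode="heterogeneous")
        )
        assert groups.n_variants == 40
        for g in (GROUP_X_ONLY, GROUP_W_ONLY, GROUP_X_AND_W):
            assert len(groups.indices(g)) == 10
        # the fourth subgroup targets R only where the structure includes R
        fourth = GROUP_R_ONLY if structure in ("D", "F") else GROUP_NULL
        assert len(groups.indices(fourth)) == 10

    def test_heterogeneous_r_group_empty_without_r(self):
        groups = assign_variant_groups(make_config("C", variant_mode="heterogeneous"))
        assert len(groups.indices(GROUP_R_ONLY)) == 0

    def test_assignment_deterministic(self):
        cfg = make_config("D", variant_mode="heterogeneous")
        assert assign_variant_groups(cfg) == assign_variant_groups(cfg)


class TestAlleleScore:
    def test_single_variant_score_is_standardized_affine_transform(self, rng):
        g, _ = draw_genotypes(10_000, 1, (0.5, 0.5), rng)
        score = build_allele_score(g, np.array([0]))
        assert score.mean() == pytest.approx(0.0, abs=1e-12)
        assert score.var() == pytest.approx(1.0, rel=1e-10)
        assert abs(np.corrcoef(score, g[:, 0])[0, 1]) == pytest.approx(1.0)

    def test_multi_variant_score_unit_variance_positive_loadings(self, rng):
        g, _ = draw_genotypes(20_000, 5, (0.2, 0.8), rng)
        score = build_allele_score(g, np.arange(5))
        assert score.var() == pytest.approx(1.0, rel=1e-10)
        for j in range(5):
            assert np.corrcoef(score, g[:, j])[0, 1] > 0

    def test_empty_member_set_rejected(self, rng):
        g, _ = draw_genotypes(100, 3, rng=rng)
        with pytest.raises(ValueError):
            build_allele_score(g, np.array([], dtype=int))


class TestSimulateCohort:
    @pytest.mark.parametrize("structure", STRUCTURES)
    @pytest.mark.parametrize("confounding", CONFOUNDING_SETTINGS)
    @pytest.mark.parametrize("variant_mode", VARIANT_MODES)
    def test_all_cells_generate_with_expected_fields(
        self, structure, confounding, variant_mode
    ):
        """The generator's dependency order is acyclic in every cell: all 60
        structure x confounding x mode combinations build without reading an
        ungenerated variable, and carry exactly the fields the cell implies."""
        cfg = make_config(
            structure, confounding, variant_mode=variant_mode, n_individuals=500
        )
        cohort = simulate_cohort(cfg)
        assert cohort.genotypes.shape == (500, 40)
        assert (cohort.R is not None) == (structure in ("D", "F"))
        assert set(cohort.confounders) == set(cfg.confounders_present)

    @pytest.mark.parametrize("structure", STRUCTURES)
    @pytest.mark.parametrize("confounding", [1, 2, 3, 4])
    def test_unit_variance_phenotypes_at_scale(self, structure, confounding):
        """Whenever the systematic part stays below unit variance, residual
        noise tops every phenotype up to variance 1."""
        cohort = simulate_cohort(
            make_config(structure, confounding, n_individuals=20_000)
        )
        arrays = [cohort.X, cohort.Y, cohort.W]
        if cohort.R is not None:
            arrays.append(cohort.R)
        for arr in arrays:
            assert arr.var() == pytest.approx(1.0, rel=0.1)

    def test_correlated_causes_floor_residual_variance(self):
        """With all three confounders plus pleiotropy (F5), Y's positively
        correlated causes alone exceed unit variance; the generator floors
        the residual rather than shrinking the stated effect fractions, so
        var(Y) ends up above 1 while X and W stay calibrated."""
        cohort = simulate_cohort(make_config("F", 5, n_individuals=50_000))
        assert cohort.X.var() == pytest.approx(1.0, rel=0.1)
        assert cohort.W.var() == pytest.approx(1.0, rel=0.1)
        assert 1.0 < cohort.Y.var() < 1.6

    def test_score_explains_ten_percent_of_exposure(self):
        cohort = simulate_cohort(make_config("B", 1, n_individuals=100_000))
        score = build_allele_score(cohort.genotypes, cohort.groups.affecting("X"))
        r2 = np.corrcoef(score, cohort.X)[0, 1] ** 2
        assert r2 == pytest.approx(0.10, abs=0.01)

    def test_direct_cause_contributes_twenty_percent(self):
        """Marginal W->Y regression in the pleiotropy structure without
        confounders recovers the 20%-of-variance direct effect."""
        cohort = simulate_cohort(
            make_config("E", 1, beta_xy_null=True, n_individuals=100_000)
        )
        coef = np.cov(cohort.Y, cohort.W)[0, 1] / cohort.W.var()
        share = coef**2 * cohort.W.var() / cohort.Y.var()
        assert share == pytest.approx(0.20, abs=0.02)

    def test_null_path_no_exposure_outcome_correlation(self):
        """Structure B, no confounders, null effect: X and Y share no open
        path, so their sample correlation is at the sqrt(n) noise level."""
        cfg = make_config("B", 1, beta_xy_null=True, n_individuals=100_000)
        cohort = simulate_cohort(cfg)
        assert cohort.beta_xy_true == 0.0
        r = np.corrcoef(cohort.X, cohort.Y)[0, 1]
        assert abs(r) < 4 / np.sqrt(cohort.n)

    def test_full_mediation_blocks_score_given_covariable(self):
        """Structure A: W fully mediates Z->X, so the allele score has no
        partial association with X given W."""
        cohort = simulate_cohort(make_config("A", 1, n_individuals=100_000))
        score = build_allele_score(cohort.genotypes, cohort.groups.affecting("W"))
        # residualize score and X on W, then correlate
        w = cohort.W - cohort.W.mean()
        resid_s = score - (score @ w) / (w @ w) * w
        resid_x = cohort.X - (cohort.X @ w) / (w @ w) * w
        partial = np.corrcoef(resid_s, resid_x)[0, 1]
        assert abs(partial) < 4 / np.sqrt(cohort.n)

    def test_pleiotropy_structure_positive_marginal_w_effect(self):
        cohort = simulate_cohort(make_config("E", 1, n_individuals=50_000))
        slope = np.cov(cohort.Y, cohort.W)[0, 1] / cohort.W.var()
        assert slope > 0

    def test_true_effect_zero_exactly_under_null(self):
        assert simulate_cohort(
            make_config("B", 1, beta_xy_null=True, n_individuals=2_000)
        ).beta_xy_true == 0.0
        nonnull = simulate_cohort(make_config("B", 1, n_individuals=50_000))
        assert nonnull.beta_xy_true == pytest.approx(np.sqrt(0.2), rel=0.05)

    def test_seeded_reproducibility(self):
        cfg = make_config("D", 3, variant_mode="heterogeneous", n_individuals=2_000)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.genotypes, b.genotypes)
        for x, y in ((a.X, b.X), (a.Y, b.Y), (a.W, b.W), (a.R, b.R)):
            assert np.array_equal(x, y)


class TestSplitSamples:
    def test_halves_are_disjoint_and_exhaustive(self, small_config, rng):
        cohort = simulate_cohort(small_config)
        # tag rows through the split via a recognisable genotype matrix
        tagged = dataclasses.replace(
            cohort, genotypes=np.arange(cohort.n)[:, None] * np.ones((1, 40), int)
        )
        a, b = split_samples(tagged, rng)
        assert a.n == b.n == cohort.n // 2
        ids_a, ids_b = set(a.genotypes[:, 0]), set(b.genotypes[:, 0])
        assert ids_a.isdisjoint(ids_b)
        assert ids_a | ids_b == set(range(cohort.n))

    def test_odd_cohort_rejected(self, small_config, rng):
        cohort = simulate_cohort(small_config).take(np.arange(101))
        with pytest.raises(ValueError):
            split_samples(cohort, rng)

    def test_seeded_split_reproducible(self, small_config):
        cohort = simulate_cohort(small_config)
        a1, _ = split_samples(cohort, np.random.default_rng(5))
        a2, _ = split_samples(cohort, np.random.default_rng(5))
        assert np.array_equal(a1.X, a2.X)


@given(st.integers(0, 2**31 - 1))
def test_simulation_determinism_property(seed):
    """Identical config + seed give identical cohorts for arbitrary seeds."""
    cfg = ScenarioConfig("E", 2, n_individuals=200, n_variants=6, seed=seed)
    assert np.array_equal(simulate_cohort(cfg).Y, simulate_cohort(cfg).Y)
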