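"""Fitness regression, permutation correlation, reporter normalization."""

import numpy as np
import pytest

from ffltune import (
    CompetitionTimecourse,
    GeneTable,
    correlation_with_permutation,
    estimate_fitness,
    normalize_gfp,
)
from ffltune.errors import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedLogError,
    ValidationError,
)

GENS = np.array([0.0, 3.0, 6.0, 9.0, 12.0, 15.0])


def timecourse_from_ratio(ratio: np.ndarray, depth: float = 10_000.0):
    freq = ratio / (1 + ratio)
    return CompetitionTimecourse(
        generations=GENS, count_query=depth * freq, count_reference=depth * (1 - freq)
    )


class TestFitness:
    def test_constant_ratio_is_neutral(self):
        est = estimate_fitness(timecourse_from_ratio(np.full(6, 1 / 9)))
        assert est.s == pytest.approx(0.0, abs=1e-12)

    def test_exact_log_linear_recovery(self):
        est = estimate_fitness(timecourse_from_ratio(0.1 * np.exp(0.05 * GENS)))
        assert est.s == pytest.approx(0.05, abs=1e-12)
        assert est.ci_reported and est.n_points == 6

    def test_scaling_one_genotype_only_shifts_intercept(self):
        tc = timecourse_from_ratio(0.1 * np.exp(0.08 * GENS))
        scaled = CompetitionTimecourse(
            generations=tc.generations,
            count_query=tc.count_query * 7.5,
            count_reference=tc.count_reference,
        )
        a, b = estimate_fitness(tc), estimate_fitness(scaled)
        assert b.s == pytest.approx(a.s, abs=1e-12)
        assert b.intercept == pytest.approx(a.intercept + np.log(7.5))

    def test_swapping_genotypes_negates_s(self):
        tc = timecourse_from_ratio(0.1 * np.exp(0.08 * GENS))
        swapped = CompetitionTimecourse(
            generations=tc.generations,
            count_query=tc.count_reference,
            count_reference=tc.count_query,
        )
        assert estimate_fitness(swapped).s == pytest.approx(-estimate_fitness(tc).s)

    @pytest.mark.parametrize("n, reported", [(3, False), (4, False), (5, True), (6, True)])
    def test_ci_suppressed_below_five_points(self, n, reported):
        gens = GENS[:n]
        ratio = 0.1 * np.exp(0.05 * gens)
        freq = ratio / (1 + ratio)
        tc = CompetitionTimecourse(gens, 1e4 * freq, 1e4 * (1 - freq))
        assert estimate_fitness(tc).ci_reported is reported

    def test_zero_count_names_time_point(self):
        tc = CompetitionTimecourse(GENS, [9.0, 5.0, 0.0, 2.0, 1.0, 1.0], np.full(6, 10.0))
        with pytest.raises(UndefinedLogError, match="generation 6"):
            estimate_fitness(tc)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            CompetitionTimecourse([0.0, 5.0], [1.0, 2.0], [9.0, 8.0])

    def test_non_increasing_generations_rejected(self):
        with pytest.raises(ValidationError):
            CompetitionTimecourse([0.0, 5.0, 5.0], [1, 2, 3], [9, 8, 7])


def make_table(rng, n_genes=300, m=10, perfect=False):
    affinity = rng.standard_normal(n_genes)
    lfc = affinity if perfect else rng.standard_normal(n_genes)
    is_target = np.zeros(n_genes, bool)
    is_target[rng.choice(n_genes, m, replace=False)] = True
    return GeneTable(
        genes=[f"g{i}" for i in range(n_genes)],
        affinity=affinity,
        lfc=lfc,
        is_target=is_target,
    )


class TestPermutation:
    def test_perfect_monotone_relation_gives_add_one_floor(self, rng):
        table = make_table(rng, perfect=True)
        res = correlation_with_permutation(table, method="spearman", n_perm=99, seed=1)
        assert res.statistic_observed == pytest.approx(1.0)
        # background genes share the same perfect relation here, so every
        # null draw also reaches 1.0 and ties count toward the p-value
        assert res.p_value == 1.0

    def test_add_one_floor_when_null_never_reaches_observed(self, rng):
        # focal set perfectly monotone, background pure noise
        n, m = 300, 10
        affinity = rng.standard_normal(n)
        lfc = rng.standard_normal(n)
        is_target = np.zeros(n, bool)
        is_target[:m] = True
        lfc[:m] = np.exp(affinity[:m])  # monotone, nonlinear
        table = GeneTable([f"g{i}" for i in range(n)], affinity, lfc, is_target)
        res = correlation_with_permutation(table, method="spearman", n_perm=200, seed=2)
        assert res.statistic_observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_spearman_invariant_under_monotone_transforms(self, rng):
        table = make_table(rng, m=12)
        res1 = correlation_with_permutation(table, "spearman", n_perm=500, seed=7)
        table2 = GeneTable(
            genes=table.genes,
            affinity=np.exp(table.affinity),
            lfc=table.lfc**3,
            is_target=table.is_target,
        )
        res2 = correlation_with_permutation(table2, "spearman", n_perm=500, seed=7)
        assert res2.statistic_observed == pytest.approx(res1.statistic_observed)
        assert res2.p_value == res1.p_value

    def test_pearson_and_spearman_both_available(self, rng):
        table = make_table(rng)
        for method in ("pearson", "spearman"):
            res = correlation_with_permutation(table, method, n_perm=200, seed=3)
            assert res.method == method
            assert 0 < res.p_value <= 1
            assert res.null_stats.size == 200

    def test_more_permutations_agree_within_monte_carlo_error(self, rng):
        table = make_table(rng, n_genes=500, m=15)
        p1 = correlation_with_permutation(table, "spearman", n_perm=1000, seed=11).p_value
        p2 = correlation_with_permutation(table, "spearman", n_perm=10_000, seed=12).p_value
        se = np.sqrt(p2 * (1 - p2) / 1000)
        assert abs(p1 - p2) < 4 * se + 2e-3

    def test_two_sided_at_least_one_sided_for_positive_association(self, rng):
        # positive focal association: two-sided can only add mass
        n, m = 300, 12
        affinity = rng.standard_normal(n)
        lfc = rng.standard_normal(n)
        is_target = np.zeros(n, bool)
        is_target[:m] = True
        lfc[:m] = 0.8 * affinity[:m] + 0.2 * lfc[:m]
        table = GeneTable([f"g{i}" for i in range(n)], affinity, lfc, is_target)
        g = correlation_with_permutation(table, "spearman", 500, seed=5, alternative="greater")
        t = correlation_with_permutation(table, "spearman", 500, seed=5, alternative="two-sided")
        assert g.statistic_observed > 0
        assert t.p_value >= g.p_value - 1e-12

    def test_degenerate_focal_variance_rejected(self, rng):
        n = 50
        affinity = np.ones(n)
        lfc = rng.standard_normal(n)
        is_target = np.zeros(n, bool)
        is_target[:5] = True
        table = GeneTable([f"g{i}" for i in range(n)], affinity, lfc, is_target)
        with pytest.raises(DegenerateInputError):
            correlation_with_permutation(table, "spearman", 100, seed=0)

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValidationError):
            GeneTable(["a", "a", "b", "c"], np.arange(4.0), np.arange(4.0),
                      np.array([1, 1, 1, 0], bool))


class TestGFP:
    def test_example_values(self):
        res = normalize_gfp([1000.0, 50.0], [100.0, 50.0])
        np.testing.assert_allclose(res.values, [1.0, 0.0])
        assert res.n_dropped == 0

    def test_fsc_scaling_shifts_by_log10(self):
        gfp = np.array([10.0, 200.0, 3000.0])
        fsc = np.array([5.0, 80.0, 900.0])
        base = normalize_gfp(gfp, fsc).values
        shifted = normalize_gfp(gfp, fsc * 10).values
        np.testing.assert_allclose(shifted, base - 1.0)

    def test_nonpositive_gfp_dropped_with_count(self):
        res = normalize_gfp([100.0, 0.0, -5.0], [10.0, 10.0, 10.0])
        assert res.n_dropped == 2
        assert res.values.size == 1

    def test_nonpositive_fsc_rejected(self):
        with pytest.raises(ValidationError):
            normalize_gfp([10.0, 10.0], [5.0, 0.0])
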