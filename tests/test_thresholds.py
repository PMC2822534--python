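"""KS statistic, adaptive threshold sweep, tiering and Cohen's kappa."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from mirsieve import (
    CountTable,
    adaptive_threshold,
    assign_tiers,
    cohens_kappa,
    count_distribution,
    ks_two_sample,
    three_phase_summary,
    tier_venn,
)
from mirsieve.errors import ConfigurationError, DataError
from mirsieve.thresholds import CountDistribution, _select_threshold


def dist(counts):
    return CountDistribution(counts=np.array(counts, dtype=np.int64))


def ks_oracle(a, b):
    """Brute-force merged-support ECDF scan, independent of the implementation."""
    support = sorted(set(a) | set(b))
    gap = 0.0
    for x in support:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        gap = max(gap, abs(fa - fb))
    return gap


class TestKSTwoSample:
    def test_identical_samples_give_zero(self):
        assert ks_two_sample(dist([1, 5, 9]), dist([1, 5, 9])) == 0.0

    def test_disjoint_supports_give_one(self):
        assert ks_two_sample(dist([1, 1, 1]), dist([100, 100])) == 1.0

    def test_shifted_quartet(self):
        assert ks_two_sample(dist([1, 2, 3, 4]), dist([2, 3, 4, 5])) == 0.25

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            ks_two_sample(dist([]), dist([1]))

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.lists(st.integers(1, 40), min_size=1, max_size=30),
        b=st.lists(st.integers(1, 40), min_size=1, max_size=30),
    )
    def test_matches_oracle_and_scipy_and_symmetry(self, a, b):
        d = ks_two_sample(dist(a), dist(b))
        assert d == pytest.approx(ks_oracle(a, b), abs=1e-12)
        assert d == pytest.approx(scipy.stats.ks_2samp(a, b).statistic, abs=1e-12)
        assert d == ks_two_sample(dist(b), dist(a))

    @settings(max_examples=50, deadline=None)
    @given(a=st.lists(st.integers(1, 20), min_size=1, max_size=20))
    def test_zero_iff_identical_ecdf(self, a):
        assert ks_two_sample(dist(a), dist(a * 2)) == 0.0  # same ECDF, doubled sizes


class TestSelectThreshold:
    def test_monotone_decreasing_returns_smallest_argmin(self):
        t = np.arange(1, 6)
        D = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        assert _select_threshold(t, D) == 5

    def test_constant_curve_returns_first_threshold(self):
        assert _select_threshold(np.arange(3, 8), np.zeros(5)) == 3

    def test_interior_minimum_found_at_first_reach(self):
        t = np.arange(1, 8)
        D = np.array([0.5, 0.3, 0.1, 0.102, 0.3, 0.4, 0.5])
        assert _select_threshold(t, D) == 3

    def test_converged_plateau_resolved_to_its_start(self):
        # micro-jitter inside the converged tail must not postpone selection
        t = np.arange(1, 9)
        D = np.array([0.5, 0.4, 0.2, 0.007, 0.007, 0.0068, 0.007, 0.007])
        assert _select_threshold(t, D) == 4


class TestAdaptiveThreshold:
    def test_identical_replicates_select_t_min(self):
        d = dist([1, 2, 4, 8, 16, 32])
        result = adaptive_threshold(d, d, t_min=1, t_max=16)
        assert np.all(result.D == 0)
        assert result.selected_threshold == 1

    def test_sweep_matches_brute_force_recomputation(self, rng):
        a = dist(rng.integers(1, 50, 60))
        b = dist(rng.integers(1, 50, 55))
        result = adaptive_threshold(a, b, t_min=1, t_max=40)
        for t, d in zip(result.thresholds, result.D):
            ra = [v for v in a.counts if v >= t]
            rb = [v for v in b.counts if v >= t]
            assert d == pytest.approx(ks_oracle(ra, rb), abs=1e-12)

    def test_n_retained_non_increasing(self, rng):
        a = dist(rng.integers(1, 100, 80))
        b = dist(rng.integers(1, 100, 80))
        result = adaptive_threshold(a, b)
        assert np.all(np.diff(result.n_retained[:, 0]) <= 0)
        assert np.all(np.diff(result.n_retained[:, 1]) <= 0)

    def test_symmetry_under_replicate_relabeling(self, rng):
        a = dist(rng.integers(1, 60, 70))
        b = dist(rng.geometric(0.2, 70))
        r_ab = adaptive_threshold(a, b, t_max=40)
        r_ba = adaptive_threshold(b, a, t_max=40)
        assert np.array_equal(r_ab.D, r_ba.D)
        assert r_ab.selected_threshold == r_ba.selected_threshold

    def test_invariance_under_shared_monotone_transform(self, rng):
        a = np.sort(rng.integers(1, 40, 50))
        b = np.sort(rng.integers(1, 40, 50))
        plain = adaptive_threshold(dist(a), dist(b), t_max=30)
        squared = adaptive_threshold(dist(a**2), dist(b**2), t_max=900)
        t_plain = plain.selected_threshold
        t_sq = squared.selected_threshold
        # the retained tag sets at the selected thresholds are identical
        assert {int(v) for v in a if v >= t_plain} == {
            int(np.sqrt(v)) for v in a**2 if v >= t_sq
        }
        assert np.isclose(plain.D.min(), squared.D.min())

    def test_too_few_tags_at_t_min_rejected(self):
        with pytest.raises(DataError):
            adaptive_threshold(dist([1]), dist([1, 2]), t_min=1, t_max=5)

    def test_inverted_range_rejected(self):
        d = dist([1, 2, 3, 4])
        with pytest.raises(ConfigurationError):
            adaptive_threshold(d, d, t_min=5, t_max=2)


class TestTiers:
    @pytest.mark.parametrize(
        "count,tier",
        [(1, "Low"), (31, "Low"), (32, "Mid"), (10_000, "Mid"), (10_001, "High")],
    )
    def test_boundary_placement(self, count, tier):
        table = CountTable(samples=["s"], counts={"AAAA": {"s": count}})
        assert assign_tiers(table).tiers["s"]["AAAA"] == tier

    def test_bundled_intracellular_all_high(self, intracellular):
        partition = assign_tiers(intracellular)
        for sample in intracellular.samples:
            assert set(partition.tiers[sample].values()) == {"High"}
        assert partition.tiers["IC1"]["TGAGGTAGTAGATTGTATAGTT"] == "High"

    def test_bundled_extracellular_has_no_high(self, extracellular):
        partition = assign_tiers(extracellular)
        for sample in extracellular.samples:
            assert "High" not in partition.tiers[sample].values()

    def test_venn_on_identical_partitions(self, intracellular):
        partition = assign_tiers(intracellular)
        result = tier_venn(partition, "IC1", "IC2", "High")
        assert (result.set_a_size, result.set_b_size, result.intersection_size) == (
            16, 16, 16,
        )

    def test_venn_disjoint_tiers(self):
        table = CountTable(
            samples=["a", "b"], counts={"T1": {"a": 5, "b": 500}, "T2": {"a": 500, "b": 5}}
        )
        partition = assign_tiers(table)
        assert tier_venn(partition, "a", "b", "Low").intersection_size == 0

    def test_unknown_tier_rejected(self, intracellular):
        partition = assign_tiers(intracellular)
        with pytest.raises(ConfigurationError):
            tier_venn(partition, "IC1", "IC2", "Extreme")


class TestCohensKappa:
    def test_perfect_agreement(self):
        universe = {f"t{i}" for i in range(100)}
        half = {f"t{i}" for i in range(50)}
        assert cohens_kappa(half, half, universe) == 1.0

    def test_worked_two_by_two_table(self):
        universe = {f"t{i}" for i in range(100)}
        a = {f"t{i}" for i in range(50)}
        b = {f"t{i}" for i in range(40)} | {f"t{i}" for i in range(50, 60)}
        # |A|=|B|=50, |A∩B|=40 -> p_o=0.8, p_e=0.5, kappa=0.6
        assert cohens_kappa(a, b, universe) == pytest.approx(0.6)

    def test_random_sets_have_near_zero_expected_kappa(self, rng):
        universe = [f"t{i}" for i in range(60)]
        a = set(universe[:30])
        kappas = []
        for _ in range(300):
            b = set(rng.choice(universe, 30, replace=False))
            kappas.append(cohens_kappa(a, b, universe))
        assert abs(np.mean(kappas)) < 0.05

    def test_set_outside_universe_rejected(self):
        with pytest.raises(DataError):
            cohens_kappa({"x"}, set(), {"a", "b"})

    def test_matches_closed_form_exhaustively_on_small_universes(self):
        """Enumerate every 2x2 configuration (n11,n10,n01,n00) up to |U|=8."""
        for n in range(1, 9):
            universe = [f"u{i}" for i in range(n)]
            for n11, n10, n01 in itertools.product(range(n + 1), repeat=3):
                n00 = n - n11 - n10 - n01
                if n00 < 0:
                    continue
                a = set(universe[: n11 + n10])
                b = set(universe[:n11]) | set(universe[n11 + n10 : n11 + n10 + n01])
                p_o = (n11 + n00) / n
                pa, pb = (n11 + n10) / n, (n11 + n01) / n
                p_e = pa * pb + (1 - pa) * (1 - pb)
                expected = 1.0 if p_e == 1 else (p_o - p_e) / (1 - p_e)
                assert cohens_kappa(a, b, universe) == pytest.approx(expected)


class TestKappaPermutation:
    def test_strong_agreement_is_significant(self):
        from mirsieve import kappa_permutation_pvalue

        universe = [f"t{i}" for i in range(40)]
        a = set(universe[:20])
        b = set(universe[:18]) | {universe[25], universe[26]}
        p = kappa_permutation_pvalue(a, b, universe, n_permutations=400, seed=1)
        assert p < 0.01

    def test_random_set_is_not_significant(self, rng):
        from mirsieve import kappa_permutation_pvalue

        universe = [f"t{i}" for i in range(40)]
        a = set(universe[:20])
        b = set(rng.choice(universe, 20, replace=False))
        p = kappa_permutation_pvalue(a, b, universe, n_permutations=400, seed=1)
        assert p > 0.05


class TestCpmScale:
    def test_scaling_preserves_order_and_floors_at_one(self):
        from mirsieve import cpm_scale

        scaled = cpm_scale(np.array([1, 10, 10**7]))
        assert scaled[0] >= 1
        assert list(scaled) == sorted(scaled)
        assert scaled.sum() == pytest.approx(1e6, rel=0.01)


class TestDistributionAndPhases:
    def test_distribution_members_and_ecdf_steps(self):
        table = CountTable(
            samples=["s"],
            counts={t: {"s": c} for t, c in zip("abcd", (1, 1, 2, 4))},
        )
        d = count_distribution(table, "s")
        assert len(d) == 4
        xs, fracs = d.ecdf()
        assert list(xs) == [0.0, 1.0, 2.0]
        assert list(fracs) == [0.5, 0.75, 1.0]

    def test_bundled_extracellular_sample1(self, extracellular):
        d = count_distribution(extracellular, "EC1")
        assert len(d) == 20
        assert d.counts.max() == 826

    def test_all_below_threshold_is_pure_phase_one(self):
        summary = three_phase_summary(dist([1, 2, 3]), 32, 10_000)
        assert summary["Low"]["mass_fraction"] == 1.0
        assert summary["Mid"]["n_tags"] == summary["High"]["n_tags"] == 0

    def test_bundled_intracellular_all_phase_three(self, intracellular):
        summary = three_phase_summary(count_distribution(intracellular, "IC1"), 32, 10_000)
        assert summary["High"]["n_tags"] == 16
        assert summary["High"]["mass_fraction"] == 1.0

    def test_mass_fractions_sum_to_one(self, rng):
        summary = three_phase_summary(dist(rng.integers(1, 10**5, 200)), 32, 10_000)
        assert sum(v["mass_fraction"] for v in summary.values()) == pytest.approx(1.0)
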