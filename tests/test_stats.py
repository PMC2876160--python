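import numpy as np
import pytest
from scipy import stats as sps

from funcdiv.stats import (
    StatsError,
    omega_histogram,
    one_way_anova,
    pearson_correlation,
    studentized_range_cdf,
    studentized_range_ppf,
    studentized_range_sf,
    tukey_hsd,
    two_way_anova,
)


class TestStudentizedRange:
    @pytest.mark.parametrize(
        "q,k,df", [(2.0, 3, 10), (3.5, 3, 10), (4.0, 20, 380), (5.2, 6, 114), (6.0, 3, 4)]
    )
    def test_sf_matches_scipy_numerics(self, q, k, df):
        ref = sps.studentized_range.sf(q, k, df)
        assert studentized_range_sf(np.array([q]), k, df).item() == pytest.approx(
            ref, abs=1e-4
        )

    def test_ppf_inverts_cdf(self):
        q = studentized_range_ppf(0.95, 5, 40)
        assert studentized_range_cdf(np.array([q]), 5, 40).item() == pytest.approx(
            0.95, abs=1e-6
        )
        assert q == pytest.approx(sps.studentized_range.ppf(0.95, 5, 40), abs=1e-3)


class TestOneWayAnova:
    def test_hand_computed_two_group_example(self):
        table = one_way_anova([0, 2, 2, 4], ["a", "a", "b", "b"])
        assert table.row("Groups").ss == pytest.approx(4.0)
        assert table.row("Error").ss == pytest.approx(4.0)
        assert table.row("Groups").df == 1 and table.row("Error").df == 2
        assert table.f == pytest.approx(2.0)

    def test_identical_groups_give_zero_f(self):
        table = one_way_anova([0, 2, 0, 2], ["a", "a", "b", "b"])
        assert table.row("Groups").ss == pytest.approx(0.0)
        assert table.f == pytest.approx(0.0)

    def test_single_group_fails(self):
        with pytest.raises(StatsError):
            one_way_anova([1, 2, 3], ["a", "a", "a"])

    def test_zero_within_variance_unequal_means(self):
        table = one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert np.isinf(table.f) and table.p == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_additivity_and_scipy_agreement(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=60)
        labels = rng.integers(0, 4, size=60)
        table = one_way_anova(values, labels)
        assert table.row("Total").ss == pytest.approx(
            table.row("Groups").ss + table.row("Error").ss, rel=1e-9
        )
        assert table.row("Total").df == table.row("Groups").df + table.row("Error").df
        f_ref, p_ref = sps.f_oneway(*(values[labels == k] for k in range(4)))
        assert table.f == pytest.approx(f_ref) and table.p == pytest.approx(p_ref)

    def test_f_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=15), rng.normal(0.4, size=12)
        table = one_way_anova(np.concatenate([a, b]), ["a"] * 15 + ["b"] * 12)
        t_ref, _ = sps.ttest_ind(a, b)
        assert table.f == pytest.approx(t_ref**2, rel=1e-9)


class TestTukey:
    def test_all_equal_observations_no_significance(self):
        res = tukey_hsd([1.0] * 12, ["a", "b", "c"] * 4)
        assert res.significant_pairs() == []
        assert all(d == 0.0 for d, _, _ in res.diffs.values())

    def test_textbook_balanced_case_matches_scipy(self):
        # three balanced groups; compare q_crit and adjusted p with scipy's
        # studentized-range numerics and its tukey_hsd implementation
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, size=10) for m in (0.0, 0.5, 2.0)]
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 10)
        res = tukey_hsd(values, labels, alpha=0.05)
        assert res.q_crit == pytest.approx(
            sps.studentized_range.ppf(0.95, 3, 27), abs=1e-3
        )
        ref = sps.tukey_hsd(*groups)
        for (i, gi), (j, gj) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")), ((1, "b"), (2, "c"))]:
            assert res.diffs[(gi, gj)][1] == pytest.approx(
                ref.pvalue[i, j], abs=1e-4
            )

    def test_flags_iff_difference_interval_excludes_zero(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(m, 1, 8) for m in (0, 0.5, 3)])
        labels = np.repeat(["a", "b", "c"], 8)
        res = tukey_hsd(values, labels)
        mse = one_way_anova(values, labels).row("Error").ms
        for (g1, g2), (diff, p, sig) in res.diffs.items():
            n1 = res.ns[res.groups.index(g1)]
            n2 = res.ns[res.groups.index(g2)]
            se = np.sqrt(mse / 2 * (1 / n1 + 1 / n2))
            excludes_zero = abs(diff) > res.q_crit * se
            assert sig == excludes_zero == (p < res.alpha)

    def test_planted_extreme_group_flagged_against_all(self):
        rng = np.random.default_rng(2)
        values = []
        labels = []
        for g in range(6):
            shift = 5.0 if g == 5 else 0.0
            values.extend(rng.normal(shift, 1.0, size=20))
            labels.extend([f"g{g}"] * 20)
        res = tukey_hsd(np.array(values), np.array(labels))
        assert "g5" in res.extreme_groups()

    def test_fewer_than_two_groups_fails(self):
        with pytest.raises(StatsError):
            tukey_hsd([1, 2, 3], ["a", "a", "a"])


class TestTwoWayAnova:
    def test_balanced_design_matches_closed_form(self):
        # 2x2 balanced additive data: SS_A = n*b*sum(a_i - mean)^2 etc.
        values, groups, copies = [], [], []
        effects_a = {"g1": -1.0, "g2": 1.0}
        effects_b = {"single": -0.5, "multiple": 0.5}
        for g in effects_a:
            for c in effects_b:
                for _ in range(5):
                    values.append(10 + effects_a[g] + effects_b[c])
                    groups.append(g)
                    copies.append(c)
        table = two_way_anova(values, groups, copies)
        assert table.row("Groups").ss == pytest.approx(10 * (1.0**2) * 2, rel=1e-9)
        assert table.row("CopyNumber").ss == pytest.approx(10 * (0.5**2) * 2, rel=1e-9)
        assert table.row("Error").ss == pytest.approx(0.0, abs=1e-18)

    def test_constant_factor_fails(self):
        with pytest.raises(StatsError):
            two_way_anova([1, 2, 3, 4], ["a", "a", "b", "b"], ["s", "s", "s", "s"])

    def test_copy_effect_only_monte_carlo(self):
        rng = np.random.default_rng(3)
        p_groups, p_copy = [], []
        for _ in range(100)  :
            groups = rng.integers(0, 4, size=80)
            copies = rng.integers(0, 2, size=80)
            values = rng.normal(size=80) + 1.5 * copies
            t = two_way_anova(values, groups.astype(str), np.where(copies, "multiple", "single"))
            p_groups.append(t.row("Groups").p)
            p_copy.append(t.row("CopyNumber").p)
        assert np.median(p_copy) < 1e-6
        # group factor p should look uniform under its null
        assert 0.25 < np.mean(np.array(p_groups) < 0.5) < 0.75


class TestCorrelationAndHistogram:
    def test_perfect_linear_relation(self):
        res = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_r(self):
        res = pearson_correlation([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5)

    def test_zero_variance_fails(self):
        with pytest.raises(StatsError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_permutation_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        ps = []
        for _ in range(300):
            ps.append(pearson_correlation(x, rng.permutation(x)).p)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.001

    def test_histogram_counts_and_boundary(self):
        h = omega_histogram([0.05, 0.15, 0.15], bin_width=0.1)
        assert list(h.counts) == [1, 2]
        h2 = omega_histogram([0.1], bin_width=0.1)
        assert list(h2.counts) == [0, 1]  # boundary lands in the second bin

    def test_fraction_below(self):
        h = omega_histogram([0.1, 0.2, 0.4, 0.6], bin_width=0.1)
        assert h.fraction_below(0.3) == pytest.approx(0.5)
        assert h.counts.sum() == 4

    def test_empty_and_negative_fail(self):
        with pytest.raises(StatsError):
            omega_histogram([])
        with pytest.raises(StatsError):
            omega_histogram([-0.1, 0.2])
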