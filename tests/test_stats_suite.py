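"""Statistical battery vs independent brute-force oracles and known results."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lactoshelf._util import DegenerateInputError, InvalidArgumentError, ValidationError
from lactoshelf.stats_suite import (
    anova,
    chi_square_test,
    normality_gate,
    one_way_anova,
    repeated_measures_anova,
    tukey_hsd,
    two_way_anova,
    variance_homogeneity,
)


# ---------------------------------------------------------------------------
# brute-force oracles (explicit summations, independent of the implementation)
# ---------------------------------------------------------------------------

def brute_one_way(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = 0.0
    for g in groups:
        ssb += len(g) * (np.mean(g) - grand) ** 2
    ssw = 0.0
    for g in groups:
        for x in g:
            ssw += (x - np.mean(g)) ** 2
    df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / df_b) / (ssw / df_w), ssb, ssw


def brute_two_way(y, a_labels, b_labels):
    """Balanced two-factor cell-mean decomposition with interaction."""
    a_levels, b_levels = sorted(set(a_labels)), sorted(set(b_labels))
    grand = np.mean(y)
    cell = {}
    for av in a_levels:
        for bv in b_levels:
            cell[av, bv] = np.mean(
                [v for v, a, b in zip(y, a_labels, b_labels) if a == av and b == bv]
            )
    n_cell = len(y) / (len(a_levels) * len(b_levels))
    mean_a = {av: np.mean([v for v, a in zip(y, a_labels) if a == av]) for av in a_levels}
    mean_b = {bv: np.mean([v for v, b in zip(y, b_labels) if b == bv]) for bv in b_levels}
    ss_a = n_cell * len(b_levels) * sum((mean_a[av] - grand) ** 2 for av in a_levels)
    ss_b = n_cell * len(a_levels) * sum((mean_b[bv] - grand) ** 2 for bv in b_levels)
    ss_ab = n_cell * sum(
        (cell[av, bv] - mean_a[av] - mean_b[bv] + grand) ** 2
        for av in a_levels for bv in b_levels
    )
    ss_err = sum(
        (v - cell[a, b]) ** 2 for v, a, b in zip(y, a_labels, b_labels)
    )
    return ss_a, ss_b, ss_ab, ss_err


def brute_chi2(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestOneWay:
    def test_hand_computed_example(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        term = res.terms["group"]
        assert term["F"] == pytest.approx(3.0)
        assert (term["df"], res.residual["df"]) == (2, 6)
        assert term["ss"] == pytest.approx(6.0)
        assert res.residual["ss"] == pytest.approx(6.0)

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.terms["group"]["F"] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.normal(0, 2), 1, rng.integers(3, 8))
                      for _ in range(k)]
            res = one_way_anova(groups)
            f_ref, ssb, ssw = brute_one_way(groups)
            assert res.terms["group"]["F"] == pytest.approx(f_ref, rel=1e-10)
            assert res.terms["group"]["ss"] == pytest.approx(ssb, rel=1e-10)
            assert res.total_ss == pytest.approx(ssb + ssw, rel=1e-10)
            # independent route through scipy
            f_sp, p_sp = sps.f_oneway(*groups)
            assert res.terms["group"]["F"] == pytest.approx(f_sp, rel=1e-10)
            assert res.terms["group"]["p"] == pytest.approx(p_sp, rel=1e-9)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(3, 10))
            b = rng.normal(0.5, 1, rng.integers(3, 10))
            res = one_way_anova([a, b])
            t, _ = sps.ttest_ind(a, b, equal_var=True)
            assert res.terms["group"]["F"] == pytest.approx(t**2, rel=1e-10)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 6) for _ in range(3)]
        shifted = [g + 1234.5 for g in groups]
        f1 = one_way_anova(groups).terms["group"]["F"]
        f2 = one_way_anova(shifted).terms["group"]["F"]
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_type_i_error_under_null(self):
        """Rejection rate at alpha=0.05 within 5%±2% over 2000 null sims."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 6) for _ in range(3)]
            if one_way_anova(groups).terms["group"]["p"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestTwoWay:
    def _balanced(self, seed=0, reps=3):
        rng = np.random.default_rng(seed)
        rows = []
        for a in ("t1", "t2", "t3"):
            for b in ("c1", "c2"):
                for _ in range(reps):
                    rows.append({"treatment": a, "conc": b,
                                 "y": rng.normal(hash(a) % 3, 1)})
        return pd.DataFrame(rows)

    def test_matches_brute_force_decomposition(self):
        for seed in range(20):
            df = self._balanced(seed)
            res = two_way_anova(df, "y", "treatment", "conc")
            ss_a, ss_b, ss_ab, ss_err = brute_two_way(
                df.y.to_numpy(), df.treatment.tolist(), df.conc.tolist()
            )
            assert res.terms["treatment"]["ss"] == pytest.approx(ss_a, rel=1e-8)
            assert res.terms["conc"]["ss"] == pytest.approx(ss_b, rel=1e-8)
            assert res.terms["treatment:conc"]["ss"] == pytest.approx(ss_ab, rel=1e-8)
            assert res.residual["ss"] == pytest.approx(ss_err, rel=1e-8)

    def test_ss_decomposition_sums_to_total(self):
        df = self._balanced(5)
        res = two_way_anova(df, "y", "treatment", "conc")
        total = ((df.y - df.y.mean()) ** 2).sum()
        parts = sum(t["ss"] for t in res.terms.values()) + res.residual["ss"]
        assert parts == pytest.approx(total, rel=1e-8)

    def test_unbalanced_rejected(self):
        df = self._balanced(1)
        with pytest.raises(ValidationError):
            two_way_anova(df.iloc[:-1], "y", "treatment", "conc")

    def test_single_rep_interaction_rejected(self):
        df = self._balanced(1, reps=1)
        with pytest.raises(ValidationError):
            two_way_anova(df, "y", "treatment", "conc")


class TestRepeatedMeasures:
    def _blocks(self, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(6):
            base = rng.normal(0, 2)
            for i, t in enumerate(("m0", "m1", "m3", "m6")):
                rows.append({"subject": f"S{s}", "time": t,
                             "y": base + effect * i + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        df = self._blocks(4, effect=0.8)
        res = repeated_measures_anova(df, "y", within="time", subject="subject")
        ref = AnovaRM(df, "y", "subject", within=["time"]).fit()
        assert res.terms["time"]["F"] == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-8
        )
        assert res.terms["time"]["p"] == pytest.approx(
            float(ref.anova_table["Pr > F"].iloc[0]), rel=1e-6
        )

    def test_incomplete_block_rejected(self):
        df = self._blocks(1)
        with pytest.raises(ValidationError):
            repeated_measures_anova(df.iloc[:-1], "y", within="time", subject="subject")

    def test_dispatch(self):
        df = self._blocks(2)
        res = anova(df, design="repeated_measures", response="y",
                    within="time", subject="subject")
        assert res.design == "repeated_measures"
        with pytest.raises(InvalidArgumentError):
            anova([], design="three_way")


class TestTukey:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        out = tukey_hsd({"a": g, "b": g, "c": g})
        assert len(out) == 3
        assert all(p.p_adjusted == pytest.approx(1.0, abs=1e-9) for p in out)
        assert not any(p.significant for p in out)

    def test_pair_count(self):
        rng = np.random.default_rng(0)
        out = tukey_hsd({k: rng.normal(0, 1, 5) for k in "abcd"})
        assert len(out) == 6

    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(1)
        groups = {lab: rng.normal(mu, 0.1, 5) for lab, mu in
                  zip("abc", (0.0, 10.0, 20.0))}
        out = tukey_hsd(groups)
        assert all(p.significant for p in out)
        ab = next(p for p in out if {p.group_a, p.group_b} == {"a", "b"})
        assert ab.mean_difference == pytest.approx(-10.0, abs=0.2)

    def test_small_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestVarianceHomogeneity:
    def test_brute_force_bartlett(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            groups = [rng.normal(0, rng.uniform(0.5, 2), rng.integers(4, 9))
                      for _ in range(3)]
            stat, p = variance_homogeneity(groups, "bartlett")
            # explicit Bartlett chi-square formula
            k = len(groups)
            n_i = np.array([len(g) for g in groups])
            s2 = np.array([np.var(g, ddof=1) for g in groups])
            n = n_i.sum()
            sp2 = ((n_i - 1) * s2).sum() / (n - k)
            num = (n - k) * np.log(sp2) - ((n_i - 1) * np.log(s2)).sum()
            c = 1 + (np.sum(1 / (n_i - 1)) - 1 / (n - k)) / (3 * (k - 1))
            assert stat == pytest.approx(num / c, rel=1e-9)
            assert p == pytest.approx(sps.chi2.sf(num / c, k - 1), rel=1e-9)

    def test_brown_forsythe_is_median_centred_levene(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, s, 12) for s in (1.0, 1.5, 2.0)]
        stat, p = variance_homogeneity(groups, "brown_forsythe")
        # oracle: one-way ANOVA of absolute deviations from group medians
        devs = [np.abs(g - np.median(g)) for g in groups]
        f_ref, _, _ = brute_one_way(devs)
        assert stat == pytest.approx(f_ref, rel=1e-9)

    def test_identical_groups_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        for method in ("bartlett", "brown_forsythe"):
            _, p = variance_homogeneity([g, list(g)], method)
            assert p == pytest.approx(1.0, abs=1e-9)

    def test_power_against_inflated_variance(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 30), rng.normal(0, 10, 30)]
        for method in ("bartlett", "brown_forsythe"):
            _, p = variance_homogeneity(groups, method)
            assert p < 0.001

    @pytest.mark.parametrize("method", ["bartlett", "brown_forsythe"])
    def test_type_i_error_under_null(self, method):
        """Rejection rate at alpha=0.05 within 5%±2% over 1000 null sims.

        Groups of 20: the median-centred Brown-Forsythe statistic is
        conservative at small n and only approaches nominal size with
        moderate group sizes.
        """
        rng = np.random.default_rng(5)
        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 20) for _ in range(3)]
            if variance_homogeneity(groups, method)[1] < 0.05:
                rej += 1
        assert 0.03 <= rej / n_sim <= 0.07

    def test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            variance_homogeneity([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], "bartlett")


class TestNormalityGate:
    def test_symmetric_sample_has_zero_skew(self):
        rep = normality_gate([-2, -1, 0, 1, 2])
        assert rep.skewness == pytest.approx(0.0, abs=1e-12)
        assert rep.normal_pass

    def test_large_normal_sample_passes(self):
        rng = np.random.default_rng(6)
        rep = normality_gate(rng.normal(0, 1, 100_000))
        assert abs(rep.skewness) <= 0.05
        assert abs(rep.excess_kurtosis) <= 0.1
        assert rep.normal_pass

    def test_exponential_sample_fails_on_skew(self):
        rng = np.random.default_rng(7)
        rep = normality_gate(rng.exponential(1.0, 10_000))
        assert rep.skewness == pytest.approx(2.0, abs=0.25)
        assert not rep.normal_pass

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            normality_gate([1.0, 2.0, 3.0])

    def test_attaches_variance_tests(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 10) for _ in range(2)]
        resid = np.concatenate([g - g.mean() for g in groups])
        rep = normality_gate(resid, groups=groups)
        assert set(rep.variance_tests) == {"bartlett", "brown_forsythe"}


class TestChiSquare:
    def test_hand_computed_example(self):
        stat, df, p = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, rel=1e-9)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(20 / 3, 1), rel=1e-9)

    def test_independent_table_statistic_zero(self):
        margins_r, margins_c = np.array([0.3, 0.7]), np.array([0.2, 0.5, 0.3])
        table = 1000 * np.outer(margins_r, margins_c)
        stat, df, _ = chi_square_test(table)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 2

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            shape = (rng.integers(2, 4), rng.integers(2, 4))
            table = rng.integers(1, 60, shape)
            stat, df, _ = chi_square_test(table)
            assert stat == pytest.approx(brute_chi2(table), rel=1e-9)
            assert df == (shape[0] - 1) * (shape[1] - 1)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(10)
        table = rng.integers(1, 50, (3, 4))
        assert chi_square_test(table)[0] == pytest.approx(
            chi_square_test(table.T)[0], rel=1e-12
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi_square_test([[0, 0], [5, 10]])
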