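"""Inferential layer: ANOVAs, post-hocs, Spearman, mediation, power
solver, chi-square and exclusion accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oxytouch.stats import (
    PowerSpec,
    anova_power,
    anova_sample_size,
    bonferroni_adjust,
    bonferroni_pairwise,
    chi_square_independence,
    exclusion_accounting,
    mediate,
    mixed_anova,
    one_way_anova,
    spearman_rho,
)


class TestOneWayAnova:
    def test_degrees_of_freedom_at_study_size(self, rng):
        y = rng.normal(size=171)
        labels = ["in"] * 56 + ["or"] * 57 + ["plc"] * 58
        t = one_way_anova(y, labels)
        assert (t.loc[0, "df1"], t.loc[0, "df2"]) == (2, 168)

    def test_equal_means_give_zero_f(self):
        y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]  # identical group means
        t = one_way_anova(y, ["a"] * 3 + ["b"] * 3)
        assert t.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)
        assert t.loc[0, "partial_eta_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_sums_of_squares(self):
        y = np.array([3.0, 4, 5, 6, 2, 2, 3, 3, 7, 8, 9, 10])
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        t = one_way_anova(y, labels)
        grand = y.mean()
        means = [y[:4].mean(), y[4:8].mean(), y[8:].mean()]
        ssb = 4 * sum((m - grand) ** 2 for m in means)
        ssw = sum(((y[4 * i : 4 * i + 4] - means[i]) ** 2).sum() for i in range(3))
        assert t.loc[0, "F"] == pytest.approx((ssb / 2) / (ssw / 9))
        assert t.loc[0, "partial_eta_sq"] == pytest.approx(ssb / (ssb + ssw))

    def test_matches_scipy(self, rng):
        y = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        t = one_way_anova(y, labels)
        F, p = sps.f_oneway(y[:10], y[10:20], y[20:])
        assert t.loc[0, "F"] == pytest.approx(F)
        assert t.loc[0, "p"] == pytest.approx(p)

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = rng.standard_normal(30)
            t = one_way_anova(y, np.repeat(["a", "b", "c"], 10))
            rejections += t.loc[0, "p"] < 0.05
        rate = rejections / n_rep
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < half + 1e-9


def _long(rows):
    return pd.DataFrame(rows, columns=["subj", "grp", "cond", "val"])


class TestMixedAnova:
    def test_between_df_at_study_size(self, rng):
        rows = []
        sid = 0
        for g, n in [("in", 56), ("or", 57), ("plc", 58)]:
            for _ in range(n):
                for c in ("massage", "touch"):
                    rows.append((f"s{sid}", g, c, rng.normal()))
                sid += 1
        t = mixed_anova(_long(rows), "val", "subj", "grp", "cond")
        between = t[t["effect"] == "grp"].iloc[0]
        assert (between["df1"], between["df2"]) == (2, 168)
        within = t[t["effect"] == "cond"].iloc[0]
        assert (within["df1"], within["df2"]) == (1, 168)

    def test_constant_within_cells_give_zero_within_f(self, rng):
        rows = []
        for sid in range(9):
            g = ["a", "b", "c"][sid % 3]
            base = rng.normal()
            for c in ("x", "y"):
                rows.append((f"s{sid}", g, c, base))  # no condition effect at all
        t = mixed_anova(_long(rows), "val", "subj", "grp", "cond")
        assert t[t["effect"] == "cond"].iloc[0]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_cell_mean_decomposition(self):
        """3 groups x 2 conditions x 3 subjects/group against an explicit
        hand computation from cell totals."""
        rng = np.random.default_rng(3)
        rows = []
        for sid in range(9):
            g = ["a", "b", "c"][sid // 3]
            for c in ("x", "y"):
                rows.append((f"s{sid}", g, c, rng.normal()))
        df = _long(rows)
        t = mixed_anova(df, "val", "subj", "grp", "cond")

        y = df.pivot_table(index="subj", columns="cond", values="val")
        groups = df.groupby("subj")["grp"].first()
        grand = y.to_numpy().mean()
        subj_means = y.mean(axis=1)
        grp_means = subj_means.groupby(groups).mean()
        ss_g = 2 * sum(3 * (grp_means[g] - grand) ** 2 for g in "abc")
        ss_s = 2 * sum((subj_means - grp_means[groups].to_numpy()) ** 2)
        cond_means = y.mean(axis=0)
        ss_c = 9 * sum((cond_means - grand) ** 2)
        cell = df.groupby(["grp", "cond"])["val"].mean().unstack()
        ss_gc = 3 * sum(
            (cell.loc[g, c] - grp_means[g] - cond_means[c] + grand) ** 2
            for g in "abc"
            for c in ("x", "y")
        )
        ss_total = ((y.to_numpy() - grand) ** 2).sum()
        ss_cs = ss_total - ss_g - ss_s - ss_c - ss_gc

        F_g = (ss_g / 2) / (ss_s / 6)
        F_c = (ss_c / 1) / (ss_cs / 6)
        F_gc = (ss_gc / 2) / (ss_cs / 6)
        by = t.set_index("effect")
        assert by.loc["grp", "F"] == pytest.approx(F_g)
        assert by.loc["cond", "F"] == pytest.approx(F_c)
        assert by.loc["grp*cond", "F"] == pytest.approx(F_gc)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        sid = 0
        for g, n in [("a", 6), ("b", 8)]:
            for _ in range(n):
                base = rng.normal()
                for c in ("x", "y", "z"):
                    rows.append((f"s{sid}", g, c, base + rng.normal()))
                sid += 1
        df = _long(rows)
        ours = mixed_anova(df, "val", "subj", "grp", "cond").set_index("effect")
        theirs = pg.mixed_anova(df, dv="val", within="cond", between="grp", subject="subj")
        theirs = theirs.set_index("Source")
        for our_key, pg_key in [("grp", "grp"), ("cond", "cond"), ("grp*cond", "Interaction")]:
            assert ours.loc[our_key, "F"] == pytest.approx(theirs.loc[pg_key, "F"])
            assert ours.loc[our_key, "p"] == pytest.approx(theirs.loc[pg_key, "p_unc"])

    def test_two_within_factor_df_structure(self, rng):
        rows = []
        sid = 0
        for g, n in [("in", 56), ("or", 57), ("plc", 58)]:
            for _ in range(n):
                for c in ("gt", "mm"):
                    for r in ("r1", "r2", "r3", "r4", "r5"):
                        rows.append((f"s{sid}", g, c, r, rng.normal()))
                sid += 1
        df = pd.DataFrame(rows, columns=["subj", "grp", "cond", "roi", "val"])
        t = mixed_anova(df, "val", "subj", "grp", ["cond", "roi"]).set_index("effect")
        assert (t.loc["roi", "df1"], t.loc["roi", "df2"]) == (4, 672)
        assert (t.loc["grp*roi", "df1"], t.loc["grp*roi", "df2"]) == (8, 672)
        assert (t.loc["cond*roi", "df1"], t.loc["cond*roi", "df2"]) == (4, 672)
        assert (t.loc["grp*cond*roi", "df1"], t.loc["grp*cond*roi", "df2"]) == (8, 672)

    def test_reduces_to_one_way_with_single_within_level(self, rng):
        y = rng.normal(size=12)
        labels = np.repeat(["a", "b", "c"], 4)
        rows = [(f"s{i}", labels[i], "only", y[i]) for i in range(12)]
        t_mixed = mixed_anova(_long(rows), "val", "subj", "grp", "cond")
        t_one = one_way_anova(y, labels)
        assert t_mixed.loc[0, "F"] == pytest.approx(t_one.loc[0, "F"])
        assert (t_mixed.loc[0, "df1"], t_mixed.loc[0, "df2"]) == (2, 9)

    def test_unbalanced_within_rejected(self):
        rows = [("s0", "a", "x", 1.0), ("s0", "a", "y", 2.0), ("s1", "b", "x", 3.0)]
        with pytest.raises(ValueError, match="within"):
            mixed_anova(_long(rows), "val", "subj", "grp", "cond")


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni_adjust(0.02, m=3) == pytest.approx(0.06)
        assert bonferroni_adjust(0.5, m=3) == 1.0

    def test_monotone_in_m(self):
        adj = [bonferroni_adjust(0.01, m=m) for m in range(1, 20)]
        assert all(b >= a for a, b in zip(adj, adj[1:]))

    def test_pairwise_table(self):
        table = bonferroni_pairwise(
            means={"a": 1.0, "b": 2.0, "c": 1.1},
            sizes={"a": 20, "b": 20, "c": 20},
            ms_error=1.0,
            df_error=57,
            comparisons=[("a", "b"), ("a", "c"), ("b", "c")],
        )
        assert (table["p_bonferroni"] >= table["p_raw"]).all()
        assert table["p_bonferroni"].max() <= 1.0
        assert table.loc[0, "difference"] == pytest.approx(-1.0)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.1, m=0)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2, 5, 9, 12])
        rho, _ = spearman_rho(x, np.exp(x / 5))
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_rho(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        rho, p = spearman_rho(x, y)
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho)
        assert p == pytest.approx(ref_p, rel=0.05)  # large-sample approximation

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMediate:
    def test_effect_decomposition_identity(self, rng):
        x = rng.integers(0, 2, 60).astype(float)
        m = 2 * x + rng.normal(size=60)
        y = 0.5 * x + 0.3 * m + rng.normal(size=60)
        res = mediate(x, m, y, n_boot=100, seed=0)
        assert res.c == pytest.approx(res.c_prime + res.indirect, abs=1e-9)

    def test_full_mediation_by_construction(self, rng):
        x = rng.integers(0, 2, 80).astype(float)
        m = x + 0.1 * rng.normal(size=80)
        y = m.copy()  # Y is caused solely by M
        res = mediate(x, m, y, n_boot=100, seed=0)
        assert res.c_prime == pytest.approx(0.0, abs=1e-9)
        assert res.indirect == pytest.approx(res.c, abs=1e-9)

    def test_collinear_mediator_rejected(self, rng):
        x = rng.integers(0, 2, 40).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            mediate(x, x.copy(), rng.normal(size=40))

    def test_bootstrap_reproducible(self, rng):
        x = rng.integers(0, 2, 50).astype(float)
        m = x + rng.normal(size=50)
        y = m + rng.normal(size=50)
        r1 = mediate(x, m, y, n_boot=500, seed=4)
        r2 = mediate(x, m, y, n_boot=500, seed=4)
        assert r1.ci_95 == r2.ci_95
        assert r1.se_boot == r2.se_boot

    def test_matches_pingouin_paths(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.integers(0, 2, 70).astype(float)
        m = 1.5 * x + rng.normal(size=70)
        y = 0.4 * x + 0.5 * m + rng.normal(size=70)
        res = mediate(x, m, y, n_boot=200, seed=0)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        ref = pg.mediation_analysis(data=df, x="x", m="m", y="y", n_boot=200, seed=0)
        ref = ref.set_index("path")["coef"]
        # pingouin's "Y ~ m" row is the simple (unadjusted) regression, so
        # compare a, the total/direct effects, and the indirect effect
        assert res.a == pytest.approx(ref["m ~ X"])
        assert res.c == pytest.approx(ref["Total"])
        assert res.c_prime == pytest.approx(ref["Direct"])
        assert res.indirect == pytest.approx(ref["Indirect"])
        assert res.b == pytest.approx(ref["Indirect"] / ref["m ~ X"])


class TestPower:
    def test_a_priori_sample_size(self):
        assert anova_sample_size(PowerSpec(k=3, f=0.25, alpha=0.05, power=0.80)) == 159

    def test_adjacent_allocation_bracket(self):
        spec = PowerSpec(k=3, f=0.25, alpha=0.05, power=0.80)
        n = anova_sample_size(spec)
        assert anova_power(n, spec) >= 0.80
        assert anova_power(n - 3, spec) < 0.80

    def test_monotone_in_effect_size(self):
        sizes = [
            anova_sample_size(PowerSpec(k=3, f=f, alpha=0.05, power=0.80))
            for f in (0.15, 0.25, 0.40)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_power_monotone_in_n(self):
        spec = PowerSpec()
        powers = [anova_power(n, spec) for n in range(30, 300, 30)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_unreachable_power(self):
        with pytest.raises(ValueError, match="unreachable"):
            anova_sample_size(PowerSpec(k=3, f=0.01, alpha=0.05, power=0.99), n_cap=300)


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        chi2, dof, p = chi_square_independence([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert (dof, p) == (1, pytest.approx(1.0))

    def test_uniform_2x2(self):
        chi2, dof, _ = chi_square_independence([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert dof == 1

    def test_matches_scipy(self, rng):
        table = rng.integers(5, 40, size=(3, 4)).astype(float)
        chi2, dof, p = chi_square_independence(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert dof == ref.dof
        assert p == pytest.approx(ref.pvalue)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [5, 5]])


class TestExclusionAccounting:
    def test_study_accounting(self):
        roster = (
            [{"exclusion_reason": None}] * 171
            + [{"exclusion_reason": "incomplete"}] * 5
            + [{"exclusion_reason": "technical"}] * 4
        )
        out = exclusion_accounting(roster)
        assert out == {
            "enrolled": 180,
            "excluded": {"incomplete": 5, "technical": 4},
            "analyzed": 171,
        }

    def test_no_exclusions(self):
        out = exclusion_accounting([{"exclusion_reason": None}] * 10)
        assert out["analyzed"] == out["enrolled"] == 10

    def test_all_excluded(self):
        out = exclusion_accounting([{"exclusion_reason": "technical"}] * 3)
        assert out["analyzed"] == 0

    def test_unknown_reason_rejected(self):
        with pytest.raises(ValueError, match="unknown exclusion reason"):
            exclusion_accounting([{"exclusion_reason": "abducted"}])
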