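import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proxhrv.errors import DesignError
from proxhrv.stats import (
    AnovaTable,
    bh_qvalues,
    bonferroni_adjust,
    bonferroni_posthoc,
    bootstrap_regression,
    chi_square,
    group_mean_difference,
    mann_whitney_rb,
    mixed_anova,
    partial_eta_squared,
    power_simulation,
    r_squared_from_f,
    rank_biserial_from_u,
    spearman_fdr,
    summarize_groups,
)


class TestEffectSizeIdentities:
    def test_partial_eta_squared_reproduces_published_group_effect(self):
        assert round(partial_eta_squared(8.999, 1, 41), 3) == 0.180

    def test_r_squared_reproduces_published_model_variance(self):
        assert round(r_squared_from_f(4.210, 3, 138) * 100, 1) == 8.4

    @pytest.mark.parametrize(
        "u,expected",
        [(18.50, 0.920), (71.50, 0.690), (105.50, 0.543), (248.50, -0.076)],
    )
    def test_rank_biserial_reproduces_published_table(self, u, expected):
        assert round(rank_biserial_from_u(u, 22, 21), 3) == expected

    def test_group_mean_difference_reproduces_published_value(self):
        assert round(group_mean_difference(103.670, 67.690), 3) == 35.980


class TestSummarizeGroups:
    def test_means_and_difference(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "y": [1.0, 2, 3, 5, 6, 7]})
        out = summarize_groups(df, "y", "g")
        assert out.loc[out["g"] == "a", "mean"].iloc[0] == 2.0
        assert out.attrs["mean_difference"] == -4.0


def brute_force_split_plot(wide: pd.DataFrame, group: pd.Series, within_levels: dict):
    """Independent split-plot oracle for balanced designs: explicit group-mean
    sums of squares on the normalised per-subject contrasts."""
    cells = list(wide.columns)
    C = len(cells)
    Y = wide.to_numpy(float)
    groups = sorted(group.unique())
    out = {}

    def one_way(z):
        zbar = z.mean()
        ss_between = sum(
            (group == g).sum() * (z[(group == g).to_numpy()].mean() - zbar) ** 2 for g in groups
        )
        ss_within = sum(
            ((z[(group == g).to_numpy()] - z[(group == g).to_numpy()].mean()) ** 2).sum()
            for g in groups
        )
        df2 = len(z) - len(groups)
        return ss_between, ss_within, df2

    # between stratum on subject means
    m = Y.mean(axis=1) * np.sqrt(C)
    ssb, ssw, df2 = one_way(m)
    out["group"] = (ssb / 1) / (ssw / df2)

    names = list(within_levels)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            signs = []
            for cell in cells:
                cell_t = cell if isinstance(cell, tuple) else (cell,)
                s = 1.0
                for w in combo:
                    lev = cell_t[names.index(w)]
                    s *= 1.0 if lev == within_levels[w][0] else -1.0
                signs.append(s)
            z = (Y @ np.array(signs)) / np.sqrt(C)
            ssb, ssw, df2 = one_way(z)
            n = len(z)
            # balanced: effect SS is n * zbar^2, interaction is the group SS
            ss_eff = n * z.mean() ** 2
            mse = ssw / df2
            out[" * ".join(combo)] = ss_eff / mse
            out[" * ".join(combo) + " * group"] = (ssb / 1) / mse
    return out


class TestMixedAnova:
    def make_long(self, rng, n_per_group=8, within=("eye", "attr")):
        rows = []
        for g, grp in enumerate(["ASD", "CP"]):
            for s in range(n_per_group):
                pid = f"{grp}{s}"
                base = rng.normal(100 - 30 * g, 20)
                for levels in itertools.product(*[["l0", "l1"]] * len(within)):
                    y = base + sum(
                        5 * (lev == "l1") * (w + 1) for w, lev in enumerate(levels)
                    ) + rng.normal(0, 5)
                    row = {"subject": pid, "group": grp, "y": y}
                    row.update(dict(zip(within, levels)))
                    rows.append(row)
        return pd.DataFrame(rows)

    def test_between_f_equals_pooled_t_squared(self, rng):
        x = rng.normal(0, 1, 9)
        y = rng.normal(0.8, 1, 12)
        df = pd.DataFrame(
            {"subject": range(21), "group": ["a"] * 9 + ["b"] * 12, "y": np.r_[x, y]}
        )
        table = mixed_anova(df, "y", "subject", "group").table
        t, p = sps.ttest_ind(x, y, equal_var=True)
        assert table["F"].iloc[0] == pytest.approx(t**2, rel=1e-8)
        assert table["p"].iloc[0] == pytest.approx(p, rel=1e-8)

    def test_eta_identity_on_every_row(self, rng):
        df = self.make_long(rng)
        table = mixed_anova(df, "y", "subject", "group", within=("eye", "attr")).table
        np.testing.assert_allclose(
            table["partial_eta_sq"],
            partial_eta_squared(table["F"], table["df1"], table["df2"]),
            atol=1e-12,
        )

    def test_balanced_2x2x2_matches_brute_force_oracle(self, rng):
        df = self.make_long(rng, n_per_group=4)
        table = mixed_anova(df, "y", "subject", "group", within=("eye", "attr")).table
        wide = df.pivot_table(index="subject", columns=["eye", "attr"], values="y")
        group = df.drop_duplicates("subject").set_index("subject")["group"].reindex(wide.index)
        oracle = brute_force_split_plot(
            wide, group, {"eye": ["l0", "l1"], "attr": ["l0", "l1"]}
        )
        for effect, f_expected in oracle.items():
            f_got = table.loc[table["effect"] == effect, "F"].iloc[0]
            assert f_got == pytest.approx(f_expected, rel=1e-8), effect

    def test_one_within_factor_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = self.make_long(rng, within=("time",))
        mine = mixed_anova(df, "y", "subject", "group", within=("time",)).table
        ref = pg.mixed_anova(data=df, dv="y", within="time", subject="subject", between="group")
        for effect, source in [("group", "group"), ("time", "time"), ("time * group", "Interaction")]:
            f_ref = ref.loc[ref["Source"] == source, "F"].iloc[0]
            f_got = mine.loc[mine["effect"] == effect, "F"].iloc[0]
            assert f_got == pytest.approx(f_ref, rel=1e-10), effect

    def test_ancova_covariate_reduces_between_df(self, rng):
        df = self.make_long(rng, within=("time",))
        meta = df.drop_duplicates("subject").copy()
        meta["cov"] = rng.normal(size=len(meta))
        df = df.merge(meta[["subject", "cov"]], on="subject")
        plain = mixed_anova(df, "y", "subject", "group", within=("time",)).table
        adj = mixed_anova(
            df, "y", "subject", "group", within=("time",), covariates=("cov",)
        ).table
        g_plain = plain[plain["effect"] == "group"].iloc[0]
        g_adj = adj[adj["effect"] == "group"].iloc[0]
        assert g_adj["df2"] == g_plain["df2"] - 1
        assert "cov" in set(adj["effect"])

    def test_three_level_factor_rejected(self):
        df = pd.DataFrame(
            {"subject": list(range(6)) * 1, "group": ["a", "b", "c"] * 2, "y": range(6)}
        )
        with pytest.raises(DesignError, match="levels"):
            mixed_anova(df, "y", "subject", "group")

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame({"subject": [1, 2], "group": ["a", "b"], "y": [1.0, 2.0]})
        with pytest.raises(DesignError, match="2 complete subjects"):
            mixed_anova(df, "y", "subject", "group")

    def test_incomplete_subject_dropped_listwise(self, rng):
        df = self.make_long(rng, within=("time",))
        df = df.drop(df[(df["subject"] == "ASD0") & (df["time"] == "l1")].index)
        result = mixed_anova(df, "y", "subject", "group", within=("time",))
        assert "ASD0" in result.dropped_subjects

    def test_identity_enforced_at_construction(self):
        bad = pd.DataFrame(
            [{"effect": "x", "sum_sq": 1.0, "df1": 1, "df2": 10, "F": 5.0,
              "p": 0.05, "partial_eta_sq": 0.9}]
        )
        with pytest.raises(AssertionError):
            AnovaTable(table=bad)


class TestBonferroni:
    def test_family_of_two(self):
        np.testing.assert_allclose(bonferroni_adjust([0.03, 0.2]), [0.06, 0.4])

    def test_cap_at_one(self):
        assert bonferroni_adjust([0.9, 0.5, 0.5, 0.5])[0] == 1.0

    def test_empty_family_rejected(self):
        with pytest.raises(DesignError):
            bonferroni_adjust([])

    def test_posthoc_paired_per_group(self, rng):
        rows = []
        for grp in ["a", "b"]:
            for s in range(10):
                base = rng.normal(0, 1)
                rows.append({"subject": f"{grp}{s}", "group": grp, "time": "t1", "y": base})
                rows.append(
                    {"subject": f"{grp}{s}", "group": grp, "time": "t2",
                     "y": base + 2 + rng.normal(0, 0.5)}
                )
        df = pd.DataFrame(rows)
        out = bonferroni_posthoc(df, "y", "time", subject="subject", by="group", paired=True)
        assert len(out) == 2
        np.testing.assert_allclose(out["p_adjusted"], np.minimum(out["p_raw"] * 2, 1.0))
        assert (out["p_adjusted"] < 0.01).all()

    def test_identical_groups_yield_large_adjusted_p(self, rng):
        adjusted = []
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "y": rng.normal(0, 1, 40),
                    "f": ["x", "y"] * 20,
                    "g": ["a"] * 20 + ["b"] * 20,
                }
            )
            out = bonferroni_posthoc(df, "y", "f", by="g")
            adjusted.extend(out["p_adjusted"])
        assert np.mean(adjusted) > 0.7


def brute_force_u(x, y):
    """Pair-counting oracle: pairs with x below y, ties count half."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi < yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestMannWhitney:
    def test_complete_separation_x_above_y(self):
        res = mann_whitney_rb([10, 11, 12], [1, 2, 3])
        assert res.u == 0.0
        assert res.rank_biserial_r == 1.0

    def test_complete_separation_x_below_y(self):
        res = mann_whitney_rb([1, 2, 3], [10, 11, 12])
        assert res.rank_biserial_r == -1.0

    def test_published_aq_row_identity(self):
        # r and the Fisher-z CI reproduce the published AQ row for U = 18.50
        r = rank_biserial_from_u(18.50, 22, 21)
        assert round(r, 3) == 0.920
        import math

        se = math.sqrt((22 + 21 + 1) / (3 * 22 * 21))
        lo = math.tanh(math.atanh(r) - 1.959963984540054 * se)
        hi = math.tanh(math.atanh(r) + 1.959963984540054 * se)
        assert round(lo, 3) == 0.845 and round(hi, 3) == 0.959

    def test_u_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 9), rng.integers(2, 9)
            x = rng.integers(0, 10, n1).astype(float)
            y = rng.integers(0, 10, n2).astype(float)
            res = mann_whitney_rb(x, y)
            assert res.u == brute_force_u(x, y)

    def test_p_matches_scipy(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(1, 1, 30)
        res = mann_whitney_rb(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(DesignError):
            mann_whitney_rb([], [1.0])


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        res = chi_square([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_published_gender_row(self):
        res = chi_square([[18, 4], [14, 7]])
        assert round(res.statistic, 3) == 1.296
        assert round(res.p, 3) == 0.255

    def test_row_swap_invariance(self):
        a = chi_square([[18, 4], [14, 7]]).statistic
        b = chi_square([[14, 7], [18, 4]]).statistic
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(DesignError, match="zero"):
            chi_square([[0, 5], [0, 7]])

    def test_continuity_correction_flag(self):
        raw = chi_square([[18, 4], [14, 7]]).statistic
        corrected = chi_square([[18, 4], [14, 7]], correction=True).statistic
        assert corrected < raw


class TestSpearmanFdr:
    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        report = spearman_fdr(df)
        assert report.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_bh_hand_example(self):
        np.testing.assert_allclose(bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(0, 1, 25)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_constant_variable_flagged(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "c": np.ones(20)})
        report = spearman_fdr(df)
        assert "c" in report.flagged
        assert np.isnan(report.rho.loc["x", "c"])

    def test_pairwise_complete_handling(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        df.loc[:16, "y"] = np.nan  # only 3 complete pairs remain
        report = spearman_fdr(df, min_n=3)
        assert not np.isnan(report.rho.loc["x", "y"])
        report2 = spearman_fdr(df, min_n=5)
        assert np.isnan(report2.rho.loc["x", "y"])

    def test_null_calibration(self, rng):
        significant = total = 0
        for _ in range(60):
            df = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
            report = spearman_fdr(df, level=0.05)
            iu = np.triu_indices(5, 1)
            significant += int(np.nansum(report.q.to_numpy()[iu] <= 0.05))
            total += len(iu[0])
        rate = significant / total
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


class TestBootstrapRegression:
    def test_noiseless_line_recovered(self):
        x = np.arange(10.0)
        res = bootstrap_regression(2 * x, pd.DataFrame({"x": x}), n_boot=200, seed=0)
        assert res.params.loc["x", "estimate"] == pytest.approx(2.0, abs=1e-10)
        assert res.params.loc["x", "bootstrap_se"] < 1e-8
        assert res.r_squared == pytest.approx(1.0)

    def test_r_squared_identity(self, rng):
        x = rng.normal(size=50)
        y = 1 + 0.5 * x + rng.normal(size=50)
        res = bootstrap_regression(y, pd.DataFrame({"x": x}), n_boot=300, seed=1)
        assert res.r_squared == pytest.approx(
            r_squared_from_f(res.f, res.df1, res.df2), abs=1e-10
        )

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(DesignError, match="x2"):
            bootstrap_regression(rng.normal(size=30), X, n_boot=100)

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        a = bootstrap_regression(y, pd.DataFrame({"x": x}), n_boot=500, seed=3)
        b = bootstrap_regression(y, pd.DataFrame({"x": x}), n_boot=500, seed=3)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_too_few_observations_rejected(self):
        with pytest.raises(DesignError, match="observations"):
            bootstrap_regression([1.0, 2.0], pd.DataFrame({"x": [1.0, 2.0]}))


def test_group_effect_direction_at_published_presets(rng):
    """Significant group effects on preset cohorts always point ASD > CP."""
    from proxhrv.synthetic import paper_presets

    presets = paper_presets()
    significant = 0
    for _ in range(200):
        rows = []
        for grp, n in (("ASD", 22), ("CP", 21)):
            p = presets[grp]
            for s in range(n):
                centre = rng.normal(p.distance_mean_cm, p.distance_sd_cm)
                for eye in ("yes", "no"):
                    for attr in ("self", "other"):
                        rows.append(
                            {"subject": f"{grp}{s}", "group": grp, "eye": eye,
                             "attr": attr, "y": max(centre + rng.normal(0, 10), 30.0)}
                        )
        df = pd.DataFrame(rows)
        table = mixed_anova(df, "y", "subject", "group", within=("eye", "attr")).table
        row = table[table["effect"] == "group"].iloc[0]
        if row["p"] < 0.05:
            significant += 1
            means = df.groupby("group")["y"].mean()
            assert means["ASD"] > means["CP"]
    assert significant > 100  # the preset effect is large; most replicates detect it


class TestPowerSimulation:
    def test_type_i_error_near_alpha(self):
        res = power_simulation([(0, 10, 20), (0, 10, 20)], n_reps=1000, alpha=0.05, seed=0)
        assert abs(res.rejection_rate - 0.05) <= 3 * res.mc_se

    def test_power_monotone_in_n(self):
        small = power_simulation([(0.5, 1, 15), (0, 1, 15)], n_reps=600, seed=1)
        large = power_simulation([(0.5, 1, 60), (0, 1, 60)], n_reps=600, seed=1)
        assert large.rejection_rate >= small.rejection_rate

    def test_too_few_reps_rejected(self):
        with pytest.raises(DesignError):
            power_simulation([(0, 1, 10), (0, 1, 10)], n_reps=50)
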