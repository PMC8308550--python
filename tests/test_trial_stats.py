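import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from celluscore.trial_sim import TrialDataset, simulate_trial
from celluscore.trial_stats import (
    COMMENT_CATEGORIES,
    baseline_contrasts,
    rm_anova,
    summarize,
    tabulate_comments,
    wilcoxon_signed_rank,
)
from conftest import css_only_config


def long_df(Y, thighs=("placebo", "herbal"), outcome="css"):
    """subjects x thighs x weeks cube -> long-format frame."""
    ns, na, nb = Y.shape
    weeks = list(range(nb))
    rows = []
    for s in range(ns):
        for a in range(na):
            for b in range(nb):
                rows.append((f"P{s:02d}", thighs[a], weeks[b], outcome, Y[s, a, b]))
    return pd.DataFrame(
        rows, columns=["participant", "thigh", "week", "outcome", "value"]
    )


def rm_anova_brute(Y):
    """Independent mean-decomposition oracle with explicit loops."""
    ns, na, nb = Y.shape
    m = Y.mean()
    m_s = [Y[s].mean() for s in range(ns)]
    m_a = [Y[:, a].mean() for a in range(na)]
    m_b = [Y[:, :, b].mean() for b in range(nb)]
    ss = {
        "subject": sum(na * nb * (m_s[s] - m) ** 2 for s in range(ns)),
        "treatment": sum(ns * nb * (m_a[a] - m) ** 2 for a in range(na)),
        "time": sum(ns * na * (m_b[b] - m) ** 2 for b in range(nb)),
    }
    ss["treatment x time"] = sum(
        ns * (Y[:, a, b].mean() - m_a[a] - m_b[b] + m) ** 2
        for a in range(na)
        for b in range(nb)
    )
    ss["treatment x subject"] = sum(
        nb * (Y[s, a].mean() - m_s[s] - m_a[a] + m) ** 2
        for s in range(ns)
        for a in range(na)
    )
    ss["time x subject"] = sum(
        na * (Y[s, :, b].mean() - m_s[s] - m_b[b] + m) ** 2
        for s in range(ns)
        for b in range(nb)
    )
    ss_total = ((Y - m) ** 2).sum()
    ss["treatment x time x subject"] = ss_total - sum(ss.values())
    f = {}
    f["treatment"] = (ss["treatment"] / (na - 1)) / (
        ss["treatment x subject"] / ((ns - 1) * (na - 1))
    )
    f["time"] = (ss["time"] / (nb - 1)) / (ss["time x subject"] / ((ns - 1) * (nb - 1)))
    f["treatment x time"] = (ss["treatment x time"] / ((na - 1) * (nb - 1))) / (
        ss["treatment x time x subject"] / ((ns - 1) * (na - 1) * (nb - 1))
    )
    return ss, f, ss_total


class TestRmAnova:
    def test_all_identical_values_yield_zero_ss_and_na_f(self):
        Y = np.full((5, 2, 3), 4.2)
        res = rm_anova(long_df(Y), "css")
        for src in ("treatment", "time", "treatment x time"):
            eff = res.effect(src)
            assert eff["ss"] == 0.0
            assert np.isnan(eff["F"]) and np.isnan(eff["p"])

    def test_pure_time_trend_no_treatment_effect(self):
        trend = np.array([10.0, 9.0, 8.0])
        Y = np.broadcast_to(trend, (6, 2, 3)).copy()
        res = rm_anova(long_df(Y), "css")
        assert res.effect("treatment")["ss"] == pytest.approx(0.0, abs=1e-10)
        assert res.effect("time")["ss"] > 0

    def test_toy_dataset_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(10, 2, size=(6, 2, 3))
        res = rm_anova(long_df(Y), "css")
        ss, f, ss_total = rm_anova_brute(Y)
        for src, expected in ss.items():
            assert res.effect(src)["ss"] == pytest.approx(expected, rel=1e-9)
        for src, expected in f.items():
            assert res.effect(src)["F"] == pytest.approx(expected, rel=1e-9)
        assert res.ss_total == pytest.approx(ss_total, rel=1e-12)

    def test_matches_pingouin_two_way_rm(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        Y = rng.normal(10, 2, size=(8, 2, 4))
        df = long_df(Y)
        res = rm_anova(df, "css")
        table = pg.rm_anova(
            data=df, dv="value", within=["thigh", "week"], subject="participant",
            detailed=True,
        )
        # pingouin labels the factors by column name
        by = {r["Source"]: r for r in table.to_dict("records")}
        assert res.effect("treatment")["F"] == pytest.approx(by["thigh"]["F"], rel=1e-6)
        assert res.effect("time")["F"] == pytest.approx(by["week"]["F"], rel=1e-6)
        assert res.effect("treatment x time")["F"] == pytest.approx(
            by["thigh * week"]["F"], rel=1e-6
        )
        assert res.effect("time")["p"] == pytest.approx(
            by["week"]["p_unc"], rel=1e-6
        )

    def test_ss_decomposition_sums_to_total(self):
        ds = simulate_trial(css_only_config(seed=3))
        res = rm_anova(
            TrialDataset(ds.complete_cases(), ds.ledger), "css"
        )
        assert res.table["ss"].sum() == pytest.approx(res.ss_total, rel=1e-8)

    def test_permuting_participant_labels_changes_nothing(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, size=(7, 2, 3))
        df = long_df(Y)
        relabel = {f"P{i:02d}": f"Q{9 - i:02d}" for i in range(7)}
        df2 = df.assign(participant=df["participant"].map(relabel))
        a, b = rm_anova(df, "css"), rm_anova(df2, "css")
        pd.testing.assert_frame_equal(
            a.table.sort_values("source").reset_index(drop=True),
            b.table.sort_values("source").reset_index(drop=True),
        )

    def test_one_way_per_arm(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(10, 1, size=(6, 2, 4))
        res = rm_anova(long_df(Y), "css", model="one-way", thigh="herbal")
        # one-way RM F for time must match scipy-style computation on that arm
        arm = Y[:, 1, :]
        ns, nb = arm.shape
        m, m_s, m_b = arm.mean(), arm.mean(axis=1), arm.mean(axis=0)
        ss_time = ns * ((m_b - m) ** 2).sum()
        ss_err = ((arm - m_s[:, None] - m_b[None, :] + m) ** 2).sum()
        F = (ss_time / (nb - 1)) / (ss_err / ((ns - 1) * (nb - 1)))
        assert res.effect("time")["F"] == pytest.approx(F, rel=1e-9)

    def test_unbalanced_data_raises(self):
        df = long_df(np.zeros((4, 2, 3)))
        with pytest.raises(ValueError, match="complete cases"):
            rm_anova(df.iloc[:-1], "css")


class TestBaselineContrasts:
    def test_identical_to_baseline_gives_zero_diff_p_one(self):
        Y = np.tile(np.array([[7.0, 7.0, 7.0]]), (6, 2, 1)).reshape(6, 2, 3)
        Y += np.random.default_rng(0).normal(0, 1, (6, 1, 1))  # subject shifts
        results = baseline_contrasts(long_df(Y), "css", "herbal")
        for r in results:
            assert r.mean_difference == pytest.approx(0.0)
            assert r.p_raw == 1.0

    def test_single_comparison_adjusted_equals_raw(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(10, 1, size=(6, 2, 2))
        (r,) = baseline_contrasts(long_df(Y), "css", "placebo")
        assert r.p_adjusted == pytest.approx(r.p_raw)

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(10, 1, size=(8, 2, 6))
        results = baseline_contrasts(long_df(Y), "css", "herbal")
        assert len(results) == 5
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 5 * r.p_raw))
            assert r.p_adjusted >= r.p_raw

    def test_power_to_detect_the_reported_css_drop(self):
        # herbal trajectory falling 13.4 -> 9.9 with study-matched noise is
        # detected at week 12 (Bonferroni-adjusted) in nearly every replicate
        rejections = 0
        n_seeds = 200
        cfg = css_only_config(
            herbal={0: 13.4, 2: 12.1, 4: 11.66, 8: 10.78, 12: 9.9},
            placebo={0: 12.9, 2: 12.8, 4: 12.7, 8: 12.5, 12: 12.4},
            weeks=(0, 2, 4, 8, 12),
            participant_sd=1.0,
            residual_sd={0: 0.78, 2: 0.78, 4: 1.3, 8: 1.8, 12: 2.34},
        )
        for seed in range(n_seeds):
            ds = simulate_trial(cfg, seed=seed)
            complete = TrialDataset(ds.complete_cases(), ds.ledger)
            res = baseline_contrasts(complete, "css", "herbal")
            wk12 = next(r for r in res if r.week == 12)
            rejections += wk12.p_adjusted < 0.05
        assert rejections / n_seeds >= 0.90

    def test_raw_scale_option(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(10, 1, size=(6, 2, 3))
        raw = baseline_contrasts(long_df(Y), "css", "herbal", normalize=False)
        norm = baseline_contrasts(long_df(Y), "css", "herbal", normalize=True)
        assert raw[0].mean_difference != pytest.approx(norm[0].mean_difference)


def wilcoxon_enumeration_oracle(diffs):
    """Exhaustive 2^n sign-assignment enumeration (independent of the DP)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    total = ranks.sum()
    lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
    count = 0
    n_assign = 0
    for signs in itertools.product([0, 1], repeat=len(ranks)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        n_assign += 1
        if w <= lo + 1e-12 or w >= hi - 1e-12:
            count += 1
    return min(w_plus, w_minus), min(1.0, count / n_assign)


class TestWilcoxon:
    def test_matches_exhaustive_enumeration(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 3, 4, 5, 1]
        res = wilcoxon_signed_rank(np.array(x), np.array(y))
        w_expected, p_expected = wilcoxon_enumeration_oracle(np.array(x) - np.array(y))
        assert res.method == "exact"
        assert res.w_statistic == pytest.approx(w_expected)
        assert res.p_value == pytest.approx(p_expected)

    def test_single_positive_pair(self):
        res = wilcoxon_signed_rank(np.array([2.0]), np.array([1.0]))
        assert res.n_nonzero == 1
        assert res.p_value == 1.0  # both sign assignments equally extreme

    def test_symmetric_pairs_centre_the_statistic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 3.0, 4.0])
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank(np.ones(6), np.ones(6))
        assert res.degenerate and res.p_value == 1.0 and res.n_nonzero == 0

    def test_matches_scipy_exact_on_continuous_data(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 10)
            res = wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(d, mode="exact")
            assert res.w_statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_normal_paths_agree_for_moderate_n(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            d = rng.normal(0.2, 1.0, 12)
            exact = wilcoxon_signed_rank(d, method="exact")
            approx = wilcoxon_signed_rank(d, method="normal-approx")
            assert abs(exact.p_value - approx.p_value) < 0.02

    def test_w_bounds(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0, 1, 25)
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal-approx"
        assert 0 <= res.w_statistic <= res.n_nonzero * (res.n_nonzero + 1) / 2
        assert 0 < res.p_value <= 1


class TestSummarize:
    def test_single_value_reports_sd_zero_and_n_one(self):
        df = long_df(np.array([[[5.0]]]))
        out = summarize(df)
        row = out.iloc[0]
        assert row["n"] == 1 and row["sd"] == 0.0 and row["sem"] == 0.0

    def test_identical_values_sd_zero(self):
        df = long_df(np.full((4, 2, 2), 3.3))
        out = summarize(df)
        assert (out["sd"] == 0.0).all() and (out["sem"] == 0.0).all()

    def test_simulated_lower_thigh_mean_recovers_configured_value(self):
        cfg = css_only_config(
            herbal={0: 47.6}, placebo={0: 47.1}, weeks=(0,),
            participant_sd=4.0, residual_sd=0.4, seed=9,
        )
        ds = simulate_trial(cfg)
        out = summarize(TrialDataset(ds.complete_cases(), ds.ledger))
        row = out.query("thigh == 'placebo' and week == 0").iloc[0]
        assert abs(row["mean"] - 47.1) < 3 * row["sem"]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["outcome", "thigh", "week", "value"]))


def comments_frame(counts: dict) -> pd.DataFrame:
    rows = []
    for (category, thigh), n in counts.items():
        for i in range(n):
            rows.append({"participant": f"P{i:02d}", "thigh": thigh, "category": category})
    return pd.DataFrame(rows, columns=["participant", "thigh", "category"])


class TestTabulateComments:
    def test_reproduces_diary_table_arithmetic(self):
        counts = {
            ("My skin seems firmer", "placebo"): 4,
            ("My skin seems firmer", "herbal"): 10,
            ("My cellulite appears to be reduced", "placebo"): 5,
            ("My cellulite appears to be reduced", "herbal"): 8,
            ("My thighs appear to be thinner", "placebo"): 2,
            ("My thighs appear to be thinner", "herbal"): 4,
            ("My thigh skin appears to be smoother", "placebo"): 5,
            ("My thigh skin appears to be smoother", "herbal"): 7,
        }
        out = tabulate_comments(comments_frame(counts), n_completers=18)
        firmer = out[out["category"] == "My skin seems firmer"].iloc[0]
        assert firmer["herbal_count"] == 10 and firmer["herbal_percent"] == 56
        assert firmer["placebo_percent"] == 22
        total = out[out["category"] == "Total comments"].iloc[0]
        assert total["placebo_count"] == 16 and total["herbal_count"] == 29

    def test_empty_comments_all_zero(self):
        out = tabulate_comments(
            pd.DataFrame(columns=["participant", "thigh", "category"]), 18
        )
        assert (out.filter(like="_count") == 0).all().all()

    def test_unknown_category_raises(self):
        df = pd.DataFrame(
            [{"participant": "P01", "thigh": "herbal", "category": "Feels tingly"}]
        )
        with pytest.raises(ValueError, match="unknown"):
            tabulate_comments(df, 18)
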