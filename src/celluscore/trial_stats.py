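"""Trial statistics: repeated-measures ANOVA, Bonferroni baseline contrasts,
Wilcoxon signed-rank for paired Likert data, summary tables and diary-comment
tabulation.

The repeated-measures decomposition is computed from first-principles sums
of squares for the fully balanced completer design (every participant, both
thighs, every visit): with subject as the repeated block, each
within-subject effect is tested against its own effect-by-subject
interaction, F = MS_effect / MS_(effect x subject).  The Wilcoxon test drops
zero differences, mid-ranks ties, enumerates the exact null for up to 12
non-zero pairs and otherwise uses the normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grading import normalize_to_baseline

__all__ = [
    "RmAnovaResult",
    "PairwiseResult",
    "WilcoxonResult",
    "rm_anova",
    "baseline_contrasts",
    "wilcoxon_signed_rank",
    "summarize",
    "tabulate_comments",
    "COMMENT_CATEGORIES",
]

COMMENT_CATEGORIES = (
    "My skin seems firmer",
    "My cellulite appears to be reduced",
    "My thighs appear to be thinner",
    "My thigh skin appears to be smoother",
)


@dataclass(frozen=True)
class RmAnovaResult:
    """ANOVA table (one row per source) plus the totals used to check the
    decomposition.  F and p are NaN where a mean square is 0/undefined."""

    table: pd.DataFrame
    ss_total: float
    grand_mean: float
    model: str

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("source").loc[name]


@dataclass(frozen=True)
class PairwiseResult:
    week: int
    mean_difference: float
    t_statistic: float
    p_raw: float
    p_adjusted: float
    n: int


@dataclass(frozen=True)
class WilcoxonResult:
    n_nonzero: int
    w_statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def _pivot_balanced(df: pd.DataFrame, outcome: str) -> np.ndarray:
    """subjects x thighs x weeks value cube; errors if any cell is missing."""
    sub = df[df["outcome"] == outcome]
    if sub.empty:
        raise ValueError(f"no records for outcome {outcome!r}")
    subjects = sorted(sub["participant"].unique())
    thighs = sorted(sub["thigh"].unique())
    weeks = sorted(sub["week"].unique())
    cube = sub.pivot_table(
        index="participant", columns=["thigh", "week"], values="value"
    )
    expected = len(thighs) * len(weeks)
    if cube.isna().any().any() or cube.shape[1] != expected:
        raise ValueError(
            "unbalanced data: repeated-measures ANOVA needs complete cases "
            "(filter to completers first)"
        )
    arr = cube.to_numpy().reshape(len(subjects), len(thighs), len(weeks))
    return arr, subjects, thighs, weeks


def rm_anova(
    dataset, outcome: str, model: str = "two-way", thigh: str | None = None
) -> RmAnovaResult:
    """Within-subject ANOVA of a trial outcome.

    model="two-way": treatment (thigh) x time with subject as the repeated
    block.  model="one-way": time only, for a single thigh given by
    ``thigh``.  Data must be balanced complete cases.
    """
    df = dataset.data if hasattr(dataset, "data") else dataset
    if model == "one-way":
        if thigh is None:
            raise ValueError("one-way model needs thigh=")
        df = df[df["thigh"] == thigh]
    Y, subjects, thighs, weeks = _pivot_balanced(df, outcome)
    ns, na, nb = Y.shape
    m = Y.mean()
    ss_total = float(((Y - m) ** 2).sum())
    # sums of squares indistinguishable from rounding noise are true zeros
    # (e.g. all values identical), for which F is undefined
    ss_tol = Y.size * (np.finfo(float).eps * max(1.0, abs(m))) ** 2 * 100.0

    def snap(ss: float) -> float:
        return 0.0 if ss < ss_tol else ss

    ss_total = snap(ss_total)

    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_subj = snap(na * nb * float(((m_s - m) ** 2).sum()))
    ss_b = snap(ns * na * float(((m_b - m) ** 2).sum()))
    ss_bs = snap(
        na * float(((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2).sum())
    )

    rows = []

    def add(source, ss, df_num, err_ss, err_df, err_name):
        ms = ss / df_num if df_num > 0 else np.nan
        ms_err = err_ss / err_df if err_df > 0 else np.nan
        if ms_err and np.isfinite(ms_err) and ms_err > 0:
            F = ms / ms_err
            p = float(stats.f.sf(F, df_num, err_df))
        else:
            F, p = np.nan, np.nan
        rows.append((source, ss, df_num, ms, F, p, err_name))

    if model == "one-way":
        # Y is ns x 1 x nb
        add("time", ss_b, nb - 1, ss_bs, (ns - 1) * (nb - 1), "time x subject")
        rows.append(
            ("subject", ss_subj, ns - 1, ss_subj / (ns - 1), np.nan, np.nan, "")
        )
        rows.append(
            (
                "time x subject",
                ss_bs,
                (ns - 1) * (nb - 1),
                ss_bs / ((ns - 1) * (nb - 1)),
                np.nan,
                np.nan,
                "",
            )
        )
    else:
        ss_a = snap(ns * nb * float(((m_a - m) ** 2).sum()))
        ss_as = snap(
            nb * float(((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2).sum())
        )
        ss_ab = snap(
            ns * float(((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2).sum())
        )
        ss_abs = ss_total - (
            ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs
        )
        ss_abs = snap(max(ss_abs, 0.0))
        df_as = (ns - 1) * (na - 1)
        df_bs = (ns - 1) * (nb - 1)
        df_abs = (ns - 1) * (na - 1) * (nb - 1)
        add("treatment", ss_a, na - 1, ss_as, df_as, "treatment x subject")
        add("time", ss_b, nb - 1, ss_bs, df_bs, "time x subject")
        add(
            "treatment x time",
            ss_ab,
            (na - 1) * (nb - 1),
            ss_abs,
            df_abs,
            "treatment x time x subject",
        )
        for nm, ss, dfree in (
            ("subject", ss_subj, ns - 1),
            ("treatment x subject", ss_as, df_as),
            ("time x subject", ss_bs, df_bs),
            ("treatment x time x subject", ss_abs, df_abs),
        ):
            rows.append(
                (nm, ss, dfree, ss / dfree if dfree else np.nan, np.nan, np.nan, "")
            )

    table = pd.DataFrame(
        rows, columns=["source", "ss", "df", "ms", "F", "p", "error_term"]
    )
    return RmAnovaResult(table, ss_total, float(m), model)


def baseline_contrasts(
    dataset,
    outcome: str,
    arm: str,
    baseline_week: int = 0,
    normalize: bool = True,
) -> list:
    """Paired comparison of each post-baseline week against baseline.

    By default values are first normalised to percent-of-baseline per
    participant (the scale on which the study tested), so each contrast is a
    one-sample t on (week − 100).  Bonferroni adjusts over the family of
    post-baseline weeks: p_adj = min(1, m·p).
    """
    df = dataset.data if hasattr(dataset, "data") else dataset
    sub = df[(df["outcome"] == outcome) & (df["thigh"] == arm)]
    if sub.empty:
        raise ValueError(f"no records for outcome {outcome!r}, arm {arm!r}")
    if normalize:
        sub = normalize_to_baseline(
            sub, baseline_week=baseline_week, group_cols=("participant", "thigh")
        )
    wide = sub.pivot_table(index="participant", columns="week", values="value")
    if baseline_week not in wide.columns:
        raise ValueError(f"baseline week {baseline_week} absent")
    post_weeks = [w for w in wide.columns if w != baseline_week]
    if not post_weeks:
        raise ValueError("need at least one post-baseline week")
    m = len(post_weeks)
    results = []
    for week in post_weeks:
        pair = wide[[baseline_week, week]].dropna()
        diffs = (pair[week] - pair[baseline_week]).to_numpy()
        if len(diffs) < 2:
            raise ValueError(f"fewer than 2 complete pairs at week {week}")
        if np.allclose(diffs.std(ddof=1), 0.0) and np.allclose(diffs.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(diffs, 0.0)
        results.append(
            PairwiseResult(
                week=int(week),
                mean_difference=float(diffs.mean()),
                t_statistic=float(t),
                p_raw=float(p),
                p_adjusted=float(min(1.0, m * p)),
                n=len(diffs),
            )
        )
    return results


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed exact p by enumerating the 2^n sign assignments.

    Ranks may be half-integer mid-ranks; doubling keeps the distribution on
    an integer lattice for a polynomial (convolution) enumeration.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = doubled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    lo = min(w2, total - w2)
    hi = max(w2, total - w2)
    p = dist[: lo + 1].sum() + dist[hi:].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x, y=None, method: str = "auto") -> WilcoxonResult:
    """Paired two-tailed Wilcoxon signed-rank test.

    Zero differences are dropped (the standard convention); ties among the
    remaining |differences| receive mid-ranks.  W is reported as
    min(W+, W−).  With every difference zero the test is degenerate and
    p = 1 is returned with a flag.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one pair")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0, 0.0, 1.0, "degenerate", degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if method == "auto":
        method = "exact" if n <= 12 else "normal-approx"
    if method == "exact":
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        if var <= 0:
            return WilcoxonResult(n, w, 1.0, "normal-approx", degenerate=True)
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(n, w, p, method)


def summarize(dataset, value_col: str = "value") -> pd.DataFrame:
    """Mean ± SD (n−1 denominator) and SEM per (outcome, thigh, week).

    Single-value groups report SD = 0 with the n = 1 flag visible in the
    ``n`` column.
    """
    df = dataset.data if hasattr(dataset, "data") else dataset
    if df.empty:
        raise ValueError("empty dataset")
    grouped = df.groupby(["outcome", "thigh", "week"])[value_col]
    out = grouped.agg(
        n="count",
        mean="mean",
        sd=lambda g: g.std(ddof=1) if len(g) > 1 else 0.0,
    ).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def tabulate_comments(
    comments: pd.DataFrame, n_completers: int, categories=COMMENT_CATEGORIES
) -> pd.DataFrame:
    """Count spontaneous diary comments per (category, thigh).

    Percentages are percent of completers, rounded to the nearest integer;
    a Total row gives per-thigh comment counts.  Unknown categories raise.
    """
    df = comments if isinstance(comments, pd.DataFrame) else pd.DataFrame(comments)
    unknown = set(df["category"]) - set(categories)
    if unknown:
        raise ValueError(f"unknown comment categories: {sorted(unknown)}")
    thighs = ("placebo", "herbal")
    rows = []
    for cat in categories:
        row = {"category": cat}
        for thigh in thighs:
            count = int(
                ((df["category"] == cat) & (df["thigh"] == thigh)).sum()
            )
            row[f"{thigh}_count"] = count
            row[f"{thigh}_percent"] = int(
                np.floor(100.0 * count / n_completers + 0.5)
            )
        rows.append(row)
    total = {"category": "Total comments"}
    for thigh in thighs:
        total[f"{thigh}_count"] = int((df["thigh"] == thigh).sum())
        total[f"{thigh}_percent"] = np.nan
    rows.append(total)
    return pd.DataFrame(rows)
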