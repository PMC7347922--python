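"""Descriptive and inferential behavioral analyses of trial logs.

Acceptance rates per option (or per the best/intermediate/worst category
collapse) and environment, poor-minus-rich difference scores, the
previous-offer (trial-to-trial) analysis, mixed-design repeated-measures
ANOVA with partial eta squared, the group t-tests, and the data-quality
exclusion screens.  Every function is a pure function of the log(s) it is
given and applies equally to synthetic or real-format data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .model import TrialLog

__all__ = [
    "CATEGORY_OF",
    "StatResult",
    "ExclusionReport",
    "acceptance_rates",
    "acceptance_table",
    "difference_score",
    "difference_scores",
    "previous_offer_table",
    "mixed_anova",
    "group_tests",
    "apply_exclusions",
]

#: Option -> value-category collapse (the two intermediates share 10 pts/s).
CATEGORY_OF = {
    "LDHR": "best",
    "LDLR": "intermediate",
    "HDHR": "intermediate",
    "HDLR": "worst",
}
_CATEGORIES = ("best", "intermediate", "worst")
_OPTIONS = ("LDHR", "LDLR", "HDHR", "HDLR")
_ENV_ORDER = ("rich", "poor", "hdlr_only")


@dataclass
class StatResult:
    """A single test statistic with its inferential context."""

    name: str
    statistic: str  # "t" | "F" | "z"
    value: float
    df: float | tuple[float, float]
    p: float
    ci: tuple[float, float] | None = None
    partial_eta_sq: float | None = None
    degenerate: bool = False
    note: str | None = None


def _free_decisions(log: TrialLog):
    """(env, option, accepted) for scored trials: free and not missed."""
    for rec in log.records:
        if rec.forced or rec.choice == "missed":
            continue
        yield rec.env, rec.option, rec.choice == "accept"


def _rate_frame(counts: dict, accepted: dict, rows, envs) -> pd.DataFrame:
    data = {}
    for env in envs:
        col = []
        for row in rows:
            n = counts.get((row, env), 0)
            col.append(accepted.get((row, env), 0) / n if n else np.nan)
        data[env] = col
    return pd.DataFrame(data, index=list(rows))


def acceptance_rates(log: TrialLog, collapse_intermediates: bool = True) -> pd.DataFrame:
    """Per-category (or per-option) acceptance fraction in each environment.

    Forced and missed trials are excluded.  The collapsed intermediate rate
    pools LDLR and HDHR trials (accepts over trials, not a mean of two
    rates).  Cells with no free trials are NaN.
    """
    counts: dict = {}
    accepted: dict = {}
    envs_seen = []
    for env, option, acc in _free_decisions(log):
        key = CATEGORY_OF[option] if collapse_intermediates else option
        counts[(key, env)] = counts.get((key, env), 0) + 1
        accepted[(key, env)] = accepted.get((key, env), 0) + int(acc)
        if env not in envs_seen:
            envs_seen.append(env)
    envs = [e for e in _ENV_ORDER if e in envs_seen]
    rows = _CATEGORIES if collapse_intermediates else _OPTIONS
    if collapse_intermediates and set(envs) == {"hdlr_only"}:
        rows = ("worst",)
    return _rate_frame(counts, accepted, rows, envs)


def acceptance_table(logs: list[TrialLog], collapse_intermediates: bool = True) -> pd.DataFrame:
    """Tidy cohort table: one row per subject x category x environment."""
    rows = []
    for log in logs:
        table = acceptance_rates(log, collapse_intermediates)
        for cat, env in product(table.index, table.columns):
            rows.append(
                (log.subject_id, log.design.order, cat, env, table.loc[cat, env])
            )
    return pd.DataFrame(
        rows, columns=["subject", "condition", "option", "env", "rate"]
    )


def difference_score(table: pd.DataFrame) -> float:
    """Mean over options of (poor acceptance - rich acceptance).

    ``table`` is an option-by-environment rate table with ``rich`` and
    ``poor`` columns.  Positive scores mean more accepting when poor.
    """
    for env in ("rich", "poor"):
        if env not in table.columns:
            raise ValueError(f"table lacks the {env!r} environment")
    diffs = table["poor"] - table["rich"]
    return float(diffs.mean(skipna=False))


def difference_scores(logs: list[TrialLog]) -> pd.DataFrame:
    """Per-subject difference scores (4-option basis) with order condition."""
    rows = [
        (
            log.subject_id,
            log.design.order,
            difference_score(acceptance_rates(log, collapse_intermediates=False)),
        )
        for log in logs
    ]
    return pd.DataFrame(rows, columns=["subject", "condition", "diff_score"])


def previous_offer_table(
    log: TrialLog,
    collapse_intermediates: bool = True,
    include_forced_current: bool = False,
    forced_history: bool = True,
) -> pd.DataFrame:
    """Acceptance by the previous trial's offer category and environment.

    Trials are partitioned by the option *offered* on the immediately
    preceding trial (regardless of the previous decision); the first trial of
    each block is excluded.  Current-trial responses come from free trials
    only unless ``include_forced_current``.  Forced trials count as history by
    default (their offers were experienced).
    """
    counts: dict = {}
    accepted: dict = {}
    envs_seen: list[str] = []
    prev = None
    for rec in log.records:
        prev_rec, prev = prev, rec
        if prev_rec is None or prev_rec.block != rec.block:
            continue
        if rec.choice == "missed":
            continue
        if rec.forced and not include_forced_current:
            continue
        if prev_rec.forced and not forced_history:
            continue
        key = CATEGORY_OF[prev_rec.option] if collapse_intermediates else prev_rec.option
        counts[(key, rec.env)] = counts.get((key, rec.env), 0) + 1
        accepted[(key, rec.env)] = accepted.get((key, rec.env), 0) + int(
            rec.choice == "accept"
        )
        if rec.env not in envs_seen:
            envs_seen.append(rec.env)
    envs = [e for e in _ENV_ORDER if e in envs_seen]
    rows = _CATEGORIES if collapse_intermediates else _OPTIONS
    return _rate_frame(counts, accepted, rows, envs)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
    between: str | None = None,
) -> pd.DataFrame:
    """Mixed-design repeated-measures ANOVA (1-2 within factors, optional between).

    Classical sums-of-squares decomposition for a balanced within-subject
    design (every subject contributes exactly one value per within-cell);
    group sizes may differ (weighted-means solution).  Each within effect is
    tested against its own subject-interaction error term; the between effect
    against subjects-within-groups.  Returns one row per effect with F, dfs,
    p and partial eta squared.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova supports one or two within factors")
    df = data[[subject] + within + ([between] if between else []) + [dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in the dependent variable")

    cell_counts = df.groupby([subject] + within, observed=True).size()
    if (cell_counts != 1).any():
        raise ValueError("unbalanced within design: need one value per subject per cell")
    levels = {f: list(df[f].unique()) for f in within}
    n_cells = int(np.prod([len(levels[f]) for f in within]))
    subjects = df[subject].unique()
    if len(df) != len(subjects) * n_cells:
        raise ValueError("unbalanced within design: subjects missing cells")
    if between is not None:
        g_per_sub = df.groupby(subject, observed=True)[between].nunique()
        if (g_per_sub != 1).any():
            raise ValueError("each subject must belong to exactly one group")

    grand = df[dv].mean()
    ss_total = float(((df[dv] - grand) ** 2).sum())
    n_sub = len(subjects)

    sub_mean = df.groupby(subject, observed=True)[dv].mean()
    if between is not None:
        g_of_s = df.groupby(subject, observed=True)[between].first()
        g_mean = df.groupby(between, observed=True)[dv].mean()
        n_groups = len(g_mean)
        n_g = g_of_s.value_counts()
        ss_g = n_cells * float((n_g * (g_mean - grand) ** 2).sum())
        ss_swg = n_cells * float(
            ((sub_mean - g_of_s.map(g_mean)) ** 2).sum()
        )
        df_g, df_swg = n_groups - 1, n_sub - n_groups
    else:
        g_of_s = None
        n_groups = 1
        ss_g = 0.0
        ss_swg = n_cells * float(((sub_mean - grand) ** 2).sum())
        df_swg = n_sub - 1

    rows = []

    def add_row(name, ss, df1, ss_err, df_err):
        ms = ss / df1 if df1 > 0 else np.nan
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if not np.isfinite(ms_err) or ms_err <= 0:
            f = np.nan if ss > 0 else 0.0
            p = np.nan
        else:
            f = ms / ms_err
            p = float(stats.f.sf(f, df1, df_err)) if np.isfinite(f) else np.nan
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        rows.append(
            {
                "effect": name,
                "SS": ss,
                "df1": df1,
                "df2": df_err,
                "F": f,
                "p": p,
                "partial_eta_sq": eta,
            }
        )

    if between is not None:
        add_row(between, ss_g, df_g, ss_swg, df_swg)

    accounted = ss_g + ss_swg
    for f_name in within:
        a = len(levels[f_name])
        other = n_cells // a
        f_mean = df.groupby(f_name, observed=True)[dv].mean()
        ss_f = other * n_sub * float(((f_mean - grand) ** 2).sum())
        if between is not None:
            fg = df.groupby([f_name, between], observed=True)[dv].mean()
            dev = fg - f_mean.reindex(fg.index.get_level_values(0)).values
            dev = dev - g_mean.reindex(fg.index.get_level_values(1)).values + grand
            w = n_g.reindex(fg.index.get_level_values(1)).values
            ss_fg = other * float((w * dev.values**2).sum())
        else:
            ss_fg = 0.0
        fs = df.groupby([f_name, subject], observed=True)[dv].mean()
        f_of = fs.index.get_level_values(0)
        s_of = fs.index.get_level_values(1)
        if between is not None:
            fg_map = df.groupby([f_name, between], observed=True)[dv].mean()
            base = fg_map.reindex(
                pd.MultiIndex.from_arrays([f_of, g_of_s.reindex(s_of).values])
            ).values
            sub_base = g_of_s.reindex(s_of).map(g_mean).values
        else:
            base = f_mean.reindex(f_of).values
            sub_base = np.full(len(fs), grand)
        ss_fswg = other * float(
            ((fs.values - base - sub_mean.reindex(s_of).values + sub_base) ** 2).sum()
        )
        df_f = a - 1
        df_fswg = (a - 1) * (n_sub - n_groups)
        add_row(f_name, ss_f, df_f, ss_fswg, df_fswg)
        if between is not None:
            add_row(f"{f_name} x {between}", ss_fg, df_f * (n_groups - 1), ss_fswg, df_fswg)
        accounted += ss_f + ss_fg + ss_fswg

    if len(within) == 2:
        f1, f2 = within
        a, b = len(levels[f1]), len(levels[f2])
        ab = df.groupby([f1, f2], observed=True)[dv].mean()
        m1 = df.groupby(f1, observed=True)[dv].mean()
        m2 = df.groupby(f2, observed=True)[dv].mean()
        dev = (
            ab.values
            - m1.reindex(ab.index.get_level_values(0)).values
            - m2.reindex(ab.index.get_level_values(1)).values
            + grand
        )
        ss_ab = n_sub * float((dev**2).sum())
        df_ab = (a - 1) * (b - 1)
        if between is not None:
            abg = df.groupby([f1, f2, between], observed=True)[dv].mean()
            i1 = abg.index.get_level_values(0)
            i2 = abg.index.get_level_values(1)
            ig = abg.index.get_level_values(2)
            f1g = df.groupby([f1, between], observed=True)[dv].mean()
            f2g = df.groupby([f2, between], observed=True)[dv].mean()
            dev_g = (
                abg.values
                - ab.reindex(pd.MultiIndex.from_arrays([i1, i2])).values
                - f1g.reindex(pd.MultiIndex.from_arrays([i1, ig])).values
                - f2g.reindex(pd.MultiIndex.from_arrays([i2, ig])).values
                + m1.reindex(i1).values
                + m2.reindex(i2).values
                + g_mean.reindex(ig).values
                - grand
            )
            w = n_g.reindex(ig).values
            ss_abg = float((w * dev_g**2).sum())
        else:
            ss_abg = 0.0
        ss_abswg = ss_total - accounted - ss_ab - ss_abg
        ss_abswg = max(ss_abswg, 0.0)
        df_abswg = df_ab * (n_sub - n_groups)
        add_row(f"{f1} x {f2}", ss_ab, df_ab, ss_abswg, df_abswg)
        if between is not None:
            add_row(
                f"{f1} x {f2} x {between}",
                ss_abg,
                df_ab * (n_groups - 1),
                ss_abswg,
                df_abswg,
            )

    return pd.DataFrame(rows)


def _one_sample_t(x: np.ndarray, name: str) -> StatResult:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.allclose(x.std(ddof=1), 0.0):
        zero = bool(np.allclose(x.mean(), 0.0))
        return StatResult(
            name, "t", 0.0 if zero else math.inf, n - 1, 1.0 if zero else 0.0,
            degenerate=True, note="zero variance",
        )
    res = stats.ttest_1samp(x, 0.0)
    ci = res.confidence_interval(0.95)
    return StatResult(
        name, "t", float(res.statistic), n - 1, float(res.pvalue),
        ci=(float(ci.low), float(ci.high)),
    )


def independent_t(x: np.ndarray, y: np.ndarray, name: str) -> StatResult:
    """Two-sided independent-samples t-test (pooled variance) with 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    dfree = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / dfree
    if np.allclose(sp2, 0.0):
        same = bool(np.allclose(x.mean(), y.mean()))
        return StatResult(
            name, "t", 0.0 if same else math.inf, dfree, 1.0 if same else 0.0,
            degenerate=True, note="zero variance",
        )
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    t_val = (x.mean() - y.mean()) / se
    p = 2 * float(stats.t.sf(abs(t_val), dfree))
    half = float(stats.t.ppf(0.975, dfree)) * se
    d = x.mean() - y.mean()
    return StatResult(name, "t", float(t_val), dfree, p, ci=(d - half, d + half))


def group_tests(scores_by_condition: dict[str, np.ndarray]) -> dict[str, StatResult]:
    """Per-condition one-sample t vs 0 plus the between-condition independent t."""
    out = {}
    for cond, scores in scores_by_condition.items():
        out[f"one_sample_{cond}"] = _one_sample_t(np.asarray(scores), f"{cond} vs 0")
    conds = list(scores_by_condition)
    if len(conds) == 2:
        a, b = conds
        out["independent"] = independent_t(
            np.asarray(scores_by_condition[a]),
            np.asarray(scores_by_condition[b]),
            f"{a} vs {b}",
        )
    return out


@dataclass
class ExclusionReport:
    """Standard a-priori data-quality screens for online foraging cohorts."""

    subject: str
    missed_count: int
    incorrect_forced_count: int
    flag_missed: bool
    flag_incorrect_forced: bool
    flag_discriminability: bool
    flag_all_same: bool
    did_not_finish: bool = False  # structurally false for synthetic data

    @property
    def keep(self) -> bool:
        return not (
            self.flag_missed
            or self.flag_incorrect_forced
            or self.flag_discriminability
            or self.flag_all_same
            or self.did_not_finish
        )


def apply_exclusions(
    log: TrialLog, missed_limit: int = 20, incorrect_forced_limit: int = 10
) -> ExclusionReport:
    """Flag a subject against the four data-quality criteria.

    Drop if: >= 20 missed responses; >= 10 incorrect forced-trial responses;
    poor discriminability (worst option accepted more often than the best on
    free trials); or accepting/rejecting every free trial.
    """
    missed = sum(1 for r in log.records if r.choice == "missed")
    incorrect_forced = sum(
        1
        for r in log.records
        if r.forced and r.choice != "missed" and r.choice != r.forced_direction
    )
    free = [(o, a) for _, o, a in _free_decisions(log)]
    best = [a for o, a in free if o == "LDHR"]
    worst = [a for o, a in free if o == "HDLR"]
    flag_disc = False
    if best and worst:
        flag_disc = (sum(worst) / len(worst)) > (sum(best) / len(best))
    accepts = [a for _, a in free]
    flag_all_same = len(accepts) > 0 and (all(accepts) or not any(accepts))
    return ExclusionReport(
        subject=log.subject_id,
        missed_count=missed,
        incorrect_forced_count=incorrect_forced,
        flag_missed=missed >= missed_limit,
        flag_incorrect_forced=incorrect_forced >= incorrect_forced_limit,
        flag_discriminability=flag_disc,
        flag_all_same=flag_all_same,
    )
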