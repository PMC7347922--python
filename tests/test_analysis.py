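"""Behavioral analyses: acceptance tables, ANOVA, t-tests, exclusions."""

import math

import numpy as np
import pandas as pd
import pytest

from mvtlearn import (
    SessionDesign,
    SubjectParams,
    TrialLog,
    TrialRecord,
    acceptance_rates,
    apply_exclusions,
    difference_score,
    group_tests,
    mixed_anova,
    previous_offer_table,
    simulate_subject,
)
from mvtlearn.analysis import independent_t, previous_offer_table


def make_log(seq, design=None):
    """Build a time-consistent log from (block, env, option, forced, dir, choice)."""
    design = design or SessionDesign("exp2", "RichPoor")
    records, t = [], 0
    for i, (block, env, option, forced, fdir, choice) in enumerate(seq):
        opt = design.options[option]
        dur = design.encounter_seconds
        reward = 0.0
        if choice == "accept":
            dur += opt.handling_seconds
            reward = opt.reward_points
        elif choice == "missed":
            dur += design.timeout_seconds
        records.append(
            TrialRecord(i, block, env, option, forced, fdir, choice, reward, t, t + dur)
        )
        t += dur
    return TrialLog("hand", design, records)


TWELVE = [
    (0, "rich", "LDHR", False, None, "accept"),
    (0, "rich", "LDHR", False, None, "reject"),
    (0, "rich", "LDLR", False, None, "accept"),
    (0, "rich", "HDHR", False, None, "reject"),
    (0, "rich", "HDLR", False, None, "reject"),
    (0, "rich", "LDHR", True, "accept", "accept"),
    (1, "poor", "HDLR", False, None, "accept"),
    (1, "poor", "HDLR", False, None, "reject"),
    (1, "poor", "LDHR", False, None, "accept"),
    (1, "poor", "LDLR", False, None, "reject"),
    (1, "poor", "HDHR", False, None, "accept"),
    (1, "poor", "HDLR", False, None, "missed"),
]


def test_acceptance_rates_hand_counts():
    log = make_log(TWELVE)
    t3 = acceptance_rates(log)
    assert t3.loc["best", "rich"] == 0.5  # forced accept excluded
    assert t3.loc["intermediate", "rich"] == 0.5
    assert t3.loc["worst", "rich"] == 0.0
    assert t3.loc["best", "poor"] == 1.0
    assert t3.loc["intermediate", "poor"] == 0.5
    assert t3.loc["worst", "poor"] == 0.5  # missed excluded

    t4 = acceptance_rates(log, collapse_intermediates=False)
    assert t4.loc["LDLR", "rich"] == 1.0 and t4.loc["HDHR", "rich"] == 0.0


def test_collapsed_equals_count_weighted_merge():
    log = make_log(TWELVE)
    t4 = acceptance_rates(log, collapse_intermediates=False)
    t3 = acceptance_rates(log)
    # count the free intermediate trials per env by hand from the sequence
    counts = {"rich": {"LDLR": 1, "HDHR": 1}, "poor": {"LDLR": 1, "HDHR": 1}}
    for env in ("rich", "poor"):
        n = sum(counts[env].values())
        merged = (
            t4.loc["LDLR", env] * counts[env]["LDLR"]
            + t4.loc["HDHR", env] * counts[env]["HDHR"]
        ) / n
        assert t3.loc["intermediate", env] == pytest.approx(merged)


def test_acceptance_rates_all_forced_is_undefined():
    log = make_log([(0, "rich", "LDHR", True, "accept", "accept")] * 4)
    table = acceptance_rates(log)
    assert table.isna().all().all()


def test_difference_score():
    table = pd.DataFrame(
        {"rich": [0.9, 0.5, 0.4, 0.1], "poor": [1.0, 0.8, 0.5, 0.2]},
        index=["LDHR", "LDLR", "HDHR", "HDLR"],
    )
    assert difference_score(table) == pytest.approx((0.1 + 0.3 + 0.1 + 0.1) / 4)
    same = pd.DataFrame({"rich": [0.5] * 4, "poor": [0.5] * 4})
    assert difference_score(same) == 0.0
    shifted = pd.DataFrame({"rich": [0.2] * 4, "poor": [0.3] * 4})
    assert difference_score(shifted) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        difference_score(pd.DataFrame({"rich": [0.5]}))


def test_previous_offer_hand_partition():
    seq = [
        (0, "rich", "LDHR", False, None, "accept"),  # first trial: excluded
        (0, "rich", "LDLR", False, None, "accept"),  # prev best
        (0, "rich", "HDLR", False, None, "reject"),  # prev intermediate
        (0, "rich", "LDHR", False, None, "accept"),  # prev worst
        (0, "rich", "LDHR", True, "accept", "accept"),  # forced current: excluded
        (0, "rich", "HDHR", False, None, "reject"),  # prev best (forced history)
    ]
    table = previous_offer_table(make_log(seq))
    assert table.loc["best", "rich"] == 0.5
    assert table.loc["intermediate", "rich"] == 0.0
    assert table.loc["worst", "rich"] == 1.0


def test_previous_offer_first_trial_of_each_block_excluded():
    seq = [
        (0, "rich", "LDHR", False, None, "accept"),
        (1, "poor", "HDLR", False, None, "accept"),  # first of block 1: excluded
        (1, "poor", "LDHR", False, None, "accept"),  # prev worst
    ]
    table = previous_offer_table(make_log(seq))
    assert math.isnan(table.loc["best", "poor"])
    assert table.loc["worst", "poor"] == 1.0


def _toy_mixed_dataset(seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(8):
        grp = "g1" if s < 4 else "g2"
        for a in ("best", "mid", "worst"):
            for e in ("rich", "poor"):
                y = rng.normal() + (0.8 if a == "best" else 0) + (0.4 if e == "poor" else 0)
                rows.append((f"s{s}", grp, a, e, y))
    return pd.DataFrame(rows, columns=["subject", "grp", "option", "env", "y"])


def test_mixed_anova_matches_anovarm_within():
    from statsmodels.stats.anova import AnovaRM

    df = _toy_mixed_dataset()
    mine = mixed_anova(df, dv="y", within=["option", "env"], subject="subject")
    oracle = AnovaRM(df, "y", "subject", within=["option", "env"]).fit().anova_table
    for effect, key in [("option", "option"), ("env", "env"), ("option x env", "option:env")]:
        row = mine[mine["effect"] == effect].iloc[0]
        assert row["F"] == pytest.approx(oracle.loc[key, "F Value"], rel=1e-8)
        assert row["p"] == pytest.approx(oracle.loc[key, "Pr > F"], abs=1e-10)


def test_mixed_anova_matches_pingouin_between():
    import pingouin as pg

    df = _toy_mixed_dataset()
    sub = df[df["env"] == "rich"]
    mine = mixed_anova(sub, dv="y", within=["option"], subject="subject", between="grp")
    oracle = pg.mixed_anova(sub, dv="y", within="option", subject="subject", between="grp")
    pairs = {"grp": "grp", "option": "option", "option x grp": "Interaction"}
    for effect, src in pairs.items():
        row = mine[mine["effect"] == effect].iloc[0]
        orow = oracle[oracle["Source"] == src].iloc[0]
        assert row["F"] == pytest.approx(orow["F"], rel=1e-8)
        assert row["partial_eta_sq"] == pytest.approx(orow["np2"], rel=1e-8)


def test_mixed_anova_constant_data_gives_zero_f():
    df = _toy_mixed_dataset()
    df["y"] = 1.0
    res = mixed_anova(df, dv="y", within=["option", "env"], subject="subject", between="grp")
    assert (res["F"].fillna(0) == 0).all()


def test_mixed_anova_group_label_swap_invariance():
    df = _toy_mixed_dataset()
    res1 = mixed_anova(df, dv="y", within=["option", "env"], subject="subject", between="grp")
    df2 = df.assign(grp=df["grp"].map({"g1": "g2", "g2": "g1"}))
    res2 = mixed_anova(df2, dv="y", within=["option", "env"], subject="subject", between="grp")
    for effect in ("option", "env", "option x env"):
        a = res1[res1["effect"] == effect].iloc[0]["F"]
        b = res2[res2["effect"] == effect].iloc[0]["F"]
        assert a == pytest.approx(b, rel=1e-12)


def test_mixed_anova_rejects_unbalanced_within():
    df = _toy_mixed_dataset().iloc[1:]
    with pytest.raises(ValueError, match="unbalanced"):
        mixed_anova(df, dv="y", within=["option", "env"], subject="subject")


def test_group_tests_hand_example():
    x = np.array([0.1, 0.2, 0.05, 0.15, 0.1])
    res = group_tests({"PoorRich": x})["one_sample_PoorRich"]
    expected_t = x.mean() / (x.std(ddof=1) / math.sqrt(5))
    assert res.value == pytest.approx(expected_t)
    assert res.df == 4

    zeros = group_tests({"RichPoor": np.zeros(6)})["one_sample_RichPoor"]
    assert zeros.value == 0.0 and zeros.p == 1.0 and zeros.degenerate


def test_group_tests_shift_invariance():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0.1, 0.05, 10), rng.normal(0.05, 0.05, 12)
    base = group_tests({"PoorRich": a, "RichPoor": b})
    shifted = group_tests({"PoorRich": a + 0.3, "RichPoor": b + 0.3})
    # independent t unchanged by a common shift; one-sample t moves
    assert shifted["independent"].value == pytest.approx(base["independent"].value)
    assert shifted["one_sample_PoorRich"].value > base["one_sample_PoorRich"].value


def test_independent_t_matches_scipy():
    from scipy import stats

    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 7)
    res = independent_t(a, b, "check")
    oracle = stats.ttest_ind(a, b)
    assert res.value == pytest.approx(oracle.statistic)
    assert res.p == pytest.approx(oracle.pvalue)


def test_exclusions(short_design, asym_params):
    clean, _ = simulate_subject(short_design, asym_params, seed=2)
    assert apply_exclusions(clean).keep

    missed = make_log([(0, "rich", "LDHR", False, None, "missed")] * 20)
    assert apply_exclusions(missed).flag_missed and not apply_exclusions(missed).keep

    all_accept = make_log(
        [(0, "rich", o, False, None, "accept") for o in ("LDHR", "LDLR", "HDHR", "HDLR")] * 3
    )
    rep = apply_exclusions(all_accept)
    assert rep.flag_all_same and not rep.keep

    # worst accepted more than best: poor discriminability
    confused = make_log(
        [
            (0, "rich", "HDLR", False, None, "accept"),
            (0, "rich", "HDLR", False, None, "accept"),
            (0, "rich", "LDHR", False, None, "reject"),
            (0, "rich", "LDHR", False, None, "accept"),
        ]
    )
    assert apply_exclusions(confused).flag_discriminability


def test_incorrect_forced_flag():
    seq = [(0, "rich", "LDHR", True, "reject", "accept")] * 10
    rep = apply_exclusions(make_log(seq))
    assert rep.incorrect_forced_count == 10 and rep.flag_incorrect_forced
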