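"""Learning-rule arithmetic, simulation and likelihood replay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvtlearn import (
    SessionDesign,
    SubjectParams,
    TrialLog,
    TrialRecord,
    accept_probability,
    initial_rate,
    opportunity_cost,
    rate_update,
    replay_loglik,
    reward_second_update,
    simulate_subject,
)
from mvtlearn.model import ModelError, validate_log
from mvtlearn.task import SessionDesign as SD


def test_opportunity_cost():
    assert opportunity_cost(10.0, 2) == 20.0
    assert opportunity_cost(0.0, 8) == 0.0
    assert opportunity_cost(320 / 22, 8) == pytest.approx(8 * 320 / 22)
    with pytest.raises(ModelError):
        opportunity_cost(-1.0, 2)


def test_rate_update_examples():
    sym = SubjectParams("symmetric", alpha=0.1, beta0=0, beta1=0)
    step = rate_update(10.0, 0.0, sym)
    assert step.rho_after == pytest.approx(9.0)
    assert step.delta == -10.0 and step.gate == "-"

    asym = SubjectParams(
        "asymmetric", alpha_pos=0.005, alpha_neg=0.0016, beta0=0, beta1=0
    )
    assert rate_update(10.0, 0.0, asym).rho_after == pytest.approx(9.984)
    up = rate_update(10.0, 80.0, asym)
    assert up.gate == "+" and up.rho_after == pytest.approx(10 + 0.005 * 70)

    # delta = 0 leaves rho unchanged for any alpha
    assert rate_update(5.0, 5.0, sym).rho_after == 5.0


def test_reward_second_update_two_steps():
    p = SubjectParams("asymmetric", alpha_pos=0.5, alpha_neg=0.1, beta0=0, beta1=0)
    s1, s2 = reward_second_update(10.0, 80.0, p)
    assert s1.rho_after == pytest.approx(9.0)
    assert s2.rho_after == pytest.approx(9.0 + 0.5 * 71.0)
    # swapped order differs in general
    r1, r2 = reward_second_update(10.0, 80.0, p, order="reward_first")
    assert r2.rho_after != pytest.approx(s2.rho_after)
    # vanishing learning rates leave rho essentially unchanged
    tiny = SubjectParams("asymmetric", alpha_pos=1e-12, alpha_neg=1e-12, beta0=0, beta1=0)
    t1, t2 = reward_second_update(10.0, 80.0, tiny)
    assert t2.rho_after == pytest.approx(10.0, abs=1e-9)


def test_accept_probability():
    assert accept_probability(20, 20, 0.0, 1.0) == 0.5
    assert accept_probability(80, 10, 0.0, 0.0) == 0.5
    assert accept_probability(80, 10, 500.0, 0.075) < 1e-12  # reject bias
    # numerically stable at extreme arguments
    assert accept_probability(80, 0, -1e6, 1e3) == 1.0
    assert accept_probability(0, 1e6, 0, 1.0) == 0.0


def test_initial_rate_accept_all():
    # single-option block: 80 points per (2 s encounter + 2 s handling)
    d3 = SD("exp3", "RichPoor", duration_seconds=600)
    # oracle from cycle compositions: rich 440/40, hdlr 20/10, poor 260/58
    assert initial_rate(d3) == pytest.approx((440 / 40 + 2.0 + 260 / 58) / 3)
    d1 = SD("exp1", "RichPoor")
    assert initial_rate(d1) == pytest.approx((11.0 + 260 / 58) / 2)
    # block order does not change the arithmetic mean
    assert initial_rate(SD("exp1", "PoorRich")) == initial_rate(d1)


def test_simulation_forced_trials_follow_direction(sim_log):
    log, _ = sim_log
    for rec in log.records:
        if rec.forced:
            assert rec.choice == rec.forced_direction


def test_simulation_deterministic(short_design, asym_params):
    a, tr_a = simulate_subject(short_design, asym_params, seed=3, trace=True)
    b, tr_b = simulate_subject(short_design, asym_params, seed=3, trace=True)
    assert a.records == b.records
    assert np.array_equal(tr_a.rho_after, tr_b.rho_after)
    c, _ = simulate_subject(short_design, asym_params, seed=4)
    assert c.records != a.records


def test_simulation_block_timing(sim_log):
    """Blocks admit no trial after their duration; trials are contiguous."""
    log, _ = sim_log
    validate_log(log)  # contiguity + per-choice durations
    dur = log.design.block_duration
    for b in sorted({r.block for r in log.records}):
        recs = [r for r in log.records if r.block == b]
        elapsed = sum(r.t_end - r.t_start for r in recs)
        last = recs[-1].t_end - recs[-1].t_start
        assert elapsed >= dur
        assert elapsed - last < dur  # the final trial started before the deadline


def _decision_rhos(log, trace):
    """rho at each trial's decision point, read off the update trace."""
    ptr = 0
    out = []
    enc = log.design.encounter_seconds
    for rec in log.records:
        out.append(trace.rho_after[ptr + enc - 1])
        n = enc
        if rec.choice == "accept":
            n += log.design.options[rec.option].handling_seconds + 1
        elif rec.choice == "missed":
            n += log.design.timeout_seconds
        ptr += n
    assert ptr == len(trace)
    return np.array(out)


def test_greedy_subject_tracks_mvt_rule(short_design):
    """With huge beta1 and beta0=0 choices implement the threshold rule."""
    p = SubjectParams("asymmetric", alpha_pos=0.01, alpha_neg=0.01, beta0=0.0, beta1=1e6)
    log, trace = simulate_subject(short_design, p, seed=9, trace=True)
    rhos = _decision_rhos(log, trace)
    free = [(i, r) for i, r in enumerate(log.records) if not r.forced]
    agree = 0
    for i, rec in free:
        opt = log.design.options[rec.option]
        mvt_says = opt.reward_points >= rhos[i] * opt.handling_seconds
        agree += (rec.choice == "accept") == mvt_says
    assert agree / len(free) >= 0.99


def test_replay_reproduces_simulation_trace(sim_log, asym_params):
    log, sim_trace = sim_log
    res = replay_loglik(log, asym_params, trace=True)
    assert np.array_equal(res.trace.rho_after, sim_trace.rho_after)
    assert np.array_equal(res.trace.r, sim_trace.r)


def test_replay_kernel_matches_trace_path(sim_log, asym_params):
    log, _ = sim_log
    fast = replay_loglik(log, asym_params)
    slow = replay_loglik(log, asym_params, trace=True)
    assert fast.loglik == pytest.approx(slow.loglik, abs=1e-9)
    assert fast.rho_final == pytest.approx(slow.rho_final, rel=1e-12)
    np.testing.assert_allclose(fast.per_trial, slow.per_trial, atol=1e-12)


def test_replay_is_pure(sim_log, asym_params):
    log, _ = sim_log
    a = replay_loglik(log, asym_params)
    b = replay_loglik(log, asym_params)
    assert a.loglik == b.loglik
    assert np.array_equal(a.per_trial, b.per_trial, equal_nan=True)


def test_asymmetric_nests_symmetric(sim_log):
    log, _ = sim_log
    sym = SubjectParams("symmetric", alpha=0.0218, beta0=0.9855, beta1=0.076)
    asym = SubjectParams(
        "asymmetric", alpha_pos=0.0218, alpha_neg=0.0218, beta0=0.9855, beta1=0.076
    )
    assert replay_loglik(log, sym).loglik == replay_loglik(log, asym).loglik


def test_forced_trials_excluded_from_likelihood_by_default(sim_log, asym_params):
    log, _ = sim_log
    res = replay_loglik(log, asym_params)
    forced = np.array([r.forced for r in log.records])
    assert np.all(np.isnan(res.per_trial[forced]))
    res_inc = replay_loglik(log, asym_params, include_forced=True)
    assert np.all(np.isfinite(res_inc.per_trial[forced]))
    assert res_inc.loglik < res.loglik  # extra (negative) terms


def _toy_two_trial_log():
    design = SessionDesign("exp1", "RichPoor")
    records = [
        TrialRecord(0, 0, "rich", "LDHR", False, None, "accept", 80.0, 0, 4),
        TrialRecord(1, 0, "rich", "HDLR", False, None, "reject", 0.0, 4, 6),
    ]
    return TrialLog("toy", design, records, rho0=10.0)


def test_replay_matches_hand_stepped_oracle():
    """Step the update and choice equations by hand on a 2-trial log."""
    log = _toy_two_trial_log()
    p = SubjectParams("asymmetric", alpha_pos=0.5, alpha_neg=0.1, beta0=0.5, beta1=0.05)

    # trial 1 (LDHR, accepted): two encounter-second decays from rho0=10
    rho = 10.0
    rho += 0.1 * (0 - rho)  # 9.0
    rho += 0.1 * (0 - rho)  # 8.1
    x1 = 0.05 * (80.0 - rho * 2) - 0.5
    ll1 = -math.log1p(math.exp(-x1))  # log P(accept)
    # handling: one zero second, then the delay+reward double update
    rho += 0.1 * (0 - rho)
    rho += 0.1 * (0 - rho)
    rho += 0.5 * (80.0 - rho)
    # trial 2 (HDLR, rejected): two encounter decays, then log P(reject)
    rho += 0.1 * (0 - rho)
    rho += 0.1 * (0 - rho)
    x2 = 0.05 * (20.0 - rho * 8) - 0.5
    ll2 = -math.log1p(math.exp(x2))
    expected = ll1 + ll2

    res = replay_loglik(log, p, rho0=10.0)
    assert res.loglik == pytest.approx(expected, abs=1e-10)
    np.testing.assert_allclose(res.per_trial, [ll1, ll2], atol=1e-10)


def test_replay_rejects_time_gaps():
    log = _toy_two_trial_log()
    bad = TrialRecord(1, 0, "rich", "HDLR", False, None, "reject", 0.0, 5, 7)
    log.records[1] = bad
    from mvtlearn.model import LogValidationError

    with pytest.raises(LogValidationError):
        replay_loglik(log, SubjectParams("symmetric", alpha=0.1, beta0=0, beta1=0))


@settings(max_examples=20, deadline=None)
@given(
    ap=st.floats(0.001, 0.99),
    am=st.floats(0.001, 0.99),
    beta0=st.floats(-3, 3),
    seed=st.integers(0, 100),
)
def test_rate_trace_bounds(ap, am, beta0, seed):
    """0 <= rho_t <= max(rho_0, 80) for any parameters: convex updates."""
    design = SessionDesign("exp2", "RichPoor", duration_seconds=120)
    p = SubjectParams("asymmetric", alpha_pos=ap, alpha_neg=am, beta0=beta0, beta1=0.075)
    _, trace = simulate_subject(design, p, seed=seed, trace=True)
    rho0 = initial_rate(design)
    assert np.all(trace.rho_after >= 0.0)
    assert np.all(trace.rho_after <= max(rho0, 80.0) + 1e-12)


def test_zero_reward_updates_all_negative(sim_log):
    """Every zero-reward second shrinks rho when rho_0 > 0."""
    _, trace = sim_log
    zero = trace.r == 0
    assert np.all(trace.delta[zero] < 0)


def _accept_all_hdlr_log(n_trials, design):
    """Hand-built stationary session: n accepted worst options in a row."""
    records = []
    t = 0
    for i in range(n_trials):
        records.append(
            TrialRecord(i, 0, "hdlr_only", "HDLR", False, None, "accept", 20.0, t, t + 10)
        )
        t += 10
    return TrialLog("stat", design, records)


def _per_second_rho(trace):
    """rho at the end of each second (the reward second holds two updates)."""
    last = np.r_[trace.t[1:] != trace.t[:-1], True]
    return trace.rho_after[last]


def test_stationary_rate_convergence():
    """Accept-all in a stationary environment: rho settles at the reward rate.

    The exact fixed point is reward per *update* (20 points / 11 updates,
    because the reward second carries two updates), which sits slightly below
    the per-second reward rate of 20 points / 10 s; the long-run mean must
    match the former tightly and the latter loosely.
    """
    design = SessionDesign("exp3", "RichPoor", duration_seconds=4000)
    log = _accept_all_hdlr_log(400, design)
    p_sym = SubjectParams("symmetric", alpha=0.01, beta0=0, beta1=0)
    res = replay_loglik(log, p_sym, rho0=2.0, trace=True, validate=False)
    rho_s = _per_second_rho(res.trace)
    tail = rho_s[len(rho_s) // 2 :]
    assert tail.mean() == pytest.approx(20 / 11, rel=0.05)
    assert tail.mean() == pytest.approx(2.0, rel=0.10)  # 20 points / 10 s

    # optimism: alpha_pos > alpha_neg inflates the asymptote
    p_asym = SubjectParams(
        "asymmetric", alpha_pos=0.05, alpha_neg=0.01, beta0=0, beta1=0
    )
    res_a = replay_loglik(log, p_asym, rho0=2.0, trace=True, validate=False)
    rho_a = _per_second_rho(res_a.trace)
    assert rho_a[len(rho_a) // 2 :].mean() > tail.mean()
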