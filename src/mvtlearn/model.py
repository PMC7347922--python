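"""Reward-rate learning models and the softmax choice rule.

The agent tracks a scalar estimate ``rho`` of the environment's reward rate
(points per second) with a delta rule applied at every elapsed second:

    rho <- rho + alpha * (r_t - rho),      delta_t = r_t - rho

where ``r_t`` is 0 on all seconds except the final handling second of an
accepted option.  That reward second is modelled as two updates: one from the
delay (delta = 0 - rho) and one from the reward (delta = r_i - rho).  The
*symmetric* model has a single learning rate alpha; the *asymmetric* model
applies ``alpha_pos`` when r_t > 0 and ``alpha_neg`` otherwise, so a positive
learning bias (alpha_pos > alpha_neg) inflates rho and makes choices
over-selective when the environment deteriorates.

Accepting an option with reward ``r_i`` and handling time ``t_i`` is weighed
against the opportunity cost ``c_i = rho * t_i`` via a softmax evaluated at
the final encounter second:

    P(accept) = 1 / (1 + exp(beta0 - beta1 * (r_i - c_i)))

``beta0 > 0`` biases toward rejecting; ``beta1`` scales value sensitivity.
``rho`` is initialised to the session's average accept-everything reward rate
and carries across blocks without resetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from . import _kernels
from .task import (
    EnvironmentSpec,
    OfferPlan,
    SessionDesign,
    accept_all_rate,
    build_session,
    session_environments,
)

__all__ = [
    "SubjectParams",
    "UpdateStep",
    "RateTrace",
    "TrialRecord",
    "TrialLog",
    "ReplayResult",
    "PARAM_NAMES",
    "opportunity_cost",
    "rate_update",
    "reward_second_update",
    "accept_probability",
    "initial_rate",
    "simulate_subject",
    "replay_loglik",
    "to_transformed",
    "params_from_transformed",
    "free_trial_earnings",
]

MODELS = ("symmetric", "asymmetric")

#: Parameter names per model, in transformed-vector order.
PARAM_NAMES = {
    "symmetric": ("alpha", "beta0", "beta1"),
    "asymmetric": ("alpha_pos", "alpha_neg", "beta0", "beta1"),
}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectParams:
    """Model parameters for one subject.

    Learning rates live in (0, 1); ``beta0``/``beta1`` are unconstrained.
    An asymmetric parameter set with alpha_pos == alpha_neg reproduces the
    symmetric model exactly (the models are nested).
    """

    model: str
    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None
    beta0: float = 0.0
    beta1: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ModelError(f"unknown model {self.model!r}")
        if self.model == "symmetric":
            if self.alpha is None:
                raise ModelError("symmetric model requires alpha")
            rates = (self.alpha,)
        else:
            if self.alpha_pos is None or self.alpha_neg is None:
                raise ModelError("asymmetric model requires alpha_pos and alpha_neg")
            rates = (self.alpha_pos, self.alpha_neg)
        for a in rates:
            if not 0.0 < a < 1.0:
                raise ModelError(f"learning rate {a} outside (0, 1)")

    @property
    def a_pos(self) -> float:
        """Learning rate applied on reward seconds (r_t > 0)."""
        return self.alpha if self.model == "symmetric" else self.alpha_pos

    @property
    def a_neg(self) -> float:
        """Learning rate applied on zero-reward seconds."""
        return self.alpha if self.model == "symmetric" else self.alpha_neg

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES[self.model]}


def to_transformed(params: SubjectParams) -> np.ndarray:
    """Map to the unconstrained fitting space: logit for rates, identity for betas."""
    out = []
    for name in PARAM_NAMES[params.model]:
        v = getattr(params, name)
        out.append(float(logit(v)) if name.startswith("alpha") else float(v))
    return np.array(out)


def params_from_transformed(model: str, theta: Sequence[float]) -> SubjectParams:
    names = PARAM_NAMES[model]
    if len(theta) != len(names):
        raise ModelError(f"expected {len(names)} parameters for {model}")
    kw = {}
    for name, v in zip(names, theta):
        kw[name] = float(expit(v)) if name.startswith("alpha") else float(v)
    return SubjectParams(model=model, **kw)


@dataclass(frozen=True)
class UpdateStep:
    """One delta-rule application."""

    t: int
    r: float
    rho_before: float
    delta: float
    gate: str  # "+" on reward seconds, "-" otherwise
    rho_after: float


@dataclass
class RateTrace:
    """Per-update rho series (two entries share the reward second's t)."""

    t: np.ndarray
    r: np.ndarray
    rho_before: np.ndarray
    delta: np.ndarray
    rho_after: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    @property
    def gate(self) -> np.ndarray:
        return np.where(self.r > 0, "+", "-")

    def steps(self) -> list[UpdateStep]:
        return [
            UpdateStep(int(t), float(r), float(b), float(d), "+" if r > 0 else "-", float(a))
            for t, r, b, d, a in zip(self.t, self.r, self.rho_before, self.delta, self.rho_after)
        ]


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    block: int
    env: str
    option: str
    forced: bool
    forced_direction: str | None
    choice: str  # "accept" | "reject" | "missed"
    reward: float
    t_start: int
    t_end: int


@dataclass
class TrialLog:
    """One subject's full session: the unit of fitting and analysis."""

    subject_id: str
    design: SessionDesign
    records: list[TrialRecord]
    true_params: SubjectParams | None = None
    rho0: float | None = None

    def n_trials(self) -> int:
        return len(self.records)


def opportunity_cost(rho: float, t_i: float) -> float:
    """Cost of the time an option consumes: rho * t_i (points)."""
    if rho < 0:
        raise ModelError("reward-rate estimate must be non-negative")
    if t_i <= 0:
        raise ModelError("handling time must be positive")
    return rho * t_i


def rate_update(rho: float, r_t: float, params: SubjectParams) -> UpdateStep:
    """One delta-rule update; gate selects alpha_pos iff r_t > 0."""
    delta = r_t - rho
    if r_t > 0:
        gate, a = "+", params.a_pos
    else:
        gate, a = "-", params.a_neg
    return UpdateStep(0, r_t, rho, delta, gate, rho + a * delta)


def reward_second_update(
    rho: float,
    r_i: float,
    params: SubjectParams,
    order: str = "delay_first",
) -> tuple[UpdateStep, UpdateStep]:
    """The reward second's two updates: from the delay and from the reward.

    Default order applies the zero-reward (delay) update first; ``order=
    "reward_first"`` swaps them (results are robust to this choice).
    """
    if r_i <= 0:
        raise ModelError("reward_second_update requires a positive reward")
    if order == "delay_first":
        s1 = rate_update(rho, 0.0, params)
        s2 = rate_update(s1.rho_after, r_i, params)
    elif order == "reward_first":
        s1 = rate_update(rho, r_i, params)
        s2 = rate_update(s1.rho_after, 0.0, params)
    else:
        raise ModelError(f"unknown update order {order!r}")
    return s1, s2


def accept_probability(r_i: float, c_i: float, beta0: float, beta1: float) -> float:
    """Softmax acceptance probability, stable for large arguments."""
    return float(expit(beta1 * (r_i - c_i) - beta0))


def initial_rate(design: SessionDesign, policy: str = "accept_all") -> float:
    """Default rho_0: the session's average reward rate, arithmetic across blocks.

    Computed from cycle compositions assuming every offer is accepted (the
    ``accept_all`` policy); other policies are not implemented because the
    initialisation is a convenience, not a process claim.
    """
    if policy != "accept_all":
        raise ModelError(f"unknown initialisation policy {policy!r}")
    envs = session_environments(design)
    return float(np.mean([accept_all_rate(env, design) for env in envs]))


class _TraceBuilder:
    __slots__ = ("t", "r", "before", "delta", "after", "on")

    def __init__(self, on: bool):
        self.on = on
        self.t, self.r, self.before, self.delta, self.after = [], [], [], [], []

    def add(self, t: int, r: float, before: float, after: float) -> None:
        if self.on:
            self.t.append(t)
            self.r.append(r)
            self.before.append(before)
            self.delta.append(r - before)
            self.after.append(after)

    def build(self) -> RateTrace | None:
        if not self.on:
            return None
        return RateTrace(
            np.array(self.t, dtype=np.int64),
            np.array(self.r),
            np.array(self.before),
            np.array(self.delta),
            np.array(self.after),
        )


def _run_session(
    design: SessionDesign,
    params: SubjectParams,
    blocks: list[tuple[EnvironmentSpec, OfferPlan]],
    rho0: float,
    rng: np.random.Generator | None,
    records_in: list[TrialRecord] | None,
    include_forced: bool,
    trace: bool,
    update_during: str,
    update_order: str,
):
    """Shared engine: simulate (rng set) or replay (records_in set).

    Returns (records, per_trial_ll, total_ll, trace, rho_final).  All rho
    arithmetic is the plain delta-rule form so simulate, replay and the jitted
    kernels agree exactly.
    """
    if update_during not in ("all", "handling"):
        raise ModelError(f"unknown update cadence {update_during!r}")
    a_pos, a_neg = params.a_pos, params.a_neg
    beta0, beta1 = params.beta0, params.beta1
    enc_upd = design.encounter_seconds if update_during == "all" else 0
    timeout_upd = design.timeout_seconds if update_during == "all" else 0

    tb = _TraceBuilder(trace)
    rho = rho0
    t = 0
    records: list[TrialRecord] = []
    ll_terms: list[float] = []
    total_ll = 0.0
    rec_iter = iter(records_in) if records_in is not None else None
    trial_idx = 0

    for block_idx, (env, plan) in enumerate(blocks):
        block_elapsed = 0
        offer_iter = iter(plan.offers)
        n_block = (
            sum(1 for r in records_in if r.block == block_idx)
            if records_in is not None
            else None
        )
        n_done = 0
        while True:
            if records_in is not None:
                if n_done >= n_block:
                    break
            elif block_elapsed >= env.duration_seconds:
                break
            offer = next(offer_iter, None)
            if records_in is not None:
                rec = next(rec_iter)
                option_label, forced = rec.option, rec.forced
                forced_dir = rec.forced_direction
            else:
                option_label, forced = offer.option, offer.forced
                forced_dir = offer.forced_direction
            opt = design.options[option_label]
            t_start = t

            for _ in range(design.encounter_seconds):
                if update_during == "all":
                    new = rho + a_neg * (0.0 - rho)
                    tb.add(t, 0.0, rho, new)
                    rho = new
                t += 1

            c = rho * opt.handling_seconds
            p_accept = accept_probability(opt.reward_points, c, beta0, beta1)

            if records_in is not None:
                choice = rec.choice
            elif forced:
                choice = forced_dir
            else:
                choice = "accept" if rng.random() < p_accept else "reject"

            term = math.nan
            if choice != "missed" and (include_forced or not forced):
                p = p_accept if choice == "accept" else 1.0 - p_accept
                # guard log(0) at extreme parameters
                term = math.log(max(p, 1e-300))
                total_ll += term
            ll_terms.append(term)

            reward = 0.0
            if choice == "accept":
                for _ in range(opt.handling_seconds - 1):
                    new = rho + a_neg * (0.0 - rho)
                    tb.add(t, 0.0, rho, new)
                    rho = new
                    t += 1
                # reward second: two updates at the same tick
                if update_order == "delay_first":
                    new = rho + a_neg * (0.0 - rho)
                    tb.add(t, 0.0, rho, new)
                    rho = new
                    new = rho + a_pos * (opt.reward_points - rho)
                    tb.add(t, opt.reward_points, rho, new)
                    rho = new
                elif update_order == "reward_first":
                    new = rho + a_pos * (opt.reward_points - rho)
                    tb.add(t, opt.reward_points, rho, new)
                    rho = new
                    new = rho + a_neg * (0.0 - rho)
                    tb.add(t, 0.0, rho, new)
                    rho = new
                else:
                    raise ModelError(f"unknown update order {update_order!r}")
                t += 1
                reward = opt.reward_points
            elif choice == "missed":
                for _ in range(design.timeout_seconds):
                    if update_during == "all":
                        new = rho + a_neg * (0.0 - rho)
                        tb.add(t, 0.0, rho, new)
                        rho = new
                    t += 1
            elif choice != "reject":
                raise ModelError(f"unknown choice {choice!r}")

            records.append(
                TrialRecord(
                    trial=trial_idx,
                    block=block_idx,
                    env=env.name,
                    option=option_label,
                    forced=forced,
                    forced_direction=forced_dir,
                    choice=choice,
                    reward=reward,
                    t_start=t_start,
                    t_end=t,
                )
            )
            block_elapsed += t - t_start
            trial_idx += 1
            n_done += 1

    return records, np.array(ll_terms), total_ll, tb.build(), rho


def simulate_subject(
    design: SessionDesign,
    params: SubjectParams,
    seed: int | np.random.SeedSequence,
    rho0: float | None = None,
    trace: bool = False,
    update_during: str = "all",
    update_order: str = "delay_first",
    subject_id: str = "sim",
) -> tuple[TrialLog, RateTrace | None]:
    """Simulate one subject's session.

    A 1-s clock advances through encounter, handling and timeout seconds; each
    elapsed second emits a zero-reward update except the final handling second
    of an accepted option, which emits the delay+reward double update.  The
    choice is sampled at the final encounter second; forced trials execute
    their mandated direction.  ``rho`` carries across blocks unreset.  A block
    admits no new trial once its duration has elapsed.  Fully reproducible
    from ``seed``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_plan, ss_choice = ss.spawn(2)
    blocks = build_session(design, ss_plan)
    rng = np.random.default_rng(ss_choice)
    if rho0 is None:
        rho0 = initial_rate(design)
    records, _, _, rate_trace, _ = _run_session(
        design, params, blocks, rho0, rng, None, True, trace, update_during, update_order
    )
    log = TrialLog(subject_id, design, records, true_params=params, rho0=rho0)
    return log, rate_trace


class LogValidationError(ValueError):
    pass


def validate_log(log: TrialLog) -> None:
    """Check time contiguity and per-choice trial durations."""
    design = log.design
    prev_end = None
    for rec in log.records:
        if prev_end is not None and rec.t_start != prev_end:
            raise LogValidationError(
                f"trial {rec.trial}: t_start {rec.t_start} != previous t_end {prev_end}"
            )
        opt = design.options[rec.option]
        if rec.choice == "accept":
            expected = design.encounter_seconds + opt.handling_seconds
        elif rec.choice == "reject":
            expected = design.encounter_seconds
        elif rec.choice == "missed":
            expected = design.encounter_seconds + design.timeout_seconds
        else:
            raise LogValidationError(f"trial {rec.trial}: unknown choice {rec.choice!r}")
        if rec.t_end - rec.t_start != expected:
            raise LogValidationError(
                f"trial {rec.trial}: duration {rec.t_end - rec.t_start} != {expected}"
            )
        prev_end = rec.t_end


@dataclass
class ReplayResult:
    loglik: float
    per_trial: np.ndarray  # NaN where no likelihood term applies
    trace: RateTrace | None
    rho_final: float


_CHOICE_CODE = {"reject": 0, "accept": 1, "missed": 2}


def log_arrays(log: TrialLog, include_forced: bool = False):
    """Flat per-trial arrays consumed by the jitted likelihood kernels."""
    n = len(log.records)
    choice = np.empty(n, dtype=np.int64)
    r_opt = np.empty(n)
    t_opt = np.empty(n)
    include = np.empty(n, dtype=np.bool_)
    for i, rec in enumerate(log.records):
        opt = log.design.options[rec.option]
        choice[i] = _CHOICE_CODE[rec.choice]
        r_opt[i] = opt.reward_points
        t_opt[i] = opt.handling_seconds
        include[i] = include_forced or not rec.forced
    return choice, r_opt, t_opt, include


def replay_loglik(
    log: TrialLog,
    params: SubjectParams,
    rho0: float | None = None,
    include_forced: bool = False,
    trace: bool = False,
    update_during: str = "all",
    update_order: str = "delay_first",
    validate: bool = True,
) -> ReplayResult:
    """Deterministically replay a log and score its choices.

    Rebuilds the rho trajectory from the recorded experience (forced and
    missed trials contribute their elapsed seconds and rewards) and sums
    ``log P(choice)`` over scored trials — free trials always, forced trials
    unless ``include_forced=False``, missed trials never.  Pure function of
    its inputs.
    """
    if validate:
        validate_log(log)
    if rho0 is None:
        rho0 = log.rho0 if log.rho0 is not None else initial_rate(log.design)
    if trace:
        blocks = [(env, OfferPlan(env.name, ())) for env in session_environments(log.design)]
        _, per_trial, total, rate_trace, rho_final = _run_session(
            log.design, params, blocks, rho0, None, log.records,
            include_forced, True, update_during, update_order,
        )
        return ReplayResult(total, per_trial, rate_trace, rho_final)

    choice, r_opt, t_opt, include = log_arrays(log, include_forced)
    enc_upd = log.design.encounter_seconds if update_during == "all" else 0
    timeout_upd = log.design.timeout_seconds if update_during == "all" else 0
    out = np.empty(len(choice))
    total, rho_final = _kernels.loglik_pertrial(
        choice, r_opt, t_opt, include, enc_upd, timeout_upd, True,
        params.a_pos, params.a_neg, params.beta0, params.beta1, rho0,
        0 if update_order == "delay_first" else 1, out,
    )
    return ReplayResult(float(total), out, None, float(rho_final))


def free_trial_earnings(log: TrialLog) -> float:
    """Points earned on free (non-forced) trials."""
    return float(sum(r.reward for r in log.records if not r.forced))
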