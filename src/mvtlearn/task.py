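"""Prey-selection task structure and Marginal Value Theorem (MVT) solutions.

The task presents a serial stream of four prey types ("options") that differ in
reward (20 or 80 points) and handling time (2 or 8 s, the last second of which
displays the reward).  Options are offered in shuffled 7-trial cycles whose
composition defines the environment: a *rich* environment where the best option
(low delay, high reward) appears four times per cycle, a *poor* environment
where the worst option dominates, and a degenerate single-option environment
used as a third block in one experiment.  A quarter of trials are forced
choices (attention checks).

This module owns the static design — options, environments, session block
structure, offer plans — and the normative MVT policy: accept option *i* iff
``r_i >= rho* * t_i`` where ``rho*`` is the long-run reward rate achieved by
the optimal acceptance set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "OptionSpec",
    "EnvironmentSpec",
    "SessionDesign",
    "Offer",
    "OfferPlan",
    "PolicySolution",
    "DEFAULT_OPTIONS",
    "OPTION_LABELS",
    "profitability",
    "rich_environment",
    "poor_environment",
    "hdlr_environment",
    "session_environments",
    "build_offer_plan",
    "build_session",
    "mvt_optimal_policy",
    "accept_all_rate",
]

OPTION_LABELS = ("LDHR", "LDLR", "HDHR", "HDLR")


class InvalidSpecError(ValueError):
    """Raised when a task specification violates its invariants."""


@dataclass(frozen=True)
class OptionSpec:
    """One prey type: reward in points and handling time in seconds.

    Handling time includes the 1-s reward display at its end.
    """

    label: str
    reward_points: float
    handling_seconds: int

    def __post_init__(self) -> None:
        if self.handling_seconds <= 0:
            raise InvalidSpecError(
                f"handling_seconds must be positive, got {self.handling_seconds}"
            )


#: The four canonical options: low/high delay x low/high reward.
DEFAULT_OPTIONS: Mapping[str, OptionSpec] = {
    "LDHR": OptionSpec("LDHR", 80.0, 2),
    "LDLR": OptionSpec("LDLR", 20.0, 2),
    "HDHR": OptionSpec("HDHR", 80.0, 8),
    "HDLR": OptionSpec("HDLR", 20.0, 8),
}


def profitability(option: OptionSpec) -> float:
    """Reward per second of handling (points/s).

    The two intermediate options (LDLR, HDHR) share a profitability of
    10 points/s, which is what makes them the diagnostic pair for
    environment-sensitive choice.
    """
    if option.handling_seconds <= 0:
        raise InvalidSpecError("handling time must be positive")
    return option.reward_points / option.handling_seconds


@dataclass(frozen=True)
class EnvironmentSpec:
    """A block type: offer-cycle composition and block duration."""

    name: str
    cycle_composition: Mapping[str, int]
    duration_seconds: int

    def __post_init__(self) -> None:
        if self.duration_seconds <= 0:
            raise InvalidSpecError("duration must be positive")
        if not self.cycle_composition:
            raise InvalidSpecError("environment has an empty cycle")
        for label, n in self.cycle_composition.items():
            if label not in DEFAULT_OPTIONS:
                raise InvalidSpecError(f"unknown option label {label!r}")
            if n < 0:
                raise InvalidSpecError("cycle counts must be non-negative")
        if self.cycle_length == 0:
            raise InvalidSpecError("environment has an empty cycle")

    @property
    def cycle_length(self) -> int:
        return sum(self.cycle_composition.values())


def rich_environment(duration_seconds: int) -> EnvironmentSpec:
    """Best option four times per 7-trial cycle, each other option once."""
    return EnvironmentSpec(
        "rich", {"LDHR": 4, "LDLR": 1, "HDHR": 1, "HDLR": 1}, duration_seconds
    )


def poor_environment(duration_seconds: int) -> EnvironmentSpec:
    """Worst option four times per 7-trial cycle, each other option once."""
    return EnvironmentSpec(
        "poor", {"LDHR": 1, "LDLR": 1, "HDHR": 1, "HDLR": 4}, duration_seconds
    )


def hdlr_environment(duration_seconds: int) -> EnvironmentSpec:
    """Degenerate environment offering only the worst option."""
    return EnvironmentSpec("hdlr_only", {"HDLR": 1}, duration_seconds)


_EXPERIMENT_DURATIONS = {"exp1": 900, "exp2": 600, "exp3": 600}
_ORDERS = ("RichPoor", "PoorRich")


@dataclass(frozen=True)
class SessionDesign:
    """Session structure: experiment variant, block order and trial timing.

    ``experiment`` selects block count and default durations: exp1 = two
    15-min blocks, exp2 = two 10-min blocks, exp3 = three 10-min blocks with
    the single-option block inserted between rich and poor.
    ``duration_seconds`` overrides the per-block duration (e.g. for reduced
    test runs); ``None`` keeps the experiment's default.
    """

    experiment: str = "exp1"
    order: str = "RichPoor"
    encounter_seconds: int = 2
    forced_fraction: float = 0.25
    timeout_seconds: int = 8
    forced_accept_prob: float = 0.5
    duration_seconds: int | None = None
    options: Mapping[str, OptionSpec] = field(default_factory=lambda: DEFAULT_OPTIONS)

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENT_DURATIONS:
            raise InvalidSpecError(f"unknown experiment tag {self.experiment!r}")
        if self.order not in _ORDERS:
            raise InvalidSpecError(f"unknown block order {self.order!r}")
        if not 0.0 <= self.forced_fraction <= 1.0:
            raise InvalidSpecError("forced_fraction must be in [0, 1]")
        if self.encounter_seconds <= 0:
            raise InvalidSpecError("encounter_seconds must be positive")

    @property
    def block_duration(self) -> int:
        if self.duration_seconds is not None:
            return int(self.duration_seconds)
        return _EXPERIMENT_DURATIONS[self.experiment]


def session_environments(design: SessionDesign) -> list[EnvironmentSpec]:
    """The ordered block environments for a design."""
    d = design.block_duration
    rich, poor = rich_environment(d), poor_environment(d)
    first, second = (rich, poor) if design.order == "RichPoor" else (poor, rich)
    if design.experiment == "exp3":
        return [first, hdlr_environment(d), second]
    return [first, second]


@dataclass(frozen=True)
class Offer:
    """One planned encounter: which option, and whether the choice is forced."""

    option: str
    forced: bool = False
    forced_direction: str | None = None  # "accept" | "reject" when forced


@dataclass(frozen=True)
class OfferPlan:
    env_name: str
    offers: tuple[Offer, ...]


def build_offer_plan(
    env: EnvironmentSpec,
    design: SessionDesign,
    seed: int | np.random.Generator,
) -> OfferPlan:
    """Draw an offer stream long enough to fill the block under any policy.

    Offers come in shuffled cycles matching ``env.cycle_composition``.  Forced
    trials follow a deterministic quota: one forced trial, at a uniformly
    random position, in every consecutive window of ``round(1/forced_fraction)``
    trials, so the realised forced fraction is exact over complete windows.
    The forced direction is accept with probability
    ``design.forced_accept_prob``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Fastest possible consumption is reject-everything: one encounter per trial.
    n_needed = math.ceil(env.duration_seconds / design.encounter_seconds) + 1
    n_cycles = math.ceil(n_needed / env.cycle_length)

    base_cycle = [
        label for label, n in sorted(env.cycle_composition.items()) for _ in range(n)
    ]
    labels: list[str] = []
    for _ in range(n_cycles):
        labels.extend(rng.permutation(base_cycle).tolist())

    forced = np.zeros(len(labels), dtype=bool)
    if design.forced_fraction > 0:
        window = max(1, round(1.0 / design.forced_fraction))
        for start in range(0, len(labels) - window + 1, window):
            forced[start + rng.integers(window)] = True

    offers = []
    for lab, is_forced in zip(labels, forced):
        direction = None
        if is_forced:
            direction = (
                "accept" if rng.random() < design.forced_accept_prob else "reject"
            )
        offers.append(Offer(lab, bool(is_forced), direction))
    return OfferPlan(env.name, tuple(offers))


def build_session(
    design: SessionDesign, seed: int | np.random.SeedSequence
) -> list[tuple[EnvironmentSpec, OfferPlan]]:
    """Ordered (environment, offer plan) blocks for one subject's session."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    envs = session_environments(design)
    children = ss.spawn(len(envs))
    return [
        (env, build_offer_plan(env, design, np.random.default_rng(child)))
        for env, child in zip(envs, children)
    ]


@dataclass(frozen=True)
class PolicySolution:
    """An acceptance set and the long-run reward rate it achieves."""

    accept_set: frozenset[str]
    long_run_rate: float


def _policy_rate(
    env: EnvironmentSpec, design: SessionDesign, accept: frozenset[str]
) -> float:
    reward = 0.0
    time = 0.0
    for label, n in env.cycle_composition.items():
        opt = design.options[label]
        time += n * design.encounter_seconds
        if label in accept:
            reward += n * opt.reward_points
            time += n * opt.handling_seconds
    return reward / time


def mvt_optimal_policy(env: EnvironmentSpec, design: SessionDesign) -> PolicySolution:
    """Exhaustively find the acceptance set maximising long-run reward rate.

    All ``2^k`` acceptance subsets of the options present in the environment
    are enumerated; the returned set is the MVT-consistent one
    ``{i : r_i >= rho* t_i}`` (ties accepted) where ``rho*`` is the maximal
    rate.  A consistency violation would indicate a broken rate computation
    and raises.
    """
    present = [lab for lab, n in env.cycle_composition.items() if n > 0]
    if not present:
        raise InvalidSpecError("environment offers no options")
    best_rate = max(
        _policy_rate(env, design, frozenset(subset))
        for k in range(len(present) + 1)
        for subset in itertools.combinations(present, k)
    )
    accept = frozenset(
        lab
        for lab in present
        if design.options[lab].reward_points >= best_rate * design.options[lab].handling_seconds
    )
    rate = _policy_rate(env, design, accept)
    if not math.isclose(rate, best_rate, rel_tol=1e-12, abs_tol=1e-12):
        raise RuntimeError("MVT consistency check failed")  # pragma: no cover
    return PolicySolution(accept, rate)


def accept_all_rate(env: EnvironmentSpec, design: SessionDesign) -> float:
    """Long-run points/s when every offer is accepted (used to seed rho_0)."""
    return _policy_rate(env, design, frozenset(env.cycle_composition))
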