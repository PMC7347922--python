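"""Synthetic cohorts of virtual foragers.

Subjects' parameters are drawn independently from Gaussian group
distributions in the transformed space (logit for learning rates, identity
for the softmax terms) and each subject is simulated through a full session.
The default group means are the reference group-average estimates for each
experiment variant; between-subject spread has no reference value, so the
beta SDs are backed out of the 95% confidence intervals accompanying those
estimates (sd = SEM * sqrt(N)) and the learning-rate SDs are calibrated so
that roughly 90% of asymmetric draws keep alpha_pos > alpha_neg, the typical
individual-level prevalence of the positive learning bias.  Treat the SDs as
calibrated defaults, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from .model import (
    PARAM_NAMES,
    SubjectParams,
    TrialLog,
    params_from_transformed,
    simulate_subject,
)
from .task import SessionDesign

__all__ = [
    "GroupDistribution",
    "CohortSpec",
    "default_group",
    "sample_params",
    "generate_cohort",
    "REFERENCE_MEANS",
]

#: Reference group-mean parameter estimates (natural space) per experiment,
#: with the 95% CI bounds used to back out between-subject beta SDs.
REFERENCE_MEANS = {
    ("exp1", "symmetric"): {
        "n": 40,
        "alpha": 0.0218,
        "beta0": (0.9855, 0.6755, 1.2954),
        "beta1": (0.076, 0.0701, 0.0819),
    },
    ("exp1", "asymmetric"): {
        "n": 40,
        "alpha_pos": 0.005,
        "alpha_neg": 0.0016,
        "beta0": (-1.8179, -2.571, -1.064),
        "beta1": (0.0748, 0.0660, 0.0837),
    },
    ("exp2", "symmetric"): {
        "n": 38,
        "alpha": 0.0278,
        "beta0": (0.846, 0.5742, 1.1178),
        "beta1": (0.0747, 0.0685, 0.0810),
    },
    ("exp2", "asymmetric"): {
        "n": 38,
        "alpha_pos": 0.0047,
        "alpha_neg": 0.0018,
        "beta0": (-1.4624, -2.1052, -0.8197),
        "beta1": (0.0742, 0.0659, 0.0825),
    },
    ("exp3", "symmetric"): {
        "n": 38,
        "alpha": 0.123,
        "beta0": (0.781, 0.4934, 1.0691),
        "beta1": (0.0751, 0.0655, 0.0848),
    },
    ("exp3", "asymmetric"): {
        "n": 38,
        "alpha_pos": 0.0279,
        "alpha_neg": 0.0152,
        "beta0": (-1.088, -1.6028, -0.5728),
        "beta1": (0.07, 0.0583, 0.0819),
    },
}

#: Logit-space SD for learning rates; calibrated so ~90% of independent
#: (alpha_pos, alpha_neg) draws at the exp1 means preserve alpha_pos > alpha_neg.
ALPHA_LOGIT_SD = 0.63


@dataclass(frozen=True)
class GroupDistribution:
    """Gaussian group-level distribution in transformed parameter space."""

    model: str
    mean: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        names = PARAM_NAMES[self.model]
        if len(self.mean) != len(names) or len(self.sd) != len(names):
            raise ValueError(f"{self.model} model needs {len(names)} means/sds")
        if any(s < 0 for s in self.sd):
            raise ValueError("standard deviations must be non-negative")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.model]

    def mean_params(self) -> SubjectParams:
        """The group mean mapped back to natural space."""
        return params_from_transformed(self.model, np.asarray(self.mean))


def _ci_sd(mean_lo_hi: tuple[float, float, float], n: int) -> float:
    """Between-subject SD from a 95% CI of the mean: sd = SEM * sqrt(n)."""
    _, lo, hi = mean_lo_hi
    sem = (hi - lo) / 2.0 / 1.96
    return sem * math.sqrt(n)


def default_group(experiment: str = "exp1", model: str = "asymmetric") -> GroupDistribution:
    """Default group distribution emulating one experiment's fitted population."""
    try:
        row = REFERENCE_MEANS[(experiment, model)]
    except KeyError:
        raise ValueError(f"no defaults for {(experiment, model)!r}") from None
    n = row["n"]
    mean, sd = [], []
    for name in PARAM_NAMES[model]:
        v = row[name]
        if name.startswith("alpha"):
            mean.append(float(logit(v)))
            sd.append(ALPHA_LOGIT_SD)
        else:
            mean.append(float(v[0]))
            sd.append(_ci_sd(v, n))
    return GroupDistribution(model, tuple(mean), tuple(sd))


def sample_params(
    dist: GroupDistribution, n: int, seed: int | np.random.SeedSequence
) -> list[SubjectParams]:
    """Draw ``n`` independent parameter sets from the group distribution."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    theta = rng.normal(
        loc=np.asarray(dist.mean), scale=np.asarray(dist.sd), size=(n, len(dist.mean))
    )
    return [params_from_transformed(dist.model, row) for row in theta]


@dataclass(frozen=True)
class CohortSpec:
    """A simulated study arm: N subjects split across block orders."""

    n_subjects: int = 40
    experiment: str = "exp1"
    allocation: dict[str, int] = field(
        default_factory=lambda: {"RichPoor": 20, "PoorRich": 20}
    )
    dist: GroupDistribution = field(default_factory=default_group)
    seed: int = 0
    duration_seconds: int | None = None  # per-block override for reduced runs

    def __post_init__(self) -> None:
        if sum(self.allocation.values()) != self.n_subjects:
            raise ValueError("allocation counts must sum to n_subjects")

    def conditions(self) -> list[str]:
        out: list[str] = []
        for order in ("RichPoor", "PoorRich"):
            out.extend([order] * self.allocation.get(order, 0))
        return out


def generate_cohort(spec: CohortSpec) -> list[TrialLog]:
    """Simulate every subject in the cohort.

    Seeding: the master seed spawns one child stream for the parameter draws
    and one per subject (subject index fixed by position), so cohorts are
    reproducible and subjects independent.  Each log carries its ground-truth
    parameters for recovery studies.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects + 1)
    params = sample_params(spec.dist, spec.n_subjects, children[0])
    conditions = spec.conditions()
    logs = []
    for i, (cond, p) in enumerate(zip(conditions, params)):
        design = SessionDesign(
            experiment=spec.experiment,
            order=cond,
            duration_seconds=spec.duration_seconds,
        )
        log, _ = simulate_subject(
            design, p, children[i + 1], subject_id=f"sub{i:03d}"
        )
        logs.append(log)
    return logs
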