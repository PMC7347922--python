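"""Serialization: trial-log CSV dialect and cohort manifests.

Trial logs are tidy CSV, one row per trial, with the columns
``subject, experiment, order, block, env, trial, option, forced, forced_dir,
choice, reward, t_start, t_end`` (times in integer seconds).  A cohort is a
trials CSV plus a JSON manifest holding what the CSV cannot carry: per-subject
condition, seed material, ground-truth parameters and the session design.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model import SubjectParams, TrialLog, TrialRecord
from .task import SessionDesign

__all__ = [
    "TRIAL_COLUMNS",
    "logs_to_frame",
    "frame_to_logs",
    "write_cohort",
    "read_cohort",
]

TRIAL_COLUMNS = [
    "subject",
    "experiment",
    "order",
    "block",
    "env",
    "trial",
    "option",
    "forced",
    "forced_dir",
    "choice",
    "reward",
    "t_start",
    "t_end",
]


def logs_to_frame(logs: list[TrialLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for rec in log.records:
            rows.append(
                (
                    log.subject_id,
                    log.design.experiment,
                    log.design.order,
                    rec.block,
                    rec.env,
                    rec.trial,
                    rec.option,
                    int(rec.forced),
                    rec.forced_direction or "",
                    rec.choice,
                    rec.reward,
                    rec.t_start,
                    rec.t_end,
                )
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_logs(
    df: pd.DataFrame,
    duration_seconds: int | None = None,
    designs: dict[str, SessionDesign] | None = None,
) -> list[TrialLog]:
    """Rebuild trial logs from the CSV dialect.

    ``designs`` (per subject) takes precedence; otherwise a design is built
    from the experiment/order columns with ``duration_seconds`` override.
    """
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    logs = []
    for subject, sub in df.groupby("subject", sort=False):
        sub = sub.sort_values("trial")
        if designs and str(subject) in designs:
            design = designs[str(subject)]
        else:
            design = SessionDesign(
                experiment=str(sub["experiment"].iloc[0]),
                order=str(sub["order"].iloc[0]),
                duration_seconds=duration_seconds,
            )
        records = [
            TrialRecord(
                trial=int(r.trial),
                block=int(r.block),
                env=str(r.env),
                option=str(r.option),
                forced=bool(r.forced),
                forced_direction=(str(r.forced_dir) or None) if r.forced else None,
                choice=str(r.choice),
                reward=float(r.reward),
                t_start=int(r.t_start),
                t_end=int(r.t_end),
            )
            for r in sub.itertuples()
        ]
        logs.append(TrialLog(str(subject), design, records))
    return logs


def write_cohort(logs: list[TrialLog], out_dir: str | Path) -> None:
    """Write trials.csv plus manifest.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logs_to_frame(logs).to_csv(out / "trials.csv", index=False)
    manifest = []
    for log in logs:
        entry: dict = {
            "subject": log.subject_id,
            "experiment": log.design.experiment,
            "order": log.design.order,
            "duration_seconds": log.design.duration_seconds,
            "rho0": log.rho0,
        }
        if log.true_params is not None:
            entry["model"] = log.true_params.model
            entry["true_params"] = log.true_params.as_dict()
        manifest.append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(in_dir: str | Path) -> list[TrialLog]:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    src = Path(in_dir)
    df = pd.read_csv(src / "trials.csv", keep_default_na=False)
    manifest = {
        e["subject"]: e for e in json.loads((src / "manifest.json").read_text())
    }
    designs = {
        s: SessionDesign(
            experiment=e["experiment"],
            order=e["order"],
            duration_seconds=e["duration_seconds"],
        )
        for s, e in manifest.items()
    }
    logs = frame_to_logs(df, designs=designs)
    for log in logs:
        entry = manifest.get(log.subject_id)
        if entry is None:
            continue
        log.rho0 = entry.get("rho0")
        if "true_params" in entry:
            log.true_params = SubjectParams(model=entry["model"], **entry["true_params"])
    return logs
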