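"""CSV serialization of trial records, subject parameters and fit results.

The trial CSV is UTF-8, comma-separated, one header row, empty string for
missing values; it round-trips losslessly through
:func:`write_trials` / :func:`read_trials`, and reads are schema-validated
with line-numbered diagnostics.
"""

from __future__ import annotations

import csv
from typing import Iterable, Sequence

from .agent_simulation import SimulatedSubject
from .model_fitting import FitResult
from .records import MAX_OPTIONS, TrialRecord
from .task_design import PHASES
from .value_models import AgentParameters, ValueState

TRIAL_COLUMNS = (
    ["subject_id", "experiment_id", "phase", "trial_index", "context_id"]
    + [f"option{i}" for i in range(1, MAX_OPTIONS + 1)]
    + [f"available{i}" for i in range(1, MAX_OPTIONS + 1)]
    + ["forced", "choice"]
    + [f"outcome{i}" for i in range(1, MAX_OPTIONS + 1)]
    + ["rating"]
)

PARAM_COLUMNS = ["alpha_c", "alpha_u", "beta", "omega", "omega_c", "omega_u"]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_trials(records: Iterable[TrialRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for r in records:
            opts = list(r.option_ids) + [None] * (MAX_OPTIONS - len(r.option_ids))
            avail = list(r.available) + [None] * (MAX_OPTIONS - len(r.available))
            outs = list(r.outcomes or [None] * len(r.option_ids))
            outs += [None] * (MAX_OPTIONS - len(outs))
            writer.writerow(
                [_fmt(v) for v in (r.subject_id, r.experiment_id, r.phase,
                                   r.trial_index, r.context_id)]
                + [_fmt(v) for v in opts]
                + [_fmt(v) for v in avail]
                + [_fmt(r.forced), _fmt(r.choice)]
                + [_fmt(v) for v in outs]
                + [_fmt(r.rating)]
            )


class TrialFileError(ValueError):
    """Raised for malformed trial CSV rows, with the offending line number."""


def _parse_row(row: dict[str, str], line: int) -> TrialRecord:
    def fail(msg: str):
        raise TrialFileError(f"line {line}: {msg}")

    phase = row["phase"]
    if phase not in PHASES:
        fail(f"unknown phase {phase!r}")
    option_ids = tuple(
        row[f"option{i}"] for i in range(1, MAX_OPTIONS + 1) if row[f"option{i}"]
    )
    if not option_ids:
        fail("no options on trial")
    available = tuple(
        row[f"available{i}"] == "1"
        for i in range(1, MAX_OPTIONS + 1)
        if row[f"option{i}"]
    )
    outcomes = tuple(
        float(row[f"outcome{i}"]) if row[f"outcome{i}"] else None
        for i in range(1, MAX_OPTIONS + 1)
        if row[f"option{i}"]
    )
    rating = float(row["rating"]) if row["rating"] else None
    if rating is not None and not 0.0 <= rating <= 100.0:
        fail(f"rating {rating} outside [0, 100]")
    choice = row["choice"] or None
    forced = row["forced"] == "1"
    if choice is not None and choice not in option_ids:
        fail(f"choice {choice!r} not among options {option_ids}")
    if phase == "learning" and not forced and choice is None:
        fail("free learning trial without a choice")
    if phase == "learning" and choice is not None:
        pos = option_ids.index(choice)
        if not available[pos]:
            fail(f"chosen option {choice!r} is marked unavailable")
    if phase == "explicit" and choice is not None:
        fail("explicit trials carry a rating, not a choice")
    try:
        trial_index = int(row["trial_index"])
    except ValueError:
        fail(f"bad trial_index {row['trial_index']!r}")
    try:
        return TrialRecord(
            subject_id=row["subject_id"],
            experiment_id=row["experiment_id"],
            phase=phase,
            trial_index=trial_index,
            context_id=row["context_id"] or None,
            option_ids=option_ids,
            available=available,
            forced=forced,
            choice=choice,
            outcomes=outcomes,
            rating=rating,
        )
    except ValueError as e:
        fail(str(e))


def read_trials(path) -> list[TrialRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRIAL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise TrialFileError(f"missing columns: {sorted(missing)}")
        for line, row in enumerate(reader, start=2):
            records.append(_parse_row(row, line))
    return records


def write_parameters(subjects: Iterable[SimulatedSubject], path) -> None:
    """Subject-level truth table: one row per simulated agent."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "model_id"] + PARAM_COLUMNS)
        for s in subjects:
            p = s.true_parameters.as_dict()
            writer.writerow(
                [s.subject_id, s.model_id] + [_fmt(p[c]) for c in PARAM_COLUMNS]
            )


def write_fit_results(fits: Iterable[FitResult], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["subject_id", "model_id"]
            + PARAM_COLUMNS
            + ["learning_loglik", "oos_loglik", "n_restarts_used", "converged"]
        )
        for f in fits:
            p = f.parameters.as_dict()
            writer.writerow(
                [f.subject_id, f.model_id]
                + [_fmt(p[c]) for c in PARAM_COLUMNS]
                + [
                    repr(f.learning_loglik),
                    "" if f.oos_loglik is None else repr(f.oos_loglik),
                    f.n_restarts_used,
                    _fmt(f.converged),
                ]
            )


def read_fit_results(path) -> list[FitResult]:
    """Read a fit-result table (final Q-values are not serialized)."""
    fits = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            params = AgentParameters(
                **{
                    c: (float(row[c]) if row[c] else None)
                    for c in PARAM_COLUMNS
                    if c in ("alpha_c", "alpha_u", "beta") or row[c]
                }
            )
            fits.append(
                FitResult(
                    subject_id=row["subject_id"],
                    model_id=row["model_id"],
                    parameters=params,
                    learning_loglik=float(row["learning_loglik"]),
                    final_q=ValueState({}),
                    oos_loglik=float(row["oos_loglik"]) if row["oos_loglik"] else None,
                    n_restarts_used=int(row["n_restarts_used"]),
                    converged=row["converged"] == "1",
                )
            )
    return fits
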