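"""Behavioral summary metrics.

Three readouts of learning, mirroring the study's analysis variables:
the correct choice rate in the learning phase (choices of the
highest-valued *available* option), the per-option choice rate in the
transfer phase (times chosen over times presented — this deliberately
does not sum to 1 across options, because each binary choice counts for
two options' scores), and the per-option mean explicit rating with its
deviation from the option's objective mean outcome.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import TrialRecord, split_by_subject
from .task_design import ExperimentDesign


def correct_choice_rate(
    trials: Iterable[TrialRecord], design: ExperimentDesign
) -> tuple[dict[str, float | None], float | None]:
    """Per-context and overall correct choice rate on free learning trials.

    Correctness is scored against the highest-mean option among the
    options *available* on the trial (on trials where the best option is
    masked, choosing the best available option counts as correct).
    Contexts with no eligible trials report ``None``, not 0.
    """
    means = {o: s.mean_outcome for o, s in design.options_by_id.items()}
    counts: dict[str, list[int]] = {c.context_id: [0, 0] for c in design.contexts}
    for rec in trials:
        if rec.phase != "learning" or rec.forced or rec.choice is None:
            continue
        avail = [o for o, a in zip(rec.option_ids, rec.available) if a]
        best = max(avail, key=lambda o: means[o])
        tally = counts[rec.context_id]
        tally[1] += 1
        if rec.choice == best:
            tally[0] += 1
    per_context = {
        ctx: (hit / n if n else None) for ctx, (hit, n) in counts.items()
    }
    total_hit = sum(hit for hit, _ in counts.values())
    total_n = sum(n for _, n in counts.values())
    overall = total_hit / total_n if total_n else None
    return per_context, overall


def transfer_choice_rate(trials: Iterable[TrialRecord]) -> dict[str, float]:
    """Times chosen / times presented, per option, over transfer trials.

    Options never presented are simply absent from the result.
    """
    chosen: dict[str, int] = {}
    presented: dict[str, int] = {}
    for rec in trials:
        if rec.phase != "transfer" or rec.choice is None:
            continue
        for opt in rec.option_ids:
            presented[opt] = presented.get(opt, 0) + 1
        chosen[rec.choice] = chosen.get(rec.choice, 0) + 1
    return {opt: chosen.get(opt, 0) / n for opt, n in presented.items()}


def explicit_summary(
    trials: Iterable[TrialRecord], design: ExperimentDesign
) -> pd.DataFrame:
    """Per-option mean explicit rating and its deviation from the
    objective mean outcome."""
    means = {o: s.mean_outcome for o, s in design.options_by_id.items()}
    ratings: dict[str, list[float]] = {}
    for rec in trials:
        if rec.phase != "explicit" or rec.rating is None:
            continue
        ratings.setdefault(rec.option_ids[0], []).append(rec.rating)
    rows = [
        {
            "option_id": opt,
            "mean_rating": float(np.mean(vals)),
            "objective_mean": means[opt],
            "deviation": float(np.mean(vals)) - means[opt],
        }
        for opt, vals in sorted(ratings.items())
    ]
    return pd.DataFrame(rows)


def cohort_summary(
    records: Iterable[TrialRecord], design: ExperimentDesign
) -> pd.DataFrame:
    """Tidy per-subject and cohort-mean summary of all three metrics.

    One row per (subject, metric, key); the cohort mean appears under
    subject_id ``__cohort__``.
    """
    rows: list[dict] = []
    by_subject = split_by_subject(records)
    for subject_id, recs in sorted(by_subject.items()):
        per_ctx, overall = correct_choice_rate(recs, design)
        for ctx, rate in per_ctx.items():
            if rate is not None:
                rows.append(
                    {
                        "subject_id": subject_id,
                        "metric": "correct_choice_rate",
                        "key": ctx,
                        "value": rate,
                    }
                )
        if overall is not None:
            rows.append(
                {
                    "subject_id": subject_id,
                    "metric": "correct_choice_rate",
                    "key": "overall",
                    "value": overall,
                }
            )
        for opt, rate in sorted(transfer_choice_rate(recs).items()):
            rows.append(
                {
                    "subject_id": subject_id,
                    "metric": "transfer_choice_rate",
                    "key": opt,
                    "value": rate,
                }
            )
        expl = explicit_summary(recs, design)
        for _, r in expl.iterrows():
            rows.append(
                {
                    "subject_id": subject_id,
                    "metric": "mean_rating",
                    "key": r["option_id"],
                    "value": r["mean_rating"],
                }
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "metric": "rating_deviation",
                    "key": r["option_id"],
                    "value": r["deviation"],
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cohort = (
        df.groupby(["metric", "key"], as_index=False)["value"]
        .mean()
        .assign(subject_id="__cohort__")
    )
    return pd.concat([df, cohort], ignore_index=True)[
        ["subject_id", "metric", "key", "value"]
    ]
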