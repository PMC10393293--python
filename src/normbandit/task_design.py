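"""Factorial bandit-task designs and reproducible trial schedules.

The built-in experiments cross the amplitude of the outcome range
(narrow vs. wide) with either the number of options in a context
(binary vs. trinary; Experiments 1 and 2) or the availability of the
highest-mean option (always available vs. masked on a fraction of
trials; Experiment 3).  Every experiment consists of a learning phase
(repeated choices within fixed contexts, with feedback), a transfer
phase (all pairwise combinations of the learned cues, no feedback) and
an explicit-rating phase (each cue alone, no feedback).

Outcomes are points between 0 and 100, drawn from normal distributions
around context-specific means and displayed as integers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

#: Option mean outcomes used by all built-in designs (points).
CANONICAL_MEANS = (14, 32, 50, 68, 86)

#: Outcome noise: distributions have variance 4, i.e. sd 2 points.
DEFAULT_OUTCOME_SD = 2.0

#: Free repetitions of each learning context in the built-in designs.
DEFAULT_REPETITIONS = 45

PHASES = ("learning", "transfer", "explicit")
FEEDBACK_MODES = ("complete", "partial", "none")

BUILTIN_EXPERIMENT_IDS = ("1a", "1b", "1c", "2a", "2b", "2c", "3a", "3b")


@dataclass(frozen=True)
class OptionSpec:
    """One bandit arm: an abstract cue paired with a reward distribution mean."""

    option_id: str
    mean_outcome: float
    context_id: str


@dataclass(frozen=True)
class ContextSpec:
    """A fixed set of 2-3 options always presented together during learning.

    The context defines the normalization frame: on every trial all of
    its options are displayed (even when one is not selectable) and all
    displayed outcomes enter the normalization computations.

    Parameters
    ----------
    unavailable_fraction
        Fraction of this context's free trials on which the highest-mean
        option is displayed but cannot be selected (Experiment 3 only).
    """

    context_id: str
    options: tuple[OptionSpec, ...]
    outcome_sd: float = DEFAULT_OUTCOME_SD
    n_repetitions: int = DEFAULT_REPETITIONS
    unavailable_fraction: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 2 <= len(self.options) <= 3:
            raise ValueError(
                f"context {self.context_id!r} must have 2 or 3 options, "
                f"got {len(self.options)}"
            )
        means = [o.mean_outcome for o in self.options]
        if len(set(means)) != len(means):
            raise ValueError(
                f"context {self.context_id!r} has non-distinct option means {means}"
            )
        if not 0.0 <= self.unavailable_fraction <= 1.0:
            raise ValueError("unavailable_fraction must be in [0, 1]")
        if self.outcome_sd < 0:
            raise ValueError("outcome_sd must be non-negative")

    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(o.option_id for o in self.options)

    @property
    def highest_option(self) -> OptionSpec:
        return max(self.options, key=lambda o: o.mean_outcome)


@dataclass(frozen=True)
class ExperimentDesign:
    """Full protocol: contexts plus forced-trial, transfer and rating plans."""

    experiment_id: str
    contexts: tuple[ContextSpec, ...]
    forced_per_option: int = 0
    forced_feedback: str = "complete"
    free_feedback: str = "complete"
    transfer_reps_per_pair: int = 4
    explicit_reps_per_cue: int = 4

    def __post_init__(self) -> None:
        if self.forced_feedback not in FEEDBACK_MODES:
            raise ValueError(f"unknown feedback mode {self.forced_feedback!r}")
        if self.free_feedback not in FEEDBACK_MODES:
            raise ValueError(f"unknown feedback mode {self.free_feedback!r}")
        ids = [o.option_id for c in self.contexts for o in c.options]
        if len(set(ids)) != len(ids):
            raise ValueError("option_id values must be unique within an experiment")

    @property
    def option_ids(self) -> tuple[str, ...]:
        """All option identifiers, in context order."""
        return tuple(o.option_id for c in self.contexts for o in c.options)

    @property
    def context_by_id(self) -> dict[str, ContextSpec]:
        return {c.context_id: c for c in self.contexts}

    @property
    def options_by_id(self) -> dict[str, OptionSpec]:
        return {o.option_id: o for c in self.contexts for o in c.options}

    @property
    def n_learning_trials(self) -> int:
        free = sum(c.n_repetitions for c in self.contexts)
        return free + self.forced_per_option * len(self.option_ids)

    @property
    def n_transfer_trials(self) -> int:
        k = len(self.option_ids)
        return (k * (k - 1) // 2) * self.transfer_reps_per_pair

    @property
    def n_explicit_trials(self) -> int:
        return len(self.option_ids) * self.explicit_reps_per_cue


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial (before any agent or participant acts on it).

    ``option_ids`` lists the cues displayed on the trial; ``available_mask``
    marks which of them are selectable.  On forced trials only
    ``forced_option`` is selectable.
    """

    phase: str
    index: int
    context_id: str | None
    option_ids: tuple[str, ...]
    available_mask: tuple[bool, ...]
    forced_option: str | None = None
    feedback_mode: str = "complete"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if len(self.available_mask) != len(self.option_ids):
            raise ValueError("available_mask must match option_ids in length")
        if self.phase == "transfer" and len(self.option_ids) != 2:
            raise ValueError("transfer trials present exactly two cues")
        if self.phase == "explicit" and len(self.option_ids) != 1:
            raise ValueError("explicit trials present exactly one cue")
        if self.forced_option is not None:
            if self.forced_option not in self.option_ids:
                raise ValueError("forced_option must be among the trial's options")
            sel = [o for o, a in zip(self.option_ids, self.available_mask) if a]
            if sel != [self.forced_option]:
                raise ValueError("forced_option must be the only selectable option")


# ---------------------------------------------------------------------------
# Built-in designs
# ---------------------------------------------------------------------------


def _make_context(label: str, means: Sequence[int], frac: float = 0.0) -> ContextSpec:
    options = tuple(
        OptionSpec(option_id=f"{label}{m}", mean_outcome=float(m), context_id=label)
        for m in means
    )
    return ContextSpec(
        context_id=label, options=options, unavailable_fraction=frac, label=label
    )


def _exp12_contexts(experiment: int) -> tuple[ContextSpec, ...]:
    if experiment == 1:
        spec = [("NB", (14, 50)), ("NT", (14, 32, 50)), ("WB", (14, 86)), ("WT", (14, 50, 86))]
    else:
        spec = [("NB", (50, 86)), ("NT", (50, 68, 86)), ("WB", (14, 86)), ("WT", (14, 50, 86))]
    return tuple(_make_context(label, means) for label, means in spec)


def _exp3_contexts(frac: float) -> tuple[ContextSpec, ...]:
    # "B" contexts are trinary contexts where the high option is masked on
    # a fraction of trials, turning those trials into binary choices.
    spec = [
        ("NT", (14, 32, 50), 0.0),
        ("NB", (14, 32, 50), frac),
        ("WT", (14, 50, 86), 0.0),
        ("WB", (14, 50, 86), frac),
    ]
    return tuple(_make_context(label, means, f) for label, means, f in spec)


def build_design(experiment_id: str) -> ExperimentDesign:
    """Return one of the eight registered experiment designs.

    Raises
    ------
    ValueError
        If ``experiment_id`` is not one of ``BUILTIN_EXPERIMENT_IDS``.
    """
    eid = str(experiment_id)
    if eid not in BUILTIN_EXPERIMENT_IDS:
        raise ValueError(
            f"unknown experiment id {experiment_id!r}; "
            f"valid ids are {', '.join(BUILTIN_EXPERIMENT_IDS)}"
        )
    family, version = eid[0], eid[1]
    if family in ("1", "2"):
        contexts = _exp12_contexts(int(family))
        forced = 0 if version == "a" else 5
        forced_feedback = "partial" if version == "c" else "complete"
        return ExperimentDesign(
            experiment_id=eid,
            contexts=contexts,
            forced_per_option=forced,
            forced_feedback=forced_feedback,
            transfer_reps_per_pair=4,
            explicit_reps_per_cue=4,
        )
    frac = 0.5 if version == "a" else 0.75
    return ExperimentDesign(
        experiment_id=eid,
        contexts=_exp3_contexts(frac),
        forced_per_option=0,
        transfer_reps_per_pair=2,
        explicit_reps_per_cue=2,
    )


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------


def _unavailable_count(fraction: float, n: int, seed: int, context_pos: int) -> int:
    """Number of trials on which the high option is masked.

    Non-integer targets are rounded to the nearest integer; exact .5 ties
    alternate deterministically with the seed and context position (so 50%
    of 45 realizes as 22 or 23).
    """
    x = fraction * n
    base = math.floor(x)
    frac_part = x - base
    if abs(frac_part - 0.5) < 1e-9:
        return base + (seed + context_pos) % 2
    return int(round(x))


def generate_learning_schedule(design: ExperimentDesign, seed: int) -> list[TrialSpec]:
    """Deterministically shuffled learning-phase schedule.

    Each context contributes exactly ``n_repetitions`` free trials, with
    the stated fraction of them masking the highest-mean option; forced
    trials (``forced_per_option`` per option) are uniformly interleaved.
    """
    rng = np.random.default_rng(seed)
    proto: list[TrialSpec] = []
    for pos, ctx in enumerate(design.contexts):
        n_unavail = _unavailable_count(
            ctx.unavailable_fraction, ctx.n_repetitions, seed, pos
        )
        high_id = ctx.highest_option.option_id
        for rep in range(ctx.n_repetitions):
            if rep < n_unavail:
                mask = tuple(o != high_id for o in ctx.option_ids)
            else:
                mask = tuple(True for _ in ctx.option_ids)
            proto.append(
                TrialSpec(
                    phase="learning",
                    index=0,
                    context_id=ctx.context_id,
                    option_ids=ctx.option_ids,
                    available_mask=mask,
                    feedback_mode=design.free_feedback,
                )
            )
        for opt in ctx.option_ids:
            for _ in range(design.forced_per_option):
                mask = tuple(o == opt for o in ctx.option_ids)
                proto.append(
                    TrialSpec(
                        phase="learning",
                        index=0,
                        context_id=ctx.context_id,
                        option_ids=ctx.option_ids,
                        available_mask=mask,
                        forced_option=opt,
                        feedback_mode=design.forced_feedback,
                    )
                )
    order = rng.permutation(len(proto))
    return [replace(proto[j], index=i) for i, j in enumerate(order)]


def enumerate_transfer_pairs(cue_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered cue pairs in canonical (lexicographic) order."""
    ids = list(cue_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({c for c in ids if ids.count(c) > 1})
        raise ValueError(f"duplicate cue ids: {dupes}")
    if len(ids) < 2:
        raise ValueError("need at least two distinct cues")
    return list(itertools.combinations(sorted(ids), 2))


def generate_transfer_schedule(design: ExperimentDesign, seed: int) -> list[TrialSpec]:
    """Transfer-phase schedule: every pair ``transfer_reps_per_pair`` times.

    No feedback is given in the transfer phase.
    """
    rng = np.random.default_rng(seed)
    pairs = enumerate_transfer_pairs(design.option_ids)
    proto = [
        TrialSpec(
            phase="transfer",
            index=0,
            context_id=None,
            option_ids=pair,
            available_mask=(True, True),
            feedback_mode="none",
        )
        for pair in pairs
        for _ in range(design.transfer_reps_per_pair)
    ]
    order = rng.permutation(len(proto))
    return [replace(proto[j], index=i) for i, j in enumerate(order)]


def generate_explicit_schedule(design: ExperimentDesign, seed: int) -> list[TrialSpec]:
    """Explicit-rating schedule: every cue ``explicit_reps_per_cue`` times."""
    rng = np.random.default_rng(seed)
    proto = [
        TrialSpec(
            phase="explicit",
            index=0,
            context_id=None,
            option_ids=(cue,),
            available_mask=(True,),
            feedback_mode="none",
        )
        for cue in sorted(design.option_ids)
        for _ in range(design.explicit_reps_per_cue)
    ]
    order = rng.permutation(len(proto))
    return [replace(proto[j], index=i) for i, j in enumerate(order)]


def sample_outcome(
    option: OptionSpec, sd: float, rng: np.random.Generator
) -> float:
    """Draw one displayed outcome: normal around the option mean, then
    rounded to the nearest integer and clipped to [0, 100] points."""
    raw = option.mean_outcome if sd == 0 else rng.normal(option.mean_outcome, sd)
    return float(min(100.0, max(0.0, round(raw))))


# ---------------------------------------------------------------------------
# Plain-config serialization
# ---------------------------------------------------------------------------


def design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "experiment_id": design.experiment_id,
        "forced_per_option": design.forced_per_option,
        "forced_feedback": design.forced_feedback,
        "free_feedback": design.free_feedback,
        "transfer_reps_per_pair": design.transfer_reps_per_pair,
        "explicit_reps_per_cue": design.explicit_reps_per_cue,
        "contexts": [
            {
                "context_id": c.context_id,
                "label": c.label,
                "outcome_sd": c.outcome_sd,
                "n_repetitions": c.n_repetitions,
                "unavailable_fraction": c.unavailable_fraction,
                "options": [
                    {"option_id": o.option_id, "mean_outcome": o.mean_outcome}
                    for o in c.options
                ],
            }
            for c in design.contexts
        ],
    }


def design_from_dict(data: Mapping) -> ExperimentDesign:
    contexts = tuple(
        ContextSpec(
            context_id=c["context_id"],
            options=tuple(
                OptionSpec(
                    option_id=o["option_id"],
                    mean_outcome=float(o["mean_outcome"]),
                    context_id=c["context_id"],
                )
                for o in c["options"]
            ),
            outcome_sd=float(c.get("outcome_sd", DEFAULT_OUTCOME_SD)),
            n_repetitions=int(c.get("n_repetitions", DEFAULT_REPETITIONS)),
            unavailable_fraction=float(c.get("unavailable_fraction", 0.0)),
            label=c.get("label", c["context_id"]),
        )
        for c in data["contexts"]
    )
    return ExperimentDesign(
        experiment_id=str(data["experiment_id"]),
        contexts=contexts,
        forced_per_option=int(data.get("forced_per_option", 0)),
        forced_feedback=data.get("forced_feedback", "complete"),
        free_feedback=data.get("free_feedback", "complete"),
        transfer_reps_per_pair=int(data.get("transfer_reps_per_pair", 4)),
        explicit_reps_per_cue=int(data.get("explicit_reps_per_cue", 4)),
    )


def load_designs(path) -> dict[str, ExperimentDesign]:
    """Load user-registered designs from a YAML file (list of documents)."""
    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    designs = [design_from_dict(d) for doc in docs for d in _as_list(doc)]
    return {d.experiment_id: d for d in designs}


def dump_designs(designs: Iterable[ExperimentDesign], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump_all([design_to_dict(d) for d in designs], fh, sort_keys=False)


def _as_list(doc):
    if doc is None:
        return []
    return doc if isinstance(doc, list) else [doc]
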