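"""The per-trial record type shared by the simulator, the fitting code and
the CSV layer.

A :class:`TrialRecord` stores what actually happened on one trial: which
cues were displayed, which were selectable, what was chosen, and which
outcomes were observed (``None`` marks an outcome that was not displayed,
as under partial feedback or in the no-feedback elicitation phases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

MAX_OPTIONS = 3


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    experiment_id: str
    phase: str  # learning | transfer | explicit
    trial_index: int
    context_id: str | None
    option_ids: tuple[str, ...]
    available: tuple[bool, ...]
    forced: bool = False
    choice: str | None = None
    outcomes: tuple[float | None, ...] = ()
    rating: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.option_ids) <= MAX_OPTIONS:
            raise ValueError("a trial displays 1-3 options")
        if len(self.available) != len(self.option_ids):
            raise ValueError("available flags must match option_ids")
        if self.outcomes and len(self.outcomes) != len(self.option_ids):
            raise ValueError("outcomes must match option_ids")
        if self.choice is not None and self.choice not in self.option_ids:
            raise ValueError(
                f"choice {self.choice!r} not among options {self.option_ids}"
            )

    @property
    def chosen_index(self) -> int:
        if self.choice is None:
            raise ValueError("trial has no recorded choice")
        return self.option_ids.index(self.choice)

    @property
    def observed_mask(self) -> tuple[bool, ...]:
        if not self.outcomes:
            return tuple(False for _ in self.option_ids)
        return tuple(o is not None for o in self.outcomes)


def split_by_subject(records: Iterable[TrialRecord]) -> dict[str, list[TrialRecord]]:
    out: dict[str, list[TrialRecord]] = {}
    for r in records:
        out.setdefault(r.subject_id, []).append(r)
    return out


def split_by_phase(records: Iterable[TrialRecord]) -> dict[str, list[TrialRecord]]:
    out: dict[str, list[TrialRecord]] = {"learning": [], "transfer": [], "explicit": []}
    for r in records:
        out.setdefault(r.phase, []).append(r)
    for phase in out:
        out[phase].sort(key=lambda r: r.trial_index)
    return out
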