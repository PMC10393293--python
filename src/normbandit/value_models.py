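"""Outcome-normalization models, delta-rule value updating and decision rules.

Five models of how a displayed outcome R is converted into the subjective
value u(R) that drives learning:

``UNBIASED``
    u(R) = R: outcomes enter learning on their objective 0-100 point scale.
``RANGE``
    u(R) = (R - Rmin) / (Rmax - Rmin), where Rmin/Rmax are the minimum and
    maximum outcomes presented on the current trial (range normalization).
``DIVISIVE``
    u(R) = R / sum of all outcomes presented on the current trial
    (divisive normalization).
``RANGE_W``
    Range normalization followed by an elementwise power transform with
    exponent omega; omega = 1 reduces to RANGE, omega > 1 bends mid
    outcomes toward the contextual minimum.
``RANGE_WPLUS``
    As RANGE_W but with separate exponents for the obtained (chosen,
    omega_c) and forgone (unchosen, omega_u) outcomes.

Learning follows a delta rule with distinct learning rates for the chosen
(alpha_c) and unchosen (alpha_u) options:

    Q <- Q + alpha * (u(R) - Q)

and choices follow a softmax over the Q-values of the selectable options
with inverse temperature beta (an argmax rule with a fair tie-break serves
as the zero-temperature limit used for transfer-phase readouts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .task_design import ExperimentDesign

MODEL_IDS = ("UNBIASED", "DIVISIVE", "RANGE", "RANGE_W", "RANGE_WPLUS")

#: Raw-points fallback used for a never-observed option's "last seen"
#: outcome; it is normalized with the trial's context like any other
#: outcome, and equals the UNBIASED initial value.
RAW_FALLBACK_OUTCOME = 50.0


@dataclass(frozen=True)
class ModelSpec:
    """A model identifier plus the Q initialization it implies."""

    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model id {self.model_id!r}; "
                f"valid ids are {', '.join(MODEL_IDS)}"
            )

    @property
    def q_init(self) -> float:
        """Initial Q: 50 on the raw scale for UNBIASED, 0.5 otherwise."""
        return 50.0 if self.model_id == "UNBIASED" else 0.5

    @property
    def uses_omega(self) -> bool:
        return self.model_id == "RANGE_W"

    @property
    def uses_split_omega(self) -> bool:
        return self.model_id == "RANGE_WPLUS"

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        base = ("alpha_c", "alpha_u", "beta")
        if self.uses_omega:
            return base + ("omega",)
        if self.uses_split_omega:
            return base + ("omega_c", "omega_u")
        return base


@dataclass(frozen=True)
class AgentParameters:
    """Delta-rule and choice parameters for one agent.

    alpha_c, alpha_u in [0, 1]; beta >= 0 (the beta = 0 limit gives
    uniform random choice); omega exponents strictly positive where a
    model uses them.
    """

    alpha_c: float
    alpha_u: float
    beta: float
    omega: float | None = None
    omega_c: float | None = None
    omega_u: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_c", "alpha_u"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        for name in ("omega", "omega_c", "omega_u"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "alpha_c": self.alpha_c,
            "alpha_u": self.alpha_u,
            "beta": self.beta,
            "omega": self.omega,
            "omega_c": self.omega_c,
            "omega_u": self.omega_u,
        }


class ValueState:
    """Learned Q-values keyed by (context_id, option_id), plus the last
    observed raw outcome per option (used under partial feedback)."""

    def __init__(
        self,
        q: Mapping[tuple[str, str], float],
        last_seen: Mapping[str, float] | None = None,
    ) -> None:
        self.q: dict[tuple[str, str], float] = dict(q)
        self.last_seen: dict[str, float] = dict(last_seen or {})

    @classmethod
    def initialize(cls, design: ExperimentDesign, model: ModelSpec) -> "ValueState":
        q = {
            (c.context_id, o.option_id): model.q_init
            for c in design.contexts
            for o in c.options
        }
        return cls(q)

    def copy(self) -> "ValueState":
        return ValueState(self.q, self.last_seen)

    def final_q_by_option(self) -> dict[str, float]:
        """Q per option (each option belongs to exactly one context)."""
        return {opt: v for (_ctx, opt), v in self.q.items()}

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ValueState)
            and self.q == other.q
            and self.last_seen == other.last_seen
        )


def _require_params(model: ModelSpec, params: AgentParameters | None) -> None:
    if model.uses_omega and (params is None or params.omega is None):
        raise ValueError("RANGE_W requires an omega parameter")
    if model.uses_split_omega and (
        params is None or params.omega_c is None or params.omega_u is None
    ):
        raise ValueError("RANGE_WPLUS requires omega_c and omega_u parameters")


def range_normalize(raw_outcomes: np.ndarray) -> np.ndarray:
    """(R - Rmin)/(Rmax - Rmin) over the trial's outcomes; a degenerate
    trial (Rmax == Rmin) maps every outcome to 0.5."""
    raw = np.asarray(raw_outcomes, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def subjective_outcomes(
    model: ModelSpec,
    raw_outcomes: Sequence[float],
    chosen_index: int,
    params: AgentParameters | None = None,
) -> np.ndarray:
    """Subjective values u(R) for every outcome presented on a trial.

    The normalization context is exactly the outcomes in ``raw_outcomes``
    (all displayed options, including masked ones).
    """
    raw = np.asarray(raw_outcomes, dtype=float)
    if not 2 <= raw.size <= 3:
        raise ValueError(f"expected 2 or 3 outcomes, got {raw.size}")
    if not 0 <= chosen_index < raw.size:
        raise ValueError("chosen_index out of range")
    _require_params(model, params)

    if model.model_id == "UNBIASED":
        return raw.copy()
    if model.model_id == "DIVISIVE":
        total = raw.sum()
        if total == 0:
            raise ValueError("divisive normalization undefined: outcomes sum to 0")
        return raw / total
    base = range_normalize(raw)
    if model.model_id == "RANGE":
        return base
    if model.model_id == "RANGE_W":
        return base ** params.omega
    # RANGE_WPLUS
    out = base ** params.omega_u
    out[chosen_index] = base[chosen_index] ** params.omega_c
    return out


def resolve_feedback(
    state: ValueState,
    raw_outcomes: Sequence[float],
    observed_mask: Sequence[bool],
    option_ids: Sequence[str],
) -> np.ndarray:
    """Fill unobserved outcome slots with each option's last seen outcome.

    Options never observed fall back to ``RAW_FALLBACK_OUTCOME``.  The
    state's ``last_seen`` map is then updated in place with every outcome
    observed on this trial.  Entries of ``raw_outcomes`` at unobserved
    positions are ignored (they may be NaN).
    """
    mask = np.asarray(observed_mask, dtype=bool)
    if not mask.any():
        raise ValueError("at least one outcome must be observed")
    raw = np.asarray(raw_outcomes, dtype=float)
    out = raw.copy()
    for i, (opt, seen) in enumerate(zip(option_ids, mask)):
        if not seen:
            out[i] = state.last_seen.get(opt, RAW_FALLBACK_OUTCOME)
    for i, (opt, seen) in enumerate(zip(option_ids, mask)):
        if seen:
            state.last_seen[opt] = float(raw[i])
    return out


def update_values(
    state: ValueState,
    context_id: str,
    option_ids: Sequence[str],
    subjective: Sequence[float],
    chosen_index: int,
    params: AgentParameters,
) -> ValueState:
    """Delta-rule update of every option presented on the trial (in place).

    The chosen (or forced) option moves with ``alpha_c``; all other
    displayed options — including masked, non-selectable ones — move with
    ``alpha_u``.  Options not on the trial are untouched.
    """
    for i, opt in enumerate(option_ids):
        key = (context_id, opt)
        if key not in state.q:
            raise KeyError(f"value state has no entry for {key}")
        alpha = params.alpha_c if i == chosen_index else params.alpha_u
        delta = float(subjective[i]) - state.q[key]
        state.q[key] += alpha * delta
    return state


def softmax_probabilities(
    q_values: Sequence[float],
    beta: float,
    available_mask: Sequence[bool] | None = None,
) -> np.ndarray:
    """Softmax choice probabilities over the available options.

    Unavailable options receive probability 0; the computation is
    numerically stable for arbitrarily large beta.
    """
    q = np.asarray(q_values, dtype=float)
    if available_mask is None:
        mask = np.ones(q.size, dtype=bool)
    else:
        mask = np.asarray(available_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no available option")
    logits = beta * q[mask]
    logits = logits - logits.max()
    expl = np.exp(logits)
    probs = np.zeros(q.size)
    probs[mask] = expl / expl.sum()
    return probs


def log_softmax_probability(
    q_values: Sequence[float],
    beta: float,
    chosen_index: int,
    available_mask: Sequence[bool] | None = None,
) -> float:
    """Log probability of the chosen option under the softmax rule."""
    q = np.asarray(q_values, dtype=float)
    if available_mask is None:
        mask = np.ones(q.size, dtype=bool)
    else:
        mask = np.asarray(available_mask, dtype=bool)
    if not mask[chosen_index]:
        raise ValueError("chosen option is not available")
    logits = beta * q[mask]
    m = logits.max()
    lse = m + np.log(np.exp(logits - m).sum())
    return float(beta * q[chosen_index] - lse)


def argmax_choice_probability(q_a: float, q_b: float) -> float:
    """Probability of choosing the first option under a hard argmax rule:
    1 if its value is higher, 0 if lower, 0.5 on an exact tie."""
    if not (np.isfinite(q_a) and np.isfinite(q_b)):
        raise ValueError("argmax rule requires finite values")
    if q_a > q_b:
        return 1.0
    if q_a < q_b:
        return 0.0
    return 0.5
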