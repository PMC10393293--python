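"""Synthetic cohorts of reinforcement-learning agents.

Agents draw their parameters from the study's priors — Beta(1.1, 1.1)
for the learning rates and Gamma(shape 1.2, scale 5) for the inverse
temperature — then play the learning phase (softmax choices, delta-rule
updates on normalized outcomes), the transfer phase (argmax or softmax
readout of the final Q-values, no learning) and the explicit-rating
phase (noisy report of the final Q-values on the 0-100 slider scale).

Cohort generation is fully reproducible: every agent owns an independent
random substream derived from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import TrialRecord
from .task_design import (
    ExperimentDesign,
    generate_explicit_schedule,
    generate_learning_schedule,
    generate_transfer_schedule,
    sample_outcome,
)
from .value_models import (
    AgentParameters,
    ModelSpec,
    ValueState,
    argmax_choice_probability,
    resolve_feedback,
    softmax_probabilities,
    subjective_outcomes,
    update_values,
)

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class PriorSpec:
    """Parameter priors for ex ante simulation and recovery studies.

    Learning rates ~ Beta(alpha_a, alpha_b); inverse temperature ~
    Gamma(beta_shape, scale=beta_scale) (mean 6 under the defaults);
    omega exponents ~ log-normal(omega_log_mean, omega_log_sd).
    """

    alpha_a: float = 1.1
    alpha_b: float = 1.1
    beta_shape: float = 1.2
    beta_scale: float = 5.0
    omega_log_mean: float = 0.0
    omega_log_sd: float = 0.5

    def sample_alpha(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha_a, self.alpha_b))

    def sample_beta(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.beta_shape, self.beta_scale))

    def sample_omega(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.omega_log_mean, self.omega_log_sd))


@dataclass
class SimulatedSubject:
    subject_id: str
    model_id: str
    true_parameters: AgentParameters
    trials: list[TrialRecord]
    final_state: ValueState

    def phase_trials(self, phase: str) -> list[TrialRecord]:
        return sorted(
            (r for r in self.trials if r.phase == phase), key=lambda r: r.trial_index
        )


def sample_agent_parameters(
    model: ModelSpec, priors: PriorSpec, rng: np.random.Generator
) -> AgentParameters:
    """Independent prior draws for every parameter the model uses."""
    kwargs = {
        "alpha_c": priors.sample_alpha(rng),
        "alpha_u": priors.sample_alpha(rng),
        "beta": priors.sample_beta(rng),
    }
    if model.uses_omega:
        kwargs["omega"] = priors.sample_omega(rng)
    if model.uses_split_omega:
        kwargs["omega_c"] = priors.sample_omega(rng)
        kwargs["omega_u"] = priors.sample_omega(rng)
    return AgentParameters(**kwargs)


def _observed_mask(feedback_mode: str, n: int, chosen_index: int) -> tuple[bool, ...]:
    if feedback_mode == "complete":
        return tuple(True for _ in range(n))
    if feedback_mode == "partial":
        return tuple(i == chosen_index for i in range(n))
    return tuple(False for _ in range(n))


def simulate_learning_phase(
    model: ModelSpec,
    params: AgentParameters,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "agent",
) -> tuple[list[TrialRecord], ValueState]:
    """Play the learning phase and return the trial records and final state.

    On every scheduled trial, outcomes are drawn for all displayed
    options, the choice is sampled from the softmax over the selectable
    options (forced trials bypass the choice), feedback is resolved
    according to the trial's feedback mode, and values are updated.
    """
    rng = np.random.default_rng(seed)
    schedule = generate_learning_schedule(design, int(rng.integers(_MAX_SEED)))
    state = ValueState.initialize(design, model)
    ctx_by_id = design.context_by_id
    records: list[TrialRecord] = []
    for trial in schedule:
        ctx = ctx_by_id[trial.context_id]
        raw = np.array(
            [sample_outcome(o, ctx.outcome_sd, rng) for o in ctx.options]
        )
        q = np.array([state.q[(ctx.context_id, o)] for o in ctx.option_ids])
        if trial.forced_option is not None:
            chosen_index = trial.option_ids.index(trial.forced_option)
        else:
            probs = softmax_probabilities(q, params.beta, trial.available_mask)
            chosen_index = int(rng.choice(len(q), p=probs))
        mask = _observed_mask(trial.feedback_mode, len(raw), chosen_index)
        resolved = resolve_feedback(state, raw, mask, trial.option_ids)
        u = subjective_outcomes(model, resolved, chosen_index, params)
        update_values(state, ctx.context_id, trial.option_ids, u, chosen_index, params)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                experiment_id=design.experiment_id,
                phase="learning",
                trial_index=trial.index,
                context_id=trial.context_id,
                option_ids=trial.option_ids,
                available=trial.available_mask,
                forced=trial.forced_option is not None,
                choice=trial.option_ids[chosen_index],
                outcomes=tuple(
                    float(r) if seen else None for r, seen in zip(raw, mask)
                ),
            )
        )
    return records, state


def simulate_transfer_phase(
    final_state: ValueState,
    design: ExperimentDesign,
    seed: int,
    rule: str = "argmax",
    beta: float | None = None,
    subject_id: str = "agent",
) -> list[TrialRecord]:
    """Decide every scheduled cue pair from the final Q-values.

    ``rule="argmax"`` picks the higher-valued cue, resolving exact ties
    with a fair coin; ``rule="softmax"`` samples with inverse temperature
    ``beta``.  No feedback is given and no learning occurs.
    """
    if rule not in ("argmax", "softmax"):
        raise ValueError(f"unknown transfer rule {rule!r}")
    if rule == "softmax" and beta is None:
        raise ValueError("softmax transfer rule requires beta")
    rng = np.random.default_rng(seed)
    schedule = generate_transfer_schedule(design, int(rng.integers(_MAX_SEED)))
    qf = final_state.final_q_by_option()
    missing = [o for o in design.option_ids if o not in qf]
    if missing:
        raise ValueError(f"final state has no Q-value for cues: {missing}")
    records = []
    for trial in schedule:
        a, b = trial.option_ids
        if rule == "argmax":
            p_a = argmax_choice_probability(qf[a], qf[b])
            choice = a if rng.random() < p_a else b
        else:
            probs = softmax_probabilities([qf[a], qf[b]], beta)
            choice = a if rng.random() < probs[0] else b
        records.append(
            TrialRecord(
                subject_id=subject_id,
                experiment_id=design.experiment_id,
                phase="transfer",
                trial_index=trial.index,
                context_id=None,
                option_ids=trial.option_ids,
                available=(True, True),
                choice=choice,
                outcomes=(None, None),
            )
        )
    return records


def ratings_from_state(
    final_state: ValueState, model: ModelSpec
) -> dict[str, float]:
    """Noise-free slider positions implied by the final Q-values: the raw
    Q for UNBIASED, 100 x Q for the normalized models."""
    qf = final_state.final_q_by_option()
    scale = 1.0 if model.model_id == "UNBIASED" else 100.0
    return {opt: float(np.clip(scale * q, 0.0, 100.0)) for opt, q in qf.items()}


def simulate_explicit_phase(
    final_state: ValueState,
    model: ModelSpec,
    design: ExperimentDesign,
    seed: int,
    rating_noise_sd: float = 5.0,
    subject_id: str = "agent",
) -> list[TrialRecord]:
    """Report each cue's value on the 0-100 slider: the (rescaled) final Q
    plus truncated Gaussian noise, clipped to the slider's range."""
    rng = np.random.default_rng(seed)
    schedule = generate_explicit_schedule(design, int(rng.integers(_MAX_SEED)))
    base = ratings_from_state(final_state, model)
    records = []
    for trial in schedule:
        cue = trial.option_ids[0]
        noise = rng.normal(0.0, rating_noise_sd) if rating_noise_sd > 0 else 0.0
        rating = float(np.clip(base[cue] + noise, 0.0, 100.0))
        records.append(
            TrialRecord(
                subject_id=subject_id,
                experiment_id=design.experiment_id,
                phase="explicit",
                trial_index=trial.index,
                context_id=None,
                option_ids=trial.option_ids,
                available=(True,),
                rating=rating,
                outcomes=(None,),
            )
        )
    return records


def simulate_subject(
    model: ModelSpec,
    params: AgentParameters,
    design: ExperimentDesign,
    seed: int,
    subject_id: str = "agent",
    transfer_rule: str = "argmax",
    rating_noise_sd: float = 5.0,
) -> SimulatedSubject:
    """All three phases for one agent with fixed parameters."""
    rng = np.random.default_rng(seed)
    s_learn, s_trans, s_expl = (int(s) for s in rng.integers(_MAX_SEED, size=3))
    learning, state = simulate_learning_phase(
        model, params, design, s_learn, subject_id
    )
    transfer = simulate_transfer_phase(
        state, design, s_trans, rule=transfer_rule, beta=params.beta,
        subject_id=subject_id,
    )
    explicit = simulate_explicit_phase(
        state, model, design, s_expl, rating_noise_sd, subject_id
    )
    return SimulatedSubject(
        subject_id=subject_id,
        model_id=model.model_id,
        true_parameters=params,
        trials=learning + transfer + explicit,
        final_state=state,
    )


def simulate_cohort(
    model: ModelSpec,
    design: ExperimentDesign,
    n_agents: int,
    priors: PriorSpec | None = None,
    seed: int = 0,
    transfer_rule: str = "argmax",
    rating_noise_sd: float = 5.0,
) -> list[SimulatedSubject]:
    """Simulate ``n_agents`` independent agents with prior-drawn parameters."""
    if n_agents < 1:
        raise ValueError("n_agents must be at least 1")
    priors = priors or PriorSpec()
    master = np.random.default_rng(seed)
    subjects = []
    for i in range(n_agents):
        rng = np.random.default_rng(int(master.integers(_MAX_SEED)))
        params = sample_agent_parameters(model, priors, rng)
        subjects.append(
            simulate_subject(
                model,
                params,
                design,
                seed=int(rng.integers(_MAX_SEED)),
                subject_id=f"sub{i:03d}",
                transfer_rule=transfer_rule,
                rating_noise_sd=rating_noise_sd,
            )
        )
    return subjects


def simulate_choices_from_ratings(
    ratings: Mapping[str, float],
    pairs: Sequence[tuple[str, str]],
) -> dict[str, float]:
    """Expected per-option transfer choice rates implied by explicit ratings.

    Each pair is decided by an argmax rule on the two ratings (exact ties
    count 0.5 for each side); an option's choice rate is its summed win
    probability divided by the number of pairs in which it appears.
    """
    wins: dict[str, float] = {}
    counts: dict[str, int] = {}
    for a, b in pairs:
        for cue in (a, b):
            if cue not in ratings:
                raise ValueError(f"missing rating for cue {cue!r}")
        p_a = argmax_choice_probability(ratings[a], ratings[b])
        wins[a] = wins.get(a, 0.0) + p_a
        wins[b] = wins.get(b, 0.0) + (1.0 - p_a)
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    return {cue: wins[cue] / counts[cue] for cue in wins}
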