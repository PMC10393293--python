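"""Maximum-likelihood fitting on learning-phase choices and out-of-sample
evaluation on transfer-phase choices.

The likelihood replays the learning phase deterministically: the observed
choices and the observed outcomes drive the delta-rule updates (nothing is
resampled), and each free choice contributes the log softmax probability
of the option actually chosen, taken over the options that were selectable
on that trial.  Forced trials contribute value updates but no likelihood
term.  The fitted parameters are then scored, without refitting or further
learning, on the transfer-phase choices: the out-of-sample log-likelihood
that serves as the model-comparison metric.

Optimization is multi-start quasi-Newton (L-BFGS-B) in a transformed
space — learning rates in logit space, inverse temperature and omega
exponents in log space — which keeps the search smooth while respecting
the parameter ranges.  The transfer likelihood uses the softmax with the
fitted beta rather than a hard argmax, which would assign zero probability
to any inconsistent choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .records import TrialRecord, split_by_phase
from .task_design import ExperimentDesign
from .value_models import (
    AgentParameters,
    ModelSpec,
    RAW_FALLBACK_OUTCOME,
    ValueState,
    range_normalize,
)

_LOG_OMEGA_BOUNDS = (-3.0, 3.0)
_LOGIT_ALPHA_BOUNDS = (-8.0, 8.0)
_LOG_BETA_BOUNDS = (-6.0, 7.0)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings: number of restarts (first start at the prior
    means, the rest drawn from the priors), restart RNG seed, and the
    L-BFGS-B iteration cap."""

    n_restarts: int = 20
    seed: int = 0
    maxiter: int = 300


@dataclass
class FitResult:
    subject_id: str
    model_id: str
    parameters: AgentParameters
    learning_loglik: float
    final_q: ValueState
    oos_loglik: float | None = None
    n_restarts_used: int = 0
    converged: bool = False


class _CompiledLearning:
    """Parameter-independent precompilation of a subject's learning phase.

    Feedback resolution (last-seen replacement with the raw fallback for
    never-observed options) and the normalization of each trial's outcome
    vector do not depend on the fitted parameters, so both are computed
    once.  The remaining per-evaluation work is a plain-Python loop over
    small tuples, fast enough for multi-start optimization.
    """

    def __init__(
        self, trials: Sequence[TrialRecord], design: ExperimentDesign, model: ModelSpec
    ) -> None:
        self.model = model
        self.opt_index = {o: i for i, o in enumerate(design.option_ids)}
        self.n_options = len(design.option_ids)
        self.q_init = model.q_init
        self.apply_omega = model.uses_omega or model.uses_split_omega

        ordered = sorted(trials, key=lambda r: r.trial_index)
        last_seen: dict[str, float] = {}
        compiled = []
        n_free = 0
        for rec in ordered:
            if rec.phase != "learning":
                raise ValueError("learning likelihood expects learning-phase trials")
            if rec.choice is None:
                raise ValueError(
                    f"trial {rec.trial_index} has no recorded choice"
                )
            chosen_pos = rec.chosen_index
            resolved = []
            for i, opt in enumerate(rec.option_ids):
                out = rec.outcomes[i] if rec.outcomes else None
                if out is None:
                    resolved.append(last_seen.get(opt, RAW_FALLBACK_OUTCOME))
                else:
                    resolved.append(float(out))
            for i, opt in enumerate(rec.option_ids):
                out = rec.outcomes[i] if rec.outcomes else None
                if out is not None:
                    last_seen[opt] = float(out)
            resolved_arr = np.asarray(resolved, dtype=float)
            if model.model_id == "UNBIASED":
                u_base = tuple(resolved_arr)
            elif model.model_id == "DIVISIVE":
                total = resolved_arr.sum()
                if total == 0:
                    raise ValueError("divisive normalization undefined: sum is 0")
                u_base = tuple(resolved_arr / total)
            else:
                u_base = tuple(range_normalize(resolved_arr))
            is_free = not rec.forced
            avail = tuple(
                p for p, a in enumerate(rec.available) if a
            )
            if is_free:
                n_free += 1
            compiled.append(
                (
                    is_free,
                    tuple(self.opt_index[o] for o in rec.option_ids),
                    chosen_pos,
                    avail,
                    u_base,
                )
            )
        self.trials = compiled
        self.n_free = n_free
        self._design = design

    def negloglik(
        self,
        alpha_c: float,
        alpha_u: float,
        beta: float,
        omega_c: float = 1.0,
        omega_u: float = 1.0,
        return_q: bool = False,
    ):
        q = [self.q_init] * self.n_options
        total = 0.0
        apply_omega = self.apply_omega
        exp = math.exp
        log = math.log
        for is_free, opts, chosen_pos, avail, u_base in self.trials:
            if is_free:
                if len(avail) == 1:
                    pass  # single selectable option: probability 1
                else:
                    logits = [beta * q[opts[p]] for p in avail]
                    m = max(logits)
                    denom = 0.0
                    chosen_logit = None
                    for p, lg in zip(avail, logits):
                        denom += exp(lg - m)
                        if p == chosen_pos:
                            chosen_logit = lg
                    total -= chosen_logit - m - log(denom)
            for p, oi in enumerate(opts):
                u = u_base[p]
                if apply_omega:
                    u = u ** (omega_c if p == chosen_pos else omega_u)
                lr = alpha_c if p == chosen_pos else alpha_u
                q[oi] += lr * (u - q[oi])
        if return_q:
            return total, q
        return total

    def negloglik_params(self, params: AgentParameters, return_q: bool = False):
        oc, ou = 1.0, 1.0
        if self.model.uses_omega:
            oc = ou = params.omega
        elif self.model.uses_split_omega:
            oc, ou = params.omega_c, params.omega_u
        return self.negloglik(
            params.alpha_c, params.alpha_u, params.beta, oc, ou, return_q=return_q
        )

    def final_state(self, params: AgentParameters) -> ValueState:
        _, q = self.negloglik_params(params, return_q=True)
        state = ValueState.initialize(self._design, self.model)
        inv = {i: o for o, i in self.opt_index.items()}
        opt_ctx = {
            o.option_id: c.context_id
            for c in self._design.contexts
            for o in c.options
        }
        for i, v in enumerate(q):
            opt = inv[i]
            state.q[(opt_ctx[opt], opt)] = float(v)
        return state


def learning_negloglik(
    params: AgentParameters,
    model: ModelSpec,
    trials: Sequence[TrialRecord],
    design: ExperimentDesign,
) -> float:
    """Negative log-likelihood of the observed learning-phase free choices."""
    return float(_CompiledLearning(trials, design, model).negloglik_params(params))


def _params_from_vector(model: ModelSpec, x: np.ndarray) -> AgentParameters:
    kwargs = {
        "alpha_c": float(expit(x[0])),
        "alpha_u": float(expit(x[1])),
        "beta": float(np.exp(x[2])),
    }
    if model.uses_omega:
        kwargs["omega"] = float(np.exp(x[3]))
    elif model.uses_split_omega:
        kwargs["omega_c"] = float(np.exp(x[3]))
        kwargs["omega_u"] = float(np.exp(x[4]))
    return AgentParameters(**kwargs)


def _start_points(model: ModelSpec, config: FitConfig) -> list[np.ndarray]:
    n_omega = 1 if model.uses_omega else (2 if model.uses_split_omega else 0)
    rng = np.random.default_rng(config.seed)
    lo_a, hi_a = _LOGIT_ALPHA_BOUNDS
    lo_b, hi_b = _LOG_BETA_BOUNDS
    lo_w, hi_w = _LOG_OMEGA_BOUNDS
    starts = [np.array([0.0, 0.0, np.log(6.0)] + [0.0] * n_omega)]
    for _ in range(max(config.n_restarts - 1, 0)):
        a_c = np.clip(logit(rng.beta(1.1, 1.1)), lo_a, hi_a)
        a_u = np.clip(logit(rng.beta(1.1, 1.1)), lo_a, hi_a)
        b = np.clip(np.log(rng.gamma(1.2, 5.0)), lo_b, hi_b)
        ws = np.clip(rng.normal(0.0, 0.5, size=n_omega), lo_w, hi_w)
        starts.append(np.concatenate([[a_c, a_u, b], ws]))
    return starts


def fit_model(
    model: ModelSpec,
    trials: Sequence[TrialRecord],
    design: ExperimentDesign,
    config: FitConfig | None = None,
    subject_id: str | None = None,
) -> FitResult:
    """Fit one model to one subject's learning-phase trials.

    Returns the best of ``config.n_restarts`` bounded quasi-Newton runs;
    deterministic given the config seed.  A result where every restart
    failed is flagged ``converged=False``.
    """
    config = config or FitConfig()
    trials = [t for t in trials if t.phase == "learning"]
    if not any(not t.forced for t in trials):
        raise ValueError("need at least one free-choice learning trial")
    if subject_id is None:
        subject_id = trials[0].subject_id
    compiled = _CompiledLearning(trials, design, model)

    def objective(x: np.ndarray) -> float:
        return compiled.negloglik_params(_params_from_vector(model, x))

    n_omega = 1 if model.uses_omega else (2 if model.uses_split_omega else 0)
    bounds = (
        [_LOGIT_ALPHA_BOUNDS, _LOGIT_ALPHA_BOUNDS, _LOG_BETA_BOUNDS]
        + [_LOG_OMEGA_BOUNDS] * n_omega
    )
    best_x, best_fun, any_success = None, np.inf, False
    for x0 in _start_points(model, config):
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        any_success = any_success or bool(res.success)
        if res.fun < best_fun:
            best_fun, best_x = float(res.fun), res.x
    params = _params_from_vector(model, best_x)
    return FitResult(
        subject_id=subject_id,
        model_id=model.model_id,
        parameters=params,
        learning_loglik=-best_fun,
        final_q=compiled.final_state(params),
        n_restarts_used=config.n_restarts,
        converged=any_success,
    )


def transfer_oos_loglik(
    fit: FitResult, transfer_trials: Sequence[TrialRecord]
) -> float:
    """Out-of-sample log-likelihood of the transfer-phase choices.

    Each trial contributes the log softmax probability (with the fitted
    beta) of the observed choice given the two cues' final Q-values; no
    learning occurs during the transfer phase.  An empty trial list
    yields 0.
    """
    qf = fit.final_q.final_q_by_option()
    beta = fit.parameters.beta
    total = 0.0
    for rec in transfer_trials:
        if rec.phase != "transfer":
            raise ValueError("expected transfer-phase trials")
        if rec.choice is None:
            raise ValueError(f"transfer trial {rec.trial_index} has no choice")
        try:
            q = [qf[o] for o in rec.option_ids]
        except KeyError as e:
            raise ValueError(f"no fitted Q-value for cue {e.args[0]!r}") from None
        chosen = rec.chosen_index
        # stable two-option log softmax
        other = q[1 - chosen]
        d = beta * (other - q[chosen])
        total -= math.log1p(math.exp(d)) if d < 30 else d
    return float(total)


def evaluate_out_of_sample(
    fit: FitResult, transfer_trials: Sequence[TrialRecord]
) -> FitResult:
    """Return a copy of ``fit`` with ``oos_loglik`` filled in."""
    return dc_replace(fit, oos_loglik=transfer_oos_loglik(fit, transfer_trials))


def fit_subject_records(
    models: Sequence[ModelSpec],
    records: Sequence[TrialRecord],
    design: ExperimentDesign,
    config: FitConfig | None = None,
) -> list[FitResult]:
    """Fit each model to one subject's records and score the transfer phase."""
    phases = split_by_phase(records)
    out = []
    for model in models:
        fit = fit_model(model, phases["learning"], design, config)
        out.append(evaluate_out_of_sample(fit, phases["transfer"]))
    return out
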