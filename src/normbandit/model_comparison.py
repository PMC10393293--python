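"""Cohort-level model comparison, ex post simulation, and parameter /
model recovery.

Models are compared by their out-of-sample log-likelihood: parameters are
fitted on the learning phase only and scored on the transfer phase, so
the comparison needs no explicit complexity penalty.  Recovery studies
validate the pipeline end to end: parameters simulated from the priors
should be recoverable (rank correlation between true and fitted values),
and data generated by each model should be best fit by that same model
(diagonal dominance of the confusion matrix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .agent_simulation import (
    PriorSpec,
    SimulatedSubject,
    simulate_cohort,
    simulate_learning_phase,
    simulate_transfer_phase,
)
from .metrics import transfer_choice_rate
from .model_fitting import FitConfig, FitResult, fit_model, fit_subject_records
from .records import TrialRecord
from .task_design import ExperimentDesign
from .value_models import ModelSpec

_MAX_SEED = 2**31 - 1


@dataclass
class ComparisonTable:
    """Mean, SD, median and n of out-of-sample log-likelihood per model."""

    table: pd.DataFrame  # index: model_id; columns: mean, sd, median, n_subjects

    @property
    def winner(self) -> str:
        return str(self.table["mean"].idxmax())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="model_id")


@dataclass
class RecoveryReport:
    """True-vs-recovered parameter pairs and their summary statistics."""

    model_id: str
    parameters: pd.DataFrame  # columns: subject_id, parameter, true, recovered
    rank_correlation: dict[str, float]
    median_bias: dict[str, float]


@dataclass
class ModelRecoveryResult:
    """Confusion matrix (rows: generating model, columns: best-fitting
    model, fractions of agents) and mean out-of-sample log-likelihood per
    generator x candidate."""

    confusion: pd.DataFrame
    mean_oos: pd.DataFrame


def compare_models(fits: Sequence[FitResult]) -> ComparisonTable:
    """Aggregate out-of-sample log-likelihoods across subjects per model.

    Every subject must be fitted under every model (over the identical
    subject set), otherwise the gaps are reported.
    """
    rows = []
    for f in fits:
        if f.oos_loglik is None:
            raise ValueError(
                f"fit for subject {f.subject_id!r} model {f.model_id!r} "
                "has no out-of-sample log-likelihood"
            )
        rows.append((f.model_id, f.subject_id, f.oos_loglik))
    df = pd.DataFrame(rows, columns=["model_id", "subject_id", "oos_loglik"])
    subject_sets = df.groupby("model_id")["subject_id"].apply(set)
    all_subjects = set(df["subject_id"])
    gaps = {
        m: sorted(all_subjects - s) for m, s in subject_sets.items() if s != all_subjects
    }
    if gaps:
        raise ValueError(f"missing fits for some subjects: {gaps}")
    table = (
        df.groupby("model_id")["oos_loglik"]
        .agg(mean="mean", sd="std", median="median", n_subjects="count")
        .sort_values("mean", ascending=False)
    )
    return ComparisonTable(table)


def ex_post_simulate(
    fits: Sequence[FitResult],
    design: ExperimentDesign,
    n_reps: int = 1,
    seed: int = 0,
    rule: str = "argmax",
) -> pd.DataFrame:
    """Simulate the task with each subject's fitted parameters.

    For every fit and repetition, the learning phase is re-simulated with
    fresh outcome draws and the transfer phase is decided by ``rule`` on
    the resulting final Q-values.  Returns per-option transfer choice
    rates: one row per (repetition, subject), plus the cohort mean row
    ``__cohort__``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        for fit in fits:
            model = ModelSpec(fit.model_id)
            records, state = simulate_learning_phase(
                model,
                fit.parameters,
                design,
                seed=int(rng.integers(_MAX_SEED)),
                subject_id=fit.subject_id,
            )
            transfer = simulate_transfer_phase(
                state,
                design,
                seed=int(rng.integers(_MAX_SEED)),
                rule=rule,
                beta=fit.parameters.beta,
                subject_id=fit.subject_id,
            )
            rates = transfer_choice_rate(transfer)
            rows.append({"rep": rep, "subject_id": fit.subject_id, **rates})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cohort = df.drop(columns=["rep", "subject_id"]).mean()
    cohort_row = {"rep": -1, "subject_id": "__cohort__", **cohort.to_dict()}
    return pd.concat([df, pd.DataFrame([cohort_row])], ignore_index=True)


_PARAM_NAMES = ("alpha_c", "alpha_u", "beta", "omega", "omega_c", "omega_u")


def parameter_recovery(
    model: ModelSpec,
    design: ExperimentDesign,
    n_agents: int,
    priors: PriorSpec | None = None,
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> RecoveryReport:
    """Simulate agents from the priors, refit the same model, and compare
    true with recovered parameters (Spearman rank correlation and median
    recovered-minus-true bias per parameter)."""
    if n_agents < 2:
        raise ValueError("n_agents must be at least 2")
    subjects = simulate_cohort(model, design, n_agents, priors, seed)
    rows = []
    for subj in subjects:
        fit = fit_model(model, subj.phase_trials("learning"), design, fit_config)
        true = subj.true_parameters.as_dict()
        rec = fit.parameters.as_dict()
        for name in model.free_parameter_names:
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "parameter": name,
                    "true": true[name],
                    "recovered": rec[name],
                }
            )
    df = pd.DataFrame(rows)
    corr, bias = {}, {}
    for name, grp in df.groupby("parameter"):
        rho = spearmanr(grp["true"], grp["recovered"]).statistic
        corr[name] = float(rho)
        bias[name] = float(np.median(grp["recovered"] - grp["true"]))
    return RecoveryReport(
        model_id=model.model_id,
        parameters=df,
        rank_correlation=corr,
        median_bias=bias,
    )


def model_recovery(
    models: Sequence[ModelSpec],
    design: ExperimentDesign,
    n_agents_per_model: int,
    priors: PriorSpec | None = None,
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> ModelRecoveryResult:
    """Cross-fit every candidate model to cohorts generated by each model.

    The best-fitting model per agent is the one with the highest
    out-of-sample log-likelihood; confusion rows are fractions and sum
    to 1.
    """
    model_ids = [m.model_id for m in models]
    master = np.random.default_rng(seed)
    confusion = pd.DataFrame(0.0, index=model_ids, columns=model_ids)
    mean_oos = pd.DataFrame(np.nan, index=model_ids, columns=model_ids)
    for gen in models:
        cohort = simulate_cohort(
            gen, design, n_agents_per_model, priors, int(master.integers(_MAX_SEED))
        )
        oos = {m: [] for m in model_ids}
        for subj in cohort:
            fits = fit_subject_records(models, subj.trials, design, fit_config)
            best = max(fits, key=lambda f: f.oos_loglik)
            confusion.loc[gen.model_id, best.model_id] += 1
            for f in fits:
                oos[f.model_id].append(f.oos_loglik)
        for cand in model_ids:
            mean_oos.loc[gen.model_id, cand] = float(np.mean(oos[cand]))
        confusion.loc[gen.model_id] /= n_agents_per_model
    return ModelRecoveryResult(confusion=confusion, mean_oos=mean_oos)
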