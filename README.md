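# normbandit

Context-dependent outcome normalization in human reinforcement learning:
simulation, model fitting, and out-of-sample model comparison for
factorial multi-armed bandit tasks.

## The scientific problem

When people learn option values from experience, the subjective value of
an outcome depends on the other outcomes around it. Two competing
accounts describe how a raw reward *R* (points in [0, 100]) is turned
into the normalized value that drives learning:

- **Range normalization** — the outcome's position within the contextual
  range:  u(R) = (R − R_min) / (R_max − R_min)
- **Divisive normalization** — the outcome divided by the summed context:
  u(R) = R / Σₖ Rₖ

These rules mimic each other in most two-option tasks. They come apart
when the *number* of options varies: only the divisive rule predicts
that adding a third option dilutes everyone's subjective value. The
designs encoded here therefore cross the amplitude of the outcome range
(narrow vs. wide) with the choice set size (binary vs. trinary), or —
in a third family of designs — with the availability of the best option
(masked on half or three-quarters of trials).

Learning follows a delta rule with separate learning rates for the
chosen and unchosen options,

    Q ← Q + α_C/U · (u(R) − Q),

choices follow a softmax with inverse temperature β, and post-learning
preferences are read out in a transfer phase (all pairwise cue
combinations, no feedback) with an argmax rule on the final Q-values.
Two refinements of range normalization are included: a nonlinear
version that raises the normalized outcome to a power ω, and a
conditional version with separate exponents for obtained (ω_c) and
forgone (ω_u) outcomes.

Model comparison is by **out-of-sample log-likelihood**: parameters are
fitted by maximum likelihood on the learning phase only, then scored on
the transfer-phase choices — so no explicit complexity penalty is
needed.

The package is aimed at computational cognitive modellers who want to
simulate these designs, validate fitting pipelines (parameter and model
recovery), or fit the five models (`UNBIASED`, `DIVISIVE`, `RANGE`,
`RANGE_W`, `RANGE_WPLUS`) to trial-level choice data in the documented
CSV schema.

## Worked example

Simulate ten range-normalizing agents on the factorial design, then
cross-fit the three primary models:

```python
import numpy as np
import normbandit as nb
from normbandit.model_fitting import FitConfig

design = nb.build_design("1a")
cohort = nb.simulate_cohort(nb.ModelSpec("RANGE"), design, n_agents=10, seed=7)

rates = {o: np.mean([nb.transfer_choice_rate(s.phase_trials("transfer"))[o]
                     for s in cohort]) for o in design.option_ids}
for opt in sorted(rates, key=rates.get, reverse=True):
    print(f"  {opt:>5}: {rates[opt]:.3f}")

models = [nb.ModelSpec(m) for m in ("UNBIASED", "DIVISIVE", "RANGE")]
config = FitConfig(n_restarts=5, seed=0)
fits = [f for s in cohort
        for f in nb.fit_subject_records(models, s.trials, design, config)]
table = nb.compare_models(fits)
print(table.table.round(2)); print("winner:", table.winner)
```

Output:

```
   NT50: 0.853
   WB86: 0.833
   WT86: 0.828
   NB50: 0.819
   NT32: 0.511
   WT50: 0.489
   WB14: 0.206
   NB14: 0.189
   NT14: 0.172
   WT14: 0.100
            mean       sd  median  n_subjects
model_id
RANGE     -47.97    19.16  -38.79          10
UNBIASED -545.25   988.72  -80.66          10
DIVISIVE -957.10  2060.13  -76.95          10
winner: RANGE
```

The transfer choice rates show the range-normalization signature: all
four contextually-best options (`NB50`, `NT50`, `WB86`, `WT86`) sit at
similar rates (~0.82–0.85) although their objective means differ (50
vs. 86 points) and they come from binary and trinary contexts alike.
The comparison table ranks the generating model first by mean
out-of-sample log-likelihood. (Choice rates do not sum to 1 across
options: each binary transfer choice counts toward two options' scores.)

The same pipeline is available from the shell:

```bash
normbandit simulate --design 1a --model RANGE --n-agents 50 --seed 7 --out trials.csv
normbandit fit --trials trials.csv --models UNBIASED,DIVISIVE,RANGE --out fits.csv
normbandit compare --fits fits.csv --out table.csv
```

## Layout

- `normbandit.task_design` — experiment designs and trial schedules
- `normbandit.value_models` — normalization rules, delta-rule updates, decision rules
- `normbandit.agent_simulation` — synthetic cohorts and priors
- `normbandit.model_fitting` — maximum-likelihood fitting and out-of-sample evaluation
- `normbandit.model_comparison` — comparison tables, ex post simulation, recovery studies
- `normbandit.metrics` / `normbandit.io` / `normbandit.cli` — behavioral metrics, CSV schema, command line

See `docs/methods.md` for the modelling details and design decisions.
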