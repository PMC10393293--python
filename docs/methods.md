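# Methods

## Task structure

A session has three phases. In the **learning phase**, options are
organized in fixed contexts of two or three cues; on each trial the
agent chooses among the selectable cues and then sees the outcome of
every displayed cue (complete feedback) or only the chosen one (partial
feedback, used on forced trials in the "c" design versions). Outcomes
are drawn per option from a normal distribution with the option's mean
(14, 32, 50, 68 or 86 points) and variance 4 (sd 2), rounded to the
nearest integer and clipped to [0, 100] — the instructions frame
outcomes as whole points on that scale. In the **transfer phase**, all
pairwise combinations of the learned cues are presented (45 pairs for
10 cues, 66 for 12), each pair a fixed number of times, with no
feedback. In the **explicit phase**, each cue is rated alone on a 0–100
slider.

Eight designs are built in. Families 1 and 2 cross range amplitude
(narrow/wide) with set size (binary/trinary); versions b and c add five
forced-choice trials per option (230 learning trials instead of 180)
with complete or partial feedback. Family 3 uses four trinary contexts
crossing range amplitude with availability: in two contexts the
highest-mean option is displayed but not selectable on a fraction of
trials (50% in 3a, 75% in 3b). Since 50% of 45 is not an integer, the
masked-trial count alternates deterministically between 22 and 23 with
the seed and context position; 75% of 45 realizes as 34. Forced trials
are uniformly interleaved with free trials, as no block structure is
specified for them.

## Models

All models share the delta rule and the softmax. For option *i* in
context *s* on trial *t*:

    Q_t(s,i) = Q_{t-1}(s,i) + α_X · δ_t,    δ_t = u(R_i) − Q_{t-1}(s,i)

with α_C for the chosen (or forced) option and α_U for every other
displayed option — including masked, non-selectable options, whose
shaded outcome is displayed and therefore both enters the normalization
context and is updated. Choice probabilities are softmax over the
*selectable* options with inverse temperature β ≥ 0.

The models differ only in the subjective outcome u(R), always computed
over exactly the outcomes presented on the current trial:

| model | u(R) | Q(t=0) |
|---|---|---|
| UNBIASED | R | 50 |
| RANGE | (R − min R) / (max R − min R) | 0.5 |
| DIVISIVE | R / Σ R | 0.5 |
| RANGE_W | range-normalized value to the power ω | 0.5 |
| RANGE_WPLUS | as RANGE_W with ω_c (chosen) and ω_u (forgone) | 0.5 |

ω is applied elementwise to every outcome in the trial; the
chosen/forgone split of RANGE_WPLUS presupposes exactly this
convention, and ω = 1 (or ω_c = ω_u = 1) reproduces RANGE bit for bit.

Degenerate inputs: if a trial's outcomes are all equal after rounding
(possible only in principle under sd 2 with distinct means), range
normalization maps every outcome to 0.5 — symmetric and range-preserving
— rather than failing. A zero outcome sum makes divisive normalization
undefined and raises an error; it cannot occur in the built-in designs.

Under partial feedback, unobserved outcomes are replaced by the
option's last seen outcome. An option never observed falls back to 50
raw points (the UNBIASED initialization; for normalized models no
context-free raw value maps to 0.5, so the raw fallback is normalized
with the trial's context). This path is exercised only by version-c
forced trials.

## Synthetic agents

The generator emulates the study conditions: cohorts of 50 agents per
experiment, parameters drawn independently per agent from Beta(1.1, 1.1)
for both learning rates and Gamma(shape 1.2, scale 5) for β. The
shape–scale reading (mean 6) was adopted because the shape–rate reading
would put the prior mean at 0.24, implausibly low for an inverse
temperature. ω parameters, needed only for recovery studies, default to
log-normal(0, 0.5).

Learning-phase choices are sampled from the softmax with the drawn β
(no special-casing, although with complete feedback the values converge
regardless of the choices). Transfer choices use a hard argmax on the
final Q-values by default, with exact ties realized as a fair coin flip
from the agent's own substream; a softmax rule is available via the
`rule` parameter, since the readout rule for ex post simulation is a
genuinely open choice. Explicit ratings are generated as 100 × the
final Q (raw Q for UNBIASED) plus truncated Gaussian noise (sd 5 by
default), clipped to [0, 100]: the study elicits ratings from humans
and provides no generative model, so this stand-in simply preserves the
monotone Q → rating link the rating-based analyses assume.

What the generator does *not* emulate: reaction times, attention and
screen-position effects, stimulus appearance, payment, training. Tests
passing on synthetic cohorts therefore validate the computational
pipeline — schedules, learning dynamics, likelihoods, recovery — not
claims about human data, which enter only through the CSV schema.

## Fitting and model comparison

Parameters are estimated by maximizing the likelihood of the observed
learning-phase free choices: the phase is replayed deterministically
(observed choices and observed outcomes drive the updates; nothing is
resampled), each free choice contributes the log softmax probability of
the chosen option over the options selectable on that trial, and forced
trials contribute updates but no likelihood term. Constrained binary
trials (family 3) enter the likelihood over their two selectable
options.

Optimization is multi-start L-BFGS-B in a transformed space: logit for
the learning rates, log for β and ω. Box bounds are wide (α within
logit ±8, β within e⁻⁶…e⁷) except for ω, bounded to [e⁻³, e³], which
covers empirically plausible curvature with margin. The first start is
the prior mean (α = 0.5, β = 6, ω = 1); the remaining starts are prior
draws, so increasing the restart count can only improve (never worsen)
the returned likelihood. The default is 20 restarts; the recovery
studies in the test suite and acceptance script use 4–8 restarts at
50-agent cohort sizes, which keeps a full model-recovery run (3 × 50
agents × 3 models) under two minutes on one CPU and was verified to
reach the same optima as larger restart counts on this likelihood
(the fitted likelihood never falls below the generating-parameter
likelihood).

The fitted parameters are then scored on the transfer phase: the
out-of-sample log-likelihood sums the log softmax probability (fitted
β) of each transfer choice given the two cues' final learning-phase
Q-values, with no updating (no feedback is given). The softmax — not
the argmax of the simulation readout — is used here because an argmax
likelihood assigns zero probability to any single inconsistent choice.
Models are compared by mean/median out-of-sample log-likelihood across
subjects; no complexity penalty is applied because the evaluation is
already out of sample. Ex post simulation re-simulates the task from
fitted parameters with fresh outcome draws (the observed outcome
sequences are not replayed), mirroring the ex ante construction.

## Validation

- The normalization rules are checked against direct elementwise
  formula evaluation on 1,000 randomized trials (1e−12 relative
  tolerance), and the compiled likelihood against an independent
  trial-by-trial replay built from the public single-step operations.
- Chance-level behavior (β = 0) reproduces the analytic uniform-policy
  values: correct rates 0.5 / 0.33 in binary / trinary contexts and a
  negative log-likelihood of n·ln 2 on n binary trials in both phases.
- Ex ante 50-agent cohorts reproduce the models' separating signatures:
  UNBIASED prefers wide-context high options; DIVISIVE prefers
  binary-context high options; RANGE yields near-equal rates for all
  contextually-best options.
- Model recovery at 3 × 50 agents shows strong diagonal dominance
  (~0.7–0.85) with the generating model attaining the highest
  cohort-mean out-of-sample log-likelihood in every row.

## Known limitations

- **Learning-rate recovery is weak under the study conditions.** With
  complete feedback, the contextual minimum and maximum normalize to
  exactly 0 and 1 on every trial, so once the values converge the
  likelihood carries no further information about α_C/α_U; only the
  early trials of each context are informative. Across prior-drawn
  cohorts the true-vs-recovered rank correlation for α_C is ~0.2–0.4
  (it rises above 0.5 when β is fixed at its prior mean), while β
  recovers at ~0.95. This is a property of the design, not of the
  optimizer: the fitted likelihood always reaches or beats the
  generating parameters'. Conclusions that rest on individual
  learning-rate point estimates should be drawn with caution; model
  comparison is unaffected (see the recovery results above).
- RANGE cohorts show a small (~0.02–0.07) systematic excess in transfer
  choice rate for trinary-context over binary-context best options:
  options chosen more often during learning converge at the α_C rather
  than the α_U rate, leaving tiny final-Q differences that the hard
  argmax readout amplifies. The effect is an order of magnitude smaller
  than the contrasts separating the models.
- Fully parameterized divisive-normalization variants (with additional
  saturation/weight constants) are out of scope, as are inferential
  statistics (the per-subject summary tables are the interface to
  standard statistics software) and fitting of the original human
  dataset (supported via the CSV schema but not bundled).
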