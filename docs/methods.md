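# Methods

`pstmodels` simulates and analyses the Probabilistic Selection Task
(PST) in medication-state designs: patients with Parkinson's disease
tested ON or OFF dopaminergic medication during learning (day 1) and/or
test (day 2), alongside once-tested healthy controls. This note
documents the model, the defaults and why, what the synthetic data do
and do not emulate, and the numerical choices.

## Task model

Two variants are built in:

* **modified** — 2 pairs with reward probabilities 80–20% and 65–35%;
  40 practice trials on dedicated stimuli; 240 learning trials in three
  blocks of 80; 40-trial feedback-free memory blocks immediately after
  learning, 30 min later, and 24 hr later; then a novel-pairs test of
  all 6 unordered stimulus combinations, 15 repetitions each (90
  trials). The 24 hr memory block and the novel test fall on day 2.
* **original** — 3 pairs (80–20%, 70–30%, 60–40%); learning in blocks
  of 60 (20 per pair) gated by per-pair accuracy thresholds (65%, 60%,
  50%) with a hard cap of 7 blocks; no memory blocks; a novel test of
  all 15 combinations, 6 repetitions each (90 trials), same day.

Design choices where the protocol is underdetermined:

* **Feedback realisation.** Default i.i.d. Bernoulli per trial at the
  pair's probabilities; an `"exact"` mode instead permutes a fixed
  outcome multiset so the realised frequencies match the nominal
  probabilities exactly over the schedule. Both pre-realise the outcome
  for *each possible choice* on every feedback trial, making a session
  fully reproducible from (schedule seed, agent seed).
* **Thresholds are strict.** "Above 65%" is read as a strict
  inequality; a block exactly at threshold does not exit training.
* **Interleaving.** No more than 3 consecutive trials of the same pair
  (sequential weighted draw with restart on dead-ends); the high
  stimulus appears on the left on exactly half of each pair's trials
  per block (floor for odd counts).
* **Practice** uses two dedicated stimuli with an 80–20% contingency;
  memory blocks split their 40 trials equally across learning pairs.
* **Counterbalancing** of which display symbol plays the
  high-probability role is a permutation keyed by a version index;
  analyses operate on role labels (A…F), so versions are metadata.

## Agent model

Each stimulus carries an action value `Q`, initialised at `q0 = 0.5`
(chance-level prior). On feedback trials the chosen stimulus updates by
the delta rule

    Q <- Q + alpha * (r - Q),     r in {0, 1},

with `alpha = alpha_gain` for positive prediction errors and
`alpha_loss` for negative ones (at a zero prediction error nothing
changes, so the selector is moot there). Choices between the two
presented stimuli follow a softmax,

    P(left) = 1 / (1 + exp(-beta * (Q_left - Q_right))),

with inverse temperature `beta >= 0`; `beta = 0` is indifference and
large `beta` approaches greedy argmax choice (ties at exactly 0.5).
Feedback-free phases (memory, novel) leave values frozen.

**Consolidation** is modelled as overnight shrinkage of values toward
the prior, applied once at the day-1/day-2 transition:

    Q' = q0 + rho * (Q - q0),     rho in [0, 1].

`rho = 1` preserves the learned values, `rho = 0` forgets everything.
This is the package's operationalisation of a consolidation effect: a
medication state active on day 1 can raise or lower `rho`.

**State conditioning.** Any of `alpha_gain`, `alpha_loss`, `beta`,
`rho` may be a mapping `{"ON": x, "OFF": y}`. The day-1 state of a
condition (e.g. the "ON" of "ON-OFF") selects the learning rates and
`rho`; the day-2 state selects the `beta` used on day-2 phases. The
three injection points — learning rates, test-phase temperature,
retention — therefore map onto the three distinct hypotheses such a
design can dissociate (learning, expression, consolidation) and are
independently switchable. Agents never produce a NO_RESPONSE; the
sentinel exists for parsing real session files.

## Likelihood and estimation

The session likelihood walks trials in order: every responded choice
trial contributes `-ln P(observed choice)` under the softmax at the
current values; values evolve on feedback trials only. Memory and
novel choices are included under frozen values by default (switchable —
which phases the original analysis fitted is not recoverable); practice
trials are excluded by default since their stimuli never recur.
NO_RESPONSE trials are skipped.

Variants: `single` (`alpha`, `beta`; k = 2), `dual`
(`alpha_gain`, `alpha_loss`, `beta`; k = 3) and `dual_by_state`
(both rates per medication state plus shared `beta`; k = 5). The
family is nested: equal rates collapse dual onto single exactly.

Estimation is bounded multi-start L-BFGS-B (`alpha` in [0, 1], `beta`
in [0, 50] — beyond 50 choices are effectively greedy and the
likelihood flattens), 20 restarts by default, tolerance 1e-6, starts
jittered uniformly in the bounds except `beta`, drawn log-uniformly on
[0.2, 20] so starts are not wasted in the near-greedy regime. The
retention fraction is *not* estimated by default: with a single
overnight interval per session it is poorly identified; a fixed value
can be supplied. Standard errors come from the inverse numerical
Hessian of the negative log-likelihood at the optimum and are reported
as NaN when an estimate sits on a bound. A flat likelihood in the
learning rates (which occurs when `beta ~ 0`) raises an
identifiability warning on the results object.

Model comparison reports AIC (primary) and BIC, with ΔAIC and Akaike
weights; the original selection criterion is unknown, so both are
shown.

## Behavioural metrics

* *Optimal accuracy*: % of responded trials choosing the stimulus with
  the higher generative reward probability, regardless of the feedback
  actually delivered. Empty scopes are NaN, never zero.
* *choose-A / avoid-B*: % of eligible novel trials containing A where A
  was chosen / containing B where B was avoided; learning pairs (AB,
  CD, and EF where present) are excluded from the denominators.
* *Memory change scores*: later minus earlier (30 min − immediate,
  24 hr − 30 min), in percentage points, so an overnight improvement is
  positive.
* *Win-stay / lose-shift*: transition probabilities on learning trials,
  defined on consecutive presentations of the same pair (a global-
  transition mode is available; the original definition is not
  recoverable, so this is documented as a reconstruction).
* *Filtering*: a condition's novel-pairs data are excluded when its
  accuracy on the easiest novel pair (A vs B) is at or below 50%;
  conditions are checked separately, and the filter applies only to
  novel-pairs analyses.

## Statistical battery

Paired/independent t (pooled variance), one-way ANOVA, Pearson r,
Wilcoxon signed-rank (zero differences dropped; exact null for
n ≤ 25, normal approximation with continuity correction above), and a
2×2 within-subject ANOVA computed as one-sample t-tests on contrast
scores with F = t², df (1, n−1) — algebraically identical to the
sums-of-squares decomposition for this design, and verified against
one in the tests. Partial η² = F·df1 / (F·df1 + df2). Bonferroni
thresholds are α/m. Missing data are deleted pairwise, mirroring
per-analysis handling of missing blocks. Both `d_z` (mean difference /
SD of differences) and `d_av` (mean difference / average SD) are
reported for paired tests, because published paired effect sizes are
computed inconsistently and neither variant can be assumed. The
reported "multivariate" group comparison is implemented as per-measure
univariate tests; a true MANOVA is out of scope and flagged as such.

## Synthetic cohorts

`CohortConfig` defaults state the world once: 18 patients × 4
counterbalanced two-day conditions (Latin-square order, distinct
stimulus version per condition) plus 18 controls, modified task.
Per-subject parameters are truncated-normal draws:

| parameter    | mean  | SD   | bounds       |
|--------------|-------|------|--------------|
| `alpha_gain` | 0.35  | 0.15 | [0.02, 0.98] |
| `alpha_loss` | 0.30  | 0.15 | [0.02, 0.98] |
| `beta`       | 3.0   | 1.0  | [0.5, 20]    |
| `rho`        | 0.775 | 0.05 | [0, 1]       |

No population values were ever published for this design, so these are
documented choices, not claims: the learning rates sit where healthy
adult fits on comparable bandit tasks typically land, and `beta = 3`
puts asymptotic softmax accuracy at ~86% on the 80–20 pair and ~71% on
the 65–35 pair, i.e. final-block learning accuracy in the observed
high-70s% regime. Medication effects are injected as ON-minus-OFF
deltas around the subject's base draw; the documented consolidation
injection is `rho_on_minus_off = 0.35`, i.e. retention 0.95 ON vs 0.60
OFF on day 1. Controls carry no medication state and receive the
OFF-level retention (they decline overnight, as observed). With all
deltas zero the cohort is an exchangeable null across conditions.

What the generator does **not** emulate: reaction times and the "GO"
prompt timing, within-session forgetting, demographic covariates,
session-order (practice/fatigue) effects, stimulus-discriminability
differences between symbol sets, and spontaneous missing blocks
(missingness can be introduced upstream of the metrics, which
propagate NaN). A green test on synthetic data therefore establishes
that the pipeline is internally correct and calibrated — not that real
patients behave like these agents.

## Numerical notes

* `-ln sigmoid(x)` is computed as `log1p(exp(-x))` with linear
  overflow guards, so likelihoods are finite at `beta = 50`.
* Schedules, sessions, cohorts and reports are bit-reproducible from
  their seeds; cohorts use a `SeedSequence` tree (root → subject →
  session) so any subject can be regenerated in isolation.
* Truncated-normal sampling is by rejection with a clip fallback after
  1000 draws (only reachable for degenerate configurations).
* Degenerate statistics (zero-variance differences, empty scopes)
  return NaN sentinels and are reported as undefined, never as zeros.

## Known limitations

* `rho` estimation is opt-in and weakly identified from one overnight
  interval; the generative role of `rho` is primarily to produce the
  memory-change patterns, not to be recovered per subject.
* The state-conditional variant shares `beta` across states; a
  state-conditional `beta` fit is possible in principle but is not in
  the implemented family (the minimal family consistent with the
  modelling question).
* The threshold-gated variant realises all 7 blocks in the schedule
  and skips the remainder at simulation time, so "blocks completed" is
  an agent property, not a schedule property.
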