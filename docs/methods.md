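# Methods

## The cumulative nutritional-intensity score

Dietetic support is recorded as episodes: contiguous runs of one support
level for one patient, with inclusive day bounds in days post-transplant
(day 0 = infusion day). Five levels are recognised, totally ordered by
invasiveness and weighted by escalating clinical effort: routine dietetic
review (1 point/day), oral nutritional support (2), enteral nutrition
(4), parenteral nutrition (6), bespoke parenteral nutrition (7). A sixth
pseudo-level, NONE (0 points), denotes absence of dietetic contact and is
never stored in an episode.

The score for patient *i* over a window *W* (default the first 100 days,
represented as inclusive days 0–99) is

    AUC_i = sum over levels j of  w_j * d_ij,

with `d_ij` the number of window days on level *j*. Weights and window
are configuration, not constants: alternative institutional weightings
can be studied by supplying a different `WeightScheme`, under the
invariant that weights increase strictly with the level order and NONE is
exactly 0. "First 100 days" admits any consistent convention; the
half-open [0, 100) window stored as inclusive [0, 99] is the default and
the window is configurable.

Two conventions resolve days on which several levels are documented
simultaneously:

- **additive** (default): every active level contributes its weight that
  day — the direct reading of the per-intervention sum above. Duplicate
  or overlapping episodes of the *same* level are merged first, so a day
  is never double-billed within one level.
- **max_per_day**: only the single highest active level contributes,
  treating higher support as superseding lower. This equals re-scoring
  the patient's daily maximum-level profile, and is bounded by
  7 × window length.

For non-overlapping episodes — the typical clinical record — the two
modes coincide. Scoring is implemented on interval set operations but is
definitionally a per-day sum; the test suite holds the two routes to
exact equality on randomised records.

### Day +100 endpoint and censoring

The binary endpoint "≥ PN at Day +100" is true iff the highest level
active on the window's final day ranks at or above parenteral nutrition.
"At Day +100" is read as *active on that day* (rather than some notion of
ongoing dependence around it), which is the only version computable from
episode bounds alone. Querying a day beyond a patient's recorded
follow-up raises rather than returning false: the outcome is censored
there. Consistently, the pipeline excludes records whose follow-up does
not cover the window (patients who died or were lost before Day +100);
an explicit override scores the truncated window instead, with a warning,
and the exclusion count is surfaced in the run manifest.

## Synthetic cohorts

No patient-level data accompany the index, so all analyses are exercised
on synthetic cohorts with two independent parts.

**Covariates** are drawn independently per patient from a configurable
categorical mixture whose defaults are a published paediatric transplant
cohort composition: 83.2% allogeneic / 12.2% CAR-T / 4.6% gene therapy;
65.6% male; ages 20.6% under 2 / 58.0% 2–12 / 21.4% over 12; and, within
the allogeneic group, 41.3% malignant disease, 28.4% cord-blood source,
12.8% total body irradiation (TBI). Disease, cell source and TBI are
defined only for allogeneic patients. No joint covariate distribution is
imposed; correlations (e.g. malignancy–TBI) can be induced via
stratum-specific configuration if needed.

**Trajectories** come from a covariate-stratified discrete-time Markov
chain over the six states NONE…BESPOKE_PN, one step per window day,
compressed into episodes. The shipped default chains are phenomenological
step-down processes: a patient starts on PN (or, with
severity-dependent probability, bespoke PN), de-escalates one level at a
time with geometric sojourn times, and leaves follow-up from routine
review; a small daily relapse probability (0.006 allogeneic, 0.002
CAR-T/gene therapy) re-escalates to PN, and NONE re-enters routine review
at 0.004/day. Severity multipliers stretch the enteral-and-above sojourn
times: ×1.90 for malignant disease, ×1.90 for TBI, ×1.20 for cord blood.
CAR-T and gene-therapy chains start lower (mostly oral/enteral) with
shorter sojourns, reflecting lighter conditioning.

These constants were hand-calibrated by simulation — not fitted to any
data — so that stratum score medians land near the real-cohort medians
the generator emulates (observed at n = 4000: overall ≈ 276 vs ≈ 294
emulated; allogeneic 330 vs 326; CAR-T 63 vs 53; gene therapy 135 vs
124.5; malignant 449 vs 444; nonmalignant 264 vs 261.5; TBI 477 vs 476;
cord blood 374 vs 362). The calibration is deliberately approximate: it
preserves ordering and rough location, not distributional shape. What the
generator does **not** emulate: mechanistic mucositis/GvHD/engraftment
dynamics, within-patient covariate correlations, length-of-stay effects,
seasonal or era effects, and any real service's documentation habits.
Tests passing on these cohorts therefore validate the *machinery*
(scoring, statistics, fitting), not clinical claims about real patients.

Reproducibility: patient *i* consumes only the substream seeded by
`(seed, i)` (numpy `SeedSequence`), so cohorts are identical across runs
and stable under changes of cohort size. An optional per-day death hazard
(off by default) produces truncated follow-up for exercising the
censoring filter.

**Simulated outcomes.** Two endpoint modes exist. `trajectory` derives
≥ PN at Day +100 from the simulated day-99 state; because the default
chains mostly de-escalate, this endpoint is nearly a threshold function
of the cumulative score, which (correctly) drives a logistic fit towards
separation. `logistic` instead draws the endpoint from a known model,
outcome ~ Bernoulli(logit⁻¹(β₀ + Σ βₖxₖ + β_auc·AUC)), stored on the
record and transparently returned by the endpoint query. The default
ground truth mirrors a published multivariable fit (β_auc = 0.009 per
unit). The end-to-end pipeline defaults to `logistic` for this reason,
and parameter-recovery tests use it to verify bias and Wald coverage of
the fitter.

## Statistics

- **Medians and CIs**: subgroup medians carry percentile-bootstrap 95%
  CIs (2000 resamples, seeded, deterministic; via `scipy.stats.bootstrap`).
  The bootstrap was chosen for distribution-freeness on a right-skewed
  score; constant or singleton samples degenerate to [median, median].
- **Group tests**: Student's t for two groups and one-way ANOVA for three
  — the parametric defaults of the analysis plan this package follows —
  with Welch, Mann-Whitney and Kruskal-Wallis available for sensitivity
  analyses. Identical constant groups return p = 1 by convention. No
  multiplicity correction is applied across subgroup tests (α = 0.05 per
  test).
- **Proportions**: k×2 tables use the Pearson chi-square without
  continuity correction (the correction is markedly conservative at the
  cell sizes in scope, distorting the test's size); a 2×2 table with any
  expected cell below 5 switches to Fisher's exact test.
- **Rounding**: tabulated percentages use decimal half-up rounding at one
  decimal place and are always recomputed from counts.

## Logistic regression

The multivariable model predicts ≥ PN at Day +100 on the allogeneic
subset from gender, age group, disease type, cell source, TBI and the
cumulative score (per unit, untransformed). Reference levels are fixed by
construction: female, age 2–12 (two dummies: under 2, over 12), malignant
disease, cord-blood source, no TBI. Estimation is maximum likelihood via
iteratively reweighted least squares — the default of standard
statistical software — with Wald covariance from the inverse observed
information; convergence when the largest coefficient change falls below
1e-8, capped at 100 iterations. The fit is verified in tests against
statsmodels and against a generic BFGS optimiser of the same likelihood
to < 1e-6 per coefficient.

Separation (coefficients diverging, as with a predictor that perfectly
determines the outcome) raises an explicit error instead of returning
huge estimates; a Firth (Jeffreys-prior score-adjusted) penalised fit is
available as a fallback flag. Odds ratios are exp(coefficient) with Wald
95% CIs; the per-100-unit OR is exp(100·β) computed from the unrounded
coefficient. Discrimination is summarised by the ROC curve over the
unique fitted probabilities (ties grouped into single steps) with
trapezoidal area, which equals the Mann-Whitney U statistic scaled by
n₁n₀ — an identity the tests assert to 1e-12. The bivariable screen fits
each predictor alone with the same machinery; failed terms are flagged
while the rest are returned.

## Numerical and design notes

- All randomness flows from explicit seeds; no module draws from global
  state.
- Episode/score/covariate interchange is plain CSV with fixed headers;
  the transition model is JSON (row-major 6×6 matrices whose rows must
  sum to 1 within 1e-12).
- Outputs are written atomically (temp file + rename). Exit codes: 0
  success, 2 validation failure, 3 computation failure.
- Problem sizes in the test suite (e.g. 1000-record oracle sweeps,
  500-replication recovery, 1000-replication calibration and coverage
  runs, n = 500 calibration cohorts) were chosen as the smallest sizes at
  which the binomial/Monte-Carlo tolerances quoted in the tests are
  informative.

## Known limitations

- The score counts intervention-days only; it does not model calorie or
  protein intake, anthropometrics, or nutritional status.
- The additive overlap convention can exceed the single-modality maximum
  (7 × window length) when concurrent modalities are documented; use
  `max_per_day` when supersession semantics are wanted.
- The generator's severity structure is multiplicative and stratum-local;
  it cannot represent, e.g., time-varying hazards of escalation or
  centre-level practice differences.
- Student's t and ANOVA are applied to a skewed score for fidelity to the
  analysis plan being reproduced; the rank-based options are the more
  defensible defaults for new analyses.
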