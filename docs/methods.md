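# Methods

This note documents the generative models, the calibration math, the
measurement conventions and the open design choices behind `lhstudy`.

## Study structure

Three treatment groups (master / yoked / control) differ only in control
over an aversive tone during a 30-trial pretreatment phase; helplessness is
then measured in an 18-trial test phase in a new context, analyzed as 6
blocks of 3 trials. Hedonic state is probed by a 4-block × 50-trial
probabilistic-reward signal-detection task with an asymmetric 15:5
rich:lean reward allocation, and by pre/post state surveys. Group
assignment is gender-stratified (round-robin within shuffled strata, with
the deal position carried across strata so totals also differ by ≤ 1), and
the rich-stimulus identity and response-key mapping are counterbalanced
within each group.

## Schedules

- **ISIs** are i.i.d. continuous Uniform(10, 20) s. Only the range and the
  15-s mean are specified by the design; the uniform is the simplest
  distribution satisfying both. The marginal is property-tested by a KS
  test at α = 0.01 on 10,000 pooled draws.
- **Escape sequences** alternate orientation strictly by trial index
  (L-R, R-L, … in pretreatment; L-R-L, R-L-R, … in test), not contingent on
  the previous trial's success. Strict alternation keeps master and yoked
  schedules identical, which the yoked design requires. The starting
  orientation (left-first) is configurable.
- **Reward flags** are placed by uniform seeded shuffle inside each
  stimulus-type subsequence of a block, honoring the 15 rich / 5 lean
  quotas exactly; no run-length constraints are imposed beyond the quotas.
  Stimulus types are balanced 25/25 per 50-trial block: the stated
  allocation requires at least 15 rich-stimulus trials per block, and
  balance keeps the log d / log b counts well-scaled.

## Latency model and effect-size calibration

Test-phase trial latency for subject *i* in group *g*, block *b*:

    latency = shift_g + trend_b + u_i + LogNormal(log median, σ_log)

with subject intercept `u_i ~ N(0, σ_u²)`, median 6 s, σ_log = 0.25, a
zero-sum learning trend of ±0.5 s across the six blocks, truncation to
[0.05 s, ceiling]. Block scores are means of 3 trials, so in closed form

    Var(block score) = σ_u² + v_LN / 3,   corr(blocks) = σ_u² / Var(block score)

where `v_LN` is the lognormal variance. Calibration proceeds in two exact
steps: σ_u is set from the target repeated-measures correlation
(ρ = 0.5 by default), then the centered group pattern
(master −0.5, yoked +1, control −0.5) is scaled so the population Cohen
*f* of block scores equals the target (0.25 by default). Because the
intercept and the group offsets are additive in seconds, both quantities
are exact rather than fitted; the only approximation is the 15-s ceiling,
whose tail mass is ~10⁻⁴ under the defaults, and `calibrate_effect_size`
raises if a requested *f* would push the slowest group's plausible range
(+2 lognormal SD, +4 intercept SD) into the ceiling.

The between-groups split-plot F equals the one-way F on subject means
across blocks; the vectorized Monte-Carlo power path exploits this identity
(asserted against the full ANOVA in tests) so thousands of cohorts simulate
in seconds.

Pretreatment: the master group draws escape latencies from a 5-s-median
lognormal with a 10-s ceiling; the yoked group's tones always last the full
10 s regardless of its keypresses (the yoking contract — tone duration is
independent of behavior by construction); the control group never presses.
Yoked exploration is Poisson pressing (rate 8/trial) that decays
geometrically (factor 0.6) after a per-subject give-up trial drawn uniformly
from trials 8–20, producing the steady post-give-up decline the exploratory
analysis must detect.

## Reward-task observer

Equal-variance Gaussian observer: evidence `x ~ N(±d′/2, 1)` on the
rich-vs-lean axis, response "rich" iff `x + c > 0`, with d′ = 1.5
(≈ 77% accuracy). Each *delivered* reward moves the criterion toward the
rewarded response by 0.005 × a per-group multiplier (1.0 for master and
control, 0.15 for the yoked preset). Reward moves the criterion only —
never d′ — so bias can grow without an accuracy confound, matching the
prediction that discriminability stays flat. A reward scheduled on a trial
answered incorrectly carries over to the next correct identification of the
*same* stimulus type (the default; carryover to any correct trial is the
obvious alternative and would be a one-line change).

Under the defaults the criterion ends near 0.17 after four blocks, i.e. a
final log b of ~0.13 for full-multiplier groups — magnitudes typical of
this task family. Per-block log b estimates from 50 trials are noisy
(SD ≈ 0.1), so the group main effect on mean bias carries far more power
than the block × group interaction; at N = 200 the preset reliably yields
the group effect and the pairwise yoked deficits while the interaction is
often non-significant. This mirrors the task's empirical literature and is
a property of the measurement, not of the simulator.

Reaction times are 150 ms + LogNormal(median 350 ms, σ = 0.35),
contaminated with 2% fast guesses (50–140 ms), 2% lapses (2600–3800 ms)
and 1% within-window outliers (1600–2400 ms) whose only purpose is to
exercise both exclusion stages.

## Surveys

Each Likert instrument is a latent-trait model: subject latent
θ ~ N(μ, σ_subject), observed item = clip(round(θ + N(0, σ_item))), with
reverse-keyed items emitted reflected so keyed scoring recovers the latent
sum. Group × time state shifts are parameterized on the **total-score SD
scale** and converted analytically to a per-item latent shift using the
item count, item noise and the uniform discretization variance (n/12); a
configured −0.5 SD shift is recovered as a −0.5 standardized pre/post
difference within Monte-Carlo error. The preset shifts (yoked: −0.5 SD on
both hedonic state scales, +0.5 SD on state anxiety) are free parameters —
the design predicts directions, not magnitudes.

Instrument *keying maps are configuration data with synthetic defaults*
(the questionnaire texts are copyrighted and the keying is not public
here): a 12-item reverse-keyed set for the 40-item anxiety inventory and
4-domain memberships for the 17-item anhedonia scale were chosen
arbitrarily and are clearly replaceable via `InstrumentSpec`.

## Measurement conventions

- Trial coding uses closed upper bounds: exactly 5 s → avoidance, exactly
  15 s → escape. Failures are latencies above the ceiling; the ceiling
  value (15 s test, 10 s pretreatment) enters the mean latency, without
  which the mean is undefined for all-fail participants. The alternative
  10-s failure definition that appears in part of the plan is available by
  passing `max_s=10` to the coder; the 15-s definition (5-s signal + 10-s
  tone) is the default because it matches the task's trial window.
- "Trials to criterion" returns the 1-based index of the last trial of the
  first qualifying run, so [A, A, A] → 3. The escape criterion accepts any
  run of 3 consecutive non-fails (the worked mix of escapes and avoidances
  generalizes to this rule); the avoidance criterion requires 3 consecutive
  avoidances.
- log d / log b use the 0.5-per-cell correction *only* when some cell is
  zero, leaving nonzero tables exact. The bias sign convention is
  rich-positive and defined on reward roles, making it invariant to the
  stimulus counterbalancing (property-tested).
- RT exclusions: absolute window first (150–2500 ms), then a single-pass
  per-participant mean ± 3 SD filter computed on the survivors. No
  iteration — the stages are applied once, in this order.
- Give-up detection: the first trial whose 3-trial median press count
  falls below 25% of the first window's median; a silent start gives
  trial 1; never declining gives not-detected. Window and threshold are
  arguments.

## Statistics

All sums of squares are computed explicitly (raw-score formulas over
subject/group/level/cell totals) so every term is auditable; scipy provides
the F, t and studentized-range distributions (the latter by numerical
integration, not table lookup), and statsmodels provides only the
Breusch–Pagan statistic inside the assumption screen. Independent oracles
in the test suite are pingouin (mixed ANOVA), statsmodels OLS/Tukey, and
hand-rolled brute-force computations.

- Sphericity is assumed (ε = 1) by default for consistency with the power
  plan's convention; Greenhouse–Geisser correction is available as an
  option (ε from the double-centered pooled covariance).
- Incomplete subjects (missing within-levels) raise by default and are
  dropped listwise with a logged report when requested — the plan excludes
  participants who do not finish.
- ANCOVA is the extra-sum-of-squares F in a GLM with treatment-coded
  groups; collinear covariates raise a singularity error naming the
  suspects, and a covariate that reproduces the outcome raises a
  zero-residual error.
- Post-hocs: Scheffé compares the pairwise contrast F to (k−1)·F_crit;
  Tukey–Kramer uses q at k means; Newman–Keuls steps down from the widest
  range with q at the range's own span and the usual protection rule
  (non-significant ranges block nested pairs). Newman–Keuls p-values are
  per-step tail probabilities, not simultaneous error rates. The plan
  names a different procedure per endpoint; the pipeline makes the mapping
  configuration.
- Only the latency↔bias correlation is one-tailed (its direction is
  pre-registered); all omnibus tests are two-tailed. The Pearson→Spearman
  fallback is driven by Shapiro–Wilk, Breusch–Pagan and a quadratic-term
  linearity F at α = 0.05.

## Power

Between-groups effect in a k-group, m-measurement repeated-measures
design: F(k−1, N−k) with noncentrality **λ = f²·N·m / (1 + (m−1)ρ)** —
averaging m measurements with compound-symmetric correlation ρ shrinks the
error variance by (1 + (m−1)ρ)/m, which is exactly the denominator. This
convention reproduces the plan's anchors: minimal N (multiple of 3) at
f = 0.25, α = 0.05, ρ = 0.5, target 0.95 is **150** for m = 6 and **189**
for m = 2; the m = 4 design evaluated at the planned N = 168 gives 0.962
(that N is not the convention's minimum — 165 already suffices — so the
module reports power *at* the planned N rather than claiming to derive it).

Correlation power under the bivariate normal is provided two ways, both
labeled: the **exact** sampling density of r (Gaussian-hypergeometric form,
integrated numerically past the null t-based critical r) and the
**Fisher-z** approximation. At ρ = 0.25, α = 0.05 one-tailed, target 0.95,
the exact method requires n = 168 and Fisher-z n = 169 — the plan's printed
168 matches the exact procedure.

`monte_carlo_power` cross-validates the analytic values by simulating
cohorts from the latency (or survey) generative model and counting
rejections, with a normal-approximation 95% CI. The test suite runs 2000
cohorts at N = 150 (agreement within ±0.02) and 5000 null cohorts
(rejection rate in [0.04, 0.06]); these sizes make the Monte-Carlo SE
(≈ 0.005 and 0.003) small against the tolerances while the vectorized
path keeps each run in seconds.

## Reproducibility

A single root seed feeds named substreams (group assignment, schedules,
per-participant simulation), so modules can be re-run independently and a
rerun with the same config is byte-identical; no timestamps are
serialized. Identical spec + seed give identical schedules, cohorts and
reports (asserted in tests).

## What the synthetic cohort does and does not show

The generator encodes the *assumed* statistical structure (effect size,
repeated-measures correlation, direction of group patterns) — it contains
no cognitive model of helplessness, no learning dynamics in the latency
trend beyond a shared block effect, and no quantitative claim about real
effect magnitudes, for which no human data exist. Passing tests therefore
demonstrate that the pipeline measures, excludes and tests exactly as
pre-registered and that the power plan is internally consistent; they say
nothing about whether the real paradigm will produce these effects.

## Known limitations

- The split-plot ANOVA assumes complete, balanced within-subject data
  after listwise dropping; no mixed-effects fallback for partial sessions.
- Newman–Keuls controls the familywise rate only under monotone mean
  configurations (a known property of the procedure, kept because the plan
  names it for the reward-task endpoint).
- The exact correlation-power integral is stable for n up to a few
  thousand; beyond that the Fisher-z method should be preferred.
- The block × group interaction for response bias is underpowered at the
  planned N under realistic per-block measurement noise (see above); the
  group main effect and Δ response bias carry the signal.
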