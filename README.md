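# lhstudy

A reusable computational pipeline for a pre-registered human
learned-helplessness experiment asking whether uncontrollable stress induces
a *state* of anhedonia. The study design is triadic: a **master** group can
terminate an aversive tone by a button sequence, a **yoked** group receives
the identical tones with no control, and a **control** group listens
passively. Helplessness is then probed in a new context (6 blocks of escape
trials), and hedonic state is probed with a probabilistic-reward
signal-detection task plus pre/post state-anhedonia and state-anxiety
surveys.

No human data exist for this design (it is a registered protocol), so the
package makes every stage testable with a synthetic cohort generator that
encodes the sampling plan's assumptions — a between-group effect of Cohen
*f* = 0.25 on escape latencies with repeated-measures correlation ρ = 0.5 —
and the hypothesized group patterns as tunable presets.

It is intended for behavioral researchers who want to (a) audit or adapt the
pre-registered analysis plan, (b) run design/power analyses for yoked
triadic paradigms, or (c) pipe real trial logs through the identical
exclusion → scoring → analysis path once data exist.

## What it computes

**Signal-detection scores.** Each 50-trial block yields a 2×2 table of
correct/incorrect responses to the rich (frequently rewarded) and lean
stimulus. Discriminability and response bias follow the log-linear
convention:

    log d = ½ · log10[(rich_c · lean_c) / (rich_i · lean_i)]
    log b = ½ · log10[(rich_c · lean_i) / (rich_i · lean_c)]

with a 0.5 added to every cell when any cell is zero. Positive log b means
bias toward the rich response regardless of counterbalancing; Δ log b across
blocks indexes reward learning.

**LH endpoints.** Test trials are coded avoidance (correct response ≤ 5 s,
during the warning light), escape (≤ 15 s) or fail, and summarized as the
five pre-registered endpoints: trials to avoidance criterion (3 consecutive
avoidances), trials to escape criterion (3 consecutive non-fails), counts of
avoidances and failures, and mean latency (fails contribute the 15-s
ceiling).

**Statistics.** Split-plot (repeated-measures × between-groups) ANOVA,
pre/post repeated-measures ANOVA, ANCOVA, Scheffé / Tukey / Newman–Keuls
post-hocs and Pearson/Spearman correlations with an assumption-driven
fallback — all from explicit sums of squares, with scipy supplying only the
reference distributions.

**Power.** The between-groups effect in a k-group, m-measurement design is
noncentral F with λ = f²·N·m / (1 + (m−1)·ρ); correlation power is offered
both as the exact bivariate-normal sampling density and the Fisher-z
approximation.

## Worked example

```bash
$ lhstudy power rm-between --k 3 --m 6 --f 0.25 --rho 0.5 --n 150
{"achieved_power": 0.953737216514535, "n_total": 150, "ncp": 16.071428571428573,
 "df": [2, 147], "method": "noncentral_f"}
```

At the planned N = 150 the 3-group × 6-block design has noncentrality
λ ≈ 16.07 and power 0.954 — i.e. the design detects a medium between-group
latency effect 95 times in 100. A full synthetic run:

```bash
$ lhstudy run --seed 1 --n 200 --out demo
report written to demo/report.json (3 significant omnibus tests)
```

`demo/report.json` then contains one entry per pre-registered hypothesis,
e.g. for the primary escape-learning question (seed 1, N = 200):

```json
"primary_1": {
  "effect": "group", "F": 7.334449, "df": [2.0, 197.0], "p": 0.00084665,
  "significant": true,
  "posthoc": [
    {"pair": ["control", "master"], "diff": -0.226412, "p": 0.48776040, "reject": false},
    {"pair": ["control", "yoked"],  "diff": -0.706615, "p": 0.00113679, "reject": true},
    {"pair": ["master", "yoked"],   "diff": -0.480203, "p": 0.04024144, "reject": true}
  ]
}
```

— the yoked group is ~0.5–0.7 s slower than both others while master and
control do not differ, the pattern the hypothesis-generating preset
encodes; the Scheffé pairs isolate it. The same run's reward-task entry
shows the yoked group's mean response bias about 0.05 log units below the
other groups (Newman–Keuls p < 0.001) and a significant negative
latency–bias correlation (r = −0.16, one-tailed p = 0.011). Under the null
preset (`--f 0`, null survey shifts) the same tests reject at the nominal
5% rate.

## Layout

- `lhstudy.schedules` — LH and reward-task trial schedules, reward quotas,
  gender-stratified group assignment, counterbalancing
- `lhstudy.cohort` — synthetic participants: calibrated latency model,
  Gaussian observer with reward-driven criterion shifts, item-level surveys
- `lhstudy.scoring` — trial coding, the five LH endpoints, log d / log b,
  RT exclusions, survey and keypress scoring
- `lhstudy.stats` — the pre-registered inferential layer
- `lhstudy.power` — analytic and Monte-Carlo power
- `lhstudy.pipeline` / `lhstudy.cli` — end-to-end runs, ingest validation,
  the `lhstudy` command

See `docs/methods.md` for the generative models, calibration math and
design choices.
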