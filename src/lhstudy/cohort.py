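"""Generative models of study participants.

Every downstream stage (scoring, statistics, power) is testable against
cohorts drawn from these models, which encode the statistical structure the
sampling plan assumes — a between-group effect of Cohen f on the test-phase
escape latencies with compound-symmetric correlation ρ among the six latency
blocks — and the hypothesized group patterns as tunable presets: elevated
yoked latencies, blunted yoked response-bias growth in the reward task, and
a yoked-only worsening of the state anhedonia/anxiety scores.

Latency model
-------------
Test-phase trial latencies are a subject random intercept plus a lognormal
residual (a shifted lognormal whose shift is the subject intercept and the
group/block offset, in seconds):

    latency[i, g, b, t] = shift_g + trend_b + u_i + LogNormal(μ, σ)

with ``u_i ~ N(0, σ_u²)``.  Block scores are means of ``trials_per_block``
trials, so their within-cell variance is ``σ_u² + v_LN/trials_per_block``
and their between-block correlation is ``σ_u²`` over that total — both in
closed form, which is what lets :func:`calibrate_effect_size` hit a target
Cohen f exactly rather than by stochastic search.

Reward-task observer
--------------------
An equal-variance Gaussian observer: evidence ``x ~ N(±d'/2, 1)`` on the
rich-vs-lean axis, response "rich" when ``x + c > 0``.  Each delivered
reward moves the criterion c toward the rewarded response by
``criterion_shift_per_reward`` times a per-group multiplier (≈0 for the
yoked preset), so the asymmetric 15:5 schedule grows a rich-ward response
bias without touching discriminability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .schedules import (
    GROUPS,
    GroupAssignment,
    LHScheduleSpec,
    LHTrialPlan,
    SDTScheduleSpec,
    SDTTrialPlan,
    assign_groups,
    generate_lh_schedule,
    generate_sdt_schedule,
)
from .scoring import InstrumentSpec, TrialRecord

__all__ = [
    "LatencyModel",
    "ObserverParams",
    "SurveyModelParams",
    "ArtifactRates",
    "CohortConfig",
    "ParticipantRecord",
    "DEFAULT_INSTRUMENTS",
    "calibrate_effect_size",
    "simulate_cohort",
    "simulate_lh_session",
    "simulate_sdt_session",
    "simulate_surveys",
    "estimate_between_f",
    "simulate_latency_blocks",
    "simulate_latency_rejections",
    "simulate_survey_rejections",
]


# --------------------------------------------------------------------------
# Instrument catalogue (synthetic keying — the real maps are copyrighted)
# --------------------------------------------------------------------------

DEFAULT_INSTRUMENTS: dict[str, InstrumentSpec] = {
    "bdi": InstrumentSpec("bdi", n_items=21, min_score=0, max_score=3),
    "stai": InstrumentSpec(
        "stai", n_items=40, min_score=1, max_score=4,
        # synthetic reverse-keyed set; the published keying is not reproduced
        reverse_keyed=frozenset({1, 5, 8, 10, 15, 19, 21, 26, 30, 33, 36, 39}),
        subscales={"state": tuple(range(1, 21)), "trait": tuple(range(21, 41))},
    ),
    "fcps": InstrumentSpec("fcps", n_items=36, min_score=1, max_score=5),
    "dars": InstrumentSpec(
        "dars", n_items=17, min_score=0, max_score=4,
        subscales={
            "hobbies": tuple(range(1, 6)),
            "food_drink": tuple(range(6, 10)),
            "social": tuple(range(10, 14)),
            "sensory": tuple(range(14, 18)),
        },
    ),
}

#: scenario valences for the 12-item attributional-style questionnaire
ASQ_VALENCES = tuple(["good", "bad"] * 6)


# --------------------------------------------------------------------------
# Model parameter blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LatencyModel:
    """Test-phase latency generative model (seconds).

    ``group_shift_s`` holds the calibrated per-group mean offsets;
    ``block_trend_s`` a zero-sum learning trend shared by all groups.
    """

    median_s: float = 6.0
    sigma_log: float = 0.25
    subject_sd_s: float = 0.9
    group_shift_s: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in GROUPS})
    block_trend_s: tuple[float, ...] = (0.5, 0.3, 0.1, -0.1, -0.3, -0.5)
    trials_per_block: int = 3
    fail_ceiling_s: float = 15.0
    min_latency_s: float = 0.05
    # pretreatment escape latencies (master group only; 10-s ceiling)
    pre_median_s: float = 5.0
    pre_sigma_log: float = 0.3
    pre_ceiling_s: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0 or self.subject_sd_s < 0:
            raise ValueError("scale parameters must be positive")

    @property
    def lognormal_mean_s(self) -> float:
        return self.median_s * math.exp(self.sigma_log ** 2 / 2)

    @property
    def lognormal_var(self) -> float:
        s2 = self.sigma_log ** 2
        return (math.exp(s2) - 1) * self.median_s ** 2 * math.exp(s2)

    @property
    def block_score_var(self) -> float:
        """Within-cell variance of a block score (mean of trials_per_block)."""
        return self.subject_sd_s ** 2 + self.lognormal_var / self.trials_per_block

    @property
    def rm_correlation(self) -> float:
        """Implied correlation between block scores of one subject."""
        return self.subject_sd_s ** 2 / self.block_score_var

    def implied_f(self, proportions: Mapping[str, float]) -> float:
        """Population Cohen f of the group means given group proportions."""
        mean = sum(proportions[g] * self.group_shift_s[g] for g in proportions)
        var = sum(proportions[g] * (self.group_shift_s[g] - mean) ** 2
                  for g in proportions)
        return math.sqrt(var / self.block_score_var)


@dataclass(frozen=True)
class ObserverParams:
    """Equal-variance Gaussian observer for the reward task."""

    d_prime: float = 1.5
    initial_criterion: float = 0.0
    criterion_shift_per_reward: float = 0.005
    group_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"master": 1.0, "yoked": 0.15, "control": 1.0})
    rt_shift_ms: float = 150.0
    rt_median_ms: float = 350.0
    rt_sigma_log: float = 0.35

    def __post_init__(self) -> None:
        if self.d_prime < 0:
            raise ValueError("d_prime must be nonnegative")


@dataclass(frozen=True)
class ArtifactRates:
    """Contamination rates for the RT stream (exercise the exclusion rules)."""

    p_inattentive_fast: float = 0.02
    p_inattentive_slow: float = 0.02
    p_outlier: float = 0.01

    def __post_init__(self) -> None:
        for r in (self.p_inattentive_fast, self.p_inattentive_slow, self.p_outlier):
            if not 0 <= r <= 1:
                raise ValueError("artifact rates must lie in [0, 1]")


@dataclass(frozen=True)
class InstrumentModel:
    """Latent-trait item-response model for one Likert instrument."""

    latent_mean: float
    subject_sd: float
    item_sd: float
    state_sd: float = 0.0  # extra pre-to-post latent fluctuation


@dataclass(frozen=True)
class SurveyModelParams:
    """Survey generative parameters.

    ``state_shift_sd`` maps ``(group, endpoint)`` to the post-minus-pre
    shift on the *total-score SD* scale; the hypothesis-generating preset
    lowers yoked hedonic scores and raises yoked state anxiety by 0.5 SD.
    The effect size is a free parameter — no quantitative prediction exists
    for it — so null presets are a single dict away.
    """

    instruments: Mapping[str, InstrumentModel] = field(default_factory=lambda: {
        "bdi": InstrumentModel(latent_mean=0.6, subject_sd=0.30, item_sd=0.55),
        "stai": InstrumentModel(latent_mean=2.2, subject_sd=0.30, item_sd=0.65,
                                state_sd=0.10),
        "fcps": InstrumentModel(latent_mean=3.3, subject_sd=0.35, item_sd=0.75,
                                state_sd=0.10),
        "dars": InstrumentModel(latent_mean=2.6, subject_sd=0.35, item_sd=0.70,
                                state_sd=0.10),
    })
    state_shift_sd: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("yoked", "fcps"): -0.5,
        ("yoked", "dars"): -0.5,
        ("yoked", "stai_state"): 0.5,
    })
    asq_mean: float = 4.0
    asq_sd: float = 1.2
    tone_annoyance_mean: float = 6.0
    tone_annoyance_sd: float = 2.0

    def null(self) -> "SurveyModelParams":
        return replace(self, state_shift_sd={})


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration of the synthetic cohort.

    Defaults are the planned study conditions: N = 200 with even gender
    mix, a between-group latency effect of Cohen f = 0.25 with
    repeated-measures correlation 0.5 over 6 blocks of 3 test trials.
    """

    n_total: int = 200
    gender_mix: float = 0.5  # proportion labelled "f"
    target_between_f: float = 0.25
    rm_correlation: float = 0.5
    latency_model: LatencyModel = field(default_factory=LatencyModel)
    observer_model: ObserverParams = field(default_factory=ObserverParams)
    survey_model: SurveyModelParams = field(default_factory=SurveyModelParams)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    group_pattern: Mapping[str, float] = field(
        default_factory=lambda: {"master": -0.5, "yoked": 1.0, "control": -0.5})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rm_correlation < 1:
            raise ValueError("rm_correlation must lie in [0, 1)")
        if not 0 <= self.gender_mix <= 1:
            raise ValueError("gender_mix must lie in [0, 1]")
        if self.target_between_f < 0:
            raise ValueError("target_between_f must be nonnegative")

    @property
    def group_proportions(self) -> dict[str, float]:
        return {g: 1.0 / len(GROUPS) for g in GROUPS}


@dataclass
class ParticipantRecord:
    assignment: GroupAssignment
    age: int
    lh_pre: list[TrialRecord]
    lh_test: list[TrialRecord]
    sdt: list[TrialRecord]
    surveys: dict
    tone_annoyance: int

    @property
    def participant_id(self) -> str:
        return self.assignment.participant_id

    @property
    def group(self) -> str:
        return self.assignment.group


# --------------------------------------------------------------------------
# Effect-size calibration
# --------------------------------------------------------------------------

def calibrate_effect_size(config: CohortConfig) -> LatencyModel:
    """Return the latency model with group offsets hitting the target f.

    The subject-intercept SD is first set from ``rm_correlation`` (the
    intercept share of block-score variance), then the centered group
    pattern is scaled so the population Cohen f of block scores equals
    ``target_between_f`` exactly.  Raises if the implied slowest group would
    press into the 15-s ceiling (truncation would bias the calibration).
    """
    base = config.latency_model
    rho = config.rm_correlation
    v_block_noise = base.lognormal_var / base.trials_per_block
    subject_sd = math.sqrt(rho / (1.0 - rho) * v_block_noise)
    model = replace(base, subject_sd_s=subject_sd)

    props = config.group_proportions
    pattern = dict(config.group_pattern)
    mean_p = sum(props[g] * pattern[g] for g in GROUPS)
    centered = {g: pattern[g] - mean_p for g in GROUPS}
    rms = math.sqrt(sum(props[g] * centered[g] ** 2 for g in GROUPS))
    if config.target_between_f == 0 or rms == 0:
        shifts = {g: 0.0 for g in GROUPS}
    else:
        a = config.target_between_f * math.sqrt(model.block_score_var) / rms
        shifts = {g: a * centered[g] for g in GROUPS}
    model = replace(model, group_shift_s=shifts)

    worst = (model.lognormal_mean_s + max(shifts.values())
             + max(model.block_trend_s)
             + 2 * math.sqrt(model.lognormal_var) + 4 * model.subject_sd_s)
    if worst > model.fail_ceiling_s:
        raise ValueError(
            f"target f={config.target_between_f} pushes the slowest group into "
            f"the {model.fail_ceiling_s}-s ceiling (upper range {worst:.1f} s); "
            "truncation would bias the calibration")
    return model


def estimate_between_f(block_scores: np.ndarray, groups: Sequence[str]) -> float:
    """Plug-in Cohen f from an (n_subjects x n_blocks) block-score matrix.

    Group deviations are taken on subject-level cell means; the error SD is
    the pooled within-cell (group x block) SD, which excludes the shared
    block trend exactly as the design's error term does.
    """
    block_scores = np.asarray(block_scores, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    grand = block_scores.mean()
    n = len(groups)
    var_between = 0.0
    ss_within = 0.0
    n_cells = 0
    for g in labels:
        rows = block_scores[groups == g]
        var_between += (len(rows) / n) * (rows.mean() - grand) ** 2
        for b in range(block_scores.shape[1]):
            cell = rows[:, b]
            ss_within += ((cell - cell.mean()) ** 2).sum()
            n_cells += len(cell) - 1
    return math.sqrt(var_between / (ss_within / n_cells))


# --------------------------------------------------------------------------
# Session simulators
# --------------------------------------------------------------------------

def _lh_test_latency(model: LatencyModel, group: str, block: int,
                     u_i: float, rng: np.random.Generator) -> float:
    raw = (model.group_shift_s.get(group, 0.0) + model.block_trend_s[block]
           + u_i + rng.lognormal(math.log(model.median_s), model.sigma_log))
    return float(np.clip(raw, model.min_latency_s, model.fail_ceiling_s + 1.0))


def simulate_lh_session(assignment: GroupAssignment,
                        schedule: Sequence[LHTrialPlan],
                        model: LatencyModel,
                        rng: np.random.Generator,
                        phase: str = "test",
                        subject_intercept: Optional[float] = None,
                        giveup_trial: Optional[int] = None,
                        ) -> list[TrialRecord]:
    """Simulate one LH phase for one participant.

    Pretreatment honors the yoking contract: yoked tones last the full trial
    regardless of presses (keypress stream from an exploration model with a
    geometric post-give-up decline), the control group never presses, and
    the master group escapes with latency drawn from its pretreatment
    distribution.  In the test phase all groups draw latencies from their
    calibrated group x block distributions.
    """
    if not schedule:
        raise ValueError("empty schedule")
    if subject_intercept is None:
        subject_intercept = float(rng.normal(0.0, model.subject_sd_s))
    records: list[TrialRecord] = []

    if phase == "pretreatment":
        if assignment.group == "yoked" and giveup_trial is None:
            giveup_trial = int(rng.integers(8, 21))
        for plan in schedule:
            ceiling = model.pre_ceiling_s
            if assignment.group == "control":
                presses: tuple[str, ...] = ()
                latency, tone = ceiling, ceiling
            elif assignment.group == "yoked":
                t = plan.trial_index
                rate = 8.0 if t < giveup_trial else 8.0 * 0.6 ** (t - giveup_trial + 1)
                n_press = int(rng.poisson(rate))
                presses = tuple(rng.choice(["L", "R"], size=n_press))
                latency, tone = ceiling, ceiling  # tone independent of presses
            else:  # master
                raw = (subject_intercept * 0.5
                       + rng.lognormal(math.log(model.pre_median_s),
                                       model.pre_sigma_log))
                latency = float(np.clip(raw, model.min_latency_s, ceiling))
                escaped = latency < ceiling
                presses = plan.correct_sequence if escaped else ("L", "R", "L")
                tone = latency if escaped else ceiling
            records.append(TrialRecord(
                task="lh_pre", trial_index=plan.trial_index,
                correct_sequence=plan.correct_sequence, keypresses=presses,
                latency_s=latency, tone_duration_s=tone))
        return records

    trials_per_block = model.trials_per_block
    for plan in schedule:
        block = (plan.trial_index - 1) // trials_per_block
        latency = _lh_test_latency(model, assignment.group, block,
                                   subject_intercept, rng)
        failed = latency > plan.max_latency_s
        presses = plan.correct_sequence if not failed else ("L", "R")
        records.append(TrialRecord(
            task="lh_test", trial_index=plan.trial_index,
            block=block + 1,
            correct_sequence=plan.correct_sequence, keypresses=presses,
            latency_s=latency,
            tone_duration_s=min(latency, plan.max_latency_s)))
    return records


def _draw_rt(obs: ObserverParams, artifacts: ArtifactRates,
             rng: np.random.Generator) -> float:
    u = rng.random()
    if u < artifacts.p_inattentive_fast:
        return float(rng.uniform(50, 140))
    if u < artifacts.p_inattentive_fast + artifacts.p_inattentive_slow:
        return float(rng.uniform(2600, 3800))
    if u < (artifacts.p_inattentive_fast + artifacts.p_inattentive_slow
            + artifacts.p_outlier):
        return float(rng.uniform(1600, 2400))
    return float(obs.rt_shift_ms
                 + rng.lognormal(math.log(obs.rt_median_ms), obs.rt_sigma_log))


def simulate_sdt_session(assignment: GroupAssignment,
                         schedule: Sequence[SDTTrialPlan],
                         model: ObserverParams,
                         rng: np.random.Generator,
                         artifacts: ArtifactRates = ArtifactRates(),
                         ) -> list[TrialRecord]:
    """Simulate the reward task for one participant.

    Rewards are delivered only on correct trials; a scheduled reward missed
    by an incorrect response carries over to the next correct identification
    of the *same* stimulus type.  Each delivered reward nudges the criterion
    toward the rewarded response by ``criterion_shift_per_reward`` times the
    participant's group multiplier.
    """
    rich = assignment.sdt_rich_stimulus
    mult = model.group_multiplier.get(assignment.group, 1.0)
    c = model.initial_criterion
    pending = {"rich": 0, "lean": 0}
    records: list[TrialRecord] = []
    for plan in schedule:
        is_rich = plan.stimulus == rich
        evidence = rng.normal(model.d_prime / 2 if is_rich else -model.d_prime / 2, 1.0)
        respond_rich = (evidence + c) > 0
        lean_label = "long" if rich == "short" else "short"
        response = rich if respond_rich else lean_label
        correct = response == plan.stimulus
        role = "rich" if is_rich else "lean"
        delivered = False
        if correct and (plan.reward_scheduled or pending[role] > 0):
            delivered = True
            if not plan.reward_scheduled:
                pending[role] -= 1
        elif plan.reward_scheduled and not correct:
            pending[role] += 1
        if delivered:
            c += model.criterion_shift_per_reward * mult * (1 if is_rich else -1)
        records.append(TrialRecord(
            task="sdt", trial_index=plan.trial_index, block=plan.block,
            stimulus=plan.stimulus, response=response, correct=correct,
            rt_ms=_draw_rt(model, artifacts, rng),
            reward_delivered=delivered))
    return records


# --------------------------------------------------------------------------
# Surveys
# --------------------------------------------------------------------------

def _total_sd(spec: InstrumentSpec, im: InstrumentModel,
              items: Optional[Sequence[int]] = None) -> float:
    n = len(items) if items is not None else spec.n_items
    # item noise + discretization variance (uniform rounding error)
    return math.sqrt(n ** 2 * im.subject_sd ** 2
                     + n * (im.item_sd ** 2 + 1.0 / 12.0))


def _items_from_latent(theta: float, spec: InstrumentSpec, im: InstrumentModel,
                       rng: np.random.Generator,
                       n_items: Optional[int] = None) -> list[int]:
    """Observed item responses for one respondent.

    Reverse-keyed items are emitted reflected (a high-trait respondent
    answers them at the low end), so that keyed scoring recovers the latent
    sum; clipping commutes with the reflection.
    """
    n = n_items if n_items is not None else spec.n_items
    raw = np.rint(theta + rng.normal(0.0, im.item_sd, size=n))
    keyed = np.clip(raw, spec.min_score, spec.max_score)
    out = []
    for i, v in enumerate(keyed, start=1):
        if i in spec.reverse_keyed:
            v = spec.min_score + spec.max_score - v
        out.append(int(v))
    return out


def simulate_surveys(assignment: GroupAssignment, model: SurveyModelParams,
                     seed: int) -> dict:
    """Generate all item-level survey responses for one participant.

    Pre/post state instruments share a subject latent trait; the post latent
    is shifted by the configured group x time effect expressed on the
    total-score SD scale (converted analytically to a per-item latent
    shift), plus a small state fluctuation.  Trait instruments (the
    depression inventory, trait anxiety, attributional style) are generated
    once.
    """
    rng = np.random.default_rng(seed)
    out: dict = {}
    group = assignment.group

    bdi_spec, bdi_m = DEFAULT_INSTRUMENTS["bdi"], model.instruments["bdi"]
    theta = rng.normal(bdi_m.latent_mean, bdi_m.subject_sd)
    out["bdi"] = _items_from_latent(theta, bdi_spec, bdi_m, rng)

    def pre_post(name: str, endpoint: str, n_items: Optional[int] = None):
        spec, im = DEFAULT_INSTRUMENTS[name], model.instruments[name]
        n = n_items if n_items is not None else spec.n_items
        theta_pre = rng.normal(im.latent_mean, im.subject_sd)
        shift_sd = model.state_shift_sd.get((group, endpoint), 0.0)
        delta = shift_sd * _total_sd(spec, im, range(n)) / n
        theta_post = theta_pre + delta + rng.normal(0.0, im.state_sd)
        return (_items_from_latent(theta_pre, spec, im, rng, n),
                _items_from_latent(theta_post, spec, im, rng, n))

    # anxiety inventory: full 40 items pre (state+trait), state half post
    stai_spec, stai_m = DEFAULT_INSTRUMENTS["stai"], model.instruments["stai"]
    theta_pre = rng.normal(stai_m.latent_mean, stai_m.subject_sd)
    out["stai_pre"] = _items_from_latent(theta_pre, stai_spec, stai_m, rng)
    shift_sd = model.state_shift_sd.get((group, "stai_state"), 0.0)
    n_state = len(stai_spec.subscales["state"])
    delta = shift_sd * _total_sd(stai_spec, stai_m, range(n_state)) / n_state
    theta_post = theta_pre + delta + rng.normal(0.0, stai_m.state_sd)
    out["stai_state_post"] = _items_from_latent(theta_post, stai_spec, stai_m,
                                                rng, n_state)

    out["fcps_pre"], out["fcps_post"] = pre_post("fcps", "fcps")
    out["dars_pre"], out["dars_post"] = pre_post("dars", "dars")

    asq = np.clip(np.rint(rng.normal(model.asq_mean, model.asq_sd, size=(12, 3))),
                  1, 7).astype(int)
    out["asq"] = asq.tolist()
    out["tone_annoyance"] = int(np.clip(
        round(rng.normal(model.tone_annoyance_mean, model.tone_annoyance_sd)), 0, 10))
    return out


# --------------------------------------------------------------------------
# Whole-cohort simulation
# --------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Draw a complete synthetic cohort: assignments, both LH phases, the
    reward-task session, and all surveys.  Fully reproducible per seed (a
    single root seed spawns named substreams)."""
    if config.n_total < 3:
        raise ValueError("need n_total >= 3 to fill three groups")
    root = np.random.SeedSequence(config.rng_seed)
    seeds = {name: s for name, s in zip(
        ("groups", "schedule", "participants"), root.spawn(3))}

    n_f = int(round(config.n_total * config.gender_mix))
    roster = [(f"P{i + 1:04d}", "f" if i < n_f else "m")
              for i in range(config.n_total)]
    group_seed = int(seeds["groups"].generate_state(1)[0] % (2 ** 31))
    assignments = assign_groups(roster, seed=group_seed)

    model = calibrate_effect_size(config)
    sched_seed = int(seeds["schedule"].generate_state(1)[0] % (2 ** 31))
    pre_sched = generate_lh_schedule(LHScheduleSpec.pretreatment(sched_seed))
    test_sched = generate_lh_schedule(LHScheduleSpec.test(sched_seed + 1))

    records: list[ParticipantRecord] = []
    child_seeds = seeds["participants"].spawn(config.n_total)
    for assignment, child in zip(assignments, child_seeds):
        rng = np.random.default_rng(child)
        sdt_seed = int(rng.integers(2 ** 31))
        sdt_sched = generate_sdt_schedule(
            SDTScheduleSpec(rich_stimulus=assignment.sdt_rich_stimulus,
                            key_mapping=assignment.sdt_key_mapping,
                            rng_seed=sdt_seed))
        u_i = float(rng.normal(0.0, model.subject_sd_s))
        lh_pre = simulate_lh_session(assignment, pre_sched, model, rng,
                                     phase="pretreatment", subject_intercept=u_i)
        lh_test = simulate_lh_session(assignment, test_sched, model, rng,
                                      phase="test", subject_intercept=u_i)
        sdt = simulate_sdt_session(assignment, sdt_sched, config.observer_model,
                                   rng, artifacts=config.artifact_rates)
        surveys = simulate_surveys(assignment, config.survey_model,
                                   seed=int(rng.integers(2 ** 31)))
        records.append(ParticipantRecord(
            assignment=assignment,
            age=int(rng.integers(18, 31)),
            lh_pre=lh_pre, lh_test=lh_test, sdt=sdt,
            surveys=surveys,
            tone_annoyance=surveys.pop("tone_annoyance"),
        ))
    return records


# --------------------------------------------------------------------------
# Vectorized fast paths for Monte-Carlo power
# --------------------------------------------------------------------------

def _round_robin_sizes(n: int, k: int = len(GROUPS)) -> list[int]:
    return [n // k + (1 if i < n % k else 0) for i in range(k)]


def simulate_latency_blocks(config: CohortConfig, n_cohorts: int,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (n_cohorts, N, m) block-score arrays from the latency model.

    Identical generative model to :func:`simulate_lh_session`'s test phase
    (including the 15-s per-trial truncation), vectorized for Monte-Carlo
    power estimation.  Returns the scores and the group label vector.
    """
    model = calibrate_effect_size(config)
    n, m, tpb = config.n_total, len(model.block_trend_s), model.trials_per_block
    sizes = _round_robin_sizes(n)
    groups = np.concatenate([[g] * s for g, s in zip(GROUPS, sizes)])
    shift = np.array([model.group_shift_s[g] for g in groups])  # (N,)
    trend = np.asarray(model.block_trend_s)  # (m,)

    u = rng.normal(0.0, model.subject_sd_s, size=(n_cohorts, n, 1, 1))
    resid = rng.lognormal(math.log(model.median_s), model.sigma_log,
                          size=(n_cohorts, n, m, tpb))
    trials = u + shift[None, :, None, None] + trend[None, None, :, None] + resid
    np.clip(trials, model.min_latency_s, model.fail_ceiling_s, out=trials)
    return trials.mean(axis=3), groups


def _oneway_f_vectorized(values: np.ndarray, groups: np.ndarray
                         ) -> tuple[np.ndarray, int, int]:
    """One-way ANOVA F over axis 1 of a (reps, N) array; returns (F, df1, df2)."""
    labels = np.unique(groups)
    n = values.shape[1]
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in labels:
        cols = values[:, groups == g]
        gm = cols.mean(axis=1, keepdims=True)
        ssb += cols.shape[1] * (gm[:, 0] - grand[:, 0]) ** 2
        ssw += ((cols - gm) ** 2).sum(axis=1)
    df1, df2 = len(labels) - 1, n - len(labels)
    return (ssb / df1) / (ssw / df2), df1, df2


def simulate_latency_rejections(config: CohortConfig, reps: int, seed: int,
                                alpha: float = 0.05) -> np.ndarray:
    """Between-groups split-plot F rejections over simulated cohorts.

    The between-groups F in the split-plot layout equals the one-way F on
    subject means across blocks, which the vectorized path exploits.
    """
    rng = np.random.default_rng(seed)
    rejections = np.zeros(reps, dtype=bool)
    chunk = max(1, min(reps, int(2e7 // (config.n_total * 18))))
    done = 0
    while done < reps:
        size = min(chunk, reps - done)
        blocks, groups = simulate_latency_blocks(config, size, rng)
        f_vals, df1, df2 = _oneway_f_vectorized(blocks.mean(axis=2), groups)
        rejections[done:done + size] = f_vals > sps.f.ppf(1 - alpha, df1, df2)
        done += size
    return rejections


def simulate_survey_rejections(config: CohortConfig, reps: int, seed: int,
                               alpha: float = 0.05,
                               endpoint: str = "fcps") -> np.ndarray:
    """Group x time interaction rejections on simulated state-survey totals.

    With two within-levels the interaction F equals the one-way F on the
    post-minus-pre difference scores, simulated here at the total-score
    level using the instrument's analytic total SD.
    """
    spec = DEFAULT_INSTRUMENTS[endpoint]
    im = config.survey_model.instruments[endpoint]
    sd_tot = _total_sd(spec, im)
    n = config.n_total
    sizes = _round_robin_sizes(n)
    groups = np.concatenate([[g] * s for g, s in zip(GROUPS, sizes)])
    shift = np.array([
        config.survey_model.state_shift_sd.get((g, endpoint), 0.0) * sd_tot
        for g in groups])
    rng = np.random.default_rng(seed)
    state_sd_tot = spec.n_items * im.state_sd
    noise_sd = math.sqrt(state_sd_tot ** 2
                         + 2 * spec.n_items * (im.item_sd ** 2 + 1 / 12))
    diffs = shift[None, :] + rng.normal(0.0, noise_sd, size=(reps, n))
    f_vals, df1, df2 = _oneway_f_vectorized(diffs, groups)
    return f_vals > sps.f.ppf(1 - alpha, df1, df2)
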