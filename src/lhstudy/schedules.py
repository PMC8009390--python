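"""Deterministic trial-schedule generation for both behavioral tasks.

The learned-helplessness (LH) task has two phases: a 30-trial unsignaled
pretreatment phase (10-s tone, two-button escape sequences) and an 18-trial
signaled test phase (5-s warning light followed by a 10-s tone, three-button
sequences).  The probabilistic-reward signal-detection task (SDT) runs four
50-trial blocks with an asymmetric 15:5 rich:lean reward allocation over the
20 rewarded trials of each block.

Everything here is deterministic given the spec's ``rng_seed``; the schedules
carry no behavior, only the planned structure a session replays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LHScheduleSpec",
    "LHTrialPlan",
    "SDTScheduleSpec",
    "SDTTrialPlan",
    "GroupAssignment",
    "GROUPS",
    "generate_lh_schedule",
    "generate_sdt_schedule",
    "assign_groups",
    "lh_schedule_frame",
    "sdt_schedule_frame",
]

GROUPS = ("master", "yoked", "control")

Phase = Literal["pretreatment", "test"]
Stimulus = Literal["short", "long"]


class ScheduleConfigError(ValueError):
    """Raised when a schedule spec violates its own invariants."""


@dataclass(frozen=True)
class LHScheduleSpec:
    """Parameters of one LH phase.

    ``signal_duration_s`` is 0 in pretreatment (tone is unsignaled) and 5 in
    the test phase (red warning light); ``max_latency_s`` is therefore the
    tone duration alone (10 s) or signal + tone (15 s).
    """

    phase: Phase
    n_trials: int
    tone_duration_s: float = 10.0
    signal_duration_s: float = 0.0
    isi_min_s: float = 10.0
    isi_max_s: float = 20.0
    sequence_length: int = 2
    start_left: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ScheduleConfigError("n_trials must be positive")
        if not (self.isi_min_s <= self.isi_mean_s <= self.isi_max_s):
            raise ScheduleConfigError(
                f"invalid ISI bounds: [{self.isi_min_s}, {self.isi_max_s}]"
            )
        if self.sequence_length not in (2, 3):
            raise ScheduleConfigError("sequence_length must be 2 or 3")

    @property
    def isi_mean_s(self) -> float:
        return 0.5 * (self.isi_min_s + self.isi_max_s)

    @property
    def max_latency_s(self) -> float:
        return self.signal_duration_s + self.tone_duration_s

    @classmethod
    def pretreatment(cls, seed: int = 0, **kw) -> "LHScheduleSpec":
        """30 unsignaled 10-s trials, two-button sequences."""
        return cls(phase="pretreatment", n_trials=30, signal_duration_s=0.0,
                   sequence_length=2, rng_seed=seed, **kw)

    @classmethod
    def test(cls, seed: int = 0, **kw) -> "LHScheduleSpec":
        """18 signaled trials: 5-s warning light, then the 10-s tone."""
        return cls(phase="test", n_trials=18, signal_duration_s=5.0,
                   sequence_length=3, rng_seed=seed, **kw)


@dataclass(frozen=True)
class LHTrialPlan:
    trial_index: int  # 1-based
    isi_s: float
    correct_sequence: tuple[str, ...]
    max_latency_s: float


def _sequence(length: int, left_first: bool) -> tuple[str, ...]:
    cycle = ("L", "R") if left_first else ("R", "L")
    return tuple(itertools.islice(itertools.cycle(cycle), length))


def generate_lh_schedule(spec: LHScheduleSpec) -> list[LHTrialPlan]:
    """Generate the trial plans for one LH phase.

    ISIs are i.i.d. Uniform(isi_min, isi_max) — the simplest distribution
    matching the stated 10–20 s range with a 15-s mean.  The correct escape
    sequence alternates orientation strictly by trial index (L-R, R-L, … or
    L-R-L, R-L-R, …), regardless of whether the previous trial succeeded, so
    that master and yoked participants face identical schedules.
    """
    rng = np.random.default_rng(spec.rng_seed)
    isis = rng.uniform(spec.isi_min_s, spec.isi_max_s, size=spec.n_trials)
    plans = []
    for t in range(spec.n_trials):
        left_first = spec.start_left if t % 2 == 0 else not spec.start_left
        plans.append(
            LHTrialPlan(
                trial_index=t + 1,
                isi_s=float(isis[t]),
                correct_sequence=_sequence(spec.sequence_length, left_first),
                max_latency_s=spec.max_latency_s,
            )
        )
    return plans


@dataclass(frozen=True)
class SDTScheduleSpec:
    """Reward-allocation plan for the signal-detection task.

    Defaults follow the probabilistic-reward paradigm: 4 blocks x 50 trials,
    20 rewarded per block split 15 (rich) : 5 (lean), balanced short/long
    stimulus presentation, 5-cent reward feedback.
    """

    n_blocks: int = 4
    trials_per_block: int = 50
    rewarded_per_block: int = 20
    rich_rewarded: int = 15
    lean_rewarded: int = 5
    rich_stimulus: Stimulus = "short"
    key_mapping: Mapping[str, str] = field(
        default_factory=lambda: {"short": "S", "long": "L"}
    )
    reward_value_cents: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rich_rewarded + self.lean_rewarded != self.rewarded_per_block:
            raise ScheduleConfigError("rich + lean rewards must equal rewarded_per_block")
        if self.rewarded_per_block > self.trials_per_block:
            raise ScheduleConfigError("cannot reward more trials than exist")
        n_each = self.trials_per_block // 2
        if max(self.rich_rewarded, self.lean_rewarded) > n_each:
            raise ScheduleConfigError(
                "reward quota exceeds per-stimulus trial count "
                f"({n_each} trials of each stimulus per block)"
            )

    @property
    def lean_stimulus(self) -> Stimulus:
        return "long" if self.rich_stimulus == "short" else "short"


@dataclass(frozen=True)
class SDTTrialPlan:
    block: int  # 1-based
    trial_index: int  # 1-based within block
    stimulus: Stimulus
    reward_scheduled: bool


def generate_sdt_schedule(spec: SDTScheduleSpec) -> list[SDTTrialPlan]:
    """Generate SDT trial plans with exact per-block reward quotas.

    Each block presents trials_per_block // 2 short and long stimuli in a
    seeded shuffle; reward flags are then placed by uniform seeded shuffle
    within each stimulus-type subsequence, honoring the rich/lean quotas
    exactly (pseudorandom placement, no run-length constraints).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_each = spec.trials_per_block // 2
    plans: list[SDTTrialPlan] = []
    for block in range(1, spec.n_blocks + 1):
        stimuli = np.array(["short"] * n_each + ["long"] * n_each +
                           (["short"] if spec.trials_per_block % 2 else []))
        rng.shuffle(stimuli)
        rewarded = np.zeros(spec.trials_per_block, dtype=bool)
        for stim, quota in ((spec.rich_stimulus, spec.rich_rewarded),
                            (spec.lean_stimulus, spec.lean_rewarded)):
            idx = np.flatnonzero(stimuli == stim)
            chosen = rng.choice(idx, size=quota, replace=False)
            rewarded[chosen] = True
        for t in range(spec.trials_per_block):
            plans.append(
                SDTTrialPlan(
                    block=block,
                    trial_index=t + 1,
                    stimulus=str(stimuli[t]),
                    reward_scheduled=bool(rewarded[t]),
                )
            )
    return plans


@dataclass(frozen=True)
class GroupAssignment:
    participant_id: str
    group: str
    gender: str
    sdt_rich_stimulus: Stimulus
    sdt_key_mapping: Mapping[str, str]


def assign_groups(
    participants: Sequence[tuple[str, str]],
    seed: int,
    groups: Sequence[str] = GROUPS,
) -> list[GroupAssignment]:
    """Gender-stratified random assignment to the three treatment groups.

    Parameters
    ----------
    participants
        Sequence of ``(participant_id, gender)`` pairs.
    seed
        Seeds both the within-stratum shuffles and the counterbalancing.

    Within each gender stratum members are shuffled and dealt round-robin to
    groups; the deal position carries over between strata so total group
    sizes also differ by at most one.  Within each group, the SDT rich
    stimulus alternates over a shuffled member order (half short-rich, half
    long-rich, +/-1) and the response-key mapping alternates within each
    rich-stimulus half.
    """
    if not participants:
        raise ValueError("empty participant roster")
    rng = np.random.default_rng(seed)
    by_gender: dict[str, list[tuple[str, str]]] = {}
    for pid, gender in participants:
        by_gender.setdefault(gender, []).append((pid, gender))

    assigned: dict[str, tuple[str, str]] = {}
    cursor = 0
    for gender in sorted(by_gender):
        members = by_gender[gender]
        order = rng.permutation(len(members))
        for i in order:
            pid, g = members[i]
            assigned[pid] = (groups[cursor % len(groups)], g)
            cursor += 1

    # counterbalance SDT mappings within each treatment group
    mappings = ({"short": "S", "long": "L"}, {"short": "L", "long": "S"})
    out: dict[str, GroupAssignment] = {}
    for group in groups:
        ids = [pid for pid, (g, _) in assigned.items() if g == group]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for j, pid in enumerate(ids):
            rich: Stimulus = "short" if j % 2 == 0 else "long"
            out[pid] = GroupAssignment(
                participant_id=pid,
                group=group,
                gender=assigned[pid][1],
                sdt_rich_stimulus=rich,
                sdt_key_mapping=mappings[(j // 2) % 2],
            )
    return [out[pid] for pid, _ in participants]


def lh_schedule_frame(spec: LHScheduleSpec, plans: Sequence[LHTrialPlan]) -> pd.DataFrame:
    """Tidy one-row-per-trial serialization of an LH schedule."""
    return pd.DataFrame(
        {
            "phase": spec.phase,
            "trial_index": [p.trial_index for p in plans],
            "isi_s": [p.isi_s for p in plans],
            "correct_sequence": ["-".join(p.correct_sequence) for p in plans],
            "max_latency_s": [p.max_latency_s for p in plans],
        }
    )


def sdt_schedule_frame(plans: Sequence[SDTTrialPlan]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block": [p.block for p in plans],
            "trial_index": [p.trial_index for p in plans],
            "stimulus": [p.stimulus for p in plans],
            "reward_scheduled": [p.reward_scheduled for p in plans],
        }
    )
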