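"""Behavioral scoring: LH trial coding and endpoints, signal-detection
discriminability and response bias, reaction-time exclusions, survey scoring,
and exploratory keypress summaries.

Signal-detection scores follow the log-linear convention of the
probabilistic-reward literature:

    log d = 1/2 * log10( (long_c * short_c) / (long_i * short_i) )
    log b = 1/2 * log10( (rich_c * lean_i) / (rich_i * lean_c) )

with ``log b`` oriented so that positive values always mean bias toward the
more frequently rewarded ("rich") response, regardless of which physical
stimulus was counterbalanced to be rich.  Whenever any cell of a table is
zero, 0.5 is added to every cell before taking logs (standard log-linear
correction); nonzero tables are left untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "TrialRecord",
    "TrialOutcome",
    "LHMeasures",
    "SDTBlockCounts",
    "SDTBlockScores",
    "ExclusionReport",
    "InstrumentSpec",
    "code_test_trial",
    "trials_to_criterion",
    "compute_lh_measures",
    "compute_log_d",
    "compute_log_b",
    "apply_rt_exclusions",
    "compute_sdt_scores",
    "sdt_window_scores",
    "score_bdi_anhedonic",
    "score_likert_instrument",
    "score_asq",
    "keypress_exploration_summary",
    "NOT_REACHED",
]

TrialOutcome = Literal["avoidance", "escape", "fail"]

#: Sentinel for acquisition criteria never met within the session.
NOT_REACHED = None


class UndefinedScoreError(ValueError):
    """Raised when a score is undefined for the given counts (e.g. all zero)."""


@dataclass
class TrialRecord:
    """One observed trial from either task.

    LH trials carry ``latency_s`` (seconds from trial start to the correct
    sequence; the phase ceiling if never completed) and ``keypresses`` (an
    ordered list of button labels).  SDT trials carry ``stimulus``,
    ``response``, ``rt_ms`` and ``reward_delivered``.
    """

    task: Literal["lh_pre", "lh_test", "sdt"]
    trial_index: int
    block: int = 1
    stimulus: Optional[str] = None
    response: Optional[str] = None
    correct: Optional[bool] = None
    rt_ms: Optional[float] = None
    reward_delivered: bool = False
    latency_s: Optional[float] = None
    correct_sequence: tuple[str, ...] = ()
    keypresses: tuple[str, ...] = ()
    tone_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.latency_s is not None and self.latency_s < 0:
            raise ValueError(f"negative latency on trial {self.trial_index}")
        if self.rt_ms is not None and self.rt_ms < 0:
            raise ValueError(f"negative RT on trial {self.trial_index}")


# --------------------------------------------------------------------------
# Learned-helplessness coding
# --------------------------------------------------------------------------

def code_test_trial(latency_s: float, max_s: float = 15.0,
                    signal_s: float = 5.0) -> TrialOutcome:
    """Code one test-phase trial from its correct-response latency.

    A correct response during the warning signal (latency <= ``signal_s``)
    terminates signal and tone: *avoidance*.  A correct response after the
    signal but within the trial window (<= ``max_s``) terminates the tone:
    *escape*.  Anything later (or no correct response, conventionally logged
    at the ceiling) is a *fail*.  Boundaries are closed from above: exactly
    5 s is an avoidance, exactly 15 s an escape.
    """
    if latency_s < 0:
        raise ValueError("latency must be nonnegative")
    if latency_s <= signal_s:
        return "avoidance"
    if latency_s <= max_s:
        return "escape"
    return "fail"


def trials_to_criterion(outcomes: Sequence[TrialOutcome],
                        criterion: Literal["avoidance", "escape"],
                        run_length: int = 3) -> Optional[int]:
    """1-based index of the trial completing the first qualifying run.

    The avoidance criterion requires ``run_length`` consecutive avoidance
    outcomes.  The escape criterion requires consecutive non-fail outcomes —
    any mix of escapes and avoidances qualifies (so three straight
    avoidances meets both criteria).  Returns ``None`` if never reached.
    """
    if criterion == "avoidance":
        ok = [o == "avoidance" for o in outcomes]
    elif criterion == "escape":
        ok = [o != "fail" for o in outcomes]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    run = 0
    for i, good in enumerate(ok):
        run = run + 1 if good else 0
        if run >= run_length:
            return i + 1
    return NOT_REACHED


@dataclass(frozen=True)
class LHMeasures:
    """The five test-phase behavioral endpoints."""

    trials_to_avoidance_criterion: Optional[int]
    trials_to_escape_criterion: Optional[int]
    n_avoidance: int
    n_failures: int
    mean_latency_s: float


def compute_lh_measures(trials: Sequence[TrialRecord],
                        max_s: float = 15.0,
                        signal_s: float = 5.0) -> LHMeasures:
    """Score one test session into its five endpoints.

    Failed trials contribute the ceiling latency (``max_s``) to the mean —
    the convention of the source paradigm, without which the mean is
    undefined for participants who never escape.
    """
    if not trials:
        raise ValueError("empty test session")
    latencies = []
    outcomes: list[TrialOutcome] = []
    for t in trials:
        if t.latency_s is None:
            raise ValueError(f"trial {t.trial_index} has no latency")
        out = code_test_trial(t.latency_s, max_s=max_s, signal_s=signal_s)
        outcomes.append(out)
        latencies.append(max_s if out == "fail" else min(t.latency_s, max_s))
    return LHMeasures(
        trials_to_avoidance_criterion=trials_to_criterion(outcomes, "avoidance"),
        trials_to_escape_criterion=trials_to_criterion(outcomes, "escape"),
        n_avoidance=sum(o == "avoidance" for o in outcomes),
        n_failures=sum(o == "fail" for o in outcomes),
        mean_latency_s=float(np.mean(latencies)),
    )


# --------------------------------------------------------------------------
# Signal-detection scores
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SDTBlockCounts:
    """Contingency counts for one block, keyed by reward role.

    ``rich``/``lean`` refer to the more/less frequently rewarded stimulus
    for this participant; the physical long/short labels are recovered via
    ``rich_stimulus`` where the discriminability formula needs them (the
    formula is symmetric, so the roles can stand in for the labels).
    """

    rich_correct: int
    rich_incorrect: int
    lean_correct: int
    lean_incorrect: int

    def __post_init__(self) -> None:
        for name in ("rich_correct", "rich_incorrect", "lean_correct", "lean_incorrect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return (self.rich_correct + self.rich_incorrect
                + self.lean_correct + self.lean_incorrect)


def _corrected(*cells: float) -> tuple[float, ...]:
    if any(c == 0 for c in cells):
        return tuple(c + 0.5 for c in cells)
    return cells


def compute_log_d(counts: SDTBlockCounts) -> float:
    """Discriminability: ½·log10 of the concordant-count cross ratio.

    Symmetric under exchange of the two stimuli, hence computable from
    rich/lean roles directly.
    """
    if counts.total == 0:
        raise UndefinedScoreError("all-zero contingency table")
    a, b, c, d = _corrected(counts.rich_correct, counts.rich_incorrect,
                            counts.lean_correct, counts.lean_incorrect)
    return 0.5 * math.log10((a * c) / (b * d))


def compute_log_b(counts: SDTBlockCounts) -> float:
    """Response bias toward the rich stimulus: ½·log10 of the cross ratio.

    Positive values mean the participant preferentially reports the rich
    stimulus; orientation is independent of which physical stimulus was
    assigned the rich role (counterbalancing neutrality).
    """
    if counts.total == 0:
        raise UndefinedScoreError("all-zero contingency table")
    a, b, c, d = _corrected(counts.rich_correct, counts.rich_incorrect,
                            counts.lean_correct, counts.lean_incorrect)
    return 0.5 * math.log10((a * d) / (b * c))


@dataclass(frozen=True)
class ExclusionReport:
    n_removed_fast: int
    n_removed_slow: int
    n_removed_sd: int
    n_retained: int
    flagged_empty: bool = False

    @property
    def n_removed(self) -> int:
        return self.n_removed_fast + self.n_removed_slow + self.n_removed_sd


def apply_rt_exclusions(trials: Sequence[TrialRecord],
                        fast_ms: float = 150.0,
                        slow_ms: float = 2500.0,
                        sd_mult: float = 3.0,
                        ) -> tuple[list[TrialRecord], ExclusionReport]:
    """Two-stage RT exclusion for one participant's SDT trials.

    Stage 1 drops inattentive trials with RT < ``fast_ms`` or > ``slow_ms``.
    Stage 2 drops trials outside mean ± ``sd_mult``·SD, with mean and SD
    computed once on the stage-1 survivors (single pass, no iteration).
    """
    fast = [t for t in trials if t.rt_ms is not None and t.rt_ms < fast_ms]
    slow = [t for t in trials if t.rt_ms is not None and t.rt_ms > slow_ms]
    stage1 = [t for t in trials
              if t.rt_ms is not None and fast_ms <= t.rt_ms <= slow_ms]
    removed_sd = 0
    retained = stage1
    if len(stage1) >= 2:
        rts = np.array([t.rt_ms for t in stage1])
        mean, sd = rts.mean(), rts.std(ddof=1)
        lo, hi = mean - sd_mult * sd, mean + sd_mult * sd
        retained = [t for t in stage1 if lo <= t.rt_ms <= hi]
        removed_sd = len(stage1) - len(retained)
    report = ExclusionReport(
        n_removed_fast=len(fast),
        n_removed_slow=len(slow),
        n_removed_sd=removed_sd,
        n_retained=len(retained),
        flagged_empty=len(retained) == 0,
    )
    assert report.n_removed + report.n_retained == len(trials)
    return retained, report


@dataclass(frozen=True)
class SDTBlockScores:
    block: int
    counts: SDTBlockCounts
    log_d: Optional[float]
    log_b: Optional[float]
    accuracy: float
    mean_rt_ms: float
    undefined: bool = False


def _counts_from_trials(trials: Sequence[TrialRecord],
                        rich_stimulus: str) -> SDTBlockCounts:
    k = {"rc": 0, "ri": 0, "lc": 0, "li": 0}
    for t in trials:
        role = "r" if t.stimulus == rich_stimulus else "l"
        k[role + ("c" if t.correct else "i")] += 1
    return SDTBlockCounts(k["rc"], k["ri"], k["lc"], k["li"])


def _score_group(block: int, trials: Sequence[TrialRecord],
                 rich_stimulus: str) -> SDTBlockScores:
    counts = _counts_from_trials(trials, rich_stimulus)
    n_rich = counts.rich_correct + counts.rich_incorrect
    n_lean = counts.lean_correct + counts.lean_incorrect
    undefined = n_rich < 1 or n_lean < 1
    return SDTBlockScores(
        block=block,
        counts=counts,
        log_d=None if undefined else compute_log_d(counts),
        log_b=None if undefined else compute_log_b(counts),
        accuracy=float(np.mean([t.correct for t in trials])) if trials else float("nan"),
        mean_rt_ms=float(np.mean([t.rt_ms for t in trials])) if trials else float("nan"),
        undefined=undefined,
    )


def compute_sdt_scores(trials: Sequence[TrialRecord], rich_stimulus: str
                       ) -> tuple[list[SDTBlockScores], list[float]]:
    """Per-block scores plus Δ response bias between consecutive blocks.

    Expects exclusions to have been applied already.  Returns the block
    scores in block order and the list of ``log_b[i+1] - log_b[i]``
    differences (NaN where either side is undefined).
    """
    blocks = sorted({t.block for t in trials})
    scores = [_score_group(b, [t for t in trials if t.block == b], rich_stimulus)
              for b in blocks]
    deltas = []
    for prev, cur in zip(scores, scores[1:]):
        if prev.log_b is None or cur.log_b is None:
            deltas.append(float("nan"))
        else:
            deltas.append(cur.log_b - prev.log_b)
    return scores, deltas


def sdt_window_scores(trials: Sequence[TrialRecord], rich_stimulus: str,
                      window: int = 20, trials_per_block: int = 50
                      ) -> tuple[list[SDTBlockScores], list[float]]:
    """Finer-grained variant of :func:`compute_sdt_scores` over consecutive
    ``window``-trial spans of the original session (windows are defined on
    planned trial positions, so excluded trials leave gaps)."""
    def pos(t: TrialRecord) -> int:
        return (t.block - 1) * trials_per_block + (t.trial_index - 1)

    n_windows = (max((pos(t) for t in trials), default=-1) + window) // window
    scores = []
    for w in range(n_windows):
        members = [t for t in trials if w * window <= pos(t) < (w + 1) * window]
        scores.append(_score_group(w + 1, members, rich_stimulus))
    deltas = []
    for prev, cur in zip(scores, scores[1:]):
        if prev.log_b is None or cur.log_b is None:
            deltas.append(float("nan"))
        else:
            deltas.append(cur.log_b - prev.log_b)
    return scores, deltas


# --------------------------------------------------------------------------
# Survey scoring
# --------------------------------------------------------------------------

def score_bdi_anhedonic(item_scores: Sequence[int]) -> int:
    """Anhedonia subscale of the 21-item depression inventory: the sum of
    items 4 (loss of pleasure), 12 (loss of interest) and 21 (loss of
    interest in sex); range 0–9."""
    if len(item_scores) != 21:
        raise ValueError(f"expected 21 items, got {len(item_scores)}")
    for i, s in enumerate(item_scores, start=1):
        if not 0 <= s <= 3:
            raise ValueError(f"item {i} score {s} outside 0-3")
    return int(item_scores[3] + item_scores[11] + item_scores[20])


@dataclass(frozen=True)
class InstrumentSpec:
    """Keying/subscale configuration for a Likert instrument.

    Reverse-keyed sets and subscale memberships are configuration data (the
    questionnaire texts are copyrighted and keying is not public here); the
    defaults shipped with the cohort simulator are synthetic.
    """

    name: str
    n_items: int
    min_score: int
    max_score: int
    reverse_keyed: frozenset[int] = frozenset()  # 1-based item numbers
    subscales: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_items = set(range(1, self.n_items + 1))
        if not set(self.reverse_keyed) <= all_items:
            raise ValueError("reverse-keyed item outside instrument")
        for name, items in self.subscales.items():
            if not set(items) <= all_items:
                raise ValueError(f"subscale {name} references missing items")


def score_likert_instrument(item_scores: Sequence[int],
                            spec: InstrumentSpec) -> dict[str, int]:
    """Reflect reverse-keyed items and sum subscales.

    Returns ``{"total": ..., <subscale>: ...}``; with no subscales defined
    only the total is returned.
    """
    if len(item_scores) != spec.n_items:
        raise ValueError(
            f"{spec.name}: expected {spec.n_items} items, got {len(item_scores)}")
    keyed = []
    for i, s in enumerate(item_scores, start=1):
        if not spec.min_score <= s <= spec.max_score:
            raise ValueError(f"{spec.name} item {i} score {s} out of range")
        keyed.append(spec.min_score + spec.max_score - s
                     if i in spec.reverse_keyed else s)
    out = {"total": int(sum(keyed))}
    for name, items in spec.subscales.items():
        out[name] = int(sum(keyed[i - 1] for i in items))
    return out


def score_asq(ratings: np.ndarray, valences: Sequence[str]) -> dict[str, float]:
    """Attributional-style composites.

    Parameters
    ----------
    ratings
        12 x 3 array of 1–7 ratings; columns are the internality, stability
        and globality dimensions.
    valences
        12 labels, each ``"good"`` or ``"bad"``.

    Returns per-valence dimension means plus ``globality_specificity_index``
    (the bad-event globality composite: high = global attributional style,
    low = specific), the quantity the secondary analysis correlates with
    helplessness transfer.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.shape != (len(valences), 3):
        raise ValueError(f"expected ({len(valences)}, 3) ratings, got {ratings.shape}")
    if np.any((ratings < 1) | (ratings > 7)):
        raise ValueError("ASQ ratings must lie in [1, 7]")
    dims = ("internality", "stability", "globality")
    out: dict[str, float] = {}
    for valence in ("good", "bad"):
        mask = np.array([v == valence for v in valences])
        if not mask.any():
            raise ValueError(f"no {valence}-event scenarios present")
        for j, dim in enumerate(dims):
            out[f"{valence}_{dim}"] = float(ratings[mask, j].mean())
    out["globality_specificity_index"] = out["bad_globality"]
    return out


# --------------------------------------------------------------------------
# Exploratory keypress summaries
# --------------------------------------------------------------------------

def keypress_exploration_summary(trials: Sequence[TrialRecord],
                                 sequence_length: Optional[int] = None,
                                 giveup_threshold: float = 0.25,
                                 giveup_window: int = 3) -> dict:
    """Exploration metrics for one session's keypress streams.

    Sequences attempted are the consecutive non-overlapping chunks of each
    trial's press stream, chunked at the phase's correct-sequence length
    (trailing partial chunks ignored).  The give-up trial is the first t
    whose ``giveup_window``-trial median press count falls below
    ``giveup_threshold`` x the median of the first window; a silent start
    (first-window median 0) gives give-up at trial 1, and a participant who
    never declines is not-detected (``None``).
    """
    if sequence_length is None:
        lengths = {len(t.correct_sequence) for t in trials if t.correct_sequence}
        sequence_length = lengths.pop() if len(lengths) == 1 else 2

    presses = [len(t.keypresses) for t in trials]
    seqs_per_trial = []
    all_seqs: set[tuple[str, ...]] = set()
    for t in trials:
        chunks = {
            tuple(t.keypresses[i:i + sequence_length])
            for i in range(0, len(t.keypresses) - sequence_length + 1, sequence_length)
        }
        seqs_per_trial.append(len(chunks))
        all_seqs |= chunks

    give_up = None
    if presses:
        baseline = float(np.median(presses[:giveup_window]))
        if baseline == 0:
            give_up = 1
        else:
            for t in range(len(presses)):
                windowed = presses[t:t + giveup_window]
                if float(np.median(windowed)) < giveup_threshold * baseline:
                    give_up = t + 1
                    break
    return {
        "n_distinct_sequences": len(all_seqs),
        "sequences_per_trial": seqs_per_trial,
        "presses_per_trial": presses,
        "give_up_trial": give_up,
    }
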