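"""Scoring oracles: trial coding, acquisition criteria, log d / log b
identities against brute-force recomputation, RT exclusions, and survey
scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lhstudy import scoring
from lhstudy.scoring import (
    InstrumentSpec,
    SDTBlockCounts,
    TrialRecord,
    apply_rt_exclusions,
    code_test_trial,
    compute_lh_measures,
    compute_log_b,
    compute_log_d,
    compute_sdt_scores,
    keypress_exploration_summary,
    score_asq,
    score_bdi_anhedonic,
    score_likert_instrument,
    trials_to_criterion,
)


class TestTrialCoding:
    @pytest.mark.parametrize("latency,expected", [
        (4.0, "avoidance"),
        (5.0, "avoidance"),   # closed boundary
        (7.3, "escape"),
        (15.0, "escape"),     # closed boundary
        (15.01, "fail"),
    ])
    def test_latency_windows(self, latency, expected):
        assert code_test_trial(latency) == expected

    def test_negative_latency_rejected(self):
        with pytest.raises(ValueError):
            code_test_trial(-0.1)

    def test_ten_second_failure_variant(self):
        # alternative convention: failures at the 10-s tone offset
        assert code_test_trial(12.0, max_s=10.0) == "fail"

    @given(lo=st.floats(0, 20), hi=st.floats(0, 20))
    def test_monotone_in_latency(self, lo, hi):
        """Raising latency never moves the outcome toward avoidance."""
        order = {"avoidance": 0, "escape": 1, "fail": 2}
        lo, hi = min(lo, hi), max(lo, hi)
        assert order[code_test_trial(lo)] <= order[code_test_trial(hi)]


class TestTrialsToCriterion:
    def test_escape_met_avoidance_not(self):
        outcomes = ["escape", "escape", "avoidance"] + ["fail"] * 15
        assert trials_to_criterion(outcomes, "escape") == 3
        assert trials_to_criterion(outcomes, "avoidance") is None

    def test_three_avoidances_meet_both(self):
        outcomes = ["avoidance"] * 3
        assert trials_to_criterion(outcomes, "avoidance") == 3
        assert trials_to_criterion(outcomes, "escape") == 3

    def test_all_fails_never_reached(self):
        outcomes = ["fail"] * 18
        assert trials_to_criterion(outcomes, "avoidance") is None
        assert trials_to_criterion(outcomes, "escape") is None

    def test_run_in_the_middle(self):
        outcomes = ["fail", "escape", "avoidance", "escape", "fail"]
        assert trials_to_criterion(outcomes, "escape") == 4


def _lh_trials(latencies):
    return [TrialRecord(task="lh_test", trial_index=i + 1, latency_s=v)
            for i, v in enumerate(latencies)]


class TestLHMeasures:
    def test_all_avoidance(self):
        m = compute_lh_measures(_lh_trials([3.0] * 18))
        assert (m.n_avoidance, m.n_failures) == (18, 0)
        assert m.mean_latency_s == pytest.approx(3.0)
        assert m.trials_to_avoidance_criterion == 3

    def test_all_failures_use_ceiling(self):
        m = compute_lh_measures(_lh_trials([16.0] * 18))
        assert m.n_failures == 18
        assert m.mean_latency_s == pytest.approx(15.0)

    def test_mixed_session_arithmetic(self):
        lat = [4.0] * 6 + [8.0] * 6 + [16.0] * 6
        m = compute_lh_measures(_lh_trials(lat))
        assert m.mean_latency_s == pytest.approx((6 * 4 + 6 * 8 + 6 * 15) / 18)
        assert m.mean_latency_s == pytest.approx(9.0)

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            compute_lh_measures([])


counts_strategy = st.tuples(*[st.integers(0, 60)] * 4).filter(
    lambda t: sum(t) > 0)


class TestSignalDetectionScores:
    def test_worked_log_d(self):
        c = SDTBlockCounts(90, 10, 60, 40)
        assert compute_log_d(c) == pytest.approx(0.5 * math.log10(13.5), abs=1e-9)
        assert compute_log_d(c) == pytest.approx(0.5652, abs=5e-4)

    def test_worked_log_b(self):
        c = SDTBlockCounts(90, 10, 60, 40)
        assert compute_log_b(c) == pytest.approx(0.5 * math.log10(6), abs=1e-9)
        assert compute_log_b(c) == pytest.approx(0.3891, abs=5e-4)

    def test_chance_performance_gives_zero_log_d(self):
        assert compute_log_d(SDTBlockCounts(25, 25, 30, 30)) == pytest.approx(0.0)

    def test_no_bias_gives_zero_log_b(self):
        # rich_c*lean_i == rich_i*lean_c
        assert compute_log_b(SDTBlockCounts(40, 20, 20, 10)) == pytest.approx(0.0)

    def test_all_zero_counts_undefined(self):
        with pytest.raises(scoring.UndefinedScoreError):
            compute_log_d(SDTBlockCounts(0, 0, 0, 0))

    def test_zero_cell_correction_keeps_scores_finite(self):
        val = compute_log_b(SDTBlockCounts(50, 0, 30, 20))
        assert math.isfinite(val)
        # correction applied to every cell: identical to direct formula
        expected = 0.5 * math.log10((50.5 * 20.5) / (0.5 * 30.5))
        assert val == pytest.approx(expected)

    @given(counts=counts_strategy)
    def test_log_d_invariant_under_stimulus_swap(self, counts):
        a = SDTBlockCounts(*counts)
        b = SDTBlockCounts(counts[2], counts[3], counts[0], counts[1])
        assert compute_log_d(a) == pytest.approx(compute_log_d(b), abs=1e-12)

    @given(counts=counts_strategy)
    def test_log_b_antisymmetric_under_role_swap(self, counts):
        a = SDTBlockCounts(*counts)
        b = SDTBlockCounts(counts[2], counts[3], counts[0], counts[1])
        assert compute_log_b(a) == pytest.approx(-compute_log_b(b), abs=1e-12)

    @given(counts=counts_strategy, seed=st.integers(0, 99))
    def test_matches_bruteforce_from_raw_trials(self, counts, seed):
        """Scores recomputed from shuffled raw trial records match the
        direct-formula values on the same table."""
        rc, ri, lc, li = counts
        trials = []
        idx = 1
        for stim, correct, n in (("short", True, rc), ("short", False, ri),
                                 ("long", True, lc), ("long", False, li)):
            for _ in range(n):
                trials.append(TrialRecord(task="sdt", trial_index=idx, block=1,
                                          stimulus=stim, correct=correct,
                                          rt_ms=500.0))
                idx += 1
        rng = np.random.default_rng(seed)
        trials = [trials[i] for i in rng.permutation(len(trials))]
        blocks, _ = compute_sdt_scores(trials, rich_stimulus="short")
        table = SDTBlockCounts(rc, ri, lc, li)
        has_both = (rc + ri) >= 1 and (lc + li) >= 1
        if has_both:
            assert blocks[0].log_d == pytest.approx(compute_log_d(table))
            assert blocks[0].log_b == pytest.approx(compute_log_b(table))
        else:
            assert blocks[0].undefined

    def test_counterbalancing_neutrality(self):
        """Swapping the rich-stimulus assignment while relabeling responses
        accordingly yields the identical log b."""
        rng = np.random.default_rng(0)
        trials = []
        for i in range(100):
            stim = "short" if i % 2 == 0 else "long"
            correct = bool(rng.random() < (0.8 if stim == "short" else 0.6))
            trials.append(TrialRecord(task="sdt", trial_index=i + 1, block=1,
                                      stimulus=stim, correct=correct, rt_ms=400))
        b1, _ = compute_sdt_scores(trials, rich_stimulus="short")
        mirrored = [TrialRecord(task="sdt", trial_index=t.trial_index, block=1,
                                stimulus="long" if t.stimulus == "short" else "short",
                                correct=t.correct, rt_ms=t.rt_ms)
                    for t in trials]
        b2, _ = compute_sdt_scores(mirrored, rich_stimulus="long")
        assert b1[0].log_b == pytest.approx(b2[0].log_b)

    def test_block_deltas(self):
        trials = []
        per_block = [(40, 10, 30, 20), (42, 8, 28, 22),
                     (44, 6, 26, 24), (46, 4, 24, 26)]
        for blk, (rc, ri, lc, li) in enumerate(per_block, start=1):
            idx = 1
            for stim, correct, n in (("short", True, rc), ("short", False, ri),
                                     ("long", True, lc), ("long", False, li)):
                for _ in range(n):
                    trials.append(TrialRecord(task="sdt", trial_index=idx,
                                              block=blk, stimulus=stim,
                                              correct=correct, rt_ms=500))
                    idx += 1
        blocks, deltas = compute_sdt_scores(trials, rich_stimulus="short")
        assert len(blocks) == 4 and len(deltas) == 3
        expected = [compute_log_b(SDTBlockCounts(*c)) for c in per_block]
        for d, (a, b) in zip(deltas, zip(expected, expected[1:])):
            assert d == pytest.approx(b - a)
        # identical counts in all blocks -> all deltas zero
        same = [t for t in trials if t.block == 1]
        rep = same + [TrialRecord(task="sdt", trial_index=t.trial_index, block=2,
                                  stimulus=t.stimulus, correct=t.correct,
                                  rt_ms=t.rt_ms) for t in same]
        _, deltas0 = compute_sdt_scores(rep, rich_stimulus="short")
        assert deltas0 == [pytest.approx(0.0)]


def _sdt_rt_trials(rts):
    return [TrialRecord(task="sdt", trial_index=i + 1, block=1, stimulus="short",
                        correct=True, rt_ms=v) for i, v in enumerate(rts)]


class TestRTExclusions:
    def test_absolute_window(self):
        retained, rep = apply_rt_exclusions(_sdt_rt_trials([100, 3000, 500, 600]))
        assert rep.n_removed_fast == 1 and rep.n_removed_slow == 1
        assert {t.rt_ms for t in retained} == {500, 600}

    def test_sd_stage_removes_constructed_outlier(self):
        rng = np.random.default_rng(1)
        rts = list(500 + rng.normal(0, 30, size=99)) + [2400.0]
        trials = _sdt_rt_trials(rts)
        # oracle: brute-force mean/SD on the absolute-window survivors
        arr = np.array(rts)
        assert 2400 > arr.mean() + 3 * arr.std(ddof=1)
        retained, rep = apply_rt_exclusions(trials)
        assert rep.n_removed_sd == 1
        assert rep.n_removed_fast == rep.n_removed_slow == 0
        assert all(t.rt_ms != 2400.0 for t in retained)

    @given(rts=st.lists(st.floats(10, 5000), min_size=0, max_size=80))
    def test_exact_accounting(self, rts):
        trials = _sdt_rt_trials(rts)
        retained, rep = apply_rt_exclusions(trials)
        assert rep.n_removed + rep.n_retained == len(trials)
        assert rep.n_retained == len(retained)

    def test_empty_retention_flagged(self):
        _, rep = apply_rt_exclusions(_sdt_rt_trials([100, 50]))
        assert rep.flagged_empty


class TestSurveyScoring:
    def test_bdi_anhedonic_examples(self):
        assert score_bdi_anhedonic([0] * 21) == 0
        items = [0] * 21
        for i in (3, 11, 20):
            items[i] = 3
        assert score_bdi_anhedonic(items) == 9
        items2 = [0] * 21
        items2[3], items2[11], items2[20] = 1, 2, 0
        assert score_bdi_anhedonic(items2) == 3

    def test_bdi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_bdi_anhedonic([0] * 20 + [4])

    def test_neutral_items_give_midpoint_totals(self):
        spec = InstrumentSpec("toy", n_items=40, min_score=1, max_score=5,
                              reverse_keyed=frozenset({2, 7, 30}),
                              subscales={"s": tuple(range(1, 21)),
                                         "t": tuple(range(21, 41))})
        out = score_likert_instrument([3] * 40, spec)
        assert out["s"] == out["t"] == 20 * 3  # midpoint survives reflection

    def test_reverse_keyed_reflection(self):
        spec = InstrumentSpec("toy", n_items=2, min_score=1, max_score=4,
                              reverse_keyed=frozenset({2}))
        assert score_likert_instrument([4, 4], spec)["total"] == 4 + 1

    def test_fcps_maximum(self):
        spec = InstrumentSpec("fcps", n_items=36, min_score=1, max_score=5)
        assert score_likert_instrument([5] * 36, spec)["total"] == 180

    def test_length_mismatch_rejected(self):
        spec = InstrumentSpec("toy", n_items=3, min_score=0, max_score=2)
        with pytest.raises(ValueError):
            score_likert_instrument([1, 1], spec)

    def test_asq_composites(self):
        valences = ["good", "bad"] * 6
        out = score_asq(np.full((12, 3), 4), valences)
        assert all(v == pytest.approx(4.0) for k, v in out.items())
        ratings = np.full((12, 3), 4.0)
        ratings[1::2, 2] = 7  # bad events, globality dimension
        out = score_asq(ratings, valences)
        assert out["bad_globality"] == pytest.approx(7.0)
        assert out["globality_specificity_index"] == pytest.approx(7.0)
        half = np.full((12, 3), 4.0)
        good_rows = list(range(0, 12, 2))
        half[good_rows[:3], 0] = 1
        half[good_rows[3:], 0] = 7
        mixed = score_asq(half, valences)
        assert mixed["good_internality"] == pytest.approx(4.0)

    def test_asq_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_asq(np.full((12, 3), 8), ["good", "bad"] * 6)


def _press_trials(counts):
    return [TrialRecord(task="lh_pre", trial_index=i + 1,
                        correct_sequence=("L", "R"),
                        keypresses=tuple(["L"] * c))
            for i, c in enumerate(counts)]


class TestKeypressExploration:
    def test_silent_control_gives_up_immediately(self):
        out = keypress_exploration_summary(_press_trials([0] * 30))
        assert out["n_distinct_sequences"] == 0
        assert out["give_up_trial"] == 1

    def test_constant_pressing_never_gives_up(self):
        out = keypress_exploration_summary(_press_trials([8] * 30))
        assert out["give_up_trial"] is None

    def test_geometric_decline_detected_near_true_point(self):
        """Give-up detection on the cohort generator's own decline model."""
        from lhstudy.cohort import LatencyModel, simulate_lh_session
        from lhstudy.schedules import (GroupAssignment, LHScheduleSpec,
                                       generate_lh_schedule)

        sched = generate_lh_schedule(LHScheduleSpec.pretreatment(seed=0))
        assignment = GroupAssignment("y1", "yoked", "f", "short",
                                     {"short": "S", "long": "L"})
        detected = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            trials = simulate_lh_session(assignment, sched, LatencyModel(), rng,
                                         phase="pretreatment", giveup_trial=12)
            out = keypress_exploration_summary(trials)
            if out["give_up_trial"] is not None:
                detected.append(out["give_up_trial"])
        assert len(detected) >= 36  # detection is near-certain
        assert 11 <= np.median(detected) <= 14

    def test_distinct_sequences_chunking(self):
        trials = [TrialRecord(task="lh_pre", trial_index=1,
                              correct_sequence=("L", "R"),
                              keypresses=("L", "R", "R", "L", "L", "R"))]
        out = keypress_exploration_summary(trials)
        assert out["n_distinct_sequences"] == 2  # {LR, RL}
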