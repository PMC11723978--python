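"""Outcome logic, d-prime, lick probabilities and burst microstructure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statistics import NormalDist

import lickchoice as lc
from lickchoice.behavior import (
    BURST_BOUNDS, EXCLUDED, INTERMEDIATE, LONG, SHORT, BehavioralCounts,
    LickBurst, TaskRule, behavioral_counts, categorize_burst, classify_outcomes,
    dprime, lick_probabilities, segment_bursts,
)
from lickchoice.core_io import CATCH, CR, EL, FA, HIT, LL, MISS, TONE, TrialTable


def _trials(onsets, kinds):
    n = len(onsets)
    return TrialTable(
        onset=np.asarray(onsets, dtype=float),
        kind=np.asarray(kinds, dtype=object),
        freq=np.where(np.asarray(kinds, dtype=object) == TONE, 6.0, np.nan),
        outcome=np.array([""] * n, dtype=object),
        first_lick_post=np.full(n, np.nan),
        quiet_period=np.full(n, 6.0),
    )


def _brute_force_outcome(onset, kind, licks, rule=TaskRule()):
    """Independent oracle: explicit interval membership of the first lick."""
    post = [t for t in licks if onset <= t < onset + 4.5]
    if kind == CATCH:
        return FA if post else CR
    if not post:
        return MISS
    t = post[0] - onset
    if 0.0 <= t < 1.5:
        return EL
    if 1.5 <= t < 3.0:
        return HIT
    return LL


class TestClassifyOutcomes:
    @pytest.mark.parametrize("lick, expected", [
        (11.2, EL), (12.0, HIT), (13.5, LL), (None, MISS),
    ])
    def test_tone_trial_windows(self, lick, expected):
        trials = _trials([10.0], [TONE])
        licks = np.array([] if lick is None else [lick])
        out = classify_outcomes(trials, licks)
        assert out.outcome[0] == expected
        if lick is not None:
            assert out.first_lick_post[0] == lick

    def test_catch_trials(self):
        trials = _trials([10.0, 30.0], [CATCH, CATCH])
        out = classify_outcomes(trials, np.array([12.0]))
        assert list(out.outcome) == [FA, CR]

    def test_matches_brute_force_on_random_schedules(self, rng):
        rule = TaskRule()
        for _ in range(300):
            n = rng.integers(1, 6)
            onsets = np.cumsum(rng.uniform(6, 12, size=n)) + 5
            kinds = rng.choice([TONE, CATCH], size=n)
            licks = np.unique(rng.uniform(0, onsets[-1] + 6,
                                          size=rng.integers(0, 25)))
            out = classify_outcomes(_trials(onsets, kinds), licks, rule)
            for i in range(n):
                assert out.outcome[i] == _brute_force_outcome(
                    onsets[i], kinds[i], licks), (onsets[i], kinds[i])

    def test_overlapping_trials_rejected(self):
        trials = _trials([10.0, 12.0], [TONE, TONE])
        with pytest.raises(lc.ValidationError):
            classify_outcomes(trials, np.array([]))


class TestDprime:
    def test_symmetric_rates_give_zero(self):
        assert dprime(BehavioralCounts(0.5, 0.5, 100, 100)) == pytest.approx(0.0)

    def test_against_stdlib_inverse_normal(self):
        got = dprime(BehavioralCounts(0.69, 0.31, 100, 100))
        want = NormalDist().inv_cdf(0.69) - NormalDist().inv_cdf(0.31)
        assert got == pytest.approx(want, abs=1e-6)
        assert got == pytest.approx(0.992, abs=1e-3)

    def test_perfect_session_clipped_finite(self):
        got = dprime(BehavioralCounts(1.0, 0.0, 20, 20))
        want = NormalDist().inv_cdf(1 - 1 / 40) - NormalDist().inv_cdf(1 / 40)
        assert got == pytest.approx(want, abs=1e-9)

    def test_antisymmetry_and_monotonicity(self):
        for h, f in [(0.8, 0.2), (0.6, 0.4), (0.9, 0.05)]:
            a = dprime(BehavioralCounts(h, f, 50, 50))
            b = dprime(BehavioralCounts(f, h, 50, 50))
            assert a == pytest.approx(-b)
        base = dprime(BehavioralCounts(0.6, 0.3, 50, 50))
        assert dprime(BehavioralCounts(0.7, 0.3, 50, 50)) > base
        assert dprime(BehavioralCounts(0.6, 0.4, 50, 50)) < base

    def test_zero_counts_rejected(self):
        with pytest.raises(lc.ValidationError):
            dprime(BehavioralCounts(0.5, 0.5, 0, 10))


class TestLickProbabilities:
    def test_no_licks(self, null_session):
        session, _ = null_session
        import dataclasses
        quiet = dataclasses.replace(session)
        quiet.licks_hi = np.empty(0)
        probs = lick_probabilities(quiet)
        assert probs["pre_lick"].mean() == 0.0
        assert probs["post_lick"].mean() == 0.0

    def test_post_only_licks(self):
        trials = _trials([10.0, 30.0], [TONE, TONE])
        licks = np.array([12.0, 32.0])
        session = _fake_session(trials, licks)
        probs = lick_probabilities(session)
        assert probs["pre_lick"].mean() == 0.0
        assert probs["post_lick"].mean() == 1.0
        assert (probs["pre_span"] <= 4.7 + 1e-9).all()


def _fake_session(trials, licks):
    return lc.SessionRecording(
        activity=np.zeros((2, int((trials.onset[-1] + 10) * 30))),
        cell_xy=np.zeros((2, 2)),
        licks_hi=licks, licks_lo=lc.downsample_licks(licks, 30.0),
        stim_onsets=trials.onset[trials.kind == TONE],
        stim_freqs=trials.freq[trials.kind == TONE],
        trials=trials, bin_index=5,
    )


def _brute_force_bursts(licks, thr=0.5):
    """O(n^2) reference segmentation: group licks whose chain of gaps stays
    within the pause threshold."""
    groups = []
    for t in licks:
        if groups and t - groups[-1][-1] <= thr:
            groups[-1].append(t)
        else:
            groups.append([t])
    bursts = [(g[0], g[-1], len(g)) for g in groups if len(g) >= 2]
    singles = [g[0] for g in groups if len(g) == 1]
    return bursts, singles


class TestSegmentBursts:
    def test_example(self):
        bursts, singles = segment_bursts(np.array([0.0, 0.1, 0.2, 1.0]))
        assert len(bursts) == 1 and singles == [1.0]
        b = bursts[0]
        assert (b.start, b.end, b.n_licks) == (0.0, 0.2, 3)
        assert b.duration == pytest.approx(0.2)

    def test_single_lick_is_singleton(self):
        bursts, singles = segment_bursts(np.array([5.0]))
        assert bursts == [] and singles == [5.0]

    def test_gap_of_exactly_threshold_stays_in_burst(self):
        bursts, singles = segment_bursts(np.array([1.0, 1.5]))
        assert len(bursts) == 1 and not singles

    @given(st.lists(st.floats(0, 30), min_size=0, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_quadratic_oracle_and_partitions(self, raw):
        licks = np.unique(np.round(raw, 4))
        bursts, singles = segment_bursts(licks)
        ref_bursts, ref_singles = _brute_force_bursts(licks)
        assert [(b.start, b.end, b.n_licks) for b in bursts] == ref_bursts
        assert singles == ref_singles
        # every lick belongs to exactly one burst or singleton
        n_in_bursts = sum(b.n_licks for b in bursts)
        assert n_in_bursts + len(singles) == licks.size


class TestCategorizeBurst:
    @pytest.mark.parametrize("duration, res, expected", [
        (0.2, "HI", INTERMEDIATE),
        (0.2, "LO", INTERMEDIATE),
        (0.1, "HI", SHORT),
        (0.1, "LO", SHORT),
        (0.5, "HI", LONG),        # half-open: 0.5 starts LONG
        (0.5, "LO", LONG),
        (1.2, "HI", EXCLUDED),
        (1.2, "LO", LONG),        # LO cap is 1.33 s
        (1.0, "HI", EXCLUDED),    # at the cap
        (0.001, "HI", EXCLUDED),  # below the lower edge
        (0.01, "LO", EXCLUDED),
    ])
    def test_boundaries(self, duration, res, expected):
        b = LickBurst(start=0.0, end=duration, n_licks=2, resolution=res)
        assert categorize_burst(b) == expected

    def test_bounds_match_conventions(self):
        assert BURST_BOUNDS["HI"][0] == 0.002
        assert BURST_BOUNDS["LO"][1] == 0.2


class TestBehaviorSummary:
    def test_outcome_counts_and_dprime(self, expert_session):
        session, _ = expert_session
        row = lc.behavior_summary(session)
        counts = behavioral_counts(session.trials)
        n_tone = (session.trials.kind == TONE).sum()
        assert row["n_HIT"] + row["n_EL"] + row["n_LL"] + row["n_MISS"] == n_tone
        assert np.isfinite(row["dprime"]) == (counts.n_catch > 0)
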