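"""Isolated-lick selection, Wilcoxon classification and peri-lick summaries."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import lickchoice as lc
from lickchoice.cell_classification import (
    ENHANCED, NONE, SUPPRESSED, anchors_for_session, classify_lick_modulation,
    classify_sound_responsive, event_window_means, pairwise_spatial_distance,
    peri_lick_summary, select_isolated_licks,
)
from lickchoice.core_io import POST_SOUND, PRE_SOUND


class TestSelectIsolatedLicks:
    def test_recent_lick_or_stim_excludes(self):
        anchors = select_isolated_licks(
            np.array([2.0, 2.1, 3.0]), np.array([1.9]))
        assert np.allclose(anchors.times, [3.0])

    def test_single_lick_no_stimuli_kept(self):
        anchors = select_isolated_licks(np.array([4.0]), np.array([]))
        assert np.allclose(anchors.times, [4.0])
        assert anchors.context[0] == PRE_SOUND

    def test_exact_clearance_is_kept(self):
        anchors = select_isolated_licks(np.array([1.0, 1.33]), np.array([]))
        assert np.allclose(anchors.times, [1.0, 1.33])

    def test_context_tagging(self):
        anchors = select_isolated_licks(
            np.array([5.0, 12.0, 18.0]), np.array([10.0]))
        # 12.0 falls inside the tone's 4.7 s post span; 18.0 is past it
        assert list(anchors.context) == [PRE_SOUND, POST_SOUND, PRE_SOUND]

    def test_membership_matches_interval_oracle(self, rng):
        licks = np.unique(rng.uniform(0, 60, 40))
        stims = np.unique(rng.uniform(0, 60, 6))
        anchors = select_isolated_licks(licks, stims)
        for t in licks:
            events = np.concatenate([licks, stims])
            clear = not np.any((events > t - 0.33) & (events < t))
            assert (t in anchors.times) == clear


class TestClassification:
    def test_planted_groups_recovered(self, expert_session):
        session, truth = expert_session
        classes = classify_lick_modulation(session, anchors_for_session(session))
        enh = truth.class_mask("ENHANCED") & classes.included
        assert np.mean(classes.label[enh] == ENHANCED) > 0.5
        # strongly modulated cells (either sign) are recovered with the
        # correct label sign
        strong = (np.abs(truth.amplitude) >= 0.5) & classes.included
        if strong.sum():
            correct = [
                (a > 0 and lbl == ENHANCED) or (a < 0 and lbl == SUPPRESSED)
                for a, lbl in zip(truth.amplitude[strong], classes.label[strong])
            ]
            assert np.mean(correct) > 0.6
        # enhanced labels always carry a positive sign
        assert np.all(classes.sign[classes.label == ENHANCED] > 0)
        assert np.all(classes.sign[classes.label == SUPPRESSED] < 0)

    def test_scale_invariance(self, expert_session):
        session, _ = expert_session
        anchors = anchors_for_session(session)
        base = classify_lick_modulation(session, anchors)
        scaled = dataclasses.replace(session)
        scaled.activity = session.activity.copy()
        scaled.activity[3] *= 7.5
        again = classify_lick_modulation(scaled, anchors)
        assert again.label[3] == base.label[3]
        assert again.p_value[3] == pytest.approx(base.p_value[3])

    def test_low_rate_cell_excluded(self, expert_session):
        session, _ = expert_session
        muted = dataclasses.replace(session)
        muted.activity = session.activity.copy()
        muted.activity[0] = 0.0
        classes = classify_lick_modulation(muted, anchors_for_session(muted))
        assert not classes.included[0]
        assert classes.label[0] == NONE

    def test_too_few_anchors_flags_insufficient(self, expert_session):
        session, _ = expert_session
        classes = classify_lick_modulation(session, np.array([50.0, 51.0]))
        assert classes.insufficient
        assert np.all(classes.label == NONE)

    def test_pre_sound_basis_sees_little_modulation(self, expert_session):
        """Lick modulation is gated by the post-sound context, so the
        pre-sound control classification finds far fewer modulated cells."""
        session, truth = expert_session
        anchors = anchors_for_session(session)
        post = classify_lick_modulation(session, anchors, basis=POST_SOUND)
        pre = classify_lick_modulation(session, anchors, basis=PRE_SOUND)
        enh = truth.class_mask("ENHANCED")
        assert np.sum(pre.label[enh] == ENHANCED) <= np.sum(post.label[enh] == ENHANCED)

    def test_sound_responsive_recovery_and_null(self, expert_session, null_session):
        session, truth = expert_session
        flags, _ = classify_sound_responsive(session)
        planted = truth.sound_responsive
        if planted.sum():
            assert np.mean(flags[planted]) > 0.5
        nsession, _ = null_session
        nflags, _ = classify_sound_responsive(nsession)
        assert nflags.mean() < 0.25


class TestPeriLickSummary:
    def test_constant_cell_has_zero_change(self):
        session = _constant_session(rate=3.0)
        anchors = np.array([5.0, 10.0, 15.0])
        classes = classify_lick_modulation(session, anchors)
        summ = peri_lick_summary(session, anchors, classes)
        assert summ["delta"].abs().max() == pytest.approx(0.0)
        assert summ["prop_change"].abs().max() == pytest.approx(0.0)
        # zero-variance cells: z-summaries undefined, raw retained
        assert summ["abs_peak"].isna().all()
        assert summ["pre_mean"].notna().all()

    def test_doubling_gives_one_third(self):
        session = _constant_session(rate=2.0)
        # post-lick frames at twice the pre-lick rate for cell 0
        fr = 30
        for t in (5.0, 10.0, 15.0):
            af = int(round(t * fr))
            session.activity[0, af:af + 5] = 4.0
        anchors = np.array([5.0, 10.0, 15.0])
        classes = classify_lick_modulation(session, anchors)
        summ = peri_lick_summary(session, anchors, classes)
        assert summ.loc[0, "prop_change"] == pytest.approx(1 / 3, abs=1e-6)
        assert summ.loc[0, "delta"] == pytest.approx(2.0, abs=1e-9)

    def test_enhanced_peak_grows_with_experience(self, tiny_cfg):
        """Group-mean |z| peak of planted enhanced cells tracks the
        experience curve across the testing phase."""
        peaks = {}
        for b in (4, 6):
            s, t = lc.generate_session(tiny_cfg, b, rng=np.random.default_rng(b))
            anchors = anchors_for_session(s)
            classes = classify_lick_modulation(s, anchors)
            summ = peri_lick_summary(s, anchors, classes)
            mask = t.class_mask("ENHANCED")
            peaks[b] = summ.loc[mask, "abs_peak"].mean()
        assert peaks[6] > peaks[4]


class TestSpatialDistance:
    def test_three_four_five(self):
        xy = np.array([[0.0, 0.0], [3.0, 4.0], [50.0, 50.0]])
        classes = _classes(["ENHANCED", "ENHANCED", "NONE"])
        d = pairwise_spatial_distance(xy, classes)
        assert d["ENHANCED"] == pytest.approx([5.0])
        assert d["SUPPRESSED"].size == 0     # empty, not an error

    def test_uniform_scatter_is_spatially_unstructured(self):
        """Classes placed uniformly give indistinguishable within-group
        distance distributions (median KS p over seeds > 0.05)."""
        ps = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            xy = rng.uniform(0, 420, size=(60, 2))
            labels = rng.choice(["ENHANCED", "NONE"], size=60, p=[0.3, 0.7])
            classes = _classes(labels)
            d = pairwise_spatial_distance(xy, classes)
            ps.append(stats.ks_2samp(d["ENHANCED"], d["NONE"]).pvalue)
        assert np.median(ps) > 0.05


def _constant_session(rate, n_cells=3, n_frames=900):
    activity = np.full((n_cells, n_frames), float(rate))
    return lc.SessionRecording(
        activity=activity, cell_xy=np.zeros((n_cells, 2)),
        licks_hi=np.array([5.0, 10.0, 15.0]),
        licks_lo=np.array([5.0, 10.0, 15.0]),
        stim_onsets=np.array([]), stim_freqs=np.array([]),
        trials=lc.TrialTable(onset=np.array([]), kind=np.array([]),
                             freq=np.array([]), outcome=np.array([]),
                             first_lick_post=np.array([]),
                             quiet_period=np.array([])),
        bin_index=6,
    )


def _classes(labels):
    from lickchoice.cell_classification import CellClassSet
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    return CellClassSet(label=labels, p_value=np.ones(n), sign=np.zeros(n),
                        included=np.ones(n, dtype=bool))


class TestEventWindowMeans:
    def test_edge_events_dropped_and_counted(self):
        activity = np.arange(300, dtype=float).reshape(1, 300)
        w = lc.AnalysisWindows()
        means, used = event_window_means(activity, np.array([0.1, 5.0]),
                                         w.baseline, 30.0)
        assert used.tolist() == [False, True]
        assert means.shape == (1, 1)
        # baseline window at anchor frame 150 averages frames [135, 145)
        assert means[0, 0] == pytest.approx(np.mean(np.arange(135, 145)))
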