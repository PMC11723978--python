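"""Trial outcomes, signal-detection performance and lick-burst microstructure.

The task: a tone (or silent catch) is presented after a 5-10 s quiet period.
The mouse must withhold licking through a 1.5 s delay window; a first lick in
the following 1.5 s "high-water" window is a Hit (large reward, 12 uL,
delivered 1 s after the lick); a first lick in the next 1.5 s "low-water"
window is a Late Lick (small reward, 4 uL); a lick during the delay is an
Early Lick (timeout); no lick at all is a Miss.  On catch trials any lick in
the 4.5 s response span is a False Alarm, none is a Correct Rejection.
During the Pavlovian training phase (bins 1-3) reward arrives 3 s after
onset regardless of licking, but outcome labels are assigned identically for
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    CATCH, CR, EL, FA, HIT, LL, MISS, POST_SOUND, PRE_SOUND, TONE,
    AnalysisWindows, SessionRecording, TrialTable, ValidationError,
)

__all__ = [
    "TaskRule", "BehavioralCounts", "LickBurst",
    "classify_outcomes", "dprime", "behavioral_counts", "lick_probabilities",
    "segment_bursts", "categorize_burst", "bursts_frame", "behavior_summary",
]

SHORT = "SHORT"
INTERMEDIATE = "INTERMEDIATE"
LONG = "LONG"
EXCLUDED = "EXCLUDED"

# Burst-duration category bounds (seconds): lower edge, two inner edges, cap.
# Native 500 Hz resolution and the 30 Hz down-sampled variant use different
# bounds; intervals are half-open low-inclusive and durations at or past the
# cap (or below the lower edge) are excluded.
BURST_BOUNDS = {
    "HI": (0.002, 0.15, 0.5, 1.0),
    "LO": (0.033, 0.2, 0.5, 4.0 / 3.0),
}


@dataclass(frozen=True)
class TaskRule:
    """Response-window geometry (seconds, relative to trial onset)."""

    delay: tuple[float, float] = (0.0, 1.5)
    high_water: tuple[float, float] = (1.5, 3.0)
    low_water: tuple[float, float] = (3.0, 4.5)
    hit_reward_ul: float = 12.0
    ll_reward_ul: float = 4.0

    @property
    def response_end(self) -> float:
        return self.low_water[1]


@dataclass(frozen=True)
class BehavioralCounts:
    """Hit rate (tone trials) and false-alarm rate (catch trials)."""

    H: float
    F: float
    n_signal: int
    n_catch: int


@dataclass
class LickBurst:
    """A maximal run of >=2 licks with inter-lick gaps <= the pause threshold."""

    start: float
    end: float
    n_licks: int
    resolution: str = "HI"          # HI (500 Hz) | LO (30 Hz)
    context: str = POST_SOUND
    bin_index: int = 0

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def classify_outcomes(
    trials: TrialTable,
    licks: np.ndarray,
    rule: TaskRule | None = None,
    phase: str = "testing",
) -> TrialTable:
    """Assign an outcome label to every trial from the lick train.

    For tone trials the first lick after onset decides: delay window -> EL,
    high-water -> HIT, low-water -> LL, none within the response span ->
    MISS.  Catch trials: any lick in the response span -> FA, else CR.
    Labels are identical in the training phase even though reward there is
    unconditional.  Returns a new table with ``outcome`` and
    ``first_lick_post`` filled in.
    """
    rule = rule or TaskRule()
    licks = np.asarray(licks, dtype=float)
    onsets = trials.onset
    if len(onsets) > 1 and np.any(np.diff(onsets) < rule.response_end):
        raise ValidationError("trials overlap within the response span")

    outcome = np.empty(len(trials), dtype=object)
    first_lick = np.full(len(trials), np.nan)
    for i, (onset, kind) in enumerate(zip(onsets, trials.kind)):
        in_span = licks[(licks >= onset) & (licks < onset + rule.response_end)]
        t_rel = in_span[0] - onset if in_span.size else None
        if kind == CATCH:
            outcome[i] = FA if t_rel is not None else CR
        else:
            if t_rel is None:
                outcome[i] = MISS
            elif t_rel < rule.delay[1]:
                outcome[i] = EL
            elif t_rel < rule.high_water[1]:
                outcome[i] = HIT
            else:
                outcome[i] = LL
        if t_rel is not None:
            first_lick[i] = in_span[0]
    return replace(trials, outcome=outcome, first_lick_post=first_lick)


# ---------------------------------------------------------------------------
# Signal-detection sensitivity
# ---------------------------------------------------------------------------

def behavioral_counts(trials: TrialTable) -> BehavioralCounts:
    """Hit rate over tone trials and false-alarm rate over catch trials.

    A tone trial counts toward H when the animal licked in the high-water
    window (Hit); catch trials count toward F when any lick occurred (FA).
    """
    tone = trials.kind == TONE
    catch = trials.kind == CATCH
    n_signal = int(tone.sum())
    n_catch = int(catch.sum())
    H = float(np.mean(trials.outcome[tone] == HIT)) if n_signal else np.nan
    F = float(np.mean(trials.outcome[catch] == FA)) if n_catch else np.nan
    return BehavioralCounts(H=H, F=F, n_signal=n_signal, n_catch=n_catch)


def dprime(counts: BehavioralCounts) -> float:
    """d' = z(H) - z(F), with extreme rates clipped to [1/(2n), 1 - 1/(2n)].

    Clipping keeps d' finite for perfect sessions; n is the relevant trial
    count for each rate.
    """
    if counts.n_signal <= 0 or counts.n_catch <= 0:
        raise ValidationError("dprime requires tone and catch trials")
    H = float(np.clip(counts.H, 1.0 / (2 * counts.n_signal),
                      1.0 - 1.0 / (2 * counts.n_signal)))
    F = float(np.clip(counts.F, 1.0 / (2 * counts.n_catch),
                      1.0 - 1.0 / (2 * counts.n_catch)))
    return float(stats.norm.ppf(H) - stats.norm.ppf(F))


# ---------------------------------------------------------------------------
# Lick probabilities around the tone
# ---------------------------------------------------------------------------

def lick_probabilities(
    session: SessionRecording,
    windows: AnalysisWindows | None = None,
) -> pd.DataFrame:
    """Per-trial indicators of licking in matched pre- and post-onset spans.

    The post window is ``[onset, onset + 4.7)``.  The pre window spans the
    same 4.7 s ending at onset, drawing on the preceding quiet period; when
    the quiet period is too short the available span is used and recorded
    (``pre_span``) so rates stay comparable.
    """
    windows = windows or AnalysisWindows()
    span = windows.pre_sound_period
    licks = session.licks_hi
    rows = []
    for i in range(len(session.trials)):
        onset = session.trials.onset[i]
        quiet = session.trials.quiet_period[i]
        # the quiet period supplies all but 1 s of the 4.7 s pre window
        pre_span = min(span, (span - 3.7) + quiet) if np.isfinite(quiet) else span
        pre = np.any((licks >= onset - pre_span) & (licks < onset))
        post = np.any((licks >= onset) & (licks < onset + span))
        rows.append({
            "trial": i, "onset": onset, "pre_span": pre_span,
            "pre_lick": bool(pre), "post_lick": bool(post),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lick-burst segmentation and categorization
# ---------------------------------------------------------------------------

def segment_bursts(
    licks: np.ndarray,
    pause_threshold: float = 0.5,
    resolution: str = "HI",
) -> tuple[list[LickBurst], list[float]]:
    """Split a lick train into bursts and singleton licks.

    A burst is a maximal run of two or more consecutive licks whose gaps are
    all <= ``pause_threshold`` (a gap of exactly the threshold stays inside
    the burst; only *greater* pauses split).  Runs of length one are
    returned separately as singletons.
    """
    t = np.asarray(licks, dtype=float)
    bursts: list[LickBurst] = []
    singles: list[float] = []
    if t.size == 0:
        return bursts, singles
    run_start = 0
    for i in range(1, t.size + 1):
        if i == t.size or t[i] - t[i - 1] > pause_threshold:
            n = i - run_start
            if n >= 2:
                bursts.append(LickBurst(start=float(t[run_start]),
                                        end=float(t[i - 1]),
                                        n_licks=n, resolution=resolution))
            else:
                singles.append(float(t[run_start]))
            run_start = i
    return bursts, singles


def categorize_burst(burst: LickBurst, resolution: str | None = None) -> str:
    """Duration category: SHORT / INTERMEDIATE / LONG, or EXCLUDED.

    Bounds depend on resolution (HI = native 500 Hz, LO = 30 Hz grid);
    intervals are half-open low-inclusive and durations below the lower edge
    or at/above the cap are excluded from burst-length analyses.
    """
    res = resolution or burst.resolution
    if res not in BURST_BOUNDS:
        raise ValidationError(f"unknown burst resolution {res!r}")
    lo, a, b, cap = BURST_BOUNDS[res]
    d = burst.duration
    if d < lo or d >= cap:
        return EXCLUDED
    if d < a:
        return SHORT
    if d < b:
        return INTERMEDIATE
    return LONG


def bursts_frame(
    session: SessionRecording,
    pause_threshold: float = 0.5,
) -> pd.DataFrame:
    """All bursts of a session at both resolutions, tagged by context.

    Context is POST_SOUND when the burst starts inside a tone trial's
    post-onset span (4.7 s), PRE_SOUND otherwise.
    """
    tone_onsets = session.trials.onset[session.trials.kind == TONE]
    rows = []
    for res, licks in (("HI", session.licks_hi), ("LO", session.licks_lo)):
        bursts, _ = segment_bursts(licks, pause_threshold, resolution=res)
        for b in bursts:
            rel = b.start - tone_onsets if tone_onsets.size else np.array([])
            post = bool(np.any((rel >= 0) & (rel < 4.7)))
            rows.append({
                "resolution": res,
                "context": POST_SOUND if post else PRE_SOUND,
                "start": b.start, "end": b.end, "n_licks": b.n_licks,
                "duration": b.duration,
                "category": categorize_burst(b, res),
                "bin_index": session.bin_index,
                "session_index": session.session_index,
            })
    return pd.DataFrame(rows, columns=[
        "resolution", "context", "start", "end", "n_licks", "duration",
        "category", "bin_index", "session_index",
    ])


# ---------------------------------------------------------------------------
# Session-level summary
# ---------------------------------------------------------------------------

def behavior_summary(
    session: SessionRecording,
    windows: AnalysisWindows | None = None,
) -> dict:
    """One row of behavioral measures for a session: H, F, d', pre/post lick
    probabilities and outcome counts."""
    counts = behavioral_counts(session.trials)
    probs = lick_probabilities(session, windows)
    row = {
        "session_index": session.session_index,
        "bin_index": session.bin_index,
        "phase": session.phase,
        "H": counts.H,
        "F": counts.F,
        "dprime": dprime(counts) if counts.n_signal and counts.n_catch else np.nan,
        "p_lick_pre": float(probs["pre_lick"].mean()) if len(probs) else np.nan,
        "p_lick_post": float(probs["post_lick"].mean()) if len(probs) else np.nan,
    }
    for out in (HIT, EL, LL, MISS, FA, CR):
        row[f"n_{out}"] = int(np.sum(session.trials.outcome == out))
    return row
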