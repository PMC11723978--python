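"""Functional cell classification and peri-lick activity summaries.

Cells are labelled enhanced / suppressed / non-modulated by a paired
two-sided Wilcoxon signed-rank test comparing, per isolated lick, the mean
deconvolved rate in the 330 ms window straddling the lick onset (165 ms
before to 165 ms after) with the 330 ms window immediately before it.
Sound-responsive cells are flagged by the analogous paired test on the half
second before versus after tone onset.  Cells whose whole-session mean rate
falls below 1 event/s are excluded from every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist

from .core_io import (
    POST_SOUND, PRE_SOUND, TONE,
    AnalysisWindows, SessionRecording, window_to_frames,
)

__all__ = [
    "ENHANCED", "SUPPRESSED", "NONE",
    "CellClassSet", "LickAnchors",
    "select_isolated_licks", "classify_lick_modulation",
    "classify_sound_responsive", "peri_lick_summary",
    "sound_window_summary", "pairwise_spatial_distance", "event_window_means",
]

ENHANCED = "ENHANCED"
SUPPRESSED = "SUPPRESSED"
NONE = "NONE"


@dataclass
class LickAnchors:
    """Isolated-lick anchor times with their sound context."""

    times: np.ndarray
    context: np.ndarray   # PRE_SOUND | POST_SOUND per anchor

    def in_context(self, context: str) -> np.ndarray:
        return self.times[self.context == context]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CellClassSet:
    """Per-cell functional labels with their test statistics.

    ``label`` is NONE whenever the Wilcoxon p-value is >= alpha or the cell
    was excluded by the rate floor; ``sign`` is the sign of the median
    during-minus-baseline difference.  ``included`` marks cells passing the
    >=1 event/s floor.  ``insufficient`` flags a session with too few
    anchors (all labels NONE).
    """

    label: np.ndarray
    p_value: np.ndarray
    sign: np.ndarray
    included: np.ndarray
    basis: str = POST_SOUND
    alpha: float = 0.05
    n_anchors_used: int = 0
    n_anchors_dropped: int = 0
    insufficient: bool = False
    sound_responsive: np.ndarray | None = None
    sound_p: np.ndarray | None = None

    def mask(self, label: str) -> np.ndarray:
        return self.label == label

    def fraction(self, label: str) -> float:
        inc = self.included
        return float(np.mean(self.label[inc] == label)) if inc.any() else np.nan

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell": np.arange(len(self.label)),
            "basis": self.basis,
            "label": self.label,
            "p": self.p_value,
            "sign": self.sign,
            "included": self.included,
        })
        if self.sound_responsive is not None:
            df["sound_responsive"] = self.sound_responsive
            df["sound_p"] = self.sound_p
        return df


# ---------------------------------------------------------------------------
# Anchor selection
# ---------------------------------------------------------------------------

def select_isolated_licks(
    licks: np.ndarray,
    stim_onsets: np.ndarray,
    clearance: float = 0.330,
    tone_spans: np.ndarray | None = None,
    post_span: float = 4.7,
) -> LickAnchors:
    """Licks preceded by at least ``clearance`` free of licks and stimuli.

    A lick at exactly ``clearance`` after the previous event is kept (the
    exclusion interval is open).  Context is POST_SOUND when the lick falls
    inside a tone trial's post-onset span, PRE_SOUND otherwise;
    ``tone_spans`` (tone onsets) defaults to ``stim_onsets``.
    """
    licks = np.asarray(licks, dtype=float)
    stim = np.asarray(stim_onsets, dtype=float)
    tones = np.asarray(tone_spans, dtype=float) if tone_spans is not None else stim

    keep = np.ones(licks.size, dtype=bool)
    for i, t in enumerate(licks):
        prev_lick = licks[(licks > t - clearance) & (licks < t)]
        prev_stim = stim[(stim > t - clearance) & (stim < t)]
        keep[i] = prev_lick.size == 0 and prev_stim.size == 0
    times = licks[keep]

    context = np.full(times.size, PRE_SOUND, dtype=object)
    if tones.size:
        idx = np.searchsorted(tones, times, side="right") - 1
        valid = idx >= 0
        rel = np.where(valid, times - tones[np.clip(idx, 0, None)], np.inf)
        context[(rel >= 0) & (rel < post_span)] = POST_SOUND
    return LickAnchors(times=times, context=context)


def anchors_for_session(session: SessionRecording,
                        clearance: float = 0.330) -> LickAnchors:
    """Isolated licks of a session on the imaging frame grid."""
    tone_onsets = session.trials.onset[session.trials.kind == TONE]
    return select_isolated_licks(session.licks_lo, session.stim_onsets,
                                 clearance=clearance, tone_spans=tone_onsets)


# ---------------------------------------------------------------------------
# Windowed means
# ---------------------------------------------------------------------------

def event_window_means(
    activity: np.ndarray,
    anchor_times: np.ndarray,
    interval: tuple[float, float],
    frame_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate per (event, cell) in a window relative to each anchor.

    Returns ``(means, used_mask)`` where ``means`` has one row per anchor
    that fits inside the recording and ``used_mask`` marks which anchors
    survived; dropped events are counted, never silently discarded.
    """
    n_cells, n_frames = activity.shape
    rows = []
    used = np.zeros(len(anchor_times), dtype=bool)
    for i, t in enumerate(np.asarray(anchor_times, dtype=float)):
        af = int(np.round(t * frame_rate))
        rng_ = window_to_frames(interval, frame_rate, af, n_frames)
        if rng_ is None:
            continue
        f0, f1 = rng_
        rows.append(activity[:, f0:f1].mean(axis=1))
        used[i] = True
    means = np.vstack(rows) if rows else np.empty((0, n_cells))
    return means, used


def rate_floor_mask(session: SessionRecording, min_rate: float = 1.0) -> np.ndarray:
    """Cells whose whole-session mean deconvolved rate passes the floor."""
    return session.activity.mean(axis=1) >= min_rate


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon signed-rank per column of paired matrices.

    Returns (p_values, signs of the median difference).  All-tied columns
    get p = 1.
    """
    n_cells = a.shape[1]
    p = np.ones(n_cells)
    sign = np.zeros(n_cells)
    for c in range(n_cells):
        d = a[:, c] - b[:, c]
        med = np.median(d)
        sign[c] = np.sign(med) if med != 0 else np.sign(np.mean(d))
        if np.allclose(d, 0):
            continue
        try:
            p[c] = stats.wilcoxon(a[:, c], b[:, c], zero_method="wilcox",
                                  alternative="two-sided").pvalue
        except ValueError:      # all differences zero after tie removal
            p[c] = 1.0
    return p, sign


def _adjust(p: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return p
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method=method)[1]


def classify_lick_modulation(
    session: SessionRecording,
    anchors: np.ndarray | LickAnchors | None = None,
    windows: AnalysisWindows | None = None,
    alpha: float = 0.05,
    min_rate: float = 1.0,
    min_anchors: int = 10,
    basis: str = POST_SOUND,
    p_adjust: str | None = None,
) -> CellClassSet:
    """Label every cell enhanced / suppressed / non-modulated.

    Paired samples per cell are the mean rates in the during window
    ([-165, +165) ms around each anchor lick) versus the baseline window
    ([-495, -165) ms).  ``basis`` selects post-sound anchors (default) or
    the pre-sound control.  With fewer than ``min_anchors`` usable anchors
    the session returns all-NONE with ``insufficient`` set.
    """
    windows = windows or AnalysisWindows()
    if anchors is None:
        anchors = anchors_for_session(session)
    if isinstance(anchors, LickAnchors):
        times = anchors.in_context(basis)
    else:
        times = np.asarray(anchors, dtype=float)

    included = rate_floor_mask(session, min_rate)
    n = session.n_cells
    during, used_d = event_window_means(session.activity, times,
                                        windows.during, session.frame_rate)
    base, used_b = event_window_means(session.activity, times,
                                      windows.baseline, session.frame_rate)
    both = used_d & used_b
    during = during[both[used_d]]
    base = base[both[used_b]]
    n_used = int(both.sum())
    n_dropped = len(times) - n_used

    label = np.full(n, NONE, dtype=object)
    p = np.ones(n)
    sign = np.zeros(n)
    insufficient = n_used < min_anchors
    if not insufficient:
        p, sign = _paired_wilcoxon(during, base)
        p_eff = _adjust(p, p_adjust)
        sig = (p_eff < alpha) & included
        label[sig & (sign > 0)] = ENHANCED
        label[sig & (sign < 0)] = SUPPRESSED
    return CellClassSet(label=label, p_value=p, sign=sign, included=included,
                        basis=basis, alpha=alpha, n_anchors_used=n_used,
                        n_anchors_dropped=n_dropped, insufficient=insufficient)


def classify_sound_responsive(
    session: SessionRecording,
    windows: AnalysisWindows | None = None,
    alpha: float = 0.05,
    min_rate: float = 1.0,
    min_trials: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag sound-responsive cells: paired Wilcoxon on mean rates in the
    half second before vs after tone onset across tone trials.

    Returns ``(flags, p_values)``; catch trials contribute nothing.
    """
    windows = windows or AnalysisWindows()
    onsets = session.trials.onset[session.trials.kind == TONE]
    included = rate_floor_mask(session, min_rate)
    pre, used_a = event_window_means(session.activity, onsets,
                                     windows.sound_pre, session.frame_rate)
    post, used_b = event_window_means(session.activity, onsets,
                                      windows.sound_post, session.frame_rate)
    both = used_a & used_b
    pre = pre[both[used_a]]
    post = post[both[used_b]]
    if both.sum() < min_trials:
        return np.zeros(session.n_cells, dtype=bool), np.ones(session.n_cells)
    p, _ = _paired_wilcoxon(post, pre)
    return (p < alpha) & included, p


def attach_sound_flags(classes: CellClassSet,
                       session: SessionRecording, **kw) -> CellClassSet:
    flags, p = classify_sound_responsive(session, **kw)
    classes.sound_responsive = flags
    classes.sound_p = p
    return classes


# ---------------------------------------------------------------------------
# Peri-event summaries
# ---------------------------------------------------------------------------

def peri_lick_summary(
    session: SessionRecording,
    anchors: np.ndarray | LickAnchors,
    classes: CellClassSet,
    windows: AnalysisWindows | None = None,
    basis: str = POST_SOUND,
    eps: float = 1e-9,
    peri_span: tuple[float, float] = (-0.825, 0.495),
) -> pd.DataFrame:
    """Per-cell peri-lick activity summary.

    The z-scored trace normalizes each cell by the mean/SD across the
    peri-event frames of all anchors (not the whole session);
    ``abs_peak`` is the peak |z| within +/-165 ms of the lick.  ``delta``
    and the symmetric proportional change ``(post - pre)/(post + pre + eps)``
    are computed on raw rates in the 165 ms flanks.  Zero-variance cells
    get NaN z summaries but keep their raw summaries.
    """
    windows = windows or AnalysisWindows()
    if isinstance(anchors, LickAnchors):
        times = anchors.in_context(basis)
    else:
        times = np.asarray(anchors, dtype=float)
    fr = session.frame_rate
    half = windows.peri_lick_half

    f_lo = int(np.round(peri_span[0] * fr))
    f_hi = int(np.round(peri_span[1] * fr))
    grid = np.arange(f_lo, f_hi)
    segments = []
    for t in times:
        af = int(np.round(t * fr))
        if af + f_lo < 0 or af + f_hi > session.n_frames:
            continue
        segments.append(session.activity[:, af + f_lo:af + f_hi])
    n = session.n_cells
    if not segments:
        return pd.DataFrame({"cell": np.arange(n)})

    stack = np.stack(segments)                     # events x cells x frames
    mean_trace = stack.mean(axis=0)                # cells x frames
    mu = stack.mean(axis=(0, 2))
    sd = stack.std(axis=(0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z_trace = (mean_trace - mu[:, None]) / sd[:, None]
    z_trace[sd == 0] = np.nan

    d_half = int(np.round(half * fr))
    during_idx = (grid >= -d_half) & (grid < d_half)
    pre_idx = (grid >= -d_half) & (grid < 0)
    post_idx = (grid >= 0) & (grid < d_half)

    abs_peak = np.nanmax(np.abs(z_trace[:, during_idx]), axis=1)
    pre_mean = mean_trace[:, pre_idx].mean(axis=1)
    post_mean = mean_trace[:, post_idx].mean(axis=1)
    delta = post_mean - pre_mean
    prop_change = delta / (post_mean + pre_mean + eps)

    return pd.DataFrame({
        "cell": np.arange(n),
        "label": classes.label,
        "included": classes.included,
        "abs_peak": abs_peak,
        "pre_mean": pre_mean,
        "post_mean": post_mean,
        "delta": delta,
        "prop_change": prop_change,
        "n_events": len(segments),
    })


def sound_window_summary(
    session: SessionRecording,
    windows: AnalysisWindows | None = None,
) -> pd.DataFrame:
    """Per-cell mean rates in the half second before/after tone onset."""
    windows = windows or AnalysisWindows()
    onsets = session.trials.onset[session.trials.kind == TONE]
    pre, ua = event_window_means(session.activity, onsets,
                                 windows.sound_pre, session.frame_rate)
    post, ub = event_window_means(session.activity, onsets,
                                  windows.sound_post, session.frame_rate)
    both = ua & ub
    pre = pre[both[ua]].mean(axis=0) if both.any() else np.full(session.n_cells, np.nan)
    post = post[both[ub]].mean(axis=0) if both.any() else np.full(session.n_cells, np.nan)
    return pd.DataFrame({
        "cell": np.arange(session.n_cells),
        "pre_sound": pre, "post_sound": post, "delta": post - pre,
    })


# ---------------------------------------------------------------------------
# Spatial structure
# ---------------------------------------------------------------------------

def pairwise_spatial_distance(
    cell_xy: np.ndarray,
    classes: CellClassSet,
) -> dict[str, np.ndarray]:
    """Euclidean distances between cell pairs, within each functional group
    and between sound-responsive cells and each group.

    Groups with fewer than two members yield empty distributions.
    """
    xy = np.asarray(cell_xy, dtype=float)
    out: dict[str, np.ndarray] = {}
    for label in (ENHANCED, SUPPRESSED, NONE):
        mask = classes.mask(label) & classes.included
        pts = xy[mask]
        out[label] = pdist(pts) if len(pts) >= 2 else np.empty(0)
    if classes.sound_responsive is not None:
        snd = xy[classes.sound_responsive & classes.included]
        for label in (ENHANCED, SUPPRESSED, NONE):
            mask = classes.mask(label) & classes.included
            pts = xy[mask]
            key = f"SOUNDx{label}"
            if len(snd) and len(pts):
                out[key] = cdist(snd, pts).ravel()
            else:
                out[key] = np.empty(0)
    return out
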