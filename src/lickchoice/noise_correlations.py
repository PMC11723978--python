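"""Windowed trial-to-trial pairwise (noise) correlations by cell group.

For each isolated lick, population activity is averaged inside one of three
330 ms windows — "during" (starting 165 ms before the lick), "before"
(starting 495 ms before) and "farther" (starting 825 ms before).  Pearson
correlations between cells' trial vectors, computed after per-cell
normalization, quantify shared trial-to-trial variability; they are
aggregated by cell-group pairing, window, trial outcome and bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    EL, HIT, LL, POST_SOUND, AnalysisWindows, SessionRecording, window_to_frames,
)
from .cell_classification import (
    ENHANCED, NONE, SUPPRESSED, CellClassSet, LickAnchors, event_window_means,
)

__all__ = ["DURING", "BEFORE", "FARTHER", "WINDOWS", "WindowMatrix",
           "window_activity_matrix", "noise_corr", "group_mean_correlations",
           "corr_contrasts", "session_noise_table"]

DURING = "DURING"
BEFORE = "BEFORE"
FARTHER = "FARTHER"
WINDOWS = (DURING, BEFORE, FARTHER)

PAIRINGS = (
    (ENHANCED, ENHANCED), (SUPPRESSED, SUPPRESSED), (NONE, NONE),
    (ENHANCED, SUPPRESSED), (ENHANCED, NONE), (SUPPRESSED, NONE),
)


def _window_interval(window: str, w: AnalysisWindows) -> tuple[float, float]:
    if window == DURING:
        return w.during
    if window == BEFORE:
        return w.baseline
    if window == FARTHER:
        return w.farther
    raise ValueError(f"unknown window {window!r}")


@dataclass
class WindowMatrix:
    """Trials x cells window-mean rates with discard bookkeeping."""

    matrix: np.ndarray
    anchor_times: np.ndarray
    n_used: int
    n_discarded: int        # all-zero population rows
    n_dropped: int          # anchors falling outside the recording
    window: str


def window_activity_matrix(
    session: SessionRecording,
    anchors: np.ndarray | LickAnchors,
    window: str = DURING,
    windows: AnalysisWindows | None = None,
    context: str = POST_SOUND,
    cell_mask: np.ndarray | None = None,
) -> WindowMatrix:
    """Window-mean rate per (anchor, cell) for one of the three windows.

    Trials with no activity at all across the population in the window are
    discarded (and counted); anchors whose window leaves the recording are
    dropped (and counted).
    """
    w = windows or AnalysisWindows()
    if isinstance(anchors, LickAnchors):
        times = anchors.in_context(context)
    else:
        times = np.asarray(anchors, dtype=float)
    interval = _window_interval(window, w)
    means, used = event_window_means(session.activity, times, interval,
                                     session.frame_rate)
    if cell_mask is not None:
        means = means[:, cell_mask]
    alive = means.sum(axis=1) > 0
    return WindowMatrix(
        matrix=means[alive],
        anchor_times=times[used][alive],
        n_used=int(alive.sum()),
        n_discarded=int((~alive).sum()),
        n_dropped=int((~used).sum()),
        window=window,
    )


def noise_corr(
    matrix: np.ndarray,
    normalization: str = "zscore",
    min_trials: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlation of cells' trial vectors.

    With ``normalization='zscore'`` each cell's vector is standardized
    first (Pearson r is invariant to this; the option matters only for the
    "raw" pathway kept for comparison).  Zero-variance cells are excluded
    from pairing.  Returns ``(r, valid)`` where ``r`` is n_cells x n_cells
    with NaN for invalid cells and ``valid`` marks cells with variance.
    """
    X = np.asarray(matrix, dtype=float)
    n_trials, n_cells = X.shape
    r = np.full((n_cells, n_cells), np.nan)
    valid = np.zeros(n_cells, dtype=bool)
    if n_trials < min_trials:
        return r, valid
    sd = X.std(axis=0)
    valid = sd > 0
    if valid.sum() < 2:
        return r, valid
    Xv = X[:, valid]
    if normalization == "zscore":
        Xv = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
    sub = np.corrcoef(Xv, rowvar=False)
    idx = np.flatnonzero(valid)
    r[np.ix_(idx, idx)] = sub
    return r, valid


def group_mean_correlations(
    r: np.ndarray,
    labels: np.ndarray,
    valid: np.ndarray,
) -> dict[tuple[str, str], tuple[float, int]]:
    """Mean off-diagonal r per group pairing -> {(a, b): (mean_r, n_pairs)}."""
    out = {}
    for a, b in PAIRINGS:
        ia = np.flatnonzero((labels == a) & valid)
        ib = np.flatnonzero((labels == b) & valid)
        if a == b:
            sub = r[np.ix_(ia, ia)]
            vals = sub[np.triu_indices(len(ia), k=1)] if len(ia) >= 2 else np.empty(0)
        else:
            vals = r[np.ix_(ia, ib)].ravel()
        vals = vals[~np.isnan(vals)] if vals.size else vals
        out[(a, b)] = (float(vals.mean()) if vals.size else np.nan, int(vals.size))
    return out


def session_noise_table(
    session: SessionRecording,
    anchors: LickAnchors,
    classes: CellClassSet,
    windows: AnalysisWindows | None = None,
    outcomes: tuple = ("ALL", HIT, EL, LL),
    min_trials: int = 3,
) -> pd.DataFrame:
    """Noise-correlation table for one session.

    Rows are keyed by (window, outcome, pairing); anchors are restricted to
    post-sound isolated licks, optionally to those whose governing trial
    had a given outcome.
    """
    w = windows or AnalysisWindows()
    post_times = anchors.in_context(POST_SOUND)
    trials = session.trials
    tone_mask = trials.kind == "TONE"
    onsets = trials.onset

    def outcome_of(t: float) -> str:
        i = int(np.searchsorted(onsets, t, side="right")) - 1
        if i < 0:
            return ""
        return str(trials.outcome[i])

    anchor_outcomes = np.array([outcome_of(t) for t in post_times], dtype=object)
    rows = []
    for outcome in outcomes:
        sel = post_times if outcome == "ALL" else post_times[anchor_outcomes == outcome]
        for window in WINDOWS:
            wm = window_activity_matrix(session, sel, window, w)
            r, valid = noise_corr(wm.matrix, min_trials=min_trials)
            valid = valid & classes.included
            groups = group_mean_correlations(r, classes.label, valid)
            for (a, b), (mean_r, n_pairs) in groups.items():
                rows.append({
                    "session_index": session.session_index,
                    "bin_index": session.bin_index,
                    "window": window,
                    "outcome": outcome,
                    "pairing": f"{a}x{b}",
                    "mean_r": mean_r,
                    "n_pairs": n_pairs,
                    "n_trials_used": wm.n_used,
                    "n_trials_discarded": wm.n_discarded,
                    "n_anchors_dropped": wm.n_dropped,
                    "insufficient": wm.n_used < min_trials,
                })
    return pd.DataFrame(rows)


def corr_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Window and outcome contrasts of mean pairwise r (utility statistics).

    Emits mean differences (during - before, before - farther; Hit - LL,
    Hit - EL on the before window) per pairing, pooled across sessions,
    with a two-way ANOVA (window x outcome) per pairing where estimable.
    Missing design cells are skipped.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    for pairing, sub in table.groupby("pairing"):
        sub = sub[~sub["insufficient"] & np.isfinite(sub["mean_r"])]
        if sub.empty:
            continue
        al = sub[sub["outcome"] == "ALL"]
        piv = al.pivot_table(index="session_index", columns="window",
                             values="mean_r")
        row = {"pairing": pairing}
        if {DURING, BEFORE}.issubset(piv.columns):
            row["during_minus_before"] = float((piv[DURING] - piv[BEFORE]).mean())
        if {BEFORE, FARTHER}.issubset(piv.columns):
            row["before_minus_farther"] = float((piv[BEFORE] - piv[FARTHER]).mean())
        hit = sub[(sub["outcome"] == HIT) & (sub["window"] == BEFORE)]["mean_r"]
        ll = sub[(sub["outcome"] == LL) & (sub["window"] == BEFORE)]["mean_r"]
        el = sub[(sub["outcome"] == EL) & (sub["window"] == BEFORE)]["mean_r"]
        if len(hit) and len(ll):
            row["hit_minus_ll_before"] = float(hit.mean() - ll.mean())
        if len(hit) and len(el):
            row["hit_minus_el_before"] = float(hit.mean() - el.mean())
        oc = sub[sub["outcome"].isin([HIT, EL, LL])]
        if oc["outcome"].nunique() >= 2 and oc["window"].nunique() >= 2 and len(oc) >= 8:
            try:
                fit = smf.ols("mean_r ~ C(window) * C(outcome)", data=oc).fit()
                aov = anova_lm(fit, typ=2)
                row["anova_F_window"] = float(aov.loc["C(window)", "F"])
                row["anova_p_window"] = float(aov.loc["C(window)", "PR(>F)"])
            except Exception:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
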