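"""Session data model, window/frame arithmetic, HDF5 container I/O and configuration.

All times are session-relative seconds; frames are 0-based; intervals are
half-open ``[start, end)``.  Neural activity is stored as deconvolved event
rates (events/s, non-negative) sampled on a regular frame grid (30 Hz by
default).  The lick train exists at two resolutions: the native 500 Hz
record (``licks_hi``) and a copy collapsed onto the imaging frame grid
(``licks_lo``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TONE", "CATCH", "HIT", "EL", "LL", "MISS", "FA", "CR",
    "PRE_SOUND", "POST_SOUND", "OUTCOMES",
    "AnalysisWindows", "PipelineConfig", "TrialTable", "SessionRecording",
    "FormatError", "ValidationError",
    "downsample_licks", "window_to_frames", "stage_rng", "stage_seed",
    "read_session", "write_session", "run_pipeline",
]

# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

TONE = "TONE"
CATCH = "CATCH"

HIT = "HIT"     # correctly timed lick (high-water window)
EL = "EL"       # early lick during the delay window
LL = "LL"       # late lick (low-water window)
MISS = "MISS"   # no lick on a tone trial
FA = "FA"       # lick on a catch trial
CR = "CR"       # correct rejection (no lick, catch trial)
OUTCOMES = (HIT, EL, LL, MISS, FA, CR)

PRE_SOUND = "PRE_SOUND"
POST_SOUND = "POST_SOUND"

TRAINING = "training"   # bins 1-3: reward delivered 3 s after onset regardless
TESTING = "testing"     # bins 4-6: reward contingent on lick timing


class FormatError(ValueError):
    """A session container is missing a required group/column."""


class ValidationError(ValueError):
    """An in-memory object violates a documented invariant."""


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisWindows:
    """Peri-event analysis windows (seconds, relative to the anchor event).

    The three lick-locked windows tile the 990 ms preceding +165 ms around
    the lick onset in 330 ms steps: ``during`` straddles the lick,
    ``baseline`` ("before") immediately precedes it and ``farther`` precedes
    that.  At 30 Hz each window is exactly 10 frames; the lick-onset frame
    belongs to the post-lick half.
    """

    peri_lick_half: float = 0.165
    sound_half: float = 0.5
    pre_sound_period: float = 4.7   # span used for pre/post lick-probability

    @property
    def during(self) -> tuple[float, float]:
        return (-self.peri_lick_half, self.peri_lick_half)

    @property
    def baseline(self) -> tuple[float, float]:
        return (-3 * self.peri_lick_half, -self.peri_lick_half)

    @property
    def farther(self) -> tuple[float, float]:
        return (-5 * self.peri_lick_half, -3 * self.peri_lick_half)

    @property
    def sound_pre(self) -> tuple[float, float]:
        return (-self.sound_half, 0.0)

    @property
    def sound_post(self) -> tuple[float, float]:
        return (0.0, self.sound_half)


def window_to_frames(
    interval: tuple[float, float],
    frame_rate: float,
    anchor: int,
    n_frames: int | None = None,
) -> tuple[int, int] | None:
    """Convert a window relative to an anchor frame into a half-open frame range.

    Offsets are rounded to the nearest frame, so 165 ms at 30 Hz is 5 frames
    and every 330 ms window is exactly 10 frames.  Returns ``None`` when the
    range does not fit inside ``[0, n_frames)`` — callers drop (and count)
    such events rather than raising.
    """
    lo = anchor + int(np.round(interval[0] * frame_rate))
    hi = anchor + int(np.round(interval[1] * frame_rate))
    if lo < 0:
        return None
    if n_frames is not None and hi > n_frames:
        return None
    return lo, hi


def downsample_licks(licks_hi: Sequence[float], frame_rate: float) -> np.ndarray:
    """Collapse lick times onto the imaging frame grid.

    Each time maps to ``floor(t * frame_rate) / frame_rate``; licks sharing a
    frame collapse to one event.  Output is sorted and unique.
    """
    t = np.asarray(licks_hi, dtype=float)
    if t.size == 0:
        return np.empty(0, dtype=float)
    if np.any(t < 0):
        raise ValidationError("lick times must be non-negative")
    # epsilon guards times already sitting on the grid against float error
    frames = np.floor(t * frame_rate + 1e-9)
    return np.unique(frames) / frame_rate


# ---------------------------------------------------------------------------
# Trial table
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ("onset", "kind", "freq", "outcome", "first_lick_post", "quiet_period")


@dataclass
class TrialTable:
    """Per-trial record: onset (s), TONE/CATCH, tone frequency (kHz, NaN for
    catch), outcome label, first post-onset lick time (s, NaN if none) and
    the preceding quiet period (s, drawn from 5-10 s)."""

    onset: np.ndarray
    kind: np.ndarray
    freq: np.ndarray
    outcome: np.ndarray
    first_lick_post: np.ndarray
    quiet_period: np.ndarray

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.freq = np.asarray(self.freq, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=object)
        self.first_lick_post = np.asarray(self.first_lick_post, dtype=float)
        self.quiet_period = np.asarray(self.quiet_period, dtype=float)
        n = len(self.onset)
        for f in fields(self):
            if len(getattr(self, f.name)) != n:
                raise ValidationError(f"trial column {f.name!r} has wrong length")

    def __len__(self) -> int:
        return len(self.onset)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRIAL_COLUMNS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trial table missing column(s): {', '.join(missing)}")
        return cls(**{c: df[c].to_numpy() for c in TRIAL_COLUMNS})

    def validate(self) -> None:
        if len(self) and np.any(np.diff(self.onset) <= 0):
            raise ValidationError("trial onsets must be strictly increasing")
        bad = ~np.isin(self.kind, (TONE, CATCH))
        if np.any(bad):
            raise ValidationError(f"unknown trial kind: {self.kind[bad][0]!r}")
        known = np.isin(self.outcome, OUTCOMES) | (self.outcome == "")
        if not np.all(known):
            raise ValidationError("unknown outcome label")
        qp = self.quiet_period
        if len(self) and (np.nanmin(qp) < 5.0 - 1e-9 or np.nanmax(qp) > 10.0 + 1e-9):
            raise ValidationError("quiet_period outside [5, 10] s")


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------

@dataclass
class SessionRecording:
    """One imaging/behavior session.

    ``activity`` is cells x frames of deconvolved event rate (events/s);
    ``cell_xy`` gives field-of-view coordinates in micrometres; lick and
    stimulus times are session-relative seconds.
    """

    activity: np.ndarray
    cell_xy: np.ndarray
    licks_hi: np.ndarray
    licks_lo: np.ndarray
    stim_onsets: np.ndarray
    stim_freqs: np.ndarray
    trials: TrialTable
    frame_rate: float = 30.0
    session_index: int = 0
    bin_index: int = 1

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.cell_xy = np.asarray(self.cell_xy, dtype=float)
        self.licks_hi = np.asarray(self.licks_hi, dtype=float)
        self.licks_lo = np.asarray(self.licks_lo, dtype=float)
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=float)
        self.stim_freqs = np.asarray(self.stim_freqs, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def phase(self) -> str:
        return TRAINING if self.bin_index <= 3 else TESTING

    def validate(self) -> None:
        if self.activity.ndim != 2:
            raise ValidationError("activity must be a 2-D cells x frames matrix")
        if np.any(self.activity < 0):
            raise ValidationError("activity must be non-negative (event rates)")
        if self.cell_xy.shape != (self.n_cells, 2):
            raise ValidationError("cell_xy must be n_cells x 2")
        for name in ("licks_hi", "licks_lo", "stim_onsets"):
            t = getattr(self, name)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")
        if len(self.stim_onsets) != len(self.stim_freqs):
            raise ValidationError("stim_onsets and stim_freqs length mismatch")
        if not 1 <= self.bin_index <= 6:
            raise ValidationError("bin_index must be in 1..6")
        self.trials.validate()
        # every tone-trial onset must appear among the stimulus onsets
        tone_onsets = self.trials.onset[self.trials.kind == TONE]
        if tone_onsets.size and not np.all(
            np.isin(np.round(tone_onsets, 6), np.round(self.stim_onsets, 6))
        ):
            raise ValidationError("tone trial onset missing from stim_onsets")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable parameters for the full analysis pipeline.

    ``min_rate`` is the whole-session mean-rate floor (events/s) a cell must
    pass to enter any analysis.  ``alpha`` governs the Wilcoxon cell
    classification.  Burst thresholds and window geometry mirror the task
    conventions (see :class:`AnalysisWindows`).
    """

    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    alpha: float = 0.05
    p_adjust: str | None = None          # None or "fdr_bh"/"bonferroni"
    min_rate: float = 1.0                # events/s inclusion floor
    min_anchors: int = 10                # isolated licks needed per context
    isolation_clearance: float = 0.330   # s free of licks/stimuli before anchor
    burst_pause: float = 0.5             # s; larger gaps split bursts
    cca_dim: int = 10                    # latent dimensionality m
    cca_reps: int = 500                  # within-day upper-bound repetitions
    cca_grid: tuple[float, float] = (-0.5, 1.0)   # peri-lick latent segment (s)
    geometry_reps: int = 10              # trial-equalization resamples
    n_permutations: int = 1000           # geometry label permutations
    decode_reps: int = 100               # per-group decode repetitions
    decode_folds: int = 10
    decode_per_fold: bool = True         # leakage-safe CV (see decoding)
    pca_variance: float = 0.80
    prop_change_eps: float = 1e-9
    min_corr_trials: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0.0 < self.pca_variance <= 1.0:
            raise ValidationError("pca_variance must lie in (0, 1]")
        for name in ("min_anchors", "cca_dim", "cca_reps", "n_permutations",
                     "decode_reps", "decode_folds", "min_corr_trials"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.min_rate < 0:
            raise ValidationError("min_rate must be non-negative")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["windows"] = {
            "peri_lick_half": self.windows.peri_lick_half,
            "sound_half": self.windows.sound_half,
            "pre_sound_period": self.windows.pre_sound_period,
        }
        d["cca_grid"] = list(self.cca_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "windows" in d and isinstance(d["windows"], dict):
            d["windows"] = AnalysisWindows(**d["windows"])
        if "cca_grid" in d:
            d["cca_grid"] = tuple(d["cca_grid"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from a root seed."""
    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream so each pipeline stage is independently reproducible."""
    return np.random.default_rng(stage_seed(seed, stage))


# ---------------------------------------------------------------------------
# Container I/O (one HDF5 file per session)
# ---------------------------------------------------------------------------

def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write a session to its HDF5 container (see module docstring layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("activity", data=session.activity.astype(np.float32))
        h5.create_dataset("cell_xy", data=session.cell_xy)
        h5.create_dataset("licks_hi", data=session.licks_hi)
        h5.create_dataset("licks_lo", data=session.licks_lo)
        g = h5.create_group("stim")
        g.create_dataset("onsets", data=session.stim_onsets)
        g.create_dataset("freqs", data=session.stim_freqs)
        t = h5.create_group("trials")
        tr = session.trials
        t.create_dataset("onset", data=tr.onset)
        t.create_dataset("kind", data=np.array([str(k) for k in tr.kind], dtype="S8"))
        t.create_dataset("freq", data=tr.freq)
        t.create_dataset("outcome", data=np.array([str(o) for o in tr.outcome], dtype="S8"))
        t.create_dataset("first_lick_post", data=tr.first_lick_post)
        t.create_dataset("quiet_period", data=tr.quiet_period)
        h5.attrs["frame_rate"] = session.frame_rate
        h5.attrs["session_index"] = session.session_index
        h5.attrs["bin_index"] = session.bin_index
        h5.attrs["phase"] = session.phase
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read a session container, validating layout and invariants."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        for key in ("activity", "cell_xy", "licks_hi", "licks_lo"):
            if key not in h5:
                raise FormatError(f"{key} missing from {path.name}")
        if "stim" not in h5 or "onsets" not in h5["stim"] or "freqs" not in h5["stim"]:
            raise FormatError(f"stim group missing from {path.name}")
        if "trials" not in h5:
            raise FormatError(f"trials group missing from {path.name}")
        tg = h5["trials"]
        cols = {}
        for c in TRIAL_COLUMNS:
            if c not in tg:
                raise FormatError(f"trials/{c} missing from {path.name}")
            data = tg[c][()]
            if data.dtype.kind == "S":
                data = np.array([b.decode() for b in data], dtype=object)
            cols[c] = data
        session = SessionRecording(
            activity=h5["activity"][()],
            cell_xy=h5["cell_xy"][()],
            licks_hi=h5["licks_hi"][()],
            licks_lo=h5["licks_lo"][()],
            stim_onsets=h5["stim"]["onsets"][()],
            stim_freqs=h5["stim"]["freqs"][()],
            trials=TrialTable(**cols),
            frame_rate=float(h5.attrs["frame_rate"]),
            session_index=int(h5.attrs["session_index"]),
            bin_index=int(h5.attrs["bin_index"]),
        )
    session.validate()
    return session


def load_sessions(directory: str | Path) -> list[SessionRecording]:
    """Read every ``*.h5`` session container in a directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.h5"))
    return [read_session(p) for p in paths]


def run_pipeline(config: PipelineConfig, sessions: Iterable[SessionRecording],
                 out_dir: str | Path | None = None, **kwargs) -> dict:
    """End-to-end driver: behavior -> classification -> noise correlations ->
    geometry -> decoding.  See :mod:`lickchoice.pipeline`."""
    from .pipeline import run_pipeline as _run
    return _run(config, sessions, out_dir=out_dir, **kwargs)
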