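"""Generative model of the delayed tone-detection task and its neural data.

Produces sessions with the statistical structure the analysis pipeline
assumes: a 6-bin experience schedule (bins 1-3 Pavlovian training, 4-6
testing), tone and catch trials separated by 5-10 s exponential quiet
periods, lick bursts whose length shrinks with experience, and neural
populations containing sound-responsive cells plus enhanced / suppressed /
non-modulated lick-locked cells.  Lick modulation is gated by the post-sound
context (with a small pre-sound leak), grows with experience, resets at the
bin 3 -> 4 rule change, and carries planted pairwise noise correlations via
a shared per-event Gaussian factor within each modulated group.

Every generated session also returns its :class:`GroundTruth` so parameter-
recovery tests can compare detected structure against planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_io import (
    CATCH, CR, EL, FA, HIT, LL, MISS, TONE,
    SessionRecording, TrialTable, ValidationError,
    downsample_licks, stage_rng, write_session,
)
from .behavior import TaskRule, classify_outcomes, segment_bursts

__all__ = ["SimConfig", "GroundTruth", "generate_behavior", "generate_neural",
           "generate_session", "generate_experiment", "write_experiment"]

ENHANCED = "ENHANCED"
SUPPRESSED = "SUPPRESSED"
NONE = "NONE"

# Per-bin study conditions.  Outcome propensities (HIT, EL, LL, MISS) shift
# toward timed hits with experience; false alarms, pre-sound licking and
# burst length all shrink.  The experience curve e_b multiplies lick-locked
# modulation; it rises within each phase and resets toward novice level at
# the bin 3 -> 4 rule change.
DEFAULT_OUTCOME_PROPENSITIES = (
    (0.30, 0.30, 0.20, 0.20),
    (0.40, 0.25, 0.20, 0.15),
    (0.50, 0.20, 0.18, 0.12),
    (0.42, 0.24, 0.22, 0.12),
    (0.52, 0.17, 0.21, 0.10),
    (0.58, 0.13, 0.21, 0.08),
)
DEFAULT_FA_PROB = (0.50, 0.45, 0.40, 0.35, 0.30, 0.25)
DEFAULT_PRE_BURST_PROB = (0.80, 0.70, 0.60, 0.50, 0.45, 0.40)
DEFAULT_BURST_LICKS_MEAN = (5.0, 4.0, 3.5, 3.0, 2.8, 2.5)
DEFAULT_EXPERIENCE_CURVE = (0.20, 0.50, 0.90, 0.25, 0.85, 1.20)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment (defaults are the study
    conditions; tests shrink counts, not effect structure)."""

    n_cells: int = 100
    f_enh: float = 0.15
    f_sup: float = 0.10
    f_sound: float = 0.15
    baseline_rate: float = 2.0            # events/s
    amp_range: tuple[float, float] = (0.2, 1.0)       # enhanced kernel gain
    sup_amp_range: tuple[float, float] = (0.2, 0.7)   # suppressed (negated)
    experience_curve: tuple[float, ...] = DEFAULT_EXPERIENCE_CURVE
    gate_leak: float = 0.10               # pre-sound fraction of the gain
    hit_extra_gain: float = 0.80          # extra enhanced-cell gain on HIT
    shared_rho: float = 0.30              # target within-group window corr
    shared_sd: float = 0.8                # event-deviation SD (events/s)
    shared_gate: str = "peri"             # "peri" (during window) | "all"
    scale_shared_with_experience: bool = True
    sound_amp: float = 1.5                # events/s at tone onset
    sound_tau: float = 0.15               # s, evoked-response decay
    noise_law: str = "gaussian"           # "gaussian" | "poisson"
    frame_noise_sd: float = 2.0           # events/s (gaussian law)
    trials_per_session: int = 150
    catch_frac: float = 0.2
    sessions_per_bin: int = 11
    outcome_propensities: tuple = DEFAULT_OUTCOME_PROPENSITIES
    fa_prob: tuple = DEFAULT_FA_PROB
    pre_burst_prob: tuple = DEFAULT_PRE_BURST_PROB
    burst_licks_mean: tuple = DEFAULT_BURST_LICKS_MEAN
    intra_burst_interval: tuple[float, float] = (0.10, 0.18)  # s (~7 Hz)
    quiet_mean: float = 1.5               # exponential part of quiet period
    quiet_cap: float = 5.0                # quiet = 5 + min(Exp(mean), cap)
    frame_rate: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.f_enh + self.f_sup > 1.0:
            raise ValidationError("f_enh + f_sup must be <= 1")
        if not 0.0 <= self.gate_leak < 1.0:
            raise ValidationError("gate_leak must lie in [0, 1)")
        if any(e < 0 for e in self.experience_curve):
            raise ValidationError("experience curve must be non-negative")
        if len(self.experience_curve) != 6:
            raise ValidationError("experience curve needs 6 entries")
        if self.baseline_rate < 0 or self.sound_amp < 0:
            raise ValidationError("rates must be non-negative")
        if not 0.0 <= self.shared_rho <= 1.0:
            raise ValidationError("shared_rho must lie in [0, 1]")
        if self.noise_law not in ("gaussian", "poisson"):
            raise ValidationError("noise_law must be 'gaussian' or 'poisson'")
        if self.shared_gate not in ("peri", "all"):
            raise ValidationError("shared_gate must be 'peri' or 'all'")

    def null(self) -> "SimConfig":
        """A copy with all planted modulation (lick-locked, shared
        co-fluctuation, sound-evoked) switched off."""
        return replace(self, experience_curve=(0.0,) * 6, shared_sd=0.0,
                       hit_extra_gain=0.0, sound_amp=0.0)


@dataclass
class GroundTruth:
    """Planted per-cell structure of one generated session."""

    cell_class: np.ndarray        # ENHANCED / SUPPRESSED / NONE per cell
    amplitude: np.ndarray         # signed kernel gain A_c (0 for NONE)
    sound_responsive: np.ndarray  # bool per cell
    shared_rho: float
    bin_index: int

    def class_mask(self, label: str) -> np.ndarray:
        return self.cell_class == label


# ---------------------------------------------------------------------------
# Behavior generation
# ---------------------------------------------------------------------------

def _draw_quiet(cfg: SimConfig, rng: np.random.Generator) -> float:
    return 5.0 + min(rng.exponential(cfg.quiet_mean), cfg.quiet_cap)


def _burst_times(start: float, n_licks: int, cfg: SimConfig,
                 rng: np.random.Generator, cap: float) -> list[float]:
    """Lick times of one burst starting at ``start``, truncated at ``cap``."""
    times = [start]
    t = start
    for _ in range(n_licks - 1):
        t += rng.uniform(*cfg.intra_burst_interval)
        if t >= cap:
            break
        times.append(t)
    return times


def generate_behavior(
    cfg: SimConfig, bin_index: int, rng: np.random.Generator | None = None,
) -> tuple[TrialTable, np.ndarray]:
    """Draw one session's trial schedule and full lick train.

    Outcomes are drawn from the bin's propensities and the first post-onset
    lick is placed inside the corresponding task window, so
    :func:`lickchoice.behavior.classify_outcomes` reproduces the drawn
    labels by construction.  Pre-sound lick bursts occur in the quiet period
    with a bin-dependent probability and end well before tone onset.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    b = bin_index - 1
    p_hit, p_el, p_ll, p_miss = cfg.outcome_propensities[b]
    rule = TaskRule()
    trial_len = 4.7

    onsets, kinds, freqs, outcomes, first_licks, quiets = [], [], [], [], [], []
    licks: list[float] = []
    cursor = 0.0
    for _ in range(cfg.trials_per_session):
        quiet = _draw_quiet(cfg, rng)
        onset = cursor + quiet
        cursor = onset + trial_len
        is_catch = rng.random() < cfg.catch_frac

        # out-of-task licking during the quiet period, clear of the tone
        if rng.random() < cfg.pre_burst_prob[b]:
            n = 1 + rng.poisson(max(cfg.burst_licks_mean[b] - 1.0, 0.0))
            start = rng.uniform(onset - quiet + 0.3, onset - 1.5)
            licks.extend(_burst_times(start, n, cfg, rng, cap=onset - 0.6))

        if is_catch:
            fa = rng.random() < cfg.fa_prob[b]
            outcome = FA if fa else CR
            t_rel = rng.uniform(0.3, 4.4) if fa else None
            freq = np.nan
        else:
            outcome = rng.choice([HIT, EL, LL, MISS], p=[p_hit, p_el, p_ll, p_miss])
            freq = float(rng.choice([6.0, 16.0]))
            if outcome == HIT:
                t_rel = rng.uniform(rule.high_water[0] + 0.1, rule.high_water[1] - 0.1)
            elif outcome == EL:
                t_rel = rng.uniform(0.4, rule.delay[1] - 0.1)
            elif outcome == LL:
                t_rel = rng.uniform(rule.low_water[0] + 0.1, rule.low_water[1] - 0.1)
            else:
                t_rel = None

        if t_rel is not None:
            first = onset + t_rel
            n = 1 + rng.poisson(max(cfg.burst_licks_mean[b] - 1.0, 0.0))
            licks.extend(_burst_times(first, n, cfg, rng, cap=onset + 4.6))
            first_licks.append(first)
        else:
            first_licks.append(np.nan)

        onsets.append(onset)
        kinds.append(CATCH if is_catch else TONE)
        freqs.append(freq)
        outcomes.append(outcome)
        quiets.append(quiet)

    trials = TrialTable(
        onset=np.array(onsets), kind=np.array(kinds, dtype=object),
        freq=np.array(freqs), outcome=np.array(outcomes, dtype=object),
        first_lick_post=np.array(first_licks), quiet_period=np.array(quiets),
    )
    return trials, np.unique(np.asarray(licks, dtype=float))


# ---------------------------------------------------------------------------
# Neural generation
# ---------------------------------------------------------------------------

def _lick_kernel(tau: np.ndarray) -> np.ndarray:
    """Gain time-course around a lick: linear ramp from 0 at -165 ms to a
    peak of 1 at +100 ms, back to 0 by +330 ms."""
    g = np.zeros_like(tau)
    rise = (tau >= -0.165) & (tau < 0.100)
    fall = (tau >= 0.100) & (tau < 0.330)
    g[rise] = (tau[rise] + 0.165) / 0.265
    g[fall] = (0.330 - tau[fall]) / 0.230
    return g


def generate_neural(
    cfg: SimConfig,
    trials: TrialTable,
    licks_hi: np.ndarray,
    bin_index: int,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate the deconvolved activity matrix for a generated behavior.

    rate(c, t) = baseline * (1 + e_b * A_c * g(t - t_lick) * gate) + sound
    term + shared per-event deviation + frame noise, rectified at zero.  The
    gate is 1 for licks inside a tone trial's post-sound span and
    ``gate_leak`` otherwise.  Modulation and shared deviations anchor on
    burst-initial licks, mirroring the isolated-lick analysis convention.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    fr = cfg.frame_rate
    e_b = cfg.experience_curve[bin_index - 1]
    if duration is None:
        duration = (trials.onset[-1] + 6.0) if len(trials) else 10.0
    n_frames = int(np.ceil(duration * fr))
    n = cfg.n_cells

    # planted classes (a partition) and amplitudes
    n_enh = int(round(cfg.f_enh * n))
    n_sup = int(round(cfg.f_sup * n))
    order = rng.permutation(n)
    cell_class = np.full(n, NONE, dtype=object)
    cell_class[order[:n_enh]] = ENHANCED
    cell_class[order[n_enh:n_enh + n_sup]] = SUPPRESSED
    amp = np.zeros(n)
    amp[cell_class == ENHANCED] = rng.uniform(*cfg.amp_range, size=n_enh)
    amp[cell_class == SUPPRESSED] = -rng.uniform(*cfg.sup_amp_range, size=n_sup)
    sound_resp = rng.random(n) < cfg.f_sound

    truth = GroundTruth(cell_class=cell_class, amplitude=amp,
                        sound_responsive=sound_resp,
                        shared_rho=cfg.shared_rho, bin_index=bin_index)

    rate = np.full((n, n_frames), cfg.baseline_rate)
    frame_t = np.arange(n_frames) / fr

    tone_onsets = trials.onset[trials.kind == TONE]
    tone_outcomes = trials.outcome[trials.kind == TONE]

    def post_sound_trial(t: float) -> int | None:
        """Index into tone trials whose post-sound span contains t."""
        if tone_onsets.size == 0:
            return None
        i = int(np.searchsorted(tone_onsets, t, side="right")) - 1
        if i >= 0 and t - tone_onsets[i] < 4.7:
            return i
        return None

    # sound-evoked term: exponential decay over the post-onset half second
    for onset in tone_onsets:
        f0 = int(np.round(onset * fr))
        f1 = min(f0 + int(np.round(0.5 * fr)), n_frames)
        if f0 >= n_frames:
            continue
        tau = frame_t[f0:f1] - onset
        rate[sound_resp, f0:f1] += cfg.sound_amp * np.exp(-tau / cfg.sound_tau)

    # lick-locked modulation + shared per-event deviations on burst onsets
    bursts, singles = segment_bursts(licks_hi, 0.5)
    anchors = sorted([bu.start for bu in bursts] + singles)
    sd_event = cfg.shared_sd * (e_b if cfg.scale_shared_with_experience else 1.0)
    enh_mask = cell_class == ENHANCED
    sup_mask = cell_class == SUPPRESSED
    # Mixing weight for the shared factor, compensated for the dilution of
    # window-mean correlations by independent frame noise, so the realized
    # during-window correlation within a modulated group equals shared_rho
    # whenever the event deviations are strong enough (gaussian law; with
    # weaker deviations the correlation saturates below the target).
    if sd_event > 0 and cfg.noise_law == "gaussian":
        v_frame = cfg.frame_noise_sd ** 2 / 10.0     # 10-frame window mean
        a_mix = min(1.0, cfg.shared_rho * (sd_event**2 + v_frame) / sd_event**2)
    else:
        a_mix = cfg.shared_rho

    for t_lick in anchors:
        af = int(np.round(t_lick * fr))
        trial_i = post_sound_trial(t_lick)
        gate = 1.0 if trial_i is not None else cfg.gate_leak
        f0 = max(af - 5, 0)
        f1 = min(af + 10, n_frames)
        if f1 <= f0:
            continue
        tau = frame_t[f0:f1] - t_lick
        g = _lick_kernel(tau)
        gain = e_b * amp * gate
        if trial_i is not None and tone_outcomes[trial_i] == HIT:
            gain = gain * np.where(enh_mask, 1.0 + cfg.hit_extra_gain, 1.0)
        rate[:, f0:f1] += cfg.baseline_rate * gain[:, None] * g[None, :]

        if sd_event > 0:
            dev = np.zeros(n)
            for mask in (enh_mask, sup_mask):
                if mask.any():
                    shared = rng.standard_normal()
                    own = rng.standard_normal(mask.sum())
                    dev[mask] = sd_event * (
                        np.sqrt(a_mix) * shared
                        + np.sqrt(1.0 - a_mix) * own
                    )
            if cfg.shared_gate == "peri":
                d0, d1 = max(af - 5, 0), min(af + 5, n_frames)
            else:
                d0, d1 = max(af - 25, 0), min(af + 5, n_frames)
            rate[:, d0:d1] += dev[:, None]

    if cfg.noise_law == "gaussian":
        activity = rate + cfg.frame_noise_sd * rng.standard_normal(rate.shape)
        activity = np.maximum(activity, 0.0)
    else:
        counts = rng.poisson(np.maximum(rate, 0.0) / fr)
        activity = counts * fr
    return activity, truth


# ---------------------------------------------------------------------------
# Sessions and experiments
# ---------------------------------------------------------------------------

def generate_session(
    cfg: SimConfig, bin_index: int, session_index: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[SessionRecording, GroundTruth]:
    """One full synthetic session (behavior + neural matrix + metadata)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    trials, licks_hi = generate_behavior(cfg, bin_index, rng)
    duration = (trials.onset[-1] + 6.0) if len(trials) else 10.0
    activity, truth = generate_neural(cfg, trials, licks_hi, bin_index, rng,
                                      duration=duration)
    tone = trials.kind == TONE
    session = SessionRecording(
        activity=activity,
        cell_xy=rng.uniform(0.0, 420.0, size=(cfg.n_cells, 2)),
        licks_hi=licks_hi,
        licks_lo=downsample_licks(licks_hi, cfg.frame_rate),
        stim_onsets=trials.onset[tone],
        stim_freqs=trials.freq[tone],
        trials=trials,
        frame_rate=cfg.frame_rate,
        session_index=session_index,
        bin_index=bin_index,
    )
    session.validate()
    return session, truth


def generate_experiment(
    cfg: SimConfig,
) -> tuple[list[SessionRecording], list[GroundTruth]]:
    """``sessions_per_bin`` sessions for each of the six bins.

    Cell identities (classes, amplitudes, positions) are resampled per
    session: the imaging returns to the same area but not necessarily the
    same cells.
    """
    sessions, truths = [], []
    idx = 0
    for bin_index in range(1, 7):
        for _ in range(cfg.sessions_per_bin):
            rng = stage_rng(cfg.seed, f"session-{idx}")
            s, t = generate_session(cfg, bin_index, session_index=idx, rng=rng)
            sessions.append(s)
            truths.append(t)
            idx += 1
    return sessions, truths


def write_experiment(cfg: SimConfig, out_dir: str | Path) -> list[Path]:
    """Generate an experiment and write session containers + ground truth."""
    import pandas as pd
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions, truths = generate_experiment(cfg)
    paths = []
    gt_rows = []
    for s, t in zip(sessions, truths):
        p = out_dir / f"session_{s.session_index:03d}.h5"
        write_session(s, p)
        paths.append(p)
        for c in range(cfg.n_cells):
            gt_rows.append({
                "session_index": s.session_index, "cell_id": c,
                "class": t.cell_class[c], "amplitude": t.amplitude[c],
                "sound_responsive": bool(t.sound_responsive[c]),
            })
    pd.DataFrame(gt_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    cfg_dict = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(cfg).items()}
    cfg_dict["outcome_propensities"] = [list(p) for p in cfg.outcome_propensities]
    with open(out_dir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
    return paths
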