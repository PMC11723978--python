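"""End-to-end driver: behavior -> classification -> noise correlations ->
population geometry -> decoding, with tabular outputs.

Every stage draws from a named substream of the root seed, so stages are
independently reproducible and the whole run is deterministic given
(config, seed, inputs).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    HIT, LL, POST_SOUND, PipelineConfig, SessionRecording, ValidationError,
    stage_rng,
)
from . import behavior as bhv
from .cell_classification import (
    ENHANCED, NONE, SUPPRESSED, anchors_for_session, attach_sound_flags,
    classify_lick_modulation, pairwise_spatial_distance, peri_lick_summary,
)
from .noise_correlations import corr_contrasts, session_noise_table
from .population_geometry import build_latents_pair, cca_bounds, compare_bins
from .decoding import ALL_CELLS, build_design, decode

__all__ = ["run_pipeline"]


ALL_STAGES = ("behavior", "classify", "noise", "geometry", "decode")

# tables each stage needs computed before it can run
_STAGE_DEPS = {"noise": ("classify",), "decode": ("classify", "behavior")}


def run_pipeline(
    config: PipelineConfig,
    sessions,
    out_dir: str | Path | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the analysis over a list of sessions.

    Returns a dict of DataFrames: ``behavior``, ``bursts``, ``classes``,
    ``peri_lick``, ``spatial``, ``noise``, ``noise_contrasts``,
    ``alignment``, ``geometry``, ``decode``.  ``stages`` restricts the run
    (dependencies are pulled in automatically).  When ``out_dir`` is given
    the tables are also written as CSV (6-decimal fixed precision).
    """
    sessions = list(sessions)
    if not sessions:
        raise ValidationError("run_pipeline needs at least one session")
    config.validate()
    w = config.windows
    wanted = set(stages)
    for stage in stages:
        wanted.update(_STAGE_DEPS.get(stage, ()))

    behavior_rows, burst_frames = [], []
    class_frames, peri_frames, spatial_rows = [], [], []
    noise_frames, decode_rows = [], []
    anchors_by_session, classes_by_session = {}, {}

    for s in sessions:
        if "behavior" in wanted:
            behavior_rows.append(bhv.behavior_summary(s, w))
            burst_frames.append(bhv.bursts_frame(s, config.burst_pause))

        if "classify" in wanted:
            anchors = anchors_for_session(s, config.isolation_clearance)
            anchors_by_session[s.session_index] = anchors
            classes = classify_lick_modulation(
                s, anchors, w, alpha=config.alpha, min_rate=config.min_rate,
                min_anchors=config.min_anchors, p_adjust=config.p_adjust,
            )
            classes = attach_sound_flags(classes, s, windows=w,
                                         alpha=config.alpha,
                                         min_rate=config.min_rate)
            classes_by_session[s.session_index] = classes
            cdf = classes.to_frame()
            cdf.insert(0, "session_index", s.session_index)
            cdf.insert(1, "bin_index", s.bin_index)
            class_frames.append(cdf)

            pls = peri_lick_summary(s, anchors, classes, w,
                                    eps=config.prop_change_eps)
            pls.insert(0, "session_index", s.session_index)
            pls.insert(1, "bin_index", s.bin_index)
            peri_frames.append(pls)

            for key, d in pairwise_spatial_distance(s.cell_xy, classes).items():
                spatial_rows.append({
                    "session_index": s.session_index, "bin_index": s.bin_index,
                    "pairing": key,
                    "mean_distance": float(d.mean()) if d.size else np.nan,
                    "n_pairs": int(d.size),
                })

        if "noise" in wanted:
            noise_frames.append(session_noise_table(
                s, anchors_by_session[s.session_index],
                classes_by_session[s.session_index], w,
                min_trials=config.min_corr_trials))

    # --- decoding, per session and feature set -----------------------------
    lick_prob = {r["session_index"]: r["p_lick_post"] for r in behavior_rows}
    for s in sessions if "decode" in wanted else []:
        anchors = anchors_by_session[s.session_index]
        classes = classes_by_session[s.session_index]
        mod_frac = classes.fraction(ENHANCED) + classes.fraction(SUPPRESSED)
        for feature_set in (ALL_CELLS, ENHANCED, SUPPRESSED, NONE):
            if feature_set != ALL_CELLS:
                if np.sum(classes.mask(feature_set) & classes.included) < 2:
                    continue
            design = build_design(s, anchors, classes, feature_set, w)
            if design is None:
                continue
            reps = 1 if feature_set == ALL_CELLS else config.decode_reps
            rng = stage_rng(config.seed,
                            f"decode-{s.session_index}-{feature_set}")
            try:
                res = decode(design, reps=reps, folds=config.decode_folds,
                             variance_frac=config.pca_variance, rng=rng,
                             per_fold=config.decode_per_fold)
            except ValueError:
                continue
            decode_rows.append({
                "session_index": s.session_index, "bin_index": s.bin_index,
                "feature_set": feature_set,
                "accuracy": res.mean_accuracy,
                "shuffled": float(res.shuffled.mean()),
                "n_components": res.n_components,
                "n_reps": reps,
                "lick_prob": lick_prob[s.session_index],
                "mod_fraction": mod_frac,
            })

    # --- population geometry: align bins 5 and 6 to bin 4 ------------------
    by_bin: dict[int, list[SessionRecording]] = {}
    for s in sessions:
        by_bin.setdefault(s.bin_index, []).append(s)
    align_rows, geom_rows = [], []
    for other in (5, 6) if "geometry" in wanted else []:
        if 4 not in by_bin or other not in by_bin:
            continue
        rng = stage_rng(config.seed, f"geometry-4-{other}")
        comparisons, mean_ccs = compare_bins(
            by_bin[4], by_bin[other], m=config.cca_dim, pair=(HIT, LL),
            grid_s=config.cca_grid, reps=config.geometry_reps,
            n_permutations=config.n_permutations, rng=rng)
        if comparisons is None:
            continue
        lat_a, lat_b = build_latents_pair(
            by_bin[4], by_bin[other], m=config.cca_dim,
            conditions=(HIT, LL), grid_s=config.cca_grid,
            rng=stage_rng(config.seed, f"bounds-4-{other}"))
        upper, lower = cca_bounds(lat_a, lat_b, reps=config.cca_reps,
                                  rng=rng)
        for i in range(min(3, len(mean_ccs))):
            align_rows.append({
                "bin_pair": f"4-{other}", "component": i + 1,
                "cc": float(mean_ccs[i]),
                "upper": float(upper[i]) if i < len(upper) else np.nan,
                "lower": float(lower[i]) if lower is not None and i < len(lower) else np.nan,
            })
        for epoch, cmp_ in comparisons.items():
            geom_rows.append({
                "bin_pair": f"4-{other}", "epoch": epoch,
                "mean_dist_bin4": float(cmp_.dist_a.mean()),
                "mean_dist_other": float(cmp_.dist_b.mean()),
                "mean_diff": cmp_.mean_diff,
                "t_p": cmp_.t_p, "perm_p": cmp_.perm_p,
            })

    def _concat(frames):
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    noise = _concat(noise_frames)
    results = {
        "behavior": pd.DataFrame(behavior_rows),
        "bursts": _concat(burst_frames),
        "classes": _concat(class_frames),
        "peri_lick": _concat(peri_frames),
        "spatial": pd.DataFrame(spatial_rows),
        "noise": noise,
        "noise_contrasts": corr_contrasts(noise) if len(noise) else pd.DataFrame(),
        "alignment": pd.DataFrame(align_rows),
        "geometry": pd.DataFrame(geom_rows),
        "decode": pd.DataFrame(decode_rows),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out_dir / f"{name}.csv", index=False,
                      float_format="%.6f")
    return results
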