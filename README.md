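# lickchoice

Analysis of how decision-related activity develops in auditory-cortex
populations as head-fixed mice gain experience in a delayed tone-detection
task, together with a synthetic-session generator that makes every stage of
the analysis testable against planted ground truth.

## The scientific problem

In the task, a tone (6 or 16 kHz) or a silent catch interval follows a
5–10 s quiet period. The mouse must withhold licking through a 1.5 s delay;
a first lick in the next 1.5 s "high-water" window is a **Hit** (large
reward), a lick in the following 1.5 s window a **Late Lick** (small
guaranteed reward), a lick during the delay an **Early Lick** (timeout),
and no lick a **Miss**. Sessions are grouped into six experience *bins*:
bins 1–3 are Pavlovian training (reward 3 s after tone regardless of
licking), bins 4–6 testing (reward contingent on timing). The neural data
are deconvolved two-photon calcium event rates (cells × frames at 30 Hz)
from auditory cortex L2/3, with lick times recorded at 500 Hz and
down-sampled onto the imaging grid.

The package asks: does lick-locked, sound-gated activity — a signature of
the animal's behavioral choice rather than of the lick movement itself —
emerge and strengthen with task experience, and does it reset when the task
rules change between bins 3 and 4?

## The analyses

- **Behavior** — trial outcomes from the task-window logic; sensitivity
  d′ = z(H) − z(F) with extreme rates clipped to [1/(2n), 1 − 1/(2n)];
  pre/post-sound lick probabilities over matched 4.7 s spans; lick-burst
  segmentation (bursts are ≥2 licks with pauses ≤ 500 ms) and duration
  categories at both temporal resolutions.
- **Cell classification** — per isolated lick (≥330 ms clear of licks and
  stimuli), a paired two-sided Wilcoxon signed-rank test compares the mean
  rate in the 330 ms window straddling lick onset (±165 ms) with the
  330 ms window before it; cells are labelled enhanced / suppressed /
  non-modulated at α = 0.05 after a ≥1 event/s session-rate floor.
  Sound-responsive cells are flagged by the analogous test on the half
  second around tone onset.
- **Noise correlations** — Pearson correlations of trial-to-trial
  window-mean rates (z-scored per cell) in three 330 ms windows tiling
  backwards from the lick ("during", "before", "farther"), aggregated by
  cell-group pairing, outcome and bin.
- **Population geometry** — per bin, Hit/Late-Lick trial counts are
  equalized, peri-lick segments concatenated and projected onto the top-m
  PCs; canonical correlation analysis aligns bins 5 and 6 to bin 4, with an
  upper bound from 500 within-bin split-half repetitions and a lower bound
  from the unaligned spaces; Euclidean distances between condition-mean
  trajectories in the aligned space measure choice discriminability, with
  one-sided t- and label-permutation tests.
- **Decoding** — pre-sound vs post-sound lick phase from 330 ms window-mean
  population rates: SMOTE-style minority oversampling, PCA to 80% variance,
  RBF-kernel SVM, stratified 10-fold cross-validation, shuffled-label
  control, per-cell-group accuracy distributions compared by permutation
  test.

The synthetic generator plants all of this structure — enhanced/suppressed
cells whose gain is gated by the post-sound context and scaled by a per-bin
experience curve that dips at the rule change, shared per-event Gaussian
factors producing within-group noise correlations, sound-evoked responses,
and bin-dependent lick statistics — and returns the ground truth per cell.

## Worked example

```python
import numpy as np
from lickchoice import (SimConfig, generate_session, behavior_summary,
                        classify_lick_modulation)
from lickchoice.cell_classification import anchors_for_session

cfg = SimConfig(n_cells=60, trials_per_session=100, seed=4)
novice, _ = generate_session(cfg, bin_index=1, rng=np.random.default_rng(1))
expert, _ = generate_session(cfg, bin_index=6, rng=np.random.default_rng(2))

for name, s in [("novice (bin 1)", novice), ("expert (bin 6)", expert)]:
    row = behavior_summary(s)
    cl = classify_lick_modulation(s, anchors_for_session(s))
    print(f"{name}: d' = {row['dprime']:.2f}, "
          f"P(lick | post-sound) = {row['p_lick_post']:.2f}, "
          f"enhanced cells = {100 * cl.fraction('ENHANCED'):.1f}%")
```

prints

```
novice (bin 1): d' = 0.12, P(lick | post-sound) = 0.70, enhanced cells = 5.0%
expert (bin 6): d' = 1.09, P(lick | post-sound) = 0.76, enhanced cells = 15.0%
```

The expert session shows better detection sensitivity and three times the
fraction of cells with significantly enhanced lick-locked activity — the
experience effect the full pipeline quantifies across all six bins.

A command-line interface mirrors the library:

```bash
lickchoice simulate --out sessions/ --seed 1 --sessions-per-bin 2
lickchoice run --sessions sessions/ --out results/ --seed 1
lickchoice config            # print every pipeline default
```

## Documentation

`docs/methods.md` describes the generative model, every tunable parameter,
the numerical choices, and what the synthetic data do and do not emulate.
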