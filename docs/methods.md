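# Methods

This note documents the models, conventions and numerical choices behind
`lickchoice`, in the order the pipeline runs.

## Time, frames and windows

All times are session-relative seconds; frames are 0-based and intervals
half-open `[start, end)`. Window offsets are converted to frames by
nearest-frame rounding, so 165 ms at 30 Hz is exactly 5 frames and every
330 ms analysis window is exactly 10 frames; the lick-onset frame belongs
to the post-lick half. These two conventions keep the three lick-locked
windows ("during" = [−165, +165) ms, "before" = [−495, −165) ms,
"farther" = [−825, −495) ms) contiguous and equal-length. Lick times are
down-sampled to the imaging grid by flooring onto frame starts; licks
sharing a frame collapse to one event (an epsilon of 1 ns guards times
already on the grid against float error). Peri-event windows that do not
fit inside the recording drop the event; every consumer reports used and
dropped counts so accounting is explicit.

## Task and outcome logic

Tone trials: the first lick in `[onset, onset + 4.5 s)` decides the
outcome — delay `[0, 1.5)` → Early Lick, high-water `[1.5, 3.0)` → Hit,
low-water `[3.0, 4.5)` → Late Lick, none → Miss. Catch trials: any lick in
the response span → False Alarm, else Correct Rejection. Outcome labels
are assigned identically in the training phase (bins 1–3) for bookkeeping
even though reward there is unconditional. d′ = z(H) − z(F) clips extreme
rates to `[1/(2n), 1 − 1/(2n)]`; the clip keeps perfect sessions finite
and is the simplest of the standard corrections. For pre/post lick
probabilities the post window is `[onset, onset + 4.7)`; the matched pre
window draws 3.7 s from the preceding quiet period, and if that period is
ever shorter the available span is used and recorded per trial. Bursts are
maximal runs of ≥2 licks with inter-lick gaps ≤ 500 ms (a gap of exactly
500 ms stays inside the burst; only greater pauses split); singleton licks
are excluded from burst-length analyses but remain valid peri-lick
anchors. Duration categories are half-open low-inclusive with bounds
{0.002, 0.15, 0.5, 1.0} s at 500 Hz and {0.033, 0.2, 0.5, 1.33} s on the
30 Hz grid; durations below the lower edge or at/above the cap are
excluded.

## Cell classification

Anchors are isolated licks: ≥330 ms free of other licks and stimulus
onsets before the lick (the exclusion interval is open, so exactly 330 ms
counts as clear). Anchors are tagged post-sound when they fall inside a
tone trial's 4.7 s post-onset span, pre-sound otherwise. Classification
uses a paired two-sided Wilcoxon signed-rank test on (during, before)
window means per anchor, at α = 0.05 without multiple-comparison
correction across cells (class *fractions* are the quantity of interest; a
`p_adjust` option exposes BH/Bonferroni). Cells below a 1 event/s
whole-session mean are excluded; sessions with fewer than 10 usable
anchors return all-non-modulated with an `insufficient` flag. The z-scored
peri-lick trace normalizes each cell by its mean/SD over the peri-event
frames of all anchors (not the whole session); zero-variance cells drop
from z summaries but keep raw summaries. The proportional change uses the
symmetric index (post − pre)/(post + pre + ε) with ε = 1e−9.

## Noise correlations

Window-mean rates per (anchor, cell) form a trials × cells matrix per
window; trials with zero activity across the entire population in the
window are discarded (and counted) — the discard is population-wide, never
per pair. Each cell's trial vector is z-scored within (session, window,
outcome) before Pearson correlation; zero-variance cells are dropped from
pairing and at least 3 trials are required, below which the table entry is
marked insufficient rather than imputed. Means are aggregated by group
pairing, and both per-session means and pooled pairs are emitted because
the pooling level is a free choice. The window/outcome contrasts come with
a two-way ANOVA utility (statsmodels OLS) for exploratory use.

## Population geometry

Latent dynamics per bin: tone trials with Hit or Late-Lick outcomes are
cut to a fixed peri-lick grid (−0.5 s to +1.0 s, 45 frames), condition
counts equalized by seeded subsampling, sessions of a bin contribute their
cells as additional columns with index-matched trials, and the
concatenated matrix is projected onto its top m = 10 principal components.
Sessions with fewer than 10 usable trials in either condition are excluded
from the latent construction rather than dragging the bin-common
equalized count down. Classical CCA (SVD-whitening, equivalent to the
textbook QR/SVD algorithm) aligns a later bin to bin 4; the later bin is
then projected back into bin 4's latent coordinates (through the canonical
transformations and the pseudo-inverse of bin 4's), so distances for both
bins live in one space with bin 4's units. We preferred this
"project-back" convention over unit-variance canonical scores because the
per-dimension variance normalization of the latter removes exactly the
amplitude structure the experience comparison is about. The upper bound is
the mean over 500 condition-matched split-half repetitions of bin 4's
trials; the lower bound is the absolute correlation between corresponding
unaligned latent dimensions. Because the trial-count equalization is a
random subsample, the pipeline averages the per-timepoint distance
profiles over 10 independent equalization draws before testing; the
comparison uses a one-sided Welch t-test over per-timepoint distances and
a within-bin condition-label permutation test (1,000 permutations,
seeded). Pre-/post-lick epochs split the grid at the lick onset; per-group
variants rebuild the latents from that group's cells only.

## Decoding

Features are during-window means per isolated lick; labels are the
pre/post-sound context. The default order
is: SMOTE-style oversampling of the minority class (synthetic points
`x_i + u·(x_nn − x_i)`, `u ~ U(0,1)`, among `k = min(5, n_min − 1)`
nearest minority neighbors; a minority of one duplicates with small
jitter), PCA keeping the fewest components reaching 80% cumulative
variance, an RBF-SVM (C = 1, γ = 'scale'), and stratified 10-fold
cross-validation. This order is optimistically biased at small sample
sizes: synthetic minority points leak across folds and the scored set is
itself oversampled. A leakage-safe variant refits the oversampler and PCA
inside each training fold and scores *balanced accuracy* over held-out
original rows (plain accuracy would sit above 1/2 under label shuffling
whenever the classes are imbalanced). The pipeline uses the leakage-safe
variant by default because the bias varies with each bin's anchor count
and imbalance and would confound cross-bin comparisons; the original order
remains available (`decode_per_fold=False`) and is the `decode()` library
default. Per-group accuracy distributions come from 100 repetitions with
fresh CV splits; groups are compared by a two-sample permutation test on
mean accuracy (5,000 resamples).

## The synthetic generator

`SimConfig` defaults are the study conditions; tests shrink counts (cells,
sessions), never the effect structure.

Behavior: 150 trials/session, 20% catch; quiet periods are
5 + min(Exp(1.5 s), 5) s. Outcomes are drawn per bin from propensities
that shift toward timed Hits with experience (Hit 0.30→0.50 over training,
0.42→0.58 over testing) while false alarms (0.50→0.25), pre-sound lick
bursts (0.80→0.40 per trial) and burst lengths (mean 5→2.5 licks,
intra-burst intervals ~7 Hz) all shrink. The first post-onset lick is
placed inside the drawn outcome's window, so the generator and the outcome
classifier agree by construction.

Neural: rate(c, t) = b·(1 + e_b·A_c·g(t − t_lick)·gate) + sound term +
shared event deviation + frame noise, rectified at zero, with baseline
b = 2 events/s. The lick kernel g ramps from 0 at −165 ms to 1 at +100 ms
and back to 0 by +330 ms, anchored on burst-initial licks. Enhanced cells
(15%) have gains A ~ U(0.2, 1.0), suppressed (10%) A ~ −U(0.2, 0.7); the
gate is 1 for post-sound licks and 0.1 (the pre-sound leak) otherwise. The
experience curve e_b = (0.20, 0.50, 0.90, 0.25, 0.85, 1.20) rises within
each phase and resets toward novice level at the bin 3→4 rule change. Hit
trials drive enhanced cells by an extra factor 1.8 relative to Late-Lick
trials (scaled by e_b) — the planted choice signal behind the geometry
contrast; its magnitude, like all effect sizes here, is chosen so the
qualitative orderings are reproducible at desk scale, not to match any
measured magnitude. Within each modulated group, a per-event shared
Gaussian factor (SD 0.8·e_b events/s, gated to the during window) plants
pairwise noise correlations; the factor's mixing weight is compensated for
the dilution by independent frame noise so the realized during-window
correlation equals the 0.3 target whenever the deviations are strong
enough, saturating below it otherwise — which is what makes the
correlation track experience. Sound-responsive cells (15%, independent
flag) add a 1.5 events/s exponential (τ = 150 ms) after tone onset. Frame
noise is Gaussian (SD 2 events/s, rectified; deconvolved traces are
non-negative and noisy) by default, with a Poisson event-count alternative
in the config. Cell identities resample every session — the imaging
returns to the same area, not the same cells.

What the generator does **not** emulate: calcium-indicator kinetics or
deconvolution artifacts, slow drift and motion, reward-consumption
responses, cross-session cell identity, tone-frequency tuning, and any
anatomical spatial organization (cells scatter uniformly, so spatial
analyses should find nothing — and tests check that they don't). Passing
tests therefore validate the statistical machinery and its calibration,
not biological magnitudes.

## Problem sizes and determinism

The default verification experiment is 2 sessions per bin × 100 cells ×
150 trials; the acceptance script uses 10 decode repetitions, 100
split-half repetitions for the CCA upper bound and 300 permutations, which
keeps a full run near one minute while leaving every ordering stable
across seeds. All randomness flows from one root seed through named
per-stage substreams (`stage_rng`), so stages are independently
reproducible and rerunning with the same seed reproduces every table
byte-for-byte.

## Known limitations

- The Wilcoxon classification is calibrated per cell; class *fractions*
  carry the α = 0.05 false-positive floor (~4% of non-modulated cells).
- The planted noise-correlation target is realized at the window level
  only under the Gaussian noise law and away from the rectification
  boundary (low baselines clip and bias correlations slightly downward).
- CCA across bins pairs trials by condition-matched index, a minimal
  construction; canonical correlations on weakly shared structure are
  accordingly modest, and the split-half upper bound uses half-sized data
  and can sit marginally below the full-data aligned correlations.
- Distances between condition means include a trial-count-dependent noise
  floor; comparisons are therefore made at matched equalized counts and
  averaged over subsampling draws, but remain desk-scale noisy relative to
  a real multi-hundred-trial dataset.
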