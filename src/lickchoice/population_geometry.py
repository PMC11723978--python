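"""CCA alignment of latent population dynamics across experience bins and
Euclidean-distance discriminability between trial types.

Per bin, peri-lick segments of Hit and Late-Lick (or Early-Lick) trials are
condition-equalized, concatenated and projected onto the leading principal
components to give latent dynamics.  Canonical correlation analysis finds
the linear transformations that make two bins' latent dynamics maximally
correlated; the top three canonical correlations are compared against an
upper bound from within-day split-half variability (resampled) and a lower
bound from the unaligned spaces.  Distances between condition-mean latent
trajectories quantify how separable the trial types are, per epoch (pre- or
post-lick) and per functional cell group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import HIT, LL, TONE, SessionRecording

__all__ = [
    "LatentDynamics", "AlignmentResult", "DistanceComparison",
    "canoncorr", "build_latents", "build_latents_pair", "align_cca",
    "cca_bounds", "condition_distance", "distance_profile", "compare_bins",
]


# ---------------------------------------------------------------------------
# Classical CCA (QR/SVD-free whitening formulation)
# ---------------------------------------------------------------------------

def canoncorr(
    X: np.ndarray, Y: np.ndarray, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlation analysis of two row-matched matrices.

    Returns ``(A, B, ccs)`` with loading matrices such that the columns of
    ``(X - mean) @ A`` and ``(Y - mean) @ B`` are successively maximally
    correlated; ``ccs`` holds the canonical correlations in decreasing
    order.  Rank deficiency is handled by truncating to the numerical rank.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    Ux, Sx, Vxt = np.linalg.svd(Xc, full_matrices=False)
    Uy, Sy, Vyt = np.linalg.svd(Yc, full_matrices=False)
    kx = Sx > tol * max(Sx[0], 1.0) if Sx.size else np.zeros(0, bool)
    ky = Sy > tol * max(Sy[0], 1.0) if Sy.size else np.zeros(0, bool)
    Ux, Sx, Vxt = Ux[:, kx], Sx[kx], Vxt[kx]
    Uy, Sy, Vyt = Uy[:, ky], Sy[ky], Vyt[ky]
    d = min(Ux.shape[1], Uy.shape[1])
    if d == 0:
        return (np.zeros((X.shape[1], 0)), np.zeros((Y.shape[1], 0)),
                np.zeros(0))
    U, S, Vt = np.linalg.svd(Ux.T @ Uy)
    ccs = np.clip(S[:d], 0.0, 1.0)
    A = (Vxt.T / Sx) @ U[:, :d] * np.sqrt(n - 1)
    B = (Vyt.T / Sy) @ Vt.T[:, :d] * np.sqrt(n - 1)
    return A, B, ccs


# ---------------------------------------------------------------------------
# Latent construction
# ---------------------------------------------------------------------------

@dataclass
class LatentDynamics:
    """Condition-equalized, trial-concatenated latent dynamics of one bin."""

    bin_index: int
    data: np.ndarray          # trials x T x cells (pooled columns per bin)
    latents: np.ndarray       # (trials*T) x m
    basis: np.ndarray         # cells x m PCA basis
    cond_labels: np.ndarray   # condition per trial (ordered blocks)
    grid: np.ndarray          # frame offsets relative to the lick

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def T(self) -> int:
        return self.data.shape[1]

    @property
    def m(self) -> int:
        return self.latents.shape[1]

    def latents_3d(self) -> np.ndarray:
        return self.latents.reshape(self.n_trials, self.T, self.m)


def _trial_segments(
    session: SessionRecording,
    conditions: tuple[str, ...],
    grid: np.ndarray,
    cell_mask: np.ndarray | None,
) -> dict[str, list[np.ndarray]]:
    """Peri-lick activity segments (T x cells) per condition for one session."""
    fr = session.frame_rate
    segs: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    tr = session.trials
    act = session.activity if cell_mask is None else session.activity[cell_mask]
    for i in range(len(tr)):
        out = tr.outcome[i]
        if tr.kind[i] != TONE or out not in conditions:
            continue
        t_lick = tr.first_lick_post[i]
        if not np.isfinite(t_lick):
            continue
        af = int(np.round(t_lick * fr))
        f0, f1 = af + grid[0], af + grid[-1] + 1
        if f0 < 0 or f1 > session.n_frames:
            continue
        segs[out].append(act[:, f0:f1].T)
    return segs


def _pca_latents(X: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Project rows of X onto its top-m principal components."""
    from sklearn.decomposition import PCA
    m_eff = min(m, min(X.shape) - 1)
    m_eff = max(m_eff, 1)
    pca = PCA(n_components=m_eff, svd_solver="full")
    lat = pca.fit_transform(X)
    return lat, pca.components_.T


def build_latents(
    sessions: list[SessionRecording],
    m: int = 10,
    conditions: tuple[str, str] = (HIT, LL),
    grid_s: tuple[float, float] = (-0.5, 1.0),
    n_per_cond: int | None = None,
    min_trials: int = 4,
    rng: np.random.Generator | None = None,
    cell_masks: list[np.ndarray] | None = None,
) -> LatentDynamics | None:
    """Assemble one bin's latent dynamics.

    Trial counts are equalized across conditions (seeded subsampling), every
    trial is cut to a fixed peri-lick frame grid, sessions of the bin
    contribute their cells as additional columns (trials are index-matched
    across sessions) and the concatenated matrix is projected onto its top-m
    PCs.  Sessions with fewer than ``min_trials`` usable trials in either
    condition are excluded (a poor session would otherwise drag the whole
    bin's equalized count down); returns ``None`` when no session survives.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    fr = sessions[0].frame_rate
    grid = np.arange(int(np.round(grid_s[0] * fr)),
                     int(np.round(grid_s[1] * fr)))
    per_session = []
    for s, mask in zip(sessions, cell_masks or [None] * len(sessions)):
        segs = _trial_segments(s, conditions, grid, mask)
        if min(len(segs[c]) for c in conditions) >= min_trials:
            per_session.append(segs)

    counts = [min(len(segs[c]) for c in conditions) for segs in per_session]
    n = min(counts) if counts else 0
    if n_per_cond is not None:
        n = min(n, n_per_cond)
    if n < min_trials:
        return None

    blocks = []      # per condition, trials x T x total_cells
    for c in conditions:
        per_trial = []
        for k in range(n):
            per_trial.append(k)
        cond_stack = []
        for segs in per_session:
            pick = np.sort(rng.choice(len(segs[c]), size=n, replace=False))
            cond_stack.append(np.stack([segs[c][j] for j in pick]))
        blocks.append(np.concatenate(cond_stack, axis=2))
    data = np.concatenate(blocks, axis=0)      # (2n) x T x cells
    cond_labels = np.repeat(list(conditions), n)

    X = data.reshape(-1, data.shape[2])
    latents, basis = _pca_latents(X, m)
    return LatentDynamics(bin_index=sessions[0].bin_index, data=data,
                          latents=latents, basis=basis,
                          cond_labels=np.asarray(cond_labels, dtype=object),
                          grid=grid)


def build_latents_pair(
    sessions_a: list[SessionRecording],
    sessions_b: list[SessionRecording],
    m: int = 10,
    conditions: tuple[str, str] = (HIT, LL),
    grid_s: tuple[float, float] = (-0.5, 1.0),
    min_trials: int = 4,
    rng: np.random.Generator | None = None,
    cell_masks_a: list[np.ndarray] | None = None,
    cell_masks_b: list[np.ndarray] | None = None,
) -> tuple[LatentDynamics | None, LatentDynamics | None]:
    """Build two bins' latents with a common trial count so rows correspond."""
    rng = rng if rng is not None else np.random.default_rng(0)
    probe_a = build_latents(sessions_a, m, conditions, grid_s, None,
                            min_trials, np.random.default_rng(0), cell_masks_a)
    probe_b = build_latents(sessions_b, m, conditions, grid_s, None,
                            min_trials, np.random.default_rng(0), cell_masks_b)
    if probe_a is None or probe_b is None:
        return None, None
    n_common = min(probe_a.n_trials, probe_b.n_trials) // len(conditions)
    lat_a = build_latents(sessions_a, m, conditions, grid_s, n_common,
                          min_trials, rng, cell_masks_a)
    lat_b = build_latents(sessions_b, m, conditions, grid_s, n_common,
                          min_trials, rng, cell_masks_b)
    return lat_a, lat_b


# ---------------------------------------------------------------------------
# Alignment and bounds
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Canonical alignment of two bins' latent dynamics."""

    bin_pair: tuple[int, int]
    ccs: np.ndarray               # canonical correlations, decreasing
    A: np.ndarray
    B: np.ndarray
    aligned_a: np.ndarray         # rows x d canonical scores
    aligned_b: np.ndarray
    upper: np.ndarray | None = None   # top-3 within-day split-half ccs
    lower: np.ndarray | None = None   # top-3 unaligned dimension correlations

    @property
    def top3(self) -> np.ndarray:
        return self.ccs[:3]


def align_cca(lat_a: LatentDynamics, lat_b: LatentDynamics) -> AlignmentResult:
    """Find transformations making two bins' latent dynamics maximally
    correlated and project the second bin back into the first bin's latent
    coordinates.

    ``aligned_a`` is bin A's centered latents in their own coordinates;
    ``aligned_b`` is bin B mapped through the canonical transformations
    (B then the pseudo-inverse of A) into those same coordinates, so
    downstream Euclidean distances for both bins live in one space with
    bin A's units.
    """
    A, B, ccs = canoncorr(lat_a.latents, lat_b.latents)
    Xa = lat_a.latents - lat_a.latents.mean(axis=0)
    Xb = lat_b.latents - lat_b.latents.mean(axis=0)
    back = B @ np.linalg.pinv(A)
    return AlignmentResult(
        bin_pair=(lat_a.bin_index, lat_b.bin_index),
        ccs=ccs, A=A, B=B, aligned_a=Xa, aligned_b=Xb @ back,
    )


def cca_bounds(
    lat_a: LatentDynamics,
    lat_b: LatentDynamics | None = None,
    reps: int = 500,
    rng: np.random.Generator | None = None,
    top: int = 3,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Upper and lower bounds for the across-bin canonical correlations.

    Upper: mean over ``reps`` random condition-matched half-splits of bin
    A's trials of the top canonical correlations between the two halves'
    latent dynamics.  Lower: correlations between corresponding *unaligned*
    latent dimensions of the bin pair (``None`` if ``lat_b`` not given).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    labels = lat_a.cond_labels
    data3 = lat_a.latents_3d()
    m = lat_a.m
    tops = []
    for _ in range(reps):
        half1, half2 = [], []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            h = len(idx) // 2
            if h == 0:
                continue
            half1.extend(idx[:h])
            half2.extend(idx[h:2 * h])
        if not half1:
            return np.full(top, np.nan), None
        X1 = data3[np.sort(half1)].reshape(-1, m)
        X2 = data3[np.sort(half2)].reshape(-1, m)
        l1, _ = _pca_latents(X1, m)
        l2, _ = _pca_latents(X2, m)
        d = min(l1.shape[1], l2.shape[1])
        _, _, ccs = canoncorr(l1[:, :d], l2[:, :d])
        tops.append(ccs[:top])
    upper = np.mean(np.vstack(tops), axis=0)

    lower = None
    if lat_b is not None:
        d = min(lat_a.m, lat_b.m, top)
        lower = np.array([
            abs(stats.pearsonr(lat_a.latents[:, i], lat_b.latents[:, i])[0])
            for i in range(d)
        ])
    return upper, lower


# ---------------------------------------------------------------------------
# Distances between trial types
# ---------------------------------------------------------------------------

def condition_distance(
    aligned: np.ndarray,
    lat: LatentDynamics,
    pair: tuple[str, str],
    epoch: str = "ALL",
) -> np.ndarray:
    """Per-timepoint Euclidean distance between condition-mean trajectories.

    ``epoch`` restricts the peri-lick grid: PRE_LICK keeps frames before
    the lick onset, POST_LICK from the onset on.
    """
    d = aligned.shape[1]
    traj = aligned.reshape(lat.n_trials, lat.T, d)
    means = []
    for c in pair:
        mask = lat.cond_labels == c
        if not mask.any():
            raise ValueError(f"condition {c!r} absent")
        means.append(traj[mask].mean(axis=0))
    dist = np.linalg.norm(means[0] - means[1], axis=1)
    if epoch == "PRE_LICK":
        return dist[lat.grid < 0]
    if epoch == "POST_LICK":
        return dist[lat.grid >= 0]
    return dist


@dataclass
class DistanceComparison:
    """Hit-vs-LL (or EL-vs-LL) separability of two bins in aligned space."""

    bin_pair: tuple[int, int]
    epoch: str
    dist_a: np.ndarray
    dist_b: np.ndarray
    mean_diff: float        # mean(dist_b) - mean(dist_a)
    t_p: float              # one-sided t-test, dist_b > dist_a
    perm_p: float           # label-permutation test


def distance_profile(
    alignment: AlignmentResult,
    lat_a: LatentDynamics,
    lat_b: LatentDynamics,
    pair: tuple[str, str] = (HIT, LL),
    epoch: str = "ALL",
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> DistanceComparison:
    """Compare condition separability between the reference bin and the
    aligned later bin.

    Per-timepoint distances are the samples for a one-sided Welch t-test
    (later bin larger); the permutation test shuffles condition labels
    within each bin and recomputes the mean distance difference.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    da = condition_distance(alignment.aligned_a, lat_a, pair, epoch)
    db = condition_distance(alignment.aligned_b, lat_b, pair, epoch)
    obs = float(db.mean() - da.mean())
    t_p = float(stats.ttest_ind(db, da, equal_var=False,
                                alternative="greater").pvalue)

    def _permuted(lat: LatentDynamics, aligned: np.ndarray) -> np.ndarray:
        labels = rng.permutation(lat.cond_labels)
        shadow = LatentDynamics(lat.bin_index, lat.data, lat.latents,
                                lat.basis, labels, lat.grid)
        return condition_distance(aligned, shadow, pair, epoch)

    count = 0
    for _ in range(n_permutations):
        pa = _permuted(lat_a, alignment.aligned_a)
        pb = _permuted(lat_b, alignment.aligned_b)
        if pb.mean() - pa.mean() >= obs:
            count += 1
    perm_p = (1 + count) / (n_permutations + 1)
    return DistanceComparison(bin_pair=alignment.bin_pair, epoch=epoch,
                              dist_a=da, dist_b=db, mean_diff=obs,
                              t_p=t_p, perm_p=perm_p)


def compare_bins(
    sessions_a: list[SessionRecording],
    sessions_b: list[SessionRecording],
    m: int = 10,
    pair: tuple[str, str] = (HIT, LL),
    epochs: tuple[str, ...] = ("ALL", "PRE_LICK", "POST_LICK"),
    grid_s: tuple[float, float] = (-0.5, 1.0),
    reps: int = 10,
    n_permutations: int = 1000,
    min_trials: int = 10,
    rng: np.random.Generator | None = None,
    cell_masks_a: list[np.ndarray] | None = None,
    cell_masks_b: list[np.ndarray] | None = None,
) -> tuple[dict[str, DistanceComparison] | None, np.ndarray | None]:
    """Full bin-pair comparison, averaged over trial-equalization resamples.

    The condition-count equalization subsamples trials, so a single draw is
    noisy at session scale; ``reps`` independent draws are aligned and
    compared, per-timepoint distances are averaged across draws, and the
    tests run on the averaged profiles.  Returns ``(comparisons by epoch,
    mean top-3 ccs)``, or ``(None, None)`` when trials are insufficient.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    dists: dict[str, list] = {e: [] for e in epochs}
    ccs_all = []
    kept = []
    for _ in range(reps):
        lat_a, lat_b = build_latents_pair(sessions_a, sessions_b, m, pair,
                                          grid_s, min_trials=min_trials,
                                          rng=rng,
                                          cell_masks_a=cell_masks_a,
                                          cell_masks_b=cell_masks_b)
        if lat_a is None or lat_b is None:
            continue
        res = align_cca(lat_a, lat_b)
        ccs_all.append(res.top3)
        kept.append((lat_a, lat_b, res))
        for e in epochs:
            dists[e].append((condition_distance(res.aligned_a, lat_a, pair, e),
                             condition_distance(res.aligned_b, lat_b, pair, e)))
    if not kept:
        return None, None
    out: dict[str, DistanceComparison] = {}
    lat_a, lat_b, res = kept[-1]
    for e in epochs:
        da = np.mean([d[0] for d in dists[e]], axis=0)
        db = np.mean([d[1] for d in dists[e]], axis=0)
        obs = float(db.mean() - da.mean())
        t_p = float(stats.ttest_ind(db, da, equal_var=False,
                                    alternative="greater").pvalue)
        # permutation null from the last draw's alignment, centered on the
        # averaged observed difference
        count = 0
        for _ in range(n_permutations):
            labels_a = rng.permutation(lat_a.cond_labels)
            labels_b = rng.permutation(lat_b.cond_labels)
            sa = LatentDynamics(lat_a.bin_index, lat_a.data, lat_a.latents,
                                lat_a.basis, labels_a, lat_a.grid)
            sb = LatentDynamics(lat_b.bin_index, lat_b.data, lat_b.latents,
                                lat_b.basis, labels_b, lat_b.grid)
            pa = condition_distance(res.aligned_a, sa, pair, e)
            pb = condition_distance(res.aligned_b, sb, pair, e)
            if pb.mean() - pa.mean() >= obs:
                count += 1
        out[e] = DistanceComparison(
            bin_pair=res.bin_pair, epoch=e, dist_a=da, dist_b=db,
            mean_diff=obs, t_p=t_p,
            perm_p=(1 + count) / (n_permutations + 1))
    return out, np.mean(ccs_all, axis=0)
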