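"""CCA correctness and invariances, bounds, and condition-distance logic."""

import numpy as np
import pytest

import lickchoice as lc
from lickchoice.population_geometry import (
    AlignmentResult, LatentDynamics, align_cca, build_latents,
    build_latents_pair, canoncorr, cca_bounds, condition_distance,
    distance_profile,
)


def _random_rotation(m, rng):
    q, _ = np.linalg.qr(rng.normal(size=(m, m)))
    return q


def _make_latents(data3, bin_index=4, labels=None):
    n, T, m = data3.shape
    if labels is None:
        labels = np.array(["HIT"] * (n // 2) + ["LL"] * (n - n // 2),
                          dtype=object)
    return LatentDynamics(bin_index=bin_index, data=data3,
                          latents=data3.reshape(-1, m), basis=np.eye(m),
                          cond_labels=labels, grid=np.arange(-T // 3, 2 * T // 3))


class TestCanoncorr:
    def test_rotation_gives_perfect_correlations(self, rng):
        X = rng.normal(size=(300, 6))
        Y = X @ _random_rotation(6, rng)
        _, _, ccs = canoncorr(X, Y)
        assert np.all(ccs[:3] >= 0.99)

    def test_independent_latents_give_small_ccs(self, rng):
        X = rng.normal(size=(2000, 5))
        Y = rng.normal(size=(2000, 5))
        _, _, ccs = canoncorr(X, Y)
        assert ccs[0] < 0.15

    def test_ccs_sorted_and_bounded(self, rng):
        X = rng.normal(size=(100, 4))
        Y = 0.5 * X + rng.normal(size=(100, 4))
        _, _, ccs = canoncorr(X, Y)
        assert np.all(np.diff(ccs) <= 1e-12)
        assert np.all((ccs >= 0) & (ccs <= 1))

    def test_matches_sklearn_cca(self, rng):
        """Independent route: correlations of sklearn CCA scores equal ours."""
        from sklearn.cross_decomposition import CCA
        X = rng.normal(size=(200, 4))
        Y = 0.7 * X @ _random_rotation(4, rng) + 0.5 * rng.normal(size=(200, 4))
        _, _, ccs = canoncorr(X, Y)
        sk = CCA(n_components=3, max_iter=2000).fit(X, Y)
        U, V = sk.transform(X, Y)
        sk_ccs = [abs(np.corrcoef(U[:, i], V[:, i])[0, 1]) for i in range(3)]
        assert np.allclose(sorted(sk_ccs, reverse=True), ccs[:3], atol=5e-3)

    def test_invariance_to_invertible_remixing(self, rng):
        X = rng.normal(size=(150, 4))
        Y = 0.6 * X + rng.normal(size=(150, 4))
        _, _, base = canoncorr(X, Y)
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        _, _, mixed = canoncorr(X @ M, Y)
        assert np.allclose(base, mixed, atol=1e-6)

    def test_time_permuted_dimension_loses_correlation(self, rng):
        X = rng.normal(size=(400, 3))
        Y = X.copy()
        Y[:, 2] = rng.permutation(Y[:, 2])
        _, _, ccs = canoncorr(X, Y)
        assert np.all(ccs[:2] >= 0.99)
        assert ccs[2] < 0.2

    def test_mismatched_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            canoncorr(rng.normal(size=(10, 2)), rng.normal(size=(11, 2)))


class TestBuildLatents:
    def test_condition_counts_equalized(self, rng):
        session = _geometry_session(n_hit=10, n_ll=14, rng=rng)
        lat = build_latents([session], m=3, rng=rng)
        assert lat.n_trials == 20
        assert np.sum(lat.cond_labels == "HIT") == 10
        assert np.sum(lat.cond_labels == "LL") == 10

    def test_same_seed_same_subsample(self, rng):
        session = _geometry_session(n_hit=8, n_ll=12, rng=rng)
        a = build_latents([session], m=3, rng=np.random.default_rng(5))
        b = build_latents([session], m=3, rng=np.random.default_rng(5))
        assert np.allclose(a.latents, b.latents)

    def test_insufficient_trials_skipped(self, rng):
        session = _geometry_session(n_hit=2, n_ll=10, rng=rng)
        assert build_latents([session], m=3, min_trials=4, rng=rng) is None

    def test_identical_trials_have_zero_condition_distance(self, rng):
        session = _geometry_session(n_hit=6, n_ll=6, rng=rng, noise=0.0)
        lat = build_latents([session], m=3, rng=rng)
        d = condition_distance(lat.latents, lat, ("HIT", "LL"))
        assert np.allclose(d, 0.0, atol=1e-8)


class TestAlignmentAndBounds:
    def test_rotated_latents_align_perfectly(self, rng):
        data = rng.normal(size=(16, 30, 5))
        lat_a = _make_latents(data)
        R = _random_rotation(5, rng)
        lat_b = _make_latents(data @ R, bin_index=5)
        res = align_cca(lat_a, lat_b)
        assert np.all(res.top3 >= 0.99)
        # projected-back bin B reproduces bin A's latents
        da = condition_distance(res.aligned_a, lat_a, ("HIT", "LL"))
        db = condition_distance(res.aligned_b, lat_b, ("HIT", "LL"))
        assert np.allclose(da, db, atol=1e-6)

    def test_aligned_ccs_exceed_unaligned_lower_bound(self, rng):
        data = rng.normal(size=(16, 30, 5))
        R = _random_rotation(5, rng)
        lat_a = _make_latents(data)
        lat_b = _make_latents(data @ R + 0.1 * rng.normal(size=data.shape),
                              bin_index=5)
        res = align_cca(lat_a, lat_b)
        upper, lower = cca_bounds(lat_a, lat_b, reps=20, rng=rng)
        assert res.top3.mean() > np.mean(lower)

    def test_noiseless_repeats_give_unit_upper_bound(self, rng):
        one = rng.normal(size=(1, 30, 4))
        data = np.repeat(one, 12, axis=0)          # identical trials
        lat = _make_latents(data)
        upper, _ = cca_bounds(lat, reps=10, rng=rng)
        assert np.all(upper >= 0.99)

    def test_bounds_reproducible_under_seed(self, rng):
        data = rng.normal(size=(12, 20, 4))
        lat = _make_latents(data)
        u1, _ = cca_bounds(lat, reps=15, rng=np.random.default_rng(3))
        u2, _ = cca_bounds(lat, reps=15, rng=np.random.default_rng(3))
        assert np.allclose(u1, u2)


class TestDistanceProfile:
    def _aligned(self, lat_a, lat_b):
        return align_cca(lat_a, lat_b)

    def test_identical_condition_means_give_zero(self, rng):
        one = rng.normal(size=(1, 30, 4))
        data = np.repeat(one, 10, axis=0)
        lat_a = _make_latents(data)
        lat_b = _make_latents(data.copy(), bin_index=5)
        res = self._aligned(lat_a, lat_b)
        cmp_ = distance_profile(res, lat_a, lat_b, ("HIT", "LL"), "ALL",
                                n_permutations=50, rng=rng)
        assert np.allclose(cmp_.dist_a, 0.0, atol=1e-8)

    def test_post_lick_offset_detected_in_post_epoch(self, rng):
        data = rng.normal(size=(20, 30, 4))
        lat_a = _make_latents(data)
        data_b = data.copy()
        lat_tmp = _make_latents(data_b, bin_index=5)
        post = lat_tmp.grid >= 0
        hit_rows = np.flatnonzero(lat_tmp.cond_labels == "HIT")
        data_b[np.ix_(hit_rows, np.flatnonzero(post))] += 2.0
        lat_b = _make_latents(data_b, bin_index=5)
        res = self._aligned(lat_a, lat_b)
        pre = distance_profile(res, lat_a, lat_b, ("HIT", "LL"), "PRE_LICK",
                               n_permutations=50, rng=rng)
        post_ = distance_profile(res, lat_a, lat_b, ("HIT", "LL"), "POST_LICK",
                                 n_permutations=50, rng=rng)
        assert post_.dist_b.mean() > pre.dist_b.mean()
        assert post_.mean_diff > 0
        assert post_.perm_p < 0.05

    def test_distances_invariant_to_shared_rotation(self, rng):
        data = rng.normal(size=(12, 20, 4))
        lat = _make_latents(data)
        R = _random_rotation(4, rng)
        d1 = condition_distance(lat.latents, lat, ("HIT", "LL"))
        d2 = condition_distance(lat.latents @ R, lat, ("HIT", "LL"))
        assert np.allclose(d1, d2, atol=1e-9)


class TestExperienceEffect:
    def test_separation_scales_with_planted_offset(self, tiny_cfg):
        """Aligned Hit-LL distance grows when the planted choice signal is
        stronger in the later bin."""
        import dataclasses
        cfg = dataclasses.replace(tiny_cfg, n_cells=60,
                                  trials_per_session=150, hit_extra_gain=1.2)
        rng = np.random.default_rng(17)
        s4, _ = lc.generate_session(cfg, 4, rng=np.random.default_rng(1))
        s6, _ = lc.generate_session(cfg, 6, rng=np.random.default_rng(2))
        lat_a, lat_b = build_latents_pair([s4], [s6], m=8, rng=rng)
        res = align_cca(lat_a, lat_b)
        cmp_ = distance_profile(res, lat_a, lat_b, ("HIT", "LL"), "ALL",
                                n_permutations=100, rng=rng)
        assert cmp_.mean_diff > 0


def _geometry_session(n_hit, n_ll, rng, noise=1.0, n_cells=12):
    """Synthetic session whose tone trials have prescribed outcome counts."""
    outcomes = ["HIT"] * n_hit + ["LL"] * n_ll
    rng.shuffle(outcomes)
    onsets, first_licks = [], []
    t = 10.0
    for out in outcomes:
        onsets.append(t)
        first_licks.append(t + (2.0 if out == "HIT" else 3.5))
        t += 12.0
    onsets = np.array(onsets)
    n_frames = int((t + 10) * 30)
    activity = np.maximum(
        2.0 + noise * rng.normal(size=(n_cells, n_frames)), 0.0)
    trials = lc.TrialTable(
        onset=onsets, kind=np.array(["TONE"] * len(onsets), dtype=object),
        freq=np.full(len(onsets), 6.0),
        outcome=np.array(outcomes, dtype=object),
        first_lick_post=np.array(first_licks),
        quiet_period=np.full(len(onsets), 6.0),
    )
    return lc.SessionRecording(
        activity=activity, cell_xy=rng.uniform(0, 400, (n_cells, 2)),
        licks_hi=np.array(first_licks), licks_lo=np.array(first_licks),
        stim_onsets=onsets, stim_freqs=np.full(len(onsets), 6.0),
        trials=trials, bin_index=4,
    )
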