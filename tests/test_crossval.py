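"""Fixed-W reconstruction, synergy matching, surrogate nulls, both modalities."""

from itertools import permutations

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from synstand import (
    CONDITIONS,
    build_condition_matrix,
    match_synergies,
    nmf,
    nnls_matrix,
    normalized_true_synergies,
    nsyn_specific,
    order_synergies,
    reconstruct_fixed_w,
    surrogate_threshold,
    trial_specific,
)
from synstand.pipeline import preprocess_trial
from synstand.segmentation import detect_events


class TestOrderSynergies:
    def test_self_match_is_identity(self, rng):
        W = rng.uniform(0.0, 1.0, size=(8, 4))
        ordered, scores = order_synergies([W], W)
        assert np.array_equal(ordered[0], W)
        assert np.allclose(scores[0], 1.0)

    def test_recovers_column_permutation(self, rng):
        W = rng.uniform(0.0, 1.0, size=(8, 4))
        perm = [2, 0, 3, 1]
        ordered, scores = order_synergies([W[:, perm]], W)
        assert np.allclose(ordered[0], W)
        assert np.allclose(scores[0], 1.0)

    def test_assignment_matches_brute_force(self, rng):
        """Hungarian matching equals exhaustive search over all 4! pairings
        on a noisy copy."""
        W = rng.uniform(0.0, 1.0, size=(8, 4))
        noisy = np.clip(W + 0.1 * rng.standard_normal(W.shape), 0.0, None)
        ref_idx, w_idx, sims = match_synergies(noisy, W)
        Wn = W / np.linalg.norm(W, axis=0)
        Nn = noisy / np.linalg.norm(noisy, axis=0)
        cos = Wn.T @ Nn
        best = max(permutations(range(4)), key=lambda p: sum(cos[i, p[i]] for i in range(4)))
        assert sims.sum() == pytest.approx(sum(cos[i, best[i]] for i in range(4)))
        assert tuple(w_idx[np.argsort(ref_idx)]) == best

    def test_muscle_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            match_synergies(rng.uniform(size=(7, 3)), rng.uniform(size=(8, 3)))


class TestNnlsMatrix:
    def test_matches_scipy_rowwise(self, rng):
        """The vectorized active-set solver equals scipy's NNLS row by row."""
        for k in (1, 3, 5):
            W = rng.uniform(0.0, 1.0, size=(8, k))
            X = np.clip(rng.standard_normal((60, 8)) + 0.5, 0.0, None)
            C = nnls_matrix(W, X)
            ref = np.vstack([scipy_nnls(W, x)[0] for x in X])
            assert np.allclose(C, ref, atol=1e-7)
            assert np.all(C >= 0)

    def test_handles_active_constraints(self, rng):
        """Rows anti-aligned with a column must pin its coefficient at zero."""
        W = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        X = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        C = nnls_matrix(W, X)
        ref = np.vstack([scipy_nnls(W, x)[0] for x in X])
        assert np.allclose(C, ref, atol=1e-10)


class TestReconstructFixedW:
    def test_complete_basis_gives_unit_r2(self, rng):
        X = rng.uniform(0.0, 1.0, size=(200, 6))
        C, r2 = reconstruct_fixed_w(X, np.eye(6))
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(C, X)

    def test_consistent_with_own_nmf(self, small_matrix):
        model = nmf(small_matrix, 3, seed=0)
        _, r2 = reconstruct_fixed_w(small_matrix, model.W)
        # re-fitting C by exact NNLS can only match or improve the NMF fit
        assert r2 >= model.r2 - 1e-9
        assert r2 == pytest.approx(model.r2, abs=1e-3)

    def test_true_w_beats_shuffled_w(self, rng):
        """Paired over 20 generated trials: the generating synergies always
        reconstruct better than a column-shuffled copy."""
        from synstand import TrialConfig, make_ground_truth_synergies, synthesize_trial

        wins = 0
        for seed in range(20):
            truth = make_ground_truth_synergies(3, seed=seed)
            cfg = TrialConfig(n_cycles=5, cycle_duration_mean=1.0, seed=seed)
            trial = synthesize_trial(truth, cfg)
            matrix = preprocess_trial(trial, "30s",
                                      events=trial.ground_truth.events)
            Wn = normalized_true_synergies(trial)
            shuffled = np.vstack([rng.permutation(col) for col in Wn.T]).T
            _, r2_true = reconstruct_fixed_w(matrix, Wn)
            _, r2_shuf = reconstruct_fixed_w(matrix, shuffled)
            wins += r2_true > r2_shuf
        assert wins == 20

    def test_r2_invariant_to_muscle_permutation(self, rng):
        X = rng.uniform(0.0, 1.0, size=(150, 6))
        W = rng.uniform(0.0, 1.0, size=(6, 3))
        perm = rng.permutation(6)
        _, a = reconstruct_fixed_w(X, W)
        _, b = reconstruct_fixed_w(X[:, perm], W[perm])
        assert a == pytest.approx(b, rel=1e-10)

    def test_nested_models_never_lose(self, rng):
        X = rng.uniform(0.0, 1.0, size=(120, 6))
        W = rng.uniform(0.0, 1.0, size=(6, 2))
        W_ext = np.column_stack([W, rng.uniform(0.0, 1.0, size=6)])
        _, r2_small = reconstruct_fixed_w(X, W)
        _, r2_big = reconstruct_fixed_w(X, W_ext)
        assert r2_big >= r2_small - 1e-12


class TestSurrogateThreshold:
    def test_bounded_by_max_surrogate(self, small_matrix):
        model = nmf(small_matrix, 3, seed=0)
        t95 = surrogate_threshold(small_matrix, model.W, n_surrogates=20, seed=1)
        t100 = surrogate_threshold(small_matrix, model.W, n_surrogates=20,
                                   seed=1, percentile=100.0)
        assert t95 <= t100

    def test_deterministic_given_seed(self, small_matrix):
        model = nmf(small_matrix, 3, seed=0)
        a = surrogate_threshold(small_matrix, model.W, n_surrogates=10, seed=4)
        b = surrogate_threshold(small_matrix, model.W, n_surrogates=10, seed=4)
        assert a == b

    def test_too_few_surrogates(self, small_matrix, rng):
        with pytest.raises(ValueError):
            surrogate_threshold(small_matrix, rng.uniform(size=(8, 3)),
                                n_surrogates=1)

    def test_true_w_clears_threshold(self, small_trial, small_matrix):
        Wn = normalized_true_synergies(small_trial)
        _, r2 = reconstruct_fixed_w(small_matrix, Wn)
        thr = surrogate_threshold(small_matrix, Wn, n_surrogates=50, seed=0)
        assert r2 > thr


@pytest.fixture(scope="module")
def six_conditions(small_trial):
    """Envelope matrices and k=3 models for all six conditions of one trial."""
    events = detect_events(small_trial.sacrum_ap, small_trial.fs_marker,
                           small_trial.fs_emg)
    from synstand.preprocessing import bandpass_filter, compute_envelope, normalize_envelope

    filt = bandpass_filter(small_trial.emg, small_trial.fs_emg)
    env = compute_envelope(filt, small_trial.fs_emg)
    n = env.shape[1]
    from synstand.segmentation import CycleEvents

    events = CycleEvents(
        cycles=tuple((s, min(t, n - 1), min(e, n)) for s, t, e in events.cycles
                     if s < n - 1),
        fs=events.fs,
    )
    norm = normalize_envelope(env, events)
    data = {
        c: build_condition_matrix(norm, events, c,
                                  muscle_labels=small_trial.muscle_labels)
        for c in CONDITIONS
    }
    models = {c: nmf(m, 3, seed=0, n_restarts=3) for c, m in data.items()}
    return models, data


class TestTrialSpecific:
    def test_shape_and_labels(self, six_conditions):
        models, data = six_conditions
        res = trial_specific(models, data, n_surrogates=10, seed=0)
        assert res.r2.shape == (6, 6)
        assert list(res.r2.index) == list(CONDITIONS)
        assert list(res.r2.columns) == list(CONDITIONS)
        assert res.surrogate_threshold.shape == (6, 6)
        assert (res.r2.values <= 1.0 + 1e-12).all()

    def test_self_and_cross_beat_surrogates(self, six_conditions):
        models, data = six_conditions
        res = trial_specific(models, data, n_surrogates=20, seed=0)
        diag = np.diag(res.r2.values)
        thr = np.diag(res.surrogate_threshold.values)
        assert np.all(diag >= thr)
        assert (res.r2.loc["30s", "30upward"]
                >= res.surrogate_threshold.loc["30s", "30upward"])

    def test_missing_condition_rejected(self, six_conditions):
        models, data = six_conditions
        incomplete = {c: m for c, m in models.items() if c != "5tsts"}
        with pytest.raises(ValueError, match="5tsts"):
            trial_specific(incomplete, data, n_surrogates=5)


class TestNsynSpecific:
    def test_cells_and_thresholds_populated(self, six_conditions):
        models, data = six_conditions
        pool_models = [nmf(data["30s"], k, seed=0, n_restarts=2) for k in (2, 3)]
        pool_data = [(data["30s"], 3), (data["30upward"], 2)]
        res = nsyn_specific(pool_models, pool_data, n_surrogates=5, seed=0)
        assert set(res.r2.index) == {2, 3}
        assert set(res.r2.columns) == {2, 3}
        assert res.surrogate_threshold.shape == res.r2.shape
        assert len(res.records) == 4
        assert not res.records[["r2", "threshold"]].isna().any().any()

    def test_richer_w_sets_reconstruct_better(self, six_conditions):
        """Mean R^2 with k_W >= k_data exceeds the mean with k_W < k_data."""
        models, data = six_conditions
        pool_models = [nmf(data["30s"], k, seed=0, n_restarts=2) for k in (1, 2, 3, 4)]
        pool_data = [(data[c], 3) for c in ("30s", "30upward", "30downward")]
        res = nsyn_specific(pool_models, pool_data, n_surrogates=2, seed=0)
        rec = res.records
        high = rec[rec.k_w >= rec.k_data].r2.mean()
        low = rec[rec.k_w < rec.k_data].r2.mean()
        assert high > low

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            nsyn_specific([], [], n_surrogates=5)
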