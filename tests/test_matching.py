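"""Cosine matching: similarity, neighborhoods, penalties, volume fits."""

import numpy as np
import pytest

from fibermatch.acquisition import VolumeStack
from fibermatch.matching import (
    FitConfig,
    cosine_similarity,
    fit_signals,
    fit_volume,
    penalized_select,
    top_k,
)


class TestCosineSimilarity:
    def test_self_match_is_one(self, small_dictionary):
        y = small_dictionary.signals[17]
        c = cosine_similarity(y, small_dictionary.signals)
        assert c[17] == pytest.approx(1.0, abs=1e-12)
        assert c.argmax() == 17

    def test_orthogonal_vectors(self):
        S = np.array([[0.0, 1.0, 0.0]])
        assert cosine_similarity(np.array([1.0, 0.0, 0.0]), S)[0] == pytest.approx(0.0)

    def test_scale_invariance(self, small_dictionary, rng):
        y = rng.random(small_dictionary.n_volumes)
        base = cosine_similarity(y, small_dictionary.signals[:50])
        for gamma in (7.3, 1e6, 1e-12):
            scaled = cosine_similarity(gamma * y, small_dictionary.signals[:50])
            assert np.allclose(scaled, base, atol=1e-12)

    def test_l2_equivalence_after_optimal_scaling(self, rng):
        """min_beta ||y - beta d||^2 == ||y||^2 (1 - cos^2), vs a 1-D oracle."""
        from scipy.optimize import minimize_scalar

        for _ in range(20):
            y = rng.random(30) + 0.1
            d = rng.random(30) + 0.1
            cos = float(y @ d / (np.linalg.norm(y) * np.linalg.norm(d)))
            closed = np.linalg.norm(y) ** 2 * (1.0 - cos**2)
            oracle = minimize_scalar(lambda b: np.sum((y - b * d) ** 2)).fun
            assert closed == pytest.approx(oracle, abs=1e-10)

    def test_zero_vector_rejected(self, small_dictionary):
        with pytest.raises(ValueError, match="unmatchable"):
            cosine_similarity(np.zeros(small_dictionary.n_volumes), small_dictionary.signals)


class TestTopK:
    def test_basic_selection(self):
        idx, vals = top_k(np.array([0.9, 0.1, 0.8]), 2)
        assert list(idx) == [0, 2]
        assert list(vals) == [0.9, 0.8]

    def test_all_equal_takes_first_k(self):
        idx, _ = top_k(np.full(10, 0.5), 4)
        assert list(idx) == [0, 1, 2, 3]

    def test_k_equal_l_is_full_sort(self, rng):
        s = rng.random(20)
        idx, vals = top_k(s, 20)
        assert np.array_equal(vals, np.sort(s)[::-1])

    def test_boundary_tie_prefers_lower_index(self):
        s = np.array([0.9, 0.5, 0.5, 0.5, 0.1])
        idx, _ = top_k(s, 2)
        assert list(idx) == [0, 1]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_k(np.ones(3), 4)


class TestPenalizedSelect:
    def test_equal_cosine_prefers_fewer_fibers(self):
        counts = np.array([2, 1])
        chosen, _ = penalized_select(np.array([0, 1]), np.array([0.9, 0.9]), counts, 1e-5)
        assert chosen == 1

    def test_alpha_zero_is_plain_argmax(self):
        counts = np.array([3, 1])
        chosen, _ = penalized_select(np.array([0, 1]), np.array([0.99, 0.98]), counts, 0.0)
        assert chosen == 0

    def test_near_tie_flipped_by_penalty(self):
        """cos 0.99000 with 3 fibers loses to cos 0.98999 with 1 fiber."""
        counts = np.array([3, 1])
        chosen, scores = penalized_select(
            np.array([0, 1]), np.array([0.99000, 0.98999]), counts, 1e-5
        )
        assert chosen == 1
        assert scores[0] == pytest.approx(0.98997)
        assert scores[1] == pytest.approx(0.98998)

    def test_huge_alpha_always_picks_fewest_fibers(self, rng):
        counts = rng.integers(0, 4, size=100)
        sims = rng.random(20)
        idx = rng.choice(100, size=20, replace=False)
        chosen, _ = penalized_select(idx, sims, counts, 1e9)
        assert counts[chosen] == counts[idx].min()

    def test_empty_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            penalized_select(np.array([], dtype=int), np.array([]), np.array([1]), 0.1)


class TestFitSignals:
    def test_noiseless_self_match_recovers_indices(self, small_dictionary):
        rows = np.arange(0, 2000, 7)
        best, cos, _, _ = fit_signals(
            small_dictionary.signals[rows], small_dictionary, FitConfig(alpha=0.0)
        )
        assert np.array_equal(best, rows)
        assert np.allclose(cos, 1.0, atol=1e-12)

    def test_per_voxel_scaling_changes_nothing(self, small_dictionary, rng):
        rows = np.arange(0, 2000, 13)
        scales = rng.uniform(1e-3, 1e3, size=len(rows))
        base, _, _, _ = fit_signals(
            small_dictionary.signals[rows], small_dictionary, FitConfig(alpha=0.0)
        )
        scaled, _, _, _ = fit_signals(
            small_dictionary.signals[rows] * scales[:, None],
            small_dictionary,
            FitConfig(alpha=0.0),
        )
        assert np.array_equal(base, scaled)

    def test_block_size_does_not_affect_results(self, small_dictionary, rng):
        y = rng.random((37, small_dictionary.n_volumes))
        fine = fit_signals(y, small_dictionary, FitConfig(block_size=1))
        coarse = fit_signals(y, small_dictionary, FitConfig(block_size=4096))
        for a, b in zip(fine, coarse):
            assert np.array_equal(a, b)

    def test_k_larger_than_dictionary_rejected(self, small_dictionary, rng):
        with pytest.raises(ValueError):
            fit_signals(
                rng.random((2, 151)), small_dictionary, FitConfig(K=10**6)
            )


class TestFitVolume:
    def _stack(self, small_dictionary, shape=(4, 3, 2)):
        n = int(np.prod(shape))
        data = small_dictionary.signals[:n].reshape(*shape, -1)
        return VolumeStack(data, np.eye(4))

    def test_volume_self_match(self, small_dictionary, gtab151):
        stack = self._stack(small_dictionary)
        res = fit_volume(stack, gtab151, small_dictionary, FitConfig(alpha=0.0))
        assert np.array_equal(res.best_index.ravel(), np.arange(24))
        assert res.mask.all()

    def test_mask_restricts_fitting(self, small_dictionary, gtab151):
        stack = self._stack(small_dictionary)
        stack.mask = np.zeros((4, 3, 2), bool)
        stack.mask[0, 0, 0] = True
        res = fit_volume(stack, gtab151, small_dictionary)
        assert res.mask.sum() == 1
        assert res.best_index[0, 0, 0] == 0
        assert np.isnan(res.best_similarity[1, 0, 0])

    def test_empty_mask_gives_empty_result(self, small_dictionary, gtab151):
        stack = self._stack(small_dictionary)
        stack.mask = np.zeros((4, 3, 2), bool)
        res = fit_volume(stack, gtab151, small_dictionary)
        assert not res.mask.any()

    def test_all_zero_voxel_flagged_unmatchable(self, small_dictionary, gtab151):
        stack = self._stack(small_dictionary)
        stack.data = stack.data.copy()
        stack.data[0, 0, 0] = 0.0
        res = fit_volume(stack, gtab151, small_dictionary)
        assert res.best_index[0, 0, 0] == -1
        assert not res.mask[0, 0, 0]

    def test_fingerprint_mismatch_refused(self, small_dictionary):
        from fibermatch.acquisition import GradientTable

        other = GradientTable(
            np.r_[0.0, np.full(150, 1000.0)],
            np.vstack([np.zeros(3), np.eye(3)[np.zeros(150, int)]]),
        )
        stack = self._stack(small_dictionary)
        with pytest.raises(ValueError, match="fingerprint"):
            fit_volume(stack, other, small_dictionary)

    def test_result_at_returns_match_result(self, small_dictionary, gtab151):
        stack = self._stack(small_dictionary)
        res = fit_volume(stack, gtab151, small_dictionary)
        mr = res.result_at(0, 0, 0)
        assert mr.best_index in mr.neighborhood_indices
        # neighborhood sorted by unpenalized cosine => penalized within alpha*3
        pen = mr.neighborhood_similarities
        assert np.all(np.diff(pen) <= 3 * res.fit_config.alpha + 1e-15)
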