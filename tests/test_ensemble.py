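"""Weighted fusion, decision rules and the weight search."""

import numpy as np
import pytest

from lungtex.ensemble import (EnsembleWeights, SearchConfig, SearchConfigError,
                              WeightedEnsemble, balanced_accuracy_objective,
                              decide, fuse, majority_vote, optimize_weights,
                              single_model_objectives)


def _random_probs(n_models=7, n=50, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(8), size=(n_models, n))
    return p


class TestFuse:
    def test_equal_weights_identical_members_scale_output(self):
        p = np.tile(np.random.default_rng(0).dirichlet(np.ones(8)), (7, 1))
        y = fuse(p, np.ones(7))
        np.testing.assert_allclose(y, 7 * p[0], rtol=1e-12)
        assert decide(y) == decide(p[0])

    def test_one_hot_weight_selects_member(self):
        p = _random_probs()
        w = np.zeros(7)
        w[3] = 1.0
        np.testing.assert_array_equal(fuse(p, w), p[3])

    def test_two_member_hand_arithmetic(self):
        p1 = np.zeros(8); p1[0] = 1.0
        p2 = np.zeros(8); p2[1] = 1.0
        y = fuse(np.stack([p1, p2]), [0.5, 0.5])
        expected = np.zeros(8); expected[0] = expected[1] = 0.5
        np.testing.assert_allclose(y, expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(_random_probs(n_models=6), np.ones(7))

    def test_permutation_equivariance(self):
        p = _random_probs(seed=3)
        w = np.random.default_rng(4).uniform(0, 1, 7)
        perm = np.random.default_rng(5).permutation(7)
        np.testing.assert_allclose(fuse(p, w), fuse(p[perm], w[perm]),
                                   rtol=1e-12)

    def test_brute_force_agreement_on_many_instances(self):
        rng = np.random.default_rng(8)
        p = rng.dirichlet(np.ones(8), size=(7, 10_000))
        w = rng.uniform(0, 1, 7)
        fused = fuse(p, w)
        brute = sum(w[i] * p[i] for i in range(7))
        np.testing.assert_allclose(fused, brute, rtol=1e-12)
        np.testing.assert_array_equal(decide(fused), brute.argmax(axis=1))


class TestDecide:
    def test_unique_maximum(self):
        y = np.zeros(8); y[3] = 2.0
        assert decide(y) == 3

    def test_tie_goes_to_lowest_index(self):
        y = np.zeros(8); y[0] = y[1] = 1.0
        assert decide(y) == 0

    def test_decision_invariant_to_positive_weight_rescaling(self):
        p = _random_probs(seed=6)
        w = np.random.default_rng(7).uniform(0.1, 1, 7)
        np.testing.assert_array_equal(decide(fuse(p, w)),
                                      decide(fuse(p, 5.0 * w)))


class TestMajorityVote:
    def test_clear_majority(self):
        votes = np.array([0, 0, 0, 0, 1, 1, 1])
        assert majority_vote(votes)[0] == 0

    def test_unanimous(self):
        assert majority_vote(np.full(7, 5))[0] == 5

    def test_all_distinct_votes_fall_back_to_summed_probability(self):
        votes = np.arange(7)
        probs = np.full((7, 8), 0.1)
        probs[:, 6] = 0.4   # class 6 has the largest summed probability
        assert majority_vote(votes, probs)[0] == 6

    def test_matches_counting_oracle_without_probs(self):
        rng = np.random.default_rng(1)
        votes = rng.integers(0, 8, size=(7, 500))
        got = majority_vote(votes)
        for n in range(500):
            counts = np.bincount(votes[:, n], minlength=8)
            assert counts[got[n]] == counts.max()
            assert got[n] == int(np.argmax(counts))  # lowest-index tie rule


class TestOptimizeWeights:
    def test_degenerate_duplicated_member(self):
        p0 = _random_probs(n_models=1, n=40, seed=2)[0]
        probs = np.stack([p0] * 7)
        labels = np.random.default_rng(3).integers(0, 8, 40)
        w, hist = optimize_weights(probs, labels,
                                   SearchConfig(n_trials=20, rng_seed=0))
        single = balanced_accuracy_objective(p0, labels)
        assert min(t.score for t in hist) == pytest.approx(single, abs=1e-12)

    def test_returns_best_of_its_own_trials(self):
        probs = _random_probs(seed=4)
        labels = np.random.default_rng(5).integers(0, 8, probs.shape[1])
        w, hist = optimize_weights(probs, labels,
                                   SearchConfig(n_trials=40, rng_seed=1))
        best = min(t.score for t in hist)
        assert balanced_accuracy_objective(fuse(probs, w), labels) == \
            pytest.approx(best, abs=1e-12)

    def test_dominates_single_members(self):
        probs = _random_probs(seed=6, n=80)
        labels = np.random.default_rng(7).integers(0, 8, 80)
        for method in ("TPE", "RS", "BO"):
            w, hist = optimize_weights(
                probs, labels, SearchConfig(method=method, n_trials=30,
                                            rng_seed=2))
            best = min(t.score for t in hist)
            assert best <= single_model_objectives(probs, labels).min() + 1e-9

    def test_identical_seed_identical_history(self):
        probs = _random_probs(seed=8)
        labels = np.random.default_rng(9).integers(0, 8, probs.shape[1])
        cfg = SearchConfig(method="TPE", n_trials=30, rng_seed=11)
        _, h1 = optimize_weights(probs, labels, cfg)
        _, h2 = optimize_weights(probs, labels, cfg)
        assert [t.score for t in h1] == [t.score for t in h2]
        for t1, t2 in zip(h1, h2):
            np.testing.assert_array_equal(t1.w, t2.w)

    def test_two_member_planted_toy_matches_grid_search(self):
        # member A perfect, member B anti-perfect
        rng = np.random.default_rng(12)
        n = 60
        labels = rng.integers(0, 8, n)
        pa = np.full((n, 8), 0.02)
        pa[np.arange(n), labels] = 0.86
        pb = np.full((n, 8), 0.02)
        pb[np.arange(n), (labels + 1) % 8] = 0.86
        probs = np.stack([pa, pb])
        w, hist = optimize_weights(
            probs, labels, SearchConfig(method="TPE", n_trials=200, rng_seed=3))
        assert w.w[0] > w.w[1]
        # oracle: exhaustive 101 x 101 grid
        grid = np.linspace(0, 1, 101)
        best_grid = min(
            balanced_accuracy_objective(fuse(probs, [wa, wb]), labels)
            for wa in grid for wb in grid)
        best_tpe = min(t.score for t in hist)
        assert best_tpe <= best_grid + 1e-3

    def test_invalid_configs_rejected(self):
        with pytest.raises(SearchConfigError):
            SearchConfig(n_trials=0)
        with pytest.raises(SearchConfigError):
            SearchConfig(gamma=1.5)
        with pytest.raises(SearchConfigError):
            SearchConfig(method="genetic")


class TestEnsembleWeightsIO:
    def test_json_round_trip(self):
        names = [f"m{i}" for i in range(7)]
        w = EnsembleWeights(np.linspace(0.1, 1.0, 7))
        text = w.to_json(names, method="TPE", seed=0)
        back = EnsembleWeights.from_json(text, names)
        np.testing.assert_allclose(back.w, w.w)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(np.array([0.5, -0.1]))
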