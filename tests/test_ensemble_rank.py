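"""Equidistant grids, diversity, pruning, annealing, and voting."""

import itertools

import numpy as np
import pytest

from eegens.ensemble_rank import (
    AnnealConfig,
    ModelPool,
    ParamSpec,
    RankEnsembleConfig,
    _vote_accuracy,
    assess_model,
    default_roster,
    divide_conquer_vote,
    equidistant_grid,
    fit_rank_ensemble,
    kappa_diversity,
    majority_vote,
    prune_kmeans,
    ranking_determination,
)


def _pool(votes, accs):
    votes = np.asarray(votes)
    t = votes.shape[0]
    return ModelPool(
        models=[object()] * t,
        names=[f"m{i}" for i in range(t)],
        params=[{}] * t,
        votes=votes,
        accuracies=np.asarray(accs, dtype=float),
    )


class TestEquidistantGrid:
    def test_canonical_k_grid(self):
        """The "k, 2, 16, 4" grid disintegrates to {2, 7, 11, 16}."""
        assert equidistant_grid(ParamSpec("k", 2, 16, 4, integer=True)) == [2, 7, 11, 16]

    def test_degenerate_and_midpoint_grids(self):
        assert equidistant_grid(ParamSpec("C", 1, 1, 1)) == [1]
        assert equidistant_grid(ParamSpec("g", 0, 1, 3)) == [0.0, 0.5, 1.0]

    def test_integer_rounding_deduplicates(self):
        grid = equidistant_grid(ParamSpec("n", 1, 3, 5, integer=True))
        assert grid == [1, 2, 3]

    def test_zero_steps_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("k", 1, 5, 0)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(0)
    x = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(4, 0.3, (40, 2))])
    y = np.r_[np.zeros(40, int), np.ones(40, int)]
    perm = rng.permutation(80)
    return x[perm], y[perm]


class TestAssessModel:

    def test_separable_data_reaches_perfect_accuracy(self, blobs):
        from sklearn.neighbors import KNeighborsClassifier

        x, y = blobs
        model, value, accs = assess_model(
            KNeighborsClassifier(),
            ParamSpec("n_neighbors", 1, 15, 15, integer=True),
            x[:60], y[:60], x[60:], y[60:],
        )
        assert max(accs.values()) == 1.0

    def test_single_value_grid(self, blobs):
        from sklearn.neighbors import KNeighborsClassifier

        x, y = blobs
        _, value, _ = assess_model(
            KNeighborsClassifier(), ParamSpec("n_neighbors", 3, 3, 1, integer=True),
            x[:60], y[:60], x[60:], y[60:],
        )
        assert value == 3

    def test_selection_order_invariant_and_tie_to_smaller(self, blobs):
        from sklearn.neighbors import KNeighborsClassifier

        x, y = blobs
        spec = ParamSpec("n_neighbors", 1, 9, 9, integer=True)
        _, v1, accs = assess_model(
            KNeighborsClassifier(), spec, x[:60], y[:60], x[60:], y[60:]
        )
        best = max(accs.values())
        assert v1 == min(k for k, a in accs.items() if a == best)

    def test_single_class_fold_rejected(self, blobs):
        from sklearn.neighbors import KNeighborsClassifier

        x, y = blobs
        with pytest.raises(ValueError, match="single class"):
            assess_model(
                KNeighborsClassifier(),
                ParamSpec("n_neighbors", 1, 3, 3, integer=True),
                x[y == 0], y[y == 0], x, y,
            )


class TestKappaDiversity:
    def test_identical_models_have_kappa_one(self):
        votes = np.array([[1, 0, 1, 0], [1, 0, 1, 0]])
        assert kappa_diversity(votes, np.array([1, 0, 0, 1])) == 1.0

    def test_complementary_errors_give_minus_one(self):
        """Two members right half the time each, disagreeing everywhere:
        kappa = 1 - 1/(2*0.5*0.5) = -1."""
        votes = np.array([[1, 0, 1, 0], [0, 1, 0, 1]])
        truth = np.array([1, 0, 0, 1])
        assert kappa_diversity(votes, truth) == pytest.approx(-1.0)

    def test_independent_coins_have_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        votes = rng.integers(0, 2, (2, 10_000))
        truth = rng.integers(0, 2, 10_000)
        assert abs(kappa_diversity(votes, truth)) < 0.05

    def test_matches_brute_force_on_random_pools(self):
        """Pairwise-loop reference implementation agrees to 1e-12."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            t, v = rng.integers(2, 7), rng.integers(5, 40)
            votes = rng.integers(0, 2, (t, v))
            truth = rng.integers(0, 2, v)
            qbar = np.mean([(votes[i] == truth).mean() for i in range(t)])
            dis = [
                (votes[i] != votes[k]).mean()
                for i in range(t)
                for k in range(t)
                if i != k
            ]
            disav = np.sum(dis) / (t * (t - 1))
            if disav == 0:
                expect = 1.0
            elif qbar in (0.0, 1.0):
                continue
            else:
                expect = 1 - disav / (2 * qbar * (1 - qbar))
            assert kappa_diversity(votes, truth) == pytest.approx(expect, abs=1e-12)

    def test_unanimous_wrong_pool_returns_one(self):
        # with binary votes, disagreement implies one member is correct,
        # so an all-wrong pool is necessarily unanimous: kappa = 1
        votes = np.array([[1, 0], [1, 0]])
        truth = np.array([0, 1])
        assert kappa_diversity(votes, truth) == 1.0

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            kappa_diversity(np.array([[1, 0]]), np.array([1, 0]))


class TestPruning:
    def test_duplicate_pairs_keep_one_each(self):
        votes = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 1, 0, 1]])
        pool = _pool(votes, [0.9, 0.8, 0.7, 0.75])
        pruned = prune_kmeans(pool, 2, seed=0)
        assert pruned.names == ["m0", "m3"]

    def test_k_at_least_pool_size_keeps_everything(self):
        votes = np.array([[1, 0], [0, 1], [1, 1]])
        pool = _pool(votes, [0.5, 0.6, 0.7])
        assert prune_kmeans(pool, 5, seed=0).n_models == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_survivors_bounded_and_best_model_kept(self, seed):
        rng = np.random.default_rng(seed)
        t, v = 12, 30
        votes = rng.integers(0, 2, (t, v))
        accs = rng.uniform(0.4, 1.0, t)
        pool = _pool(votes, accs)
        k = int(rng.integers(2, 6))
        pruned = prune_kmeans(pool, k, seed=seed)
        assert pruned.n_models <= k
        assert set(pruned.names) <= set(pool.names)
        assert pool.names[int(np.argmax(accs))] in pruned.names


class TestRankingDetermination:
    def test_perfect_member_dominates(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 50)
        votes = np.vstack([truth, rng.integers(0, 2, (4, 50))])
        pool = _pool(votes, [1.0, 0.5, 0.5, 0.5, 0.5])
        inc = ranking_determination(pool, truth, seed=0)
        assert _vote_accuracy(votes, inc, truth) == 1.0

    def test_single_model_included(self):
        pool = _pool(np.array([[1, 0, 1]]), [0.7])
        assert ranking_determination(pool, np.array([1, 0, 1])).tolist() == [1]

    def test_best_ever_at_least_initial(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 2, 40)
        votes = rng.integers(0, 2, (6, 40))
        pool = _pool(votes, np.full(6, 0.5))
        cfg = AnnealConfig(iterations=100)
        inc = ranking_determination(pool, truth, config=cfg, seed=3)
        # reconstruct the seeded initial solution
        rng2 = np.random.default_rng(3)
        init = (rng2.random(6) < cfg.init_prob).astype(int)
        if init.sum() == 0:
            init[int(np.argmax(pool.accuracies))] = 1
        assert _vote_accuracy(votes, inc, truth) >= _vote_accuracy(
            votes, init, truth
        )


class TestVoting:
    def test_majority_rules(self):
        assert majority_vote(np.array([[1], [1], [0]]))[0] == 1
        assert majority_vote(np.array([[1], [0]]))[0] == 1  # tie -> 1
        assert majority_vote(np.array([[0], [0], [1]]))[0] == 0

    def test_weighted_vote(self):
        votes = np.array([[1], [0], [0]])
        assert majority_vote(votes, weights=[0.6, 0.2, 0.2])[0] == 1
        assert majority_vote(votes, weights=[0.4, 0.3, 0.3])[0] == 0

    def test_weight_validation(self):
        votes = np.array([[1], [0]])
        with pytest.raises(ValueError, match="sum to 1"):
            majority_vote(votes, weights=[0.5, 0.6])
        with pytest.raises(ValueError, match="non-negative"):
            majority_vote(votes, weights=[1.5, -0.5])

    def test_divide_conquer_exhaustive_small_shapes(self):
        """Exhaustive over all vote matrices for t*v <= 12, plus every
        threshold: outputs are bit-identical to the plain vote."""
        for t in range(1, 6):
            for v in range(0, 9):
                if t * v > 12:
                    continue
                for bits in itertools.product((0, 1), repeat=t * v):
                    m = np.array(bits).reshape(t, v)
                    expect = majority_vote(m) if v else np.zeros(0, int)
                    for threshold in (1, 2, 3, 10**6):
                        assert np.array_equal(
                            divide_conquer_vote(m, threshold), expect
                        )

    def test_divide_conquer_random_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t, v = int(rng.integers(1, 10)), int(rng.integers(0, 201))
            m = rng.integers(0, 2, (t, v))
            thr = int(rng.integers(1, 64))
            assert np.array_equal(divide_conquer_vote(m, thr), majority_vote(m))

    def test_empty_instance_set(self):
        assert divide_conquer_vote(np.zeros((3, 0), dtype=int), 4).size == 0


class TestRankEnsemble:
    def test_easy_benchmark_and_determinism(self, small_features, small_split):
        tr = small_features.subset_rows(small_split.train_indices)
        te = small_features.subset_rows(small_split.test_indices)
        ens = fit_rank_ensemble(tr, seed=2)
        acc = (ens.predict(te) == te.labels).mean()
        assert acc >= 0.90
        ens2 = fit_rank_ensemble(tr, seed=2)
        assert ens.manifest() == ens2.manifest()
        assert np.array_equal(ens.predict(te), ens2.predict(te))

    def test_label_permuted_accuracy_is_chance(self, small_features):
        rng = np.random.default_rng(11)
        from eegens.featurebank import FeatureTable

        perm = FeatureTable(
            values=small_features.values,
            feature_names=small_features.feature_names,
            labels=rng.permutation(small_features.labels),
        )
        tr = perm.subset_rows(range(0, 150))
        te = perm.subset_rows(range(150, 200))
        ens = fit_rank_ensemble(tr, seed=4)
        acc = (ens.predict(te) == te.labels).mean()
        assert 0.3 <= acc <= 0.7

    def test_empty_roster_rejected(self, small_features):
        with pytest.raises(ValueError):
            fit_rank_ensemble(small_features, roster=[], seed=0)
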