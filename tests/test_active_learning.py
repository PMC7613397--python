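"""Query heuristics, metrics, and the improvement-gated AL loop."""

import numpy as np
import pytest

from specal.active_learning import (
    ALOptions, STRATEGIES, al_loop, r2, rmse, rrmse, score_abd, score_cbd,
    score_ebd, score_eqb, score_pal, score_random, score_rsal,
)
from specal.regression import GPROptions, fit_ensemble, fit_gpr


class TestMetrics:
    def test_hand_values(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.0, 2.0, 4.0])
        assert rmse(pred, obs) == pytest.approx(np.sqrt(1.0 / 3.0))
        assert rrmse(pred, obs) == pytest.approx(100 * np.sqrt(1 / 3) / 2)

    def test_perfect_and_null_fits(self, rng):
        obs = rng.normal(size=30)
        assert rmse(obs, obs) == 0.0
        assert r2(obs, obs) == 1.0
        assert r2(np.full(30, obs.mean()), obs) == pytest.approx(0.0)

    def test_zero_mean_rrmse_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            rrmse(np.array([1.0, 2.0]), np.array([-1.0, 1.0]))


class TestEBD:
    def test_candidate_in_training_scores_zero(self, rng):
        train = rng.normal(size=(10, 4))
        scores = score_ebd(train[:3], train)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_hand_example(self):
        scores = score_ebd(np.array([[1.0], [3.0]]), np.array([[0.0]]))
        np.testing.assert_allclose(scores, [1.0, 9.0])

    def test_matches_brute_force(self, rng):
        pool = rng.normal(size=(50, 6))
        train = rng.normal(size=(50, 6))
        scores = score_ebd(pool, train)
        brute = np.array([
            min(np.sum((p - t) ** 2) for t in train) for p in pool
        ])
        np.testing.assert_allclose(scores, brute, atol=1e-12)

    def test_mean_aggregate_option(self, rng):
        pool = rng.normal(size=(10, 3))
        train = rng.normal(size=(7, 3))
        scores = score_ebd(pool, train, aggregate="mean")
        brute = np.array([
            np.mean([np.sum((p - t) ** 2) for t in train]) for p in pool
        ])
        np.testing.assert_allclose(scores, brute, atol=1e-12)


class TestABD:
    def test_parallel_vector_scores_zero(self):
        scores = score_abd(np.array([[2.0, 2.0]]), np.array([[1.0, 1.0]]))
        assert scores[0] == pytest.approx(0.0, abs=1e-7)

    def test_hand_trigonometry(self):
        train = np.array([[1.0, 0.0]])
        scores = score_abd(np.array([[0.0, 1.0], [1.0, 1.0]]), train)
        np.testing.assert_allclose(scores, [np.pi / 2, np.pi / 4], atol=1e-12)

    def test_scale_invariance(self, rng):
        pool = rng.normal(size=(20, 5))
        train = rng.normal(size=(10, 5))
        s1 = score_abd(pool, train)
        s2 = score_abd(pool * 7.3, train)
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            score_abd(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]))


class TestCBD:
    def test_underrepresented_cluster_ranks_first(self, rng):
        blob_a = rng.normal(0, 0.3, size=(30, 2))
        blob_b = rng.normal(8, 0.3, size=(30, 2))
        pool = np.vstack([blob_a, blob_b])
        train = blob_a[:5] + 0.01          # training drawn from blob A only
        scores = score_cbd(pool, train, n_clusters=2, seed=0)
        assert scores[30:].min() > scores[:30].max()

    def test_single_cluster_falls_back_to_centroid(self, rng):
        pool = rng.normal(size=(20, 3))
        train = rng.normal(size=(5, 3))
        scores = score_cbd(pool, train, n_clusters=1, seed=0)
        d = np.linalg.norm(pool - pool.mean(axis=0), axis=1)
        # closer to the centroid ranks higher once cluster counts tie
        assert np.argmax(scores) == np.argmin(
            np.linalg.norm(pool - _kmeans_center(pool, seed=0), axis=1))

    def test_deterministic(self, rng):
        pool = rng.normal(size=(40, 4))
        train = rng.normal(size=(8, 4))
        s1 = score_cbd(pool, train, n_clusters=4, seed=3)
        s2 = score_cbd(pool, train, n_clusters=4, seed=3)
        np.testing.assert_array_equal(s1, s2)


def _kmeans_center(pool, seed):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=1, n_init=5, random_state=seed).fit(pool)
    return km.cluster_centers_[0]


@pytest.fixture()
def toy_model(rng):
    X = rng.uniform(-1, 1, size=(30, 2))
    y = X[:, 0] + 0.5 * X[:, 1] ** 2
    model = fit_gpr(X, y, GPROptions(optimize=False,
                                     hyperparams=(1.0, 0.7, 0.01)))
    return X, y, model


class TestPAL:
    def test_degenerate_ensemble_scores_zero(self, toy_model, rng):
        X, y, model = toy_model
        pool = rng.uniform(-1, 1, size=(10, 2))
        scores = score_pal(pool, X, y, model=model, fraction=1.0, seed=0)
        assert scores.max() < 1e-20

    def test_extrapolation_scores_higher(self, toy_model):
        X, y, model = toy_model
        inside = np.array([[0.0, 0.0]])
        outside = np.array([[6.0, 6.0]])
        s_in = score_pal(inside, X, y, model=model, seed=0)
        s_out = score_pal(outside, X, y, model=model, seed=0)
        assert s_out[0] > s_in[0]

    def test_equals_direct_member_variance(self, toy_model, rng):
        X, y, model = toy_model
        pool = rng.uniform(-1, 1, size=(12, 2))
        ens = fit_ensemble(X, y, k=5, fraction=0.75, seed=4, base_model=model)
        scores = score_pal(pool, X, y, ensemble=ens)
        preds = ens.predict_members(pool)
        ybar = preds.mean(axis=0)
        np.testing.assert_allclose(scores,
                                   np.mean((preds - ybar) ** 2, axis=0),
                                   atol=1e-12)


class _StubEnsemble:
    def __init__(self, preds):
        self._preds = np.asarray(preds, dtype=float)

    def predict_members(self, Xq):
        return self._preds


class TestEQB:
    def test_agreement_gives_zero_entropy(self):
        ens = _StubEnsemble([[1.0], [1.0], [1.0], [1.0]])
        scores = score_eqb(np.zeros((1, 2)), np.zeros((2, 2)), np.zeros(2),
                           ensemble=ens)
        assert scores[0] == 0.0

    def test_uniform_spread_gives_log_k(self):
        ens = _StubEnsemble([[0.0], [1.0], [2.0], [3.0]])
        scores = score_eqb(np.zeros((1, 2)), np.zeros((2, 2)), np.zeros(2),
                           ensemble=ens, n_bins=4)
        assert scores[0] == pytest.approx(np.log(4))

    def test_member_permutation_invariant(self, rng):
        preds = rng.normal(size=(5, 6))
        s1 = score_eqb(np.zeros((6, 2)), np.zeros((2, 2)), np.zeros(2),
                       ensemble=_StubEnsemble(preds))
        s2 = score_eqb(np.zeros((6, 2)), np.zeros((2, 2)), np.zeros(2),
                       ensemble=_StubEnsemble(preds[::-1]))
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestRSAL:
    def test_interpolating_model_scores_near_zero(self, rng):
        X = rng.uniform(-1, 1, size=(25, 2))
        y = X[:, 0]
        model = fit_gpr(X, y, GPROptions(optimize=False,
                                         hyperparams=(1.0, 1.0, 1e-8)))
        scores = score_rsal(X, X, y, model=model, seed=0)
        assert np.abs(scores).max() < 1e-3

    def test_misfit_region_ranks_first(self):
        # step function fit with a long-lengthscale GP: misfit near the jump
        X = np.linspace(-1, 1, 40)[:, None]
        y = np.sign(X[:, 0])
        model = fit_gpr(X, y, GPROptions(optimize=False,
                                         hyperparams=(1.0, 0.8, 0.01)))
        pool = np.array([[0.0], [0.9], [-0.9]])
        scores = score_rsal(pool, X, y, model=model, seed=0)
        assert scores[0] > scores[1] and scores[0] > scores[2]

    def test_deterministic(self, toy_model, rng):
        X, y, model = toy_model
        pool = rng.uniform(-1, 1, size=(10, 2))
        np.testing.assert_array_equal(
            score_rsal(pool, X, y, model=model, seed=2),
            score_rsal(pool, X, y, model=model, seed=2))


class TestRandom:
    def test_deterministic_and_feature_independent(self, rng):
        pool = rng.normal(size=(30, 4))
        s1 = score_random(pool, seed=9)
        s2 = score_random(pool[:, ::-1], seed=9)
        np.testing.assert_array_equal(s1, s2)

    def test_top_rank_roughly_uniform(self):
        n = 5
        pool = np.zeros((n, 2))
        wins = np.zeros(n)
        for seed in range(4000):
            wins[np.argmax(score_random(pool, seed=seed))] += 1
        freq = wins / 4000
        np.testing.assert_allclose(freq, 1.0 / n, atol=0.03)


def _toy_pool(rng, n=80, n_val=40):
    X = rng.uniform(-2, 2, size=(n + n_val, 3))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + 0.05 * rng.normal(size=n + n_val)
    return X[:n], y[:n], X[n:], y[n:]


LOOP_OPTS = dict(
    gpr=GPROptions(optimize=False, hyperparams=(1.0, 1.0, 0.05)),
    reopt_every=0,
)


class TestALLoop:
    @pytest.mark.parametrize("strategy", sorted(STRATEGIES))
    def test_soundness_every_strategy(self, strategy, rng):
        pool_X, pool_y, val_X, val_y = _toy_pool(rng)
        res = al_loop(pool_X, pool_y, val_X, val_y, strategy=strategy,
                      opts=ALOptions(init_n=5, init_seed=1, stop=8,
                                     **LOOP_OPTS))
        tested_idx = [t[0] for t in res.tested]
        assert len(tested_idx) == len(set(tested_idx))
        assert set(res.accepted_indices) <= set(tested_idx)
        assert res.n_accepted <= 8
        curve_vals = [r for _, r in res.curve]
        assert np.all(np.diff(curve_vals) <= 1e-15)
        assert not (set(res.accepted_indices) & set(res.init_indices))

    @pytest.mark.parametrize("strategy", ["ebd", "pal"])
    def test_deterministic_runs(self, strategy, rng):
        pool_X, pool_y, val_X, val_y = _toy_pool(rng)
        opts = ALOptions(init_n=5, init_seed=3, stop=6, **LOOP_OPTS)
        r1 = al_loop(pool_X, pool_y, val_X, val_y, strategy=strategy, opts=opts)
        r2 = al_loop(pool_X, pool_y, val_X, val_y, strategy=strategy, opts=opts)
        assert r1.tested == r2.tested
        assert r1.curve == r2.curve

    def test_duplicate_pool_accepts_nothing(self):
        # pool contains only exact copies of the initial labeled samples
        rng = np.random.default_rng(0)
        seed = 11
        n, init_n = 40, 10
        init_idx = np.sort(np.random.default_rng(seed).choice(n, init_n,
                                                              replace=False))
        X = np.zeros((n, 2))
        y = np.zeros(n)
        base = rng.normal(size=(init_n, 2))
        base_y = base[:, 0]
        X[init_idx] = base
        y[init_idx] = base_y
        others = np.setdiff1d(np.arange(n), init_idx)
        X[others] = base[others % init_n]
        y[others] = base_y[others % init_n]
        res = al_loop(X, y, base, base_y, strategy="ebd",
                      opts=ALOptions(init_n=init_n, init_seed=seed,
                                     min_improvement=1e-6, reopt_every=0,
                                     gpr=GPROptions(optimize=False,
                                                    hyperparams=(1.0, 1.0,
                                                                 1e-8))))
        assert res.n_accepted == 0

    def test_unknown_strategy_rejected(self, rng):
        pool_X, pool_y, val_X, val_y = _toy_pool(rng)
        with pytest.raises(ValueError, match="unknown strategy"):
            al_loop(pool_X, pool_y, val_X, val_y, strategy="nope")

    def test_stop_limits_accepted(self, rng):
        pool_X, pool_y, val_X, val_y = _toy_pool(rng)
        res = al_loop(pool_X, pool_y, val_X, val_y, strategy="random",
                      opts=ALOptions(init_n=5, init_seed=2, stop=3,
                                     **LOOP_OPTS))
        assert res.n_accepted <= 3
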