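"""Pool-based active learning for regression: query heuristics and loop.

Starting from a small seeded random labeled set, the loop ranks the
remaining pool with a query strategy, tentatively adds the best candidate,
refits the regressor and keeps the candidate only if the validation RMSE
strictly improves; rejected candidates are removed permanently and the next
in the current ranking is tried.  After each acceptance the pool is
re-ranked.  The loop ends when the pool is exhausted or the accepted count
reaches an optional stop.

Diversity strategies (scores computed in feature space):

* EBD — squared-Euclidean distance to the nearest training sample
  (max-min selection: the farthest candidates rank first);
* ABD — smallest angle to any training vector;
* CBD — k-means cluster under-representation in the training set.

Uncertainty strategies (scores from the model):

* PAL — population variance of k bagged-GP member predictions;
* EQB — Shannon entropy of the member predictions binned per candidate;
* RSAL — predicted magnitude of the model residual, from an auxiliary GP
  fit on |training residuals|.

Random scoring is the baseline.  All strategies are deterministic given
(pool, training, seed, options).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .regression import (
    EnsembleModel,
    GPRModel,
    GPROptions,
    ensemble_variance,
    fit_ensemble,
    fit_gpr,
    refit,
)

__all__ = [
    "rmse", "rrmse", "r2",
    "score_ebd", "score_abd", "score_cbd",
    "score_pal", "score_eqb", "score_rsal", "score_random",
    "STRATEGIES", "ALOptions", "ALResult", "al_loop",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Root mean squared error."""
    pred, obs = _paired(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def rrmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Relative RMSE: 100 * RMSE / mean(obs), in percent."""
    pred, obs = _paired(pred, obs)
    m = float(np.mean(obs))
    if m == 0:
        raise ValueError("rRMSE undefined: mean of observations is zero")
    return 100.0 * rmse(pred, obs) / m


def r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    pred, obs = _paired(pred, obs)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _paired(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size:
        raise ValueError("pred and obs lengths differ")
    if pred.size < 2:
        raise ValueError("metrics need at least two samples")
    return pred, obs


# ---------------------------------------------------------------------------
# diversity criteria
# ---------------------------------------------------------------------------

def score_ebd(pool_X: np.ndarray, train_X: np.ndarray, *,
              aggregate: str = "min", **_) -> np.ndarray:
    """Squared Euclidean distance to the training set (higher = more diverse).

    ``aggregate='min'`` is the standard max-min rule; ``'mean'`` averages
    distances over all training samples instead.
    """
    pool_X, train_X = _check_dims(pool_X, train_X)
    d = cdist(pool_X, train_X, metric="sqeuclidean")
    if aggregate == "min":
        return d.min(axis=1)
    if aggregate == "mean":
        return d.mean(axis=1)
    raise ValueError("aggregate must be 'min' or 'mean'")


def score_abd(pool_X: np.ndarray, train_X: np.ndarray, **_) -> np.ndarray:
    """Smallest angle (radians) to any training vector; higher = more diverse."""
    pool_X, train_X = _check_dims(pool_X, train_X)
    pn = np.linalg.norm(pool_X, axis=1)
    tn = np.linalg.norm(train_X, axis=1)
    if np.any(pn == 0):
        raise ValueError(f"zero-norm candidate vector at index {int(np.argmin(pn))}")
    if np.any(tn == 0):
        raise ValueError(f"zero-norm training vector at index {int(np.argmin(tn))}")
    cos = (pool_X @ train_X.T) / np.outer(pn, tn)
    ang = np.arccos(np.clip(cos, -1.0, 1.0))
    return ang.min(axis=1)


def score_cbd(pool_X: np.ndarray, train_X: np.ndarray, *,
              n_clusters: int = 5, seed: int = 0, **_) -> np.ndarray:
    """Cluster-based diversity: prefer clusters under-represented in training.

    The pool is k-means clustered (seeded); a candidate in a cluster with m
    training members scores 1/(1+m), with ties broken by proximity to its own
    centroid (closer first).
    """
    pool_X, train_X = _check_dims(pool_X, train_X)
    if pool_X.shape[0] == 0:
        raise ValueError("empty pool")
    n_clusters = min(n_clusters, pool_X.shape[0])
    km = KMeans(n_clusters=n_clusters, n_init=5, random_state=seed)
    labels = km.fit_predict(pool_X)
    train_labels = km.predict(train_X)
    members = np.bincount(train_labels, minlength=n_clusters)
    base = 1.0 / (1.0 + members[labels])
    d_centroid = np.linalg.norm(pool_X - km.cluster_centers_[labels], axis=1)
    # tie-break term strictly smaller than any gap between base levels
    return base + 1e-9 / (1.0 + d_centroid)


# ---------------------------------------------------------------------------
# uncertainty criteria
# ---------------------------------------------------------------------------

def score_pal(pool_X: np.ndarray, train_X: np.ndarray, train_y: np.ndarray, *,
              model: GPRModel | None = None, k: int = 5,
              fraction: float = 0.75, seed: int = 0,
              ensemble: EnsembleModel | None = None, **_) -> np.ndarray:
    """Variance of a pool-of-regressors ensemble at each candidate."""
    ens = ensemble or fit_ensemble(train_X, train_y, k=k, fraction=fraction,
                                   seed=seed, base_model=model)
    return ensemble_variance(ens.predict_members(pool_X))


def score_eqb(pool_X: np.ndarray, train_X: np.ndarray, train_y: np.ndarray, *,
              model: GPRModel | None = None, k: int = 5,
              fraction: float = 0.75, seed: int = 0, n_bins: int = 5,
              ensemble: EnsembleModel | None = None, **_) -> np.ndarray:
    """Entropy query-by-bagging: Shannon entropy of binned member predictions.

    Per candidate, the k member predictions are histogrammed into ``n_bins``
    equal-width bins spanning that candidate's prediction range; agreement
    (all members in one bin, or zero range) gives entropy 0.
    """
    ens = ensemble or fit_ensemble(train_X, train_y, k=k, fraction=fraction,
                                   seed=seed, base_model=model)
    preds = ens.predict_members(pool_X)          # (k, n)
    kk, n = preds.shape
    lo = preds.min(axis=0)
    rng_ = preds.max(axis=0) - lo
    out = np.zeros(n)
    nonzero = rng_ > 0
    if np.any(nonzero):
        scaled = (preds[:, nonzero] - lo[nonzero]) / rng_[nonzero]
        bins = np.minimum((scaled * n_bins).astype(int), n_bins - 1)
        for j, col in enumerate(np.where(nonzero)[0]):
            counts = np.bincount(bins[:, j], minlength=n_bins)
            p = counts[counts > 0] / kk
            out[col] = float(-(p * np.log(p)).sum())
    return out


def score_rsal(pool_X: np.ndarray, train_X: np.ndarray, train_y: np.ndarray, *,
               model: GPRModel, seed: int = 0, **_) -> np.ndarray:
    """Residual-regression AL: predicted |residual| of the primary model.

    An auxiliary GP maps features to the absolute training residuals of the
    primary model; its posterior mean at each candidate is the score.
    """
    resid = np.abs(model.predict(train_X) - np.asarray(train_y, float).ravel())
    if np.all(resid == 0):
        return np.zeros(pool_X.shape[0])
    aux = fit_gpr(train_X, resid, GPROptions(n_restarts=1, seed=seed))
    return aux.predict(pool_X)


def score_random(pool_X: np.ndarray, *, seed: int = 0, **_) -> np.ndarray:
    """Seeded uniform random scores (the random-sampling baseline)."""
    rng = np.random.default_rng(seed)
    return rng.random(pool_X.shape[0])


def _check_dims(pool_X, train_X) -> tuple[np.ndarray, np.ndarray]:
    pool_X = np.atleast_2d(np.asarray(pool_X, dtype=float))
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if pool_X.shape[1] != train_X.shape[1]:
        raise ValueError("pool and training feature dimensions differ")
    return pool_X, train_X


#: strategy registry: name -> needs_model flag
STRATEGIES: dict[str, Callable] = {
    "ebd": score_ebd,
    "abd": score_abd,
    "cbd": score_cbd,
    "pal": score_pal,
    "eqb": score_eqb,
    "rsal": score_rsal,
    "random": score_random,
}
_UNCERTAINTY = {"pal", "eqb", "rsal"}


# ---------------------------------------------------------------------------
# the AL loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ALOptions:
    """Loop settings.

    ``init_n`` seeded random samples start the labeled set (10 = 1% of the
    default 1k pool); one candidate is tested per iteration and accepted only
    on strict validation-RMSE improvement.  Hyperparameters are re-optimized
    every ``reopt_every`` acceptances (tentative tests reuse them).
    ``rerank_on_reject=True`` re-scores the pool after every rejection as
    well (slower; default re-ranks only after acceptances).
    """

    init_n: int = 10
    init_seed: int = 0
    stop: int | None = None
    reopt_every: int = 10
    rerank_on_reject: bool = False
    min_improvement: float = 0.0        # required RMSE decrease (absolute)
    # diversity criteria measure distances/angles in a z-scored copy of the
    # feature space (per-feature stats over the full pool), so no single
    # high-variance component dominates the geometry; the regressor itself
    # sees the raw features
    standardize_diversity: bool = True
    gpr: GPROptions = GPROptions()
    strategy_opts: dict = field(default_factory=dict)


@dataclass
class ALResult:
    """Ordered record of an AL run and its learning curve."""

    strategy: str
    seed: int
    init_indices: np.ndarray
    tested: list[tuple[int, bool, float]]     # (pool index, accepted, val RMSE)
    curve: list[tuple[int, float]]            # (labeled size, best val RMSE)
    accepted_indices: list[int]
    model: GPRModel
    wall_time: float

    @property
    def final_rmse(self) -> float:
        return self.curve[-1][1]

    @property
    def n_accepted(self) -> int:
        return len(self.accepted_indices)


def al_loop(
    pool_X: np.ndarray,
    pool_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    strategy: str = "ebd",
    opts: ALOptions | None = None,
) -> ALResult:
    """Run the greedy validation-guided AL loop over a labeled pool.

    The pool labels are available but treated as unlabeled until queried.
    Returns the full tested/accepted log, the monotone learning curve and the
    final model.
    """
    opts = opts or ALOptions()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; have {sorted(STRATEGIES)}")
    pool_X = np.atleast_2d(np.asarray(pool_X, dtype=float))
    pool_y = np.asarray(pool_y, dtype=float).ravel()
    val_X = np.atleast_2d(np.asarray(val_X, dtype=float))
    val_y = np.asarray(val_y, dtype=float).ravel()
    if opts.init_n < 2:
        raise ValueError("init_n must be at least 2")
    if val_y.size == 0:
        raise ValueError("validation set is empty")
    n = pool_X.shape[0]
    if opts.init_n > n:
        raise ValueError("init_n exceeds pool size")

    t0 = time.perf_counter()
    rng = np.random.default_rng(opts.init_seed)
    init_idx = np.sort(rng.choice(n, size=opts.init_n, replace=False))
    labeled = list(init_idx)
    remaining = sorted(set(range(n)) - set(labeled))

    model = fit_gpr(pool_X[labeled], pool_y[labeled], opts.gpr)
    best = rmse(model.predict(val_X), val_y)
    curve = [(len(labeled), best)]
    tested: list[tuple[int, bool, float]] = []
    accepted: list[int] = []
    since_reopt = 0
    score_fn = STRATEGIES[strategy]

    div_X = pool_X
    if opts.standardize_diversity and strategy in ("ebd", "abd", "cbd"):
        mu = pool_X.mean(axis=0)
        sd = pool_X.std(axis=0)
        sd[sd == 0] = 1.0
        div_X = (pool_X - mu) / sd

    def scores_for(cand: list[int], round_seed: int) -> np.ndarray:
        kw = dict(opts.strategy_opts)
        kw.setdefault("seed", opts.init_seed * 100003 + round_seed)
        if strategy in _UNCERTAINTY:
            kw["model"] = model
            return score_fn(pool_X[cand], pool_X[labeled],
                            train_y=pool_y[labeled], **kw)
        if strategy == "random":
            return score_fn(pool_X[cand], **kw)
        return score_fn(div_X[cand], div_X[labeled],
                        train_y=pool_y[labeled], **kw)

    rounds = 0
    need_rank = True
    ranked: list[int] = []
    while remaining and (opts.stop is None or len(accepted) < opts.stop):
        if need_rank:
            s = scores_for(remaining, rounds)
            order = np.argsort(-s, kind="stable")
            ranked = [remaining[i] for i in order]
            rounds += 1
            need_rank = False
        if not ranked:
            break
        cand = ranked.pop(0)
        trial = labeled + [cand]
        trial_model = refit(model, pool_X[trial], pool_y[trial])
        cand_rmse = rmse(trial_model.predict(val_X), val_y)
        remaining.remove(cand)
        if cand_rmse < best - opts.min_improvement:
            labeled.append(cand)
            accepted.append(cand)
            model = trial_model
            best = cand_rmse
            since_reopt += 1
            if opts.reopt_every and since_reopt >= opts.reopt_every:
                reopt = fit_gpr(pool_X[labeled], pool_y[labeled], opts.gpr)
                reopt_rmse = rmse(reopt.predict(val_X), val_y)
                if reopt_rmse <= best:   # keep the better of the two fits
                    model, best = reopt, reopt_rmse
                since_reopt = 0
            tested.append((cand, True, cand_rmse))
            curve.append((len(labeled), best))
            need_rank = True
        else:
            tested.append((cand, False, cand_rmse))
            if opts.rerank_on_reject:
                need_rank = True

    return ALResult(
        strategy=strategy,
        seed=opts.init_seed,
        init_indices=init_idx,
        tested=tested,
        curve=curve,
        accepted_indices=accepted,
        model=model,
        wall_time=time.perf_counter() - t0,
    )
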