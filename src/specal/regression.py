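"""Gaussian-process regression with analytic predictive mean and variance.

The GP uses an isotropic RBF kernel plus a noise term,

    k(x, x') = sigma_f^2 exp(-||x - x'||^2 / (2 l^2)) + sigma_n^2 delta(x, x'),

with hyperparameters chosen by maximizing the log marginal likelihood via
multi-start bounded L-BFGS-B in log space.  Targets are centered (and
internally scaled to unit variance) before fitting; predictions are mapped
back.  A fixed-hyperparameter refit path makes the one-sample-at-a-time
active-learning loop cheap: adding a candidate costs one Cholesky.

Bagged ensembles of GPs provide the spread-based uncertainty scores (pool of
regressors, query-by-bagging): k members are each trained on a seeded random
subset of the current training set, and the population variance of their
predictions at a candidate,

    sigma_y^2 = (1/k) sum_i (y_i - ybar)^2,   ybar = (1/k) sum_i y_i,

measures disagreement.

All pairwise distances go through ``scipy.spatial.distance.cdist`` and the
reductions through non-optimized ``einsum`` so that predictions are bitwise
identical regardless of how the query set is chunked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "GPROptions",
    "GPRModel",
    "EnsembleModel",
    "fit_gpr",
    "refit",
    "predict",
    "fit_ensemble",
    "ensemble_variance",
]


@dataclass(frozen=True)
class GPROptions:
    """Hyperparameter-search settings for :func:`fit_gpr`.

    n_restarts extra seeded random starts are run in addition to the
    median-heuristic start; jitter is added to the kernel diagonal for
    numerical stability and is the floor of the predictive variance.
    """

    n_restarts: int = 4
    seed: int = 0
    jitter: float = 1e-8
    max_iter: int = 100
    optimize: bool = True
    # hyperparameters are searched on a seeded subsample of at most this many
    # rows (the O(n^3) likelihood makes full-pool search needlessly slow);
    # the final solve always uses all data
    max_opt_n: int = 400
    # optional fixed hyperparameters (sigma_f2, lengthscale, sigma_n2) on the
    # *standardized-target* scale; used when optimize is False
    hyperparams: tuple[float, float, float] | None = None


@dataclass
class GPRModel:
    """Trained GP: hyperparameters, training data and precomputed solves.

    ``sigma_f2``/``lengthscale``/``sigma_n2`` live on the standardized-target
    scale; ``y_mean``/``y_std`` map predictions back to trait units.
    """

    X: np.ndarray
    y: np.ndarray                          # training targets, trait units
    y_mean: float
    y_std: float
    sigma_f2: float
    lengthscale: float
    sigma_n2: float
    jitter: float
    alpha: np.ndarray                      # K^-1 (y - mean)/std
    chol: tuple[np.ndarray, bool]          # cho_factor of K
    log_marginal_likelihood: float = np.nan
    _kinv: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_train(self) -> int:
        return self.X.shape[0]

    def _kinv_matrix(self) -> np.ndarray:
        if self._kinv is None:
            self._kinv = cho_solve(self.chol, np.eye(self.n_train))
        return self._kinv

    def _cross_kernel(self, Xq: np.ndarray) -> np.ndarray:
        d = cdist(Xq, self.X, metric="sqeuclidean")
        return self.sigma_f2 * np.exp(-0.5 * d / self.lengthscale**2)

    def predict(
        self, Xq: np.ndarray, return_std: bool = False
    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        """Closed-form GP posterior mean (and predictive std) at ``Xq``.

        The predictive variance includes the noise term sigma_n^2, so it lies
        in [jitter, sigma_f2 + sigma_n2 + jitter] (standardized scale).
        """
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        if Xq.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: model {self.X.shape[1]}, "
                f"query {Xq.shape[1]}"
            )
        ks = self._cross_kernel(Xq)
        mean = np.einsum("ij,j->i", ks, self.alpha, optimize=False)
        mean = mean * self.y_std + self.y_mean
        if not return_std:
            return mean
        kinv = self._kinv_matrix()
        q = np.einsum("ij,jk,ik->i", ks, kinv, ks, optimize=False)
        var = self.sigma_f2 + self.sigma_n2 + self.jitter - q
        var = np.clip(var, self.jitter, None)
        return mean, np.sqrt(var) * self.y_std


def _sq_dists(X: np.ndarray) -> np.ndarray:
    return cdist(X, X, metric="sqeuclidean")


def _median_heuristic(D: np.ndarray) -> float:
    off = D[np.triu_indices_from(D, k=1)]
    off = off[off > 0]
    if off.size == 0:
        return 1.0
    return float(np.sqrt(np.median(off)))


def _neg_lml_and_grad(theta: np.ndarray, D: np.ndarray, y: np.ndarray,
                      jitter: float) -> tuple[float, np.ndarray]:
    sf2, ls, sn2 = np.exp(theta)
    n = y.size
    R = np.exp(-0.5 * D / ls**2)
    K = sf2 * R + (sn2 + jitter) * np.eye(n)
    try:
        c = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(3)
    alpha = cho_solve(c, y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(c[0]))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    kinv = cho_solve(c, np.eye(n))
    W = np.outer(alpha, alpha) - kinv        # dLML/dK = W/2
    g_sf2 = 0.5 * float(np.sum(W * (sf2 * R)))
    g_ls = 0.5 * float(np.sum(W * (sf2 * R * (D / ls**2))))
    g_sn2 = 0.5 * sn2 * float(np.trace(W))
    return -lml, -np.array([g_sf2, g_ls, g_sn2])


def _build_model(X: np.ndarray, y_raw: np.ndarray, y_mean: float, y_std: float,
                 sf2: float, ls: float, sn2: float, jitter: float) -> GPRModel:
    n = X.shape[0]
    D = _sq_dists(X)
    K = sf2 * np.exp(-0.5 * D / ls**2) + (sn2 + jitter) * np.eye(n)
    c = cho_factor(K, lower=True)
    y = (y_raw - y_mean) / y_std
    alpha = cho_solve(c, y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(c[0]))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    return GPRModel(
        X=X, y=y_raw, y_mean=y_mean, y_std=y_std,
        sigma_f2=sf2, lengthscale=ls, sigma_n2=sn2, jitter=jitter,
        alpha=alpha, chol=c, log_marginal_likelihood=lml,
    )


def fit_gpr(X: np.ndarray, y: np.ndarray,
            opts: GPROptions | None = None) -> GPRModel:
    """Fit the RBF+noise GP by multi-start maximum marginal likelihood.

    Deterministic given ``opts.seed``.  With ``opts.optimize=False`` the
    hyperparameters are taken from ``opts.hyperparams`` (or the median
    heuristic) without any search.
    """
    opts = opts or GPROptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if X.shape[0] < 2:
        raise ValueError("at least two training samples are required")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in training data")

    y_mean = float(y.mean())
    y_std = float(y.std())
    if y_std < 1e-12:
        # constant target: the posterior mean is that constant everywhere
        y_std = 1.0
        m = _build_model(X, y, y_mean, y_std, 1e-8, 1.0, 1e-8, opts.jitter)
        return m

    X_opt, y_opt = X, y
    if opts.optimize and X.shape[0] > opts.max_opt_n:
        sub = np.sort(np.random.default_rng(opts.seed).choice(
            X.shape[0], size=opts.max_opt_n, replace=False))
        X_opt, y_opt = X[sub], y[sub]
    D = _sq_dists(X_opt)
    ls0 = _median_heuristic(D)

    if opts.hyperparams is not None and not opts.optimize:
        sf2, ls, sn2 = opts.hyperparams
        return _build_model(X, y, y_mean, y_std, sf2, ls, sn2, opts.jitter)
    if not opts.optimize:
        return _build_model(X, y, y_mean, y_std, 1.0, ls0, 0.05, opts.jitter)

    yn = (y_opt - y_mean) / y_std
    bounds = [
        (np.log(1e-4), np.log(1e3)),                      # log sigma_f2
        (np.log(ls0) - 5.0, np.log(ls0) + 5.0),           # log lengthscale
        (np.log(1e-8), np.log(10.0)),                     # log sigma_n2
    ]
    starts = [np.array([0.0, np.log(ls0), np.log(0.05)])]
    rng = np.random.default_rng(opts.seed)
    for _ in range(opts.n_restarts):
        starts.append(np.array([
            rng.uniform(np.log(1e-2), np.log(1e2)),
            np.log(ls0) + rng.uniform(-2.0, 2.0),
            rng.uniform(np.log(1e-6), np.log(1.0)),
        ]))

    best_val, best_theta = np.inf, starts[0]
    for x0 in starts:
        res = minimize(
            _neg_lml_and_grad, x0, args=(D, yn, opts.jitter),
            method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": opts.max_iter},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_theta = float(res.fun), res.x
    if not np.isfinite(best_val):
        warnings.warn("GP hyperparameter search failed; falling back to the "
                      "median-heuristic lengthscale", RuntimeWarning)
        return _build_model(X, y, y_mean, y_std, 1.0, ls0, 0.05, opts.jitter)

    sf2, ls, sn2 = np.exp(best_theta)
    return _build_model(X, y, y_mean, y_std, float(sf2), float(ls), float(sn2),
                        opts.jitter)


def refit(model: GPRModel, X: np.ndarray, y: np.ndarray,
          keep_scaling: bool = False) -> GPRModel:
    """Refit on new data keeping the model's hyperparameters (one Cholesky).

    Target centering/scaling statistics are recomputed from the new data
    unless ``keep_scaling`` is set, in which case the model's prior (its
    centering and scale) is kept — appropriate when *augmenting* an existing
    training set, since at fixed prior adding data never increases the
    predictive variance anywhere.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if keep_scaling:
        y_mean, y_std = model.y_mean, model.y_std
    else:
        y_mean = float(y.mean())
        y_std = float(y.std())
        if y_std < 1e-12:
            y_std = 1.0
    return _build_model(X, y, y_mean, y_std, model.sigma_f2,
                        model.lengthscale, model.sigma_n2, model.jitter)


def predict(model: GPRModel, Xq: np.ndarray, return_std: bool = False):
    """Module-level alias of :meth:`GPRModel.predict`."""
    return model.predict(Xq, return_std=return_std)


# ---------------------------------------------------------------------------
# bagged ensembles (pool of regressors)
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """k GP members, each trained on a seeded random training subset."""

    members: list[GPRModel]
    subsets: list[np.ndarray]

    @property
    def k(self) -> int:
        return len(self.members)

    def predict_members(self, Xq: np.ndarray) -> np.ndarray:
        """(k, n_query) matrix of member posterior means."""
        return np.stack([m.predict(Xq) for m in self.members])


def fit_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    fraction: float = 0.75,
    seed: int = 0,
    base_model: GPRModel | None = None,
    opts: GPROptions | None = None,
) -> EnsembleModel:
    """Train ``k`` GPs on random subsets (without replacement) of (X, y).

    Subset size is ceil(fraction * n).  When ``base_model`` is given its
    hyperparameters are reused for every member (single Cholesky each);
    otherwise each member runs its own hyperparameter search.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k < 2:
        raise ValueError("ensemble needs k >= 2 members")
    m = int(np.ceil(fraction * n))
    if m < 2:
        raise ValueError("fraction * n must be at least 2")
    if m > n:
        raise ValueError("fraction must not exceed 1")
    rng = np.random.default_rng(seed)
    members, subsets = [], []
    for i in range(k):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        if base_model is not None:
            member = refit(base_model, X[idx], y[idx])
        else:
            member_opts = replace(opts or GPROptions(), seed=(opts.seed if opts else 0) + i)
            member = fit_gpr(X[idx], y[idx], member_opts)
        members.append(member)
        subsets.append(idx)
    return EnsembleModel(members=members, subsets=subsets)


def ensemble_variance(predictions: np.ndarray | Sequence[float]) -> np.ndarray:
    """Population variance of k member predictions.

    ``predictions`` is (k,) for one candidate or (k, n) for n candidates:
    sigma_y^2 = (1/k) sum_i (y_i - ybar)^2 with ybar the member mean.
    """
    preds = np.asarray(predictions, dtype=float)
    if preds.ndim == 1:
        preds = preds[:, None]
        squeeze = True
    else:
        squeeze = False
    if preds.shape[0] < 2:
        raise ValueError("variance needs at least k = 2 predictions")
    var = preds.var(axis=0, ddof=0)
    return float(var[0]) if squeeze else var
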