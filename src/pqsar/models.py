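"""The four regression methods and their parameter-selection protocols.

All methods share one contract: ``fit(X, y, config)`` on an
already-scaled training matrix returns a :class:`FittedModel`;
``predict(model, X_new)`` is deterministic given the stored state.

* PLS — univariate NIPALS partial least squares; the number of latent
  variables (NLV) is chosen by adding components while the increase in
  cumulative cross-validated q^2 = 1 - PRESS/TSS stays at or above a
  threshold (default 0.097).
* SVR — epsilon-insensitive support vector regression with the radial
  kernel exp(-||u-v||^2 / (2 sigma^2)); (epsilon, C, sigma^2) picked by
  systematic grid search minimizing k-fold RMSE_cv.
* RF — random forest regression; (ntree, mtry) picked the same way, with
  out-of-bag statistics reported as auxiliary output.
* GP — zero-mean Gaussian process with an isotropic squared-exponential
  kernel plus a noise term; Theta = (signal variance, length-scale, noise
  variance) set by maximizing the log marginal likelihood from several
  seeded restarts.

Default scaling follows the per-method convention (PLS and GP autoscale;
SVR and RF scale to [-1, +1]); it is overridable per configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import joblib
import numpy as np
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.svm import SVR

from .stats import make_folds, rmse

METHODS = ("pls", "svr", "rf", "gp")

#: per-method default feature scaling
DEFAULT_SCALING = {"pls": "autoscale", "svr": "range_pm1",
                   "rf": "range_pm1", "gp": "autoscale"}

_GP_MAX_N = 10_000


class ConfigError(ValueError):
    """Raised for inconsistent regressor configurations."""


@dataclass(frozen=True)
class RegressorConfig:
    """Method choice plus scaling, CV folds, seed and candidate grids."""

    method: str
    scaling: str | None = None          # None -> per-method default
    cv_folds: int = 10
    seed: int = 0
    # PLS
    pls_q2_threshold: float = 0.097
    pls_max_nlv: int | None = None      # None -> min(n-1, p, 50)
    pls_fixed_nlv: int | None = None
    # SVR
    svr_epsilon: tuple = (0.01, 0.05, 0.1, 0.2)
    svr_C: tuple = (0.1, 1.0, 10.0, 100.0)
    svr_sigma2_factors: tuple = (0.25, 1.0, 4.0, 16.0)
    svr_sigma2: tuple | None = None     # absolute values override the factors
    # RF
    rf_ntree: tuple = (100, 300, 500)
    rf_mtry: tuple | None = None        # None -> {sqrt(p), p/3, p/2}
    # GP
    gp_restarts: int = 5
    gp_fixed_theta: tuple | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.pls_q2_threshold <= 0:
            raise ConfigError("the q^2-increase threshold must be positive")


def scaling_for(config: RegressorConfig) -> str:
    return config.scaling or DEFAULT_SCALING[config.method]


@dataclass
class FittedModel:
    """A trained model: selected parameters, selection trace, predict state."""

    method: str
    params: dict
    n_features: int
    trace: list = field(default_factory=list)
    q2_trace: tuple = ()
    state: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and aligned with the 1-D response y")
    if X.shape[0] == 0:
        raise ValueError("cannot fit on an empty training set")
    return X, y


def fit(X, y, config: RegressorConfig) -> FittedModel:
    """Dispatch to the configured method's fit routine."""
    return {"pls": fit_pls, "svr": fit_svr, "rf": fit_rf, "gp": fit_gp}[
        config.method
    ](X, y, config)


def predict(model: FittedModel, X_new, return_std: bool = False) -> np.ndarray:
    """Predict responses for scaled rows; deterministic given the model state."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new must have {model.n_features} columns, got shape {X_new.shape}"
        )
    if return_std and model.method != "gp":
        raise ValueError("predictive standard deviations require a GP model")
    if X_new.shape[0] == 0:
        return (np.empty(0), np.empty(0)) if return_std else np.empty(0)
    if model.method == "pls":
        st = model.state
        return st["y_mean"] + (X_new - st["x_mean"]) @ st["coef"]
    if return_std:
        return model.state["estimator"].predict(X_new, return_std=True)
    return model.state["estimator"].predict(X_new)


# ---------------------------------------------------------------------------
# PLS (NIPALS, q^2-based component selection)
# ---------------------------------------------------------------------------

def _nipals_pls1(X, y, ncomp, tol=1e-12):
    """Univariate NIPALS; returns (x_mean, y_mean, W, P, q) loadings."""
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xr = X - x_mean
    yr = y - y_mean
    W, P, q = [], [], []
    for _ in range(ncomp):
        w = Xr.T @ yr
        wn = np.linalg.norm(w)
        if wn <= tol:
            break
        w = w / wn
        t = Xr @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p = Xr.T @ t / tt
        c = float(yr @ t) / tt
        Xr = Xr - np.outer(t, p)
        yr = yr - c * t
        W.append(w)
        P.append(p)
        q.append(c)
    return x_mean, y_mean, W, P, q


def _pls_coef(W, P, q, k):
    Wk = np.column_stack(W[:k])
    Pk = np.column_stack(P[:k])
    return Wk @ np.linalg.solve(Pk.T @ Wk, np.asarray(q[:k]))


def _pls_oof_predictions(X, y, max_nlv, folds):
    """Pooled out-of-fold predictions for every NLV in 1..max_nlv."""
    n = len(y)
    preds = np.empty((max_nlv, n))
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        xm, ym, W, P, q = _nipals_pls1(X[mask], y[mask], max_nlv)
        r = len(W)
        Xc = X[test_idx] - xm
        for k in range(1, max_nlv + 1):
            kk = min(k, r)  # rank-deficient folds reuse their last component
            if kk == 0:
                preds[k - 1, test_idx] = ym
            else:
                preds[k - 1, test_idx] = ym + Xc @ _pls_coef(W, P, q, kk)
    return preds


def fit_pls(X, y, config: RegressorConfig) -> FittedModel:
    """NIPALS PLS with the cumulative-q^2 stopping rule for NLV."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    if np.var(y) == 0:
        raise ValueError("PLS requires a non-constant response")
    cap = min(n - 1, p)
    if config.pls_max_nlv is not None:
        cap = min(cap, config.pls_max_nlv)
    else:
        cap = min(cap, 50)
    cap = max(cap, 1)

    if config.pls_fixed_nlv is not None:
        nlv = min(max(config.pls_fixed_nlv, 0), cap)
        q2_trace = ()
        trace = [{"nlv": nlv, "q2": None, "fixed": True}]
    else:
        if n < config.cv_folds:
            raise ValueError(
                f"NLV selection needs n >= cv_folds ({config.cv_folds}), got {n}"
            )
        folds = make_folds(n, config.cv_folds, config.seed)
        preds = _pls_oof_predictions(X, y, cap, folds)
        tss = float(np.sum((y - y.mean()) ** 2))
        q2 = 1.0 - np.sum((preds - y) ** 2, axis=1) / tss
        # add components from the empty model (q^2 = 0) while each one
        # improves cumulative q^2 by at least the threshold
        nlv = 0
        for k in range(1, cap + 1):
            prev = q2[k - 2] if k > 1 else 0.0
            if q2[k - 1] - prev >= config.pls_q2_threshold:
                nlv = k
            else:
                break
        q2_trace = tuple(float(v) for v in q2)
        trace = [{"nlv": k + 1, "q2": float(v)} for k, v in enumerate(q2)]

    if nlv == 0:
        xm, ym = X.mean(axis=0), float(y.mean())
        coef = np.zeros(p)
        nlv_eff = 0
    else:
        xm, ym, W, P, q = _nipals_pls1(X, y, nlv)
        nlv_eff = len(W)
        coef = _pls_coef(W, P, q, nlv_eff) if nlv_eff else np.zeros(p)
    return FittedModel(
        method="pls",
        params={"nlv": nlv_eff},
        n_features=p,
        trace=trace,
        q2_trace=q2_trace,
        state={"x_mean": xm, "y_mean": ym, "coef": coef},
    )


# ---------------------------------------------------------------------------
# grid-search helpers (SVR, RF)
# ---------------------------------------------------------------------------

def _grid_rmse_cv(X, y, folds, make_estimator, candidates):
    """k-fold RMSE_cv for every candidate; returns list of (cand, rmse)."""
    n = len(y)
    results = []
    for cand in candidates:
        oof = np.empty(n)
        for test_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            est = make_estimator(cand).fit(X[mask], y[mask])
            oof[test_idx] = est.predict(X[test_idx])
        results.append((cand, rmse(y, oof)))
    return results


def _median_sqdist(X, rng, max_rows=400):
    sub = X if len(X) <= max_rows else X[rng.choice(len(X), max_rows, replace=False)]
    if len(sub) < 2:
        return 1.0
    med = float(np.median(pdist(sub, "sqeuclidean")))
    return med if med > 0 else 1.0


def fit_svr(X, y, config: RegressorConfig) -> FittedModel:
    """Epsilon-SVR with RBF kernel; grid search over (epsilon, C, sigma^2)."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    if config.svr_sigma2 is not None:
        sigma2s = list(config.svr_sigma2)
    else:
        med = _median_sqdist(X, rng)
        sigma2s = [f * med for f in config.svr_sigma2_factors]
    grid = list(product(config.svr_epsilon, config.svr_C, sigma2s))
    if not grid:
        raise ConfigError("the SVR parameter grid is empty")

    def make(cand):
        eps, C, s2 = cand
        return SVR(kernel="rbf", gamma=1.0 / (2.0 * s2), C=C, epsilon=eps)

    if len(grid) == 1:
        best, trace = grid[0], [{"epsilon": grid[0][0], "C": grid[0][1],
                                 "sigma2": grid[0][2], "rmse_cv": None}]
    else:
        folds = make_folds(n, config.cv_folds, config.seed)
        results = _grid_rmse_cv(X, y, folds, make, grid)
        # ties: prefer smaller C, then larger epsilon, then larger sigma^2
        best = min(results, key=lambda r: (r[1], r[0][1], -r[0][0], -r[0][2]))[0]
        trace = [{"epsilon": c[0], "C": c[1], "sigma2": c[2], "rmse_cv": v}
                 for c, v in results]

    est = make(best).fit(X, y)
    return FittedModel(
        method="svr",
        params={"epsilon": best[0], "C": best[1], "sigma2": best[2]},
        n_features=p,
        trace=trace,
        state={"estimator": est},
        extras={"n_support": int(est.n_support_.sum())},
    )


def fit_rf(X, y, config: RegressorConfig) -> FittedModel:
    """Random-forest regression; grid search over (ntree, mtry), OOB reported."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    if config.rf_mtry is not None:
        mtrys = list(dict.fromkeys(int(m) for m in config.rf_mtry))
    else:
        mtrys = sorted({max(1, int(np.sqrt(p))), max(1, p // 3), max(1, p // 2)})
    bad = [m for m in mtrys if m > p or m < 1]
    if bad:
        raise ConfigError(f"mtry value(s) {bad} outside [1, p={p}]")
    grid = list(product(config.rf_ntree, mtrys))
    if not grid:
        raise ConfigError("the RF parameter grid is empty")

    def make(cand):
        nt, mt = cand
        return RandomForestRegressor(
            n_estimators=int(nt), max_features=mt,
            random_state=config.seed, n_jobs=1,
        )

    if len(grid) == 1:
        best, trace = grid[0], [{"ntree": grid[0][0], "mtry": grid[0][1],
                                 "rmse_cv": None}]
    else:
        folds = make_folds(n, config.cv_folds, config.seed)
        results = _grid_rmse_cv(X, y, folds, make, grid)
        best = min(results, key=lambda r: (r[1], r[0][0], r[0][1]))[0]
        trace = [{"ntree": c[0], "mtry": c[1], "rmse_cv": v} for c, v in results]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # sparse-OOB warning
        est = RandomForestRegressor(
            n_estimators=int(best[0]), max_features=best[1],
            random_state=config.seed, n_jobs=1, oob_score=True,
        ).fit(X, y)
    oob = est.oob_prediction_
    ok = np.isfinite(oob)
    extras = {
        "oob_predictions": oob,
        "oob_rmse": rmse(y[ok], oob[ok]) if ok.any() else float("nan"),
    }
    return FittedModel(
        method="rf",
        params={"ntree": int(best[0]), "mtry": int(best[1])},
        n_features=p,
        trace=trace,
        state={"estimator": est},
        extras=extras,
    )


# ---------------------------------------------------------------------------
# GP (squared-exponential + noise, restarted marginal-likelihood ascent)
# ---------------------------------------------------------------------------

def _gp_fit_with_jitter(kernel, X, y, optimizer):
    jitter = 1e-10
    while True:
        est = GaussianProcessRegressor(
            kernel=kernel, alpha=jitter, optimizer=optimizer,
            n_restarts_optimizer=0, normalize_y=False,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                return est.fit(X, y), jitter
        except np.linalg.LinAlgError:
            if jitter >= 1e-4:
                raise
            jitter *= 100.0


def _gp_kernel(sv, ls, nv, fixed=False):
    b = "fixed" if fixed else None
    return (
        ConstantKernel(sv, constant_value_bounds=b or (1e-8, 1e6))
        * RBF(ls, length_scale_bounds=b or (1e-3, 1e5))
        + WhiteKernel(nv, noise_level_bounds=b or (1e-10, 1e4))
    )


def fit_gp(X, y, config: RegressorConfig) -> FittedModel:
    """Zero-mean GP regression with Theta from restarted LML maximization."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n > _GP_MAX_N:
        raise ValueError(
            f"dense GP solve guarded at n <= {_GP_MAX_N}; got n = {n}"
        )
    if config.gp_fixed_theta is not None:
        sv, ls, nv = (float(v) for v in config.gp_fixed_theta)
        est, jitter = _gp_fit_with_jitter(
            _gp_kernel(sv, ls, nv, fixed=True), X, y, optimizer=None
        )
        return FittedModel(
            method="gp",
            params={"signal_variance": sv, "length_scale": ls,
                    "noise_variance": nv},
            n_features=p,
            trace=[{"theta": (sv, ls, nv), "fixed": True,
                    "lml": float(est.log_marginal_likelihood_value_)}],
            state={"estimator": est},
            extras={"lml": float(est.log_marginal_likelihood_value_),
                    "jitter": jitter},
        )

    rng = np.random.default_rng(config.seed)
    var_y = max(float(np.var(y)), 1e-8)
    ls0 = np.sqrt(_median_sqdist(X, rng))
    starts = [(0.9 * var_y, ls0, 0.1 * var_y)]
    for _ in range(max(config.gp_restarts - 1, 0)):
        starts.append((
            0.9 * var_y * 10 ** rng.uniform(-1, 1),
            ls0 * 10 ** rng.uniform(-1, 1),
            0.1 * var_y * 10 ** rng.uniform(-1.5, 1.5),
        ))

    best_est, best_lml, best_jitter, trace = None, -np.inf, None, []
    for sv, ls, nv in starts:
        est, jitter = _gp_fit_with_jitter(
            _gp_kernel(sv, ls, nv), X, y, optimizer="fmin_l_bfgs_b"
        )
        lml_init = float(est.log_marginal_likelihood(np.log([sv, ls, nv])))
        lml_opt = float(est.log_marginal_likelihood_value_)
        trace.append({"theta_init": (sv, ls, nv), "lml_init": lml_init,
                      "theta_opt": tuple(np.exp(est.kernel_.theta)),
                      "lml_opt": lml_opt})
        if lml_opt > best_lml:
            best_est, best_lml, best_jitter = est, lml_opt, jitter

    k = best_est.kernel_
    params = {
        "signal_variance": float(k.k1.k1.constant_value),
        "length_scale": float(k.k1.k2.length_scale),
        "noise_variance": float(k.k2.noise_level),
    }
    return FittedModel(
        method="gp",
        params=params,
        n_features=p,
        trace=trace,
        state={"estimator": best_est},
        extras={"lml": best_lml, "jitter": best_jitter},
    )


# ---------------------------------------------------------------------------
# flat-mode pinning and serialization
# ---------------------------------------------------------------------------

def pin_config(config: RegressorConfig, fitted: FittedModel) -> RegressorConfig:
    """Config whose grids are pinned to the parameters ``fitted`` selected."""
    if fitted.method != config.method:
        raise ConfigError("fitted model method does not match the config")
    p = fitted.params
    if config.method == "pls":
        return replace(config, pls_fixed_nlv=p["nlv"])
    if config.method == "svr":
        return replace(config, svr_epsilon=(p["epsilon"],), svr_C=(p["C"],),
                       svr_sigma2=(p["sigma2"],))
    if config.method == "rf":
        return replace(config, rf_ntree=(p["ntree"],), rf_mtry=(p["mtry"],))
    return replace(config, gp_fixed_theta=(
        p["signal_variance"], p["length_scale"], p["noise_variance"]))


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model (joblib archive); round-trips bit-identically."""
    joblib.dump(model, path, compress=3)


def load_model(path) -> FittedModel:
    model = joblib.load(path)
    if not isinstance(model, FittedModel):
        raise TypeError(f"{path} does not contain a FittedModel")
    return model
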