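"""Uniform adapters for the ten regression methods.

Every method — LM, GLM (stepwise-AIC linear model), PLS, LASSO, ENET, SVRM
(radial SVM), NN (single-hidden-layer perceptron), RF, RF-RFE, SVM-RFE —
is exposed through the same contract: hyperparameters are tuned by minimum
mean cross-validated RMSE over a grid, the winner is refit on the full
training partition, and the result is a :class:`FittedModel` carrying the
chosen hyperparameters, the selected features, feature importances and a
predict method.  Downstream code never branches on the method name except
through ``cv_schemes_allowed``.

The underlying estimators are scikit-learn's; the tuning loop, grids and
feature-selection logic live here so that all methods share one
standardized cross-validation scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .resampling import CVScheme, iter_resamples, make_cv_folds
from .stats import CVMetrics, r_squared, r_squared_fit, rmse

METHOD_NAMES = ("LM", "GLM", "PLS", "LASSO", "ENET", "SVRM", "NN", "RF", "RF-RFE", "SVM-RFE")

#: Methods too expensive for leave-one-out; repeated k-fold only.
_REPEATED_ONLY = frozenset({"RF", "RF-RFE", "SVM-RFE"})
_SELECTS_FEATURES = frozenset({"GLM", "LASSO", "ENET", "RF-RFE", "SVM-RFE"})


class RegressorError(ValueError):
    pass


@dataclass
class MethodSpec:
    """Configuration of one regression method.

    ``tuning_grid`` of None means "build the default grid from the data";
    ``options`` holds non-tuned knobs (e.g. RF tree count, RFE subset sizes).
    """

    name: str
    tuning_grid: list[dict] | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise RegressorError(f"unknown method {self.name!r}")

    @property
    def cv_schemes_allowed(self) -> frozenset:
        if self.name in _REPEATED_ONLY:
            return frozenset({"repeated_kfold"})
        return frozenset({"repeated_kfold", "loo"})

    @property
    def performs_feature_selection(self) -> bool:
        return self.name in _SELECTS_FEATURES


def method_spec(name: str, tuning_grid=None, **options) -> MethodSpec:
    return MethodSpec(name=name, tuning_grid=tuning_grid, options=options)


@dataclass
class FittedModel:
    """A trained method with chosen hyperparameters and a predict contract.

    ``predict`` accepts the full training-feature matrix layout and
    projects internally to the columns the underlying estimator was fit
    on, so callers never need to subset by hand.
    """

    method: str
    hyperparameters: dict
    selected_features: list[str]
    importances: dict
    fit_r2: float
    feature_names: list[str]
    _estimator: object = None
    _col_idx: np.ndarray = None
    _fallback_value: float = None  # intercept-only prediction (GLM null case)

    @property
    def n_features(self) -> int:
        return len(self.selected_features)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._estimator is None:
            return np.full(X.shape[0], self._fallback_value)
        Xs = X[:, self._col_idx] if self._col_idx is not None else X
        return np.asarray(self._estimator.predict(Xs)).ravel()


# --------------------------------------------------------------------------
# Estimator factory and default tuning grids


def _make_estimator(name: str, params: dict, seed: int, options: dict):
    if name in ("LM", "GLM"):
        return LinearRegression()
    if name == "PLS":
        return PLSRegression(n_components=params["ncomp"], scale=False)
    if name == "LASSO":
        return Lasso(alpha=params["alpha"], max_iter=50_000)
    if name == "ENET":
        return ElasticNet(alpha=params["alpha"], l1_ratio=params["l1_ratio"], max_iter=50_000)
    if name == "SVRM":
        return SVR(kernel="rbf", C=params["cost"], gamma=params["gamma"])
    if name == "NN":
        return MLPRegressor(
            hidden_layer_sizes=(params["size"],),
            alpha=params["decay"],
            solver="lbfgs",
            max_iter=2000,
            random_state=seed % (2**31),
        )
    if name == "RF":
        return RandomForestRegressor(
            n_estimators=options.get("n_estimators", 500),
            max_features=params["mtry"],
            random_state=seed % (2**31),
            n_jobs=1,
        )
    raise RegressorError(f"no estimator for {name!r}")


def _lasso_alpha_grid(X, y, n_values: int = 10) -> np.ndarray:
    """Log grid spanning [alpha_max·1e-4, alpha_max] for L1 paths.

    alpha_max is the smallest penalty that zeroes every coefficient for the
    lasso with intercept: max |X_cᵀ(y − ȳ)| / n.
    """
    n = len(y)
    Xc = X - X.mean(axis=0)
    alpha_max = float(np.max(np.abs(Xc.T @ (y - y.mean()))) / n)
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.logspace(np.log10(alpha_max * 1e-4), np.log10(alpha_max), n_values)


def _median_heuristic_gamma(X, seed: int = 0) -> float:
    """RBF width from the median pairwise squared distance (subsampled)."""
    rng = np.random.default_rng(seed % (2**31))
    n = X.shape[0]
    sub = X if n <= 200 else X[rng.choice(n, 200, replace=False)]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = float(np.median(d2[np.triu_indices_from(d2, 1)]))
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med)


def default_grid(name: str, X, y, seed: int = 0) -> list[dict]:
    """The method's default hyperparameter grid, built from the data."""
    n, p = X.shape
    if name in ("LM", "GLM"):
        return [{}]
    if name == "PLS":
        kmax = max(1, min(p, 10, n - 1))
        return [{"ncomp": k} for k in range(1, kmax + 1)]
    if name == "LASSO":
        return [{"alpha": float(a)} for a in _lasso_alpha_grid(X, y)]
    if name == "ENET":
        alphas = _lasso_alpha_grid(X, y)
        mixes = np.round(np.arange(0.1, 1.01, 0.1), 2)
        return [{"alpha": float(a), "l1_ratio": float(m)} for m in mixes for a in alphas]
    if name == "SVRM":
        g = _median_heuristic_gamma(X, seed)
        costs = 2.0 ** np.arange(-2, 8)
        return [
            {"cost": float(c), "gamma": float(gm)}
            for c in costs
            for gm in (g / 2, g, 2 * g)
        ]
    if name == "NN":
        return [
            {"size": s, "decay": d}
            for s in (1, 3, 5, 7)
            for d in (0.0, 0.001, 0.01, 0.1)
        ]
    if name == "RF":
        mtries = sorted({max(1, p // 3), max(1, int(np.sqrt(p))), p})
        return [{"mtry": m} for m in mtries]
    raise RegressorError(f"no default grid for {name!r}")


# --------------------------------------------------------------------------
# Stepwise AIC (the GLM method's feature selection)


def _ols_rss(X, y, cols) -> float:
    """Residual sum of squares of an intercept OLS on the given columns."""
    n = len(y)
    if cols:
        A = np.column_stack([np.ones(n), X[:, cols]])
    else:
        A = np.ones((n, 1))
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid)


def _aic(X, y, cols) -> float:
    """AIC = n·ln(RSS/n) + 2(k+1) for an intercept OLS model with k features."""
    n = len(y)
    rss = max(_ols_rss(X, y, cols), 1e-300)
    return n * np.log(rss / n) + 2 * (len(cols) + 1)


def _drop_aliased(X, cols):
    """Greedily keep columns that increase the design rank (full-rank start)."""
    kept = []
    for c in cols:
        trial = kept + [c]
        A = np.column_stack([np.ones(X.shape[0]), X[:, trial]])
        if np.linalg.matrix_rank(A) == len(trial) + 1:
            kept.append(c)
    if len(kept) < len(cols):
        warnings.warn("singular design: aliased columns dropped before stepwise search")
    return kept


def stepwise_aic_select(X, y, feature_names=None, direction: str = "both") -> list[str]:
    """Bidirectional greedy AIC minimization for a linear model.

    Starts from the full model (aliased columns dropped), considers every
    single-feature addition and removal, takes the move that most decreases
    AIC, and stops when no move improves.  Deterministic; ties resolved
    toward the earlier column index.  May return an empty list (the
    intercept-only model) on pure-noise responses.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(p)]
    start = _drop_aliased(X, list(range(p)))
    if n <= len(start) + 2:  # full start infeasible: begin from the empty model
        start = []
    current = list(start)
    current_aic = _aic(X, y, current)
    pool = [j for j in range(p)]
    while True:
        best_move, best_aic = None, current_aic
        for j in current:  # drops
            cand = [c for c in current if c != j]
            a = _aic(X, y, cand)
            if a < best_aic - 1e-10:
                best_move, best_aic = cand, a
        if direction == "both":
            for j in pool:  # additions
                if j in current:
                    continue
                cand = sorted(current + [j])
                a = _aic(X, y, cand)
                if a < best_aic - 1e-10:
                    best_move, best_aic = cand, a
        if best_move is None:
            break
        current, current_aic = best_move, best_aic
    return [feature_names[j] for j in sorted(current)]


# --------------------------------------------------------------------------
# Recursive feature elimination (RF-RFE, SVM-RFE)


def _rfe_ranker(base: str, seed: int, options: dict):
    if base == "RF":
        return RandomForestRegressor(
            n_estimators=options.get("n_estimators", 500),
            random_state=seed % (2**31),
            n_jobs=1,
        )
    return SVR(kernel="linear", C=options.get("cost", 1.0))


def _rfe_importance(base: str, est) -> np.ndarray:
    if base == "RF":
        return np.asarray(est.feature_importances_, dtype=float)
    # squared components of the SVM hyperplane weight vector
    return np.asarray(est.coef_, dtype=float).ravel() ** 2


def rfe_select(
    base_method: str,
    X,
    y,
    subset_sizes,
    scheme: CVScheme,
    seed: int,
    feature_names=None,
    options: dict | None = None,
):
    """Recursive feature elimination with external cross-validation.

    Per CV resample: rank features by importance fitted on the resample's
    kept part (RF: impurity importance; SVM: squared linear-SVR weights),
    then evaluate each candidate subset size on the held-out part.  The
    size with minimal mean RMSE wins (ties toward fewer features).  The
    final feature set comes from a ranking fit on the full training
    partition at the winning size.

    Returns (best_size, selected_names, per_size_mean_rmse,
    final_estimator, winner_cv_rmse, winner_cv_r2).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    options = options or {}
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(p)]
    sizes = sorted({int(s) for s in subset_sizes})
    if any(s < 1 for s in sizes) or any(s > p for s in sizes):
        raise RegressorError("subset sizes must be within 1..p")
    base = "RF" if base_method.upper().startswith("RF") else "SVM"

    folds = make_cv_folds(np.arange(n), scheme, seed)
    rmse_by_size: dict[int, list[float]] = {s: [] for s in sizes}
    r2_by_size: dict[int, list[float]] = {s: [] for s in sizes}
    for hold, keep in iter_resamples(np.arange(n), folds):
        ranker = _rfe_ranker(base, seed, options)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ranker.fit(X[keep], y[keep])
            order = np.argsort(-_rfe_importance(base, ranker), kind="stable")
            for s in sizes:
                cols = np.sort(order[:s])
                est = _rfe_ranker(base, seed, options)
                est.fit(X[keep][:, cols], y[keep])
                pred = np.asarray(est.predict(X[hold][:, cols])).ravel()
                rmse_by_size[s].append(rmse(y[hold], pred))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r2_by_size[s].append(r_squared(y[hold], pred))
    mean_rmse = {s: float(np.mean(v)) for s, v in rmse_by_size.items()}
    best_size = min(sizes, key=lambda s: (mean_rmse[s], s))

    ranker = _rfe_ranker(base, seed, options)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ranker.fit(X, y)
        order = np.argsort(-_rfe_importance(base, ranker), kind="stable")
        cols = np.sort(order[:best_size])
        final = _rfe_ranker(base, seed, options)
        final.fit(X[:, cols], y)
    selected = [feature_names[j] for j in cols]
    return (
        best_size,
        selected,
        mean_rmse,
        (final, cols),
        rmse_by_size[best_size],
        r2_by_size[best_size],
    )


# --------------------------------------------------------------------------
# Importances


def _importances(name, est, X, y, feature_names, seed) -> dict:
    if name in ("LM", "GLM", "LASSO", "ENET"):
        coefs = np.abs(np.asarray(est.coef_, dtype=float).ravel())
        return dict(zip(feature_names, coefs.tolist()))
    if name == "PLS":
        coefs = np.abs(np.asarray(est.coef_, dtype=float).ravel())
        return dict(zip(feature_names, coefs.tolist()))
    if name == "RF":
        return dict(zip(feature_names, est.feature_importances_.tolist()))
    # kernel SVR and NN have no native importance; seeded permutation importance
    from sklearn.inspection import permutation_importance

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = permutation_importance(
            est, X, y, n_repeats=3, random_state=seed % (2**31), scoring="r2"
        )
    return dict(zip(feature_names, res.importances_mean.tolist()))


# --------------------------------------------------------------------------
# The tuning loop


def _fit_with_restarts(name, params, seed, options, X, y, max_restarts=3):
    """Fit an estimator, restarting stochastic methods up to 3 times."""
    for k in range(max_restarts):
        est = _make_estimator(name, params, seed + k, options)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X, y)
            return est
        except Exception:  # noqa: BLE001 — non-convergence handled by restart
            if k == max_restarts - 1:
                raise
    raise RuntimeError("unreachable")


def tune_and_fit(
    spec: MethodSpec,
    X,
    y,
    scheme: CVScheme,
    seed: int = 0,
    feature_names=None,
) -> tuple[FittedModel, CVMetrics]:
    """Grid search by minimum mean CV RMSE, then refit on the full partition.

    For each grid point the mean RMSE over all held-out resamples is
    computed; the minimizing point is refit on the whole training
    partition.  Per-resample metrics of the winning point are returned for
    the statistics record.  Grid points that fail to fit are skipped with
    a warning and never reported as best.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(p)]
    if scheme.kind not in spec.cv_schemes_allowed:
        raise RegressorError(f"{spec.name} does not allow CV scheme {scheme.kind!r}")
    if np.std(y) == 0:
        raise RegressorError("degenerate response: zero variance")

    if spec.name in ("RF-RFE", "SVM-RFE"):
        return _tune_rfe(spec, X, y, scheme, seed, feature_names)
    if spec.name == "GLM":
        return _tune_glm(spec, X, y, scheme, seed, feature_names)

    grid = spec.tuning_grid if spec.tuning_grid is not None else default_grid(
        spec.name, X, y, seed
    )
    folds = make_cv_folds(np.arange(n), scheme, seed)
    resamples = list(iter_resamples(np.arange(n), folds))

    results = []  # (mean_rmse, grid index, params, per-resample metrics)
    for gi, params in enumerate(grid):
        rmses, r2s = [], []
        pooled_obs, pooled_pred = [], []
        failed = False
        for hold, keep in resamples:
            try:
                est = _fit_with_restarts(spec.name, params, seed, spec.options, X[keep], y[keep])
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"{spec.name} grid point {params} failed to fit: {exc}")
                failed = True
                break
            pred = np.asarray(est.predict(X[hold])).ravel()
            if scheme.kind == "loo":
                pooled_obs.extend(y[hold])
                pooled_pred.extend(pred)
            else:
                rmses.append(rmse(y[hold], pred))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r2s.append(r_squared(y[hold], pred))
        if failed:
            continue
        if scheme.kind == "loo":
            score = rmse(np.array(pooled_obs), np.array(pooled_pred))
            metrics = CVMetrics(
                kind="loo",
                per_resample_rmse=[],
                per_resample_r2=[],
                pooled_obs=np.array(pooled_obs),
                pooled_pred=np.array(pooled_pred),
            )
        else:
            score = float(np.mean(rmses))
            metrics = CVMetrics(kind="repeated_kfold", per_resample_rmse=rmses, per_resample_r2=r2s)
        results.append((score, gi, params, metrics))
    if not results:
        raise RegressorError(f"{spec.name}: every grid point failed to fit")
    _, _, best_params, best_metrics = min(results, key=lambda t: (t[0], t[1]))

    est = _fit_with_restarts(spec.name, best_params, seed, spec.options, X, y)
    if spec.name in ("LASSO", "ENET"):
        coefs = np.asarray(est.coef_, dtype=float).ravel()
        sel = [feature_names[j] for j in range(p) if abs(coefs[j]) > 1e-12]
        if not sel:  # fully shrunk: keep the largest-|coef| slot for the contract
            sel = [feature_names[int(np.argmax(np.abs(coefs)))]]
    else:
        sel = list(feature_names)
    model = FittedModel(
        method=spec.name,
        hyperparameters=dict(best_params),
        selected_features=sel,
        importances=_importances(spec.name, est, X, y, feature_names, seed),
        fit_r2=r_squared_fit(y, np.asarray(est.predict(X)).ravel()),
        feature_names=list(feature_names),
        _estimator=est,
        _col_idx=None,
    )
    return model, best_metrics


def _tune_glm(spec, X, y, scheme, seed, feature_names):
    """Gaussian linear model with stepwise-AIC selection, CV-refit per resample."""
    n = X.shape[0]
    folds = make_cv_folds(np.arange(n), scheme, seed)
    rmses, r2s = [], []
    pooled_obs, pooled_pred = [], []
    for hold, keep in iter_resamples(np.arange(n), folds):
        sel = stepwise_aic_select(X[keep], y[keep], feature_names)
        cols = [feature_names.index(s) for s in sel]
        if cols:
            est = LinearRegression().fit(X[keep][:, cols], y[keep])
            pred = est.predict(X[hold][:, cols])
        else:
            pred = np.full(len(hold), float(y[keep].mean()))
        if scheme.kind == "loo":
            pooled_obs.extend(y[hold])
            pooled_pred.extend(pred)
        else:
            rmses.append(rmse(y[hold], pred))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2s.append(r_squared(y[hold], pred))
    if scheme.kind == "loo":
        metrics = CVMetrics(
            kind="loo",
            per_resample_rmse=[],
            per_resample_r2=[],
            pooled_obs=np.array(pooled_obs),
            pooled_pred=np.array(pooled_pred),
        )
    else:
        metrics = CVMetrics(kind="repeated_kfold", per_resample_rmse=rmses, per_resample_r2=r2s)

    sel = stepwise_aic_select(X, y, feature_names)
    cols = np.array([feature_names.index(s) for s in sel], dtype=int)
    if len(cols):
        est = LinearRegression().fit(X[:, cols], y)
        fit_r2 = r_squared_fit(y, est.predict(X[:, cols]))
        imp = _importances("GLM", est, X[:, cols], y, sel, seed)
        model = FittedModel(
            method="GLM",
            hyperparameters={},
            selected_features=sel,
            importances=imp,
            fit_r2=fit_r2,
            feature_names=list(feature_names),
            _estimator=est,
            _col_idx=cols,
        )
    else:  # pure-noise null case: intercept-only model, 0 features recorded
        model = FittedModel(
            method="GLM",
            hyperparameters={},
            selected_features=[],
            importances={},
            fit_r2=0.0,
            feature_names=list(feature_names),
            _estimator=None,
            _fallback_value=float(y.mean()),
        )
    return model, metrics


#: RFE methods use their own (cheaper) internal CV, as configured here.
RFE_CV = {"SVM-RFE": CVScheme("repeated_kfold", folds=3, repeats=1),
          "RF-RFE": CVScheme("repeated_kfold", folds=5, repeats=1)}


def _tune_rfe(spec, X, y, scheme, seed, feature_names):
    p = X.shape[1]
    sizes = spec.options.get("subset_sizes")
    if sizes is None:
        # p, then roughly halving down to 2, plus 1..4 for small p
        sizes = sorted({p} | {max(1, p // k) for k in (2, 4)} | set(range(1, min(p, 4) + 1)))
    rfe_scheme = RFE_CV[spec.name]
    best_size, sel, per_size, (final, cols), cv_rmse, cv_r2 = rfe_select(
        "RF" if spec.name == "RF-RFE" else "SVM",
        X,
        y,
        sizes,
        rfe_scheme,
        seed,
        feature_names,
        spec.options,
    )
    base = "RF" if spec.name == "RF-RFE" else "SVM"
    if base == "RF":
        imp = dict(zip(sel, final.feature_importances_.tolist()))
    else:
        imp = dict(zip(sel, (np.asarray(final.coef_).ravel() ** 2).tolist()))
    model = FittedModel(
        method=spec.name,
        hyperparameters={"subset_size": best_size, "per_size_mean_rmse": per_size},
        selected_features=sel,
        importances=imp,
        fit_r2=r_squared_fit(y, np.asarray(final.predict(X[:, cols])).ravel()),
        feature_names=list(feature_names),
        _estimator=final,
        _col_idx=cols,
    )
    metrics = CVMetrics(kind="repeated_kfold", per_resample_rmse=cv_rmse, per_resample_r2=cv_r2)
    return model, metrics
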