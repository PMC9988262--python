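"""Gaussian-process age prediction from harmonized MRI features.

Unimodal models are GP regressions with a rational-quadratic kernel
(a scale mixture of squared-exponential kernels), a constant prior mean and
internally standardized features, predicting chronological age. The noise
hyperparameter σ is tuned over [1e-4, 10·SD(age)]; the remaining kernel
hyperparameters (signal variance, length scale, mixture exponent α) maximize
the log marginal likelihood at the selected σ.

The multimodal model stacks the two unimodal models: a second-level GP takes
the out-of-fold first-level age predictions as its only features. A shuffled-
FC permutation null quantifies whether the stacking gain over the structural
model exceeds what adding uninformative features would produce.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, RationalQuadratic

from .tables import FeatureTable, ModelPerformance, performance_from_predictions

SIGMA_LOWER = 1e-4
SIGMA_UPPER_FACTOR = 10.0      # upper bound = 10 · SD(age)
SIGMA_SEARCH_BUDGET = 100
SIGMA_SEARCH_INNER_FOLDS = 5


def rq_kernel(x, y, s2: float, length_scale: float, alpha: float) -> np.ndarray:
    """Closed-form rational-quadratic covariance.

    k(x, x') = s² · (1 + ‖x−x'‖² / (2αℓ²))^(−α). Accepts vectors or
    row-stacked matrices; returns the cross-covariance matrix (or scalar for
    two single points).
    """
    if s2 <= 0 or length_scale <= 0 or alpha <= 0:
        raise ValueError("s2, length_scale and alpha must all be > 0")
    xa = np.atleast_2d(np.asarray(x, dtype=float))
    ya = np.atleast_2d(np.asarray(y, dtype=float))
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite kernel inputs")
    d2 = _sqdist(xa, ya)
    k = s2 * (1.0 + d2 / (2.0 * alpha * length_scale**2)) ** (-alpha)
    return float(k[0, 0]) if k.size == 1 else k


def _sqdist(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances via BLAS matmul."""
    xx = np.einsum("ij,ij->i", x, x)
    yy = np.einsum("ij,ij->i", y, y)
    d2 = xx[:, None] + yy[None, :] - 2.0 * (x @ y.T)
    return np.maximum(d2, 0.0)


# Small strong-reference cache so repeated marginal-likelihood evaluations on
# the same training matrix reuse its O(n²p) distance matrix.
_SQDIST_CACHE: list[tuple[np.ndarray, np.ndarray]] = []
_SQDIST_CACHE_MAX = 4


def _sqdist_cached(x: np.ndarray) -> np.ndarray:
    for arr, d2 in _SQDIST_CACHE:
        if arr is x:
            return d2
    d2 = _sqdist(x, x)
    _SQDIST_CACHE.append((x, d2))
    if len(_SQDIST_CACHE) > _SQDIST_CACHE_MAX:
        _SQDIST_CACHE.pop(0)
    return d2


class FastRationalQuadratic(RationalQuadratic):
    """Rational-quadratic kernel with matmul-based distances.

    Mathematically identical to sklearn's ``RationalQuadratic`` (asserted in
    the test suite, values and gradients); only the distance computation is
    replaced and cached, which dominates run time for wide feature tables.
    """

    def __call__(self, X, Y=None, eval_gradient=False):
        X = np.asarray(X, dtype=float)
        if Y is None:
            d2 = _sqdist_cached(X)
        else:
            if eval_gradient:
                raise ValueError("Gradient can only be evaluated when Y is None.")
            d2 = _sqdist(X, np.asarray(Y, dtype=float))
        ls, al = self.length_scale, self.alpha
        base = 1.0 + d2 / (2.0 * al * ls**2)
        k = base ** (-al)
        if not eval_gradient:
            return k
        grads = []
        if not self.hyperparameter_alpha.fixed:
            # d k / d log α
            grads.append(k * (-al * np.log(base) + d2 / (2.0 * ls**2 * base)))
        if not self.hyperparameter_length_scale.fixed:
            # d k / d log ℓ
            grads.append(k * d2 / (ls**2 * base))
        if grads:
            return k, np.dstack(grads)
        return k, np.empty((*k.shape, 0))


@dataclass
class AgePredModel:
    """A fitted unimodal GP age model.

    Stores the kernel hyperparameters, noise σ, feature and target
    standardization, and the dual coefficients sufficient for prediction.
    """

    modality: str
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    y_mean: float               # constant prior-mean (basis) value, years
    y_sd: float
    sigma: float                # observation-noise SD, years
    signal_variance: float      # s², in standardized-target units
    length_scale: float
    alpha_mix: float            # rational-quadratic mixture exponent
    training_ids: list[str]
    x_train: np.ndarray = field(repr=False)
    dual_coef: np.ndarray = field(repr=False)
    log_marginal_likelihood: float = float("nan")
    sigma_search: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("signal_variance", "length_scale", "alpha_mix", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def _standardize(self, table) -> np.ndarray:
        if isinstance(table, FeatureTable):
            if table.feature_names != self.feature_names:
                raise ValueError("feature names do not match the fitted model")
            x = table.values
        else:
            x = np.asarray(table, dtype=float)
        return (x - self.feature_means) / self.feature_sds

    def predict(self, table) -> np.ndarray:
        """Posterior-mean predicted ages (years)."""
        xs = self._standardize(table)
        k_cross = rq_kernel(xs, self.x_train, self.signal_variance,
                            self.length_scale, self.alpha_mix)
        k_cross = np.atleast_2d(k_cross)
        return self.y_mean + self.y_sd * (k_cross @ self.dual_coef)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "modality": self.modality, "feature_names": self.feature_names,
            "y_mean": self.y_mean, "y_sd": self.y_sd, "sigma": self.sigma,
            "signal_variance": self.signal_variance,
            "length_scale": self.length_scale, "alpha_mix": self.alpha_mix,
            "training_ids": self.training_ids,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "sigma_search": self.sigma_search,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "x_train": self.x_train.tolist(),
            "dual_coef": self.dual_coef.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "AgePredModel":
        doc = json.loads(Path(path).read_text())
        for key in ("feature_means", "feature_sds", "x_train", "dual_coef"):
            doc[key] = np.asarray(doc[key], dtype=float)
        return cls(**doc)


def _standardize_features(x: np.ndarray, standardize: bool = True):
    if not standardize:
        # identity transform; used when features share meaningful units
        # (e.g. first-level age predictions in years)
        return x.copy(), np.zeros(x.shape[1]), np.ones(x.shape[1])
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    return (x - means) / sds, means, sds


def _table_values(table) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(table, FeatureTable):
        return table.values, table.feature_names, [str(i) for i in table.ids]
    x = np.asarray(table, dtype=float)
    return x, [f"f{i}" for i in range(x.shape[1])], [str(i) for i in range(len(x))]


def sigma_search_bounds(ages) -> tuple[float, float]:
    sd = float(np.std(np.asarray(ages, dtype=float), ddof=0))
    return SIGMA_LOWER, SIGMA_UPPER_FACTOR * sd


def _sigma_candidates(ages, strategy: str, budget: int, seed: int) -> np.ndarray:
    lo, hi = sigma_search_bounds(ages)
    if strategy == "grid":
        return np.logspace(np.log10(lo), np.log10(hi), budget)
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), budget)))
    raise ValueError(f"unknown sigma search strategy: {strategy!r}")


def _heuristic_kernel_params(xs: np.ndarray, seed: int = 0):
    """Median-distance length scale; unit signal variance (standardized y)."""
    n = xs.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(n, 256), replace=False)
    d2 = _sqdist(xs[idx], xs[idx])
    med = np.sqrt(np.median(d2[np.triu_indices(idx.size, k=1)]))
    return 1.0, float(max(med, 1e-3)), 1.0


def search_sigma(table, ages, strategy: str = "grid",
                 budget: int = SIGMA_SEARCH_BUDGET, seed: int = 0,
                 folds: int = SIGMA_SEARCH_INNER_FOLDS) -> dict:
    """Select the GP noise SD σ by inner cross-validation.

    Kernel hyperparameters are held at median-distance heuristics during the
    search; each fold's train-kernel eigendecomposition is reused across all
    σ candidates, so the full budget costs a handful of O(n³) factorizations.
    Returns a dict with the selected σ, the candidate grid and their CV RMSE.
    """
    x, _, _ = _table_values(table)
    y = np.asarray(ages, dtype=float)
    xs, *_ = _standardize_features(x)
    ys = (y - y.mean()) / y.std(ddof=0)
    s2, ls, al = _heuristic_kernel_params(xs, seed)
    sigmas = _sigma_candidates(ages, strategy, budget, seed)
    sig2_std = (sigmas / y.std(ddof=0)) ** 2    # noise in standardized-y units

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y, folds, rng)
    sse = np.zeros(sigmas.size)
    for f in range(folds):
        te = fold_of == f
        tr = ~te
        k_tr = rq_kernel(xs[tr], xs[tr], s2, ls, al)
        k_te = rq_kernel(xs[te], xs[tr], s2, ls, al)
        w, v = eigh(k_tr)
        vty = v.T @ ys[tr]
        k_te_v = k_te @ v
        for i, s2n in enumerate(sig2_std):
            pred = k_te_v @ (vty / (w + s2n))
            sse[i] += np.sum((ys[te] - pred) ** 2)
    rmse = np.sqrt(sse / y.size) * y.std(ddof=0)
    best = int(np.argmin(rmse))
    return {"sigma": float(sigmas[best]), "strategy": strategy,
            "candidates": sigmas.tolist(), "cv_rmse": rmse.tolist(),
            "budget": int(budget)}


def fit_gpr(table, ages, sigma="search", *, modality: str = "",
            sigma_strategy: str = "grid", sigma_budget: int = SIGMA_SEARCH_BUDGET,
            seed: int = 0, optimize_kernel: bool = True, standardize: bool = True,
            kernel_params: tuple[float, float, float] | None = None) -> AgePredModel:
    """Fit a rational-quadratic GP age model.

    ``sigma`` is either a positive noise SD in years or ``"search"`` (inner-CV
    selection over [1e-4, 10·SD(age)], default seeded log-grid with 100
    evaluations). With ``optimize_kernel`` the signal variance, length scale
    and mixture exponent maximize the log marginal likelihood at fixed σ;
    ``kernel_params`` pins them instead (used by permutation nulls).
    """
    x, feature_names, ids = _table_values(table)
    y = np.asarray(ages, dtype=float)
    if len(y) != x.shape[0]:
        raise ValueError("ages and feature rows misaligned")
    if len(y) < 3:
        raise ValueError("need at least 3 participants to fit an age model")
    if isinstance(sigma, str) and len(y) < 20:
        raise ValueError("sigma search needs at least 20 participants; "
                         "pass a numeric sigma for smaller samples")
    if np.std(y) == 0:
        raise ValueError("ages are constant; nothing to regress")

    search_info: dict = {}
    if isinstance(sigma, str):
        if sigma != "search":
            raise ValueError(f"sigma must be a float or 'search', got {sigma!r}")
        search_info = search_sigma(table, y, sigma_strategy, sigma_budget, seed)
        sigma_val = search_info["sigma"]
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be > 0")

    xs, means, sds = _standardize_features(x, standardize)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=0))
    ys = (y - y_mean) / y_sd
    noise = (sigma_val / y_sd) ** 2

    if kernel_params is not None:
        s2, ls, al = kernel_params
        kernel = ConstantKernel(s2, "fixed") * FastRationalQuadratic(
            length_scale=ls, alpha=al,
            length_scale_bounds="fixed", alpha_bounds="fixed")
        opt = None
    else:
        s2_0, ls_0, al_0 = _heuristic_kernel_params(xs, seed)
        kernel = ConstantKernel(s2_0, (1e-3, 1e3)) * FastRationalQuadratic(
            length_scale=ls_0, alpha=al_0,
            length_scale_bounds=(ls_0 * 1e-2, ls_0 * 1e2),
            alpha_bounds=(1e-3, 1e3))
        opt = "fmin_l_bfgs_b" if optimize_kernel else None

    gpr = GaussianProcessRegressor(kernel=kernel, alpha=noise, optimizer=opt,
                                   normalize_y=False, random_state=seed)
    with warnings.catch_warnings():
        # the mixture exponent α often runs to its upper bound, where the
        # rational-quadratic kernel degenerates to a squared exponential;
        # the likelihood is flat there and the fit is fine
        warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(xs, ys)
    k_const, k_rq = gpr.kernel_.k1, gpr.kernel_.k2
    return AgePredModel(
        modality=modality, feature_names=feature_names,
        feature_means=means, feature_sds=sds, y_mean=y_mean, y_sd=y_sd,
        sigma=sigma_val, signal_variance=float(k_const.constant_value),
        length_scale=float(k_rq.length_scale), alpha_mix=float(k_rq.alpha),
        training_ids=ids, x_train=xs, dual_coef=np.asarray(gpr.alpha_).ravel(),
        log_marginal_likelihood=float(gpr.log_marginal_likelihood_value_),
        sigma_search=search_info)


def _stratified_folds(y: np.ndarray, folds: int, rng) -> np.ndarray:
    """Fold assignment stratified by age decile (round-robin within strata)."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    deciles = ranks * 10 // n
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for d in range(10):
        idx = np.flatnonzero(deciles == d)
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size
    return fold_of


def cv_predict(table, ages, folds: int = 10, seed: int = 0, *,
               sigma="search", modality: str = "",
               sigma_strategy: str = "grid",
               sigma_budget: int = SIGMA_SEARCH_BUDGET,
               optimize_kernel: bool = True, standardize: bool = True,
               kernel_params: tuple[float, float, float] | None = None):
    """Out-of-fold age predictions with merged performance metrics.

    σ (when searched) is selected once on the full sample and held fixed
    across folds, mirroring a tune-once-apply-everywhere protocol; kernel
    hyperparameters are refit within each training fold. Metrics (r, R² as
    1−SS_res/SS_tot, MAE, RMSE) are computed once on the merged out-of-fold
    vector, not averaged over folds.

    Returns ``(predictions, ModelPerformance, fold_assignments)``.
    """
    x, _, _ = _table_values(table)
    y = np.asarray(ages, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(y) < folds:
        raise ValueError("more folds than participants")

    if isinstance(sigma, str):
        info = search_sigma(table, y, sigma_strategy, sigma_budget, seed)
        sigma_val = info["sigma"]
    else:
        sigma_val = float(sigma)

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y, folds, rng)
    counts = np.bincount(fold_of, minlength=folds)
    if (counts < 2).any():
        raise ValueError("a fold has fewer than 2 participants")

    preds = np.empty(len(y))
    for f in range(folds):
        te = fold_of == f
        model = fit_gpr(x[~te], y[~te], sigma=sigma_val, seed=seed,
                        optimize_kernel=optimize_kernel, standardize=standardize,
                        kernel_params=kernel_params, modality=modality)
        preds[te] = model.predict(x[te])
    perf = performance_from_predictions(y, preds, context="train-CV")
    return preds, perf, fold_of


@dataclass
class StackedModel:
    """Two first-level unimodal GP models plus a second-level GP on their
    predictions. First-level inputs to the second level are out-of-fold
    during training (leakage-safe stacking); at apply time the fully trained
    first-level models produce them."""

    fc_model: AgePredModel
    s_model: AgePredModel
    second_level: AgePredModel
    oof_first_level: pd.DataFrame = field(repr=False)
    performance: dict = field(default_factory=dict)

    def predict(self, fc_table, s_table) -> np.ndarray:
        pred_fc = self.fc_model.predict(fc_table)
        pred_s = self.s_model.predict(s_table)
        return self.second_level.predict(np.column_stack([pred_fc, pred_s]))


def fit_stacked(fc_table, s_table, ages, seed: int = 0, folds: int = 10, *,
                sigma="search", sigma_strategy: str = "grid",
                sigma_budget: int = SIGMA_SEARCH_BUDGET) -> StackedModel:
    """Train the stacked multimodal (S+FC) model.

    Requires identical participant sets (same order) in both tables. The
    second-level model is trained on out-of-fold first-level predictions;
    its own CV performance is evaluated with the same fold assignment.
    """
    if isinstance(fc_table, FeatureTable) and isinstance(s_table, FeatureTable):
        if not fc_table.ids.equals(s_table.ids):
            raise ValueError("FC and structural tables cover different participants")
        ids = [str(i) for i in fc_table.ids]
    else:
        if len(fc_table) != len(s_table):
            raise ValueError("FC and structural tables cover different participants")
        ids = [str(i) for i in range(len(ages))]
    y = np.asarray(ages, dtype=float)

    oof_fc, perf_fc, _ = cv_predict(fc_table, y, folds, seed, sigma=sigma,
                                    modality="FC", sigma_strategy=sigma_strategy,
                                    sigma_budget=sigma_budget)
    oof_s, perf_s, _ = cv_predict(s_table, y, folds, seed, sigma=sigma,
                                  modality="S", sigma_strategy=sigma_strategy,
                                  sigma_budget=sigma_budget)
    z = np.column_stack([oof_fc, oof_s])
    oof_stacked, perf_stacked, _ = cv_predict(z, y, folds, seed, sigma=sigma,
                                              modality="S+FC", standardize=False,
                                              sigma_strategy=sigma_strategy,
                                              sigma_budget=sigma_budget)

    fc_model = fit_gpr(fc_table, y, sigma=sigma, modality="FC", seed=seed,
                       sigma_strategy=sigma_strategy, sigma_budget=sigma_budget)
    s_model = fit_gpr(s_table, y, sigma=sigma, modality="S", seed=seed,
                      sigma_strategy=sigma_strategy, sigma_budget=sigma_budget)
    second = fit_gpr(z, y, sigma=sigma, modality="S+FC", seed=seed,
                     standardize=False,
                     sigma_strategy=sigma_strategy, sigma_budget=sigma_budget)
    oof = pd.DataFrame({"pred_fc": oof_fc, "pred_s": oof_s,
                        "pred_stacked": oof_stacked, "age": y},
                       index=pd.Index(ids, name="id"))
    return StackedModel(fc_model=fc_model, s_model=s_model, second_level=second,
                        oof_first_level=oof,
                        performance={"FC": perf_fc, "S": perf_s,
                                     "S+FC": perf_stacked})


def permute_columns(x: np.ndarray, rng) -> np.ndarray:
    """Independently permute each column across rows.

    Destroys row-wise (participant-level) structure while preserving every
    column's multiset of values exactly.
    """
    x = np.asarray(x)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        out[:, j] = x[rng.permutation(n), j]
    return out


@dataclass
class ShuffledFcNull:
    observed_r2: float
    null_r2: np.ndarray
    p_value: float
    n_resamples: int


def shuffled_fc_null(s_table, fc_table, ages, n_resamples: int = 1000,
                     seed: int = 0, folds: int = 10, *,
                     force: bool = False,
                     stacked: StackedModel | None = None) -> ShuffledFcNull:
    """Permutation null for the stacking gain.

    Each resample permutes every FC feature column independently across
    participants (destroying participant-level FC signal while preserving
    each feature's marginal distribution), retrains the FC model on the
    shuffled features, stacks it with the unchanged structural model, and
    records the stacked CV R². The add-one convention gives
    p = (1 + #{null R² ≥ observed R²}) / (n_resamples + 1).

    Kernel hyperparameters and σ for the resample fits are pinned to the
    observed models' values; only the GP dual coefficients are refit, which
    is what the permuted features can change.
    """
    if n_resamples < 100 and not force:
        raise ValueError("n_resamples < 100 gives a coarse null; pass force=True "
                         "to override")
    y = np.asarray(ages, dtype=float)
    if stacked is None:
        stacked = fit_stacked(fc_table, s_table, y, seed=seed, folds=folds)
    observed = stacked.performance["S+FC"].r2
    oof_s = stacked.oof_first_level["pred_s"].to_numpy()

    fc_x, _, _ = _table_values(fc_table)
    fc_kp = (stacked.fc_model.signal_variance, stacked.fc_model.length_scale,
             stacked.fc_model.alpha_mix)
    sec_kp = (stacked.second_level.signal_variance,
              stacked.second_level.length_scale, stacked.second_level.alpha_mix)
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y, folds, np.random.default_rng(seed))

    null_r2 = np.empty(n_resamples)
    for b in range(n_resamples):
        perm = permute_columns(fc_x, rng)
        oof_fc = _oof_fixed(perm, y, fold_of, folds, stacked.fc_model.sigma, fc_kp)
        z = np.column_stack([oof_fc, oof_s])
        oof_st = _oof_fixed(z, y, fold_of, folds, stacked.second_level.sigma,
                            sec_kp, standardize=False)
        null_r2[b] = performance_from_predictions(y, oof_st).r2
    p = (1 + int(np.sum(null_r2 >= observed))) / (n_resamples + 1)
    return ShuffledFcNull(observed_r2=observed, null_r2=null_r2, p_value=p,
                          n_resamples=n_resamples)


def _oof_fixed(x, y, fold_of, folds, sigma, kernel_params,
               standardize: bool = True) -> np.ndarray:
    """Out-of-fold GP posterior means with pinned hyperparameters."""
    s2, ls, al = kernel_params
    xs, *_ = _standardize_features(np.asarray(x, dtype=float), standardize)
    y_mean, y_sd = y.mean(), y.std(ddof=0)
    ys = (y - y_mean) / y_sd
    noise = (sigma / y_sd) ** 2
    k_full = rq_kernel(xs, xs, s2, ls, al)
    preds = np.empty(len(y))
    for f in range(folds):
        te = fold_of == f
        tr = ~te
        k_tr = k_full[np.ix_(tr, tr)].copy()
        k_tr[np.diag_indices_from(k_tr)] += noise
        c = cho_factor(k_tr, lower=True)
        dual = cho_solve(c, ys[tr])
        preds[te] = y_mean + y_sd * (k_full[np.ix_(te, tr)] @ dual)
    return preds
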