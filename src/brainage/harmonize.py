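"""Parametric empirical-Bayes batch harmonization (ComBat).

Location-scale model for multi-site feature tables (Johnson's parametric
ComBat): each feature is standardized against a covariate fit and pooled
variance; per-batch location (γ) and scale (δ²) effects are estimated and
shrunk toward batch-level normal / inverse-gamma priors by an iterative
empirical-Bayes update; the adjusted data keep the covariate-explained
structure (age signal by default) while removing batch differences.

The fitted model is serializable and can transform new tables from the same
batches (fit-on-train / apply-to-test protocols).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable

EB_TOL = 1e-6
EB_MAX_ITER = 500


@dataclass
class HarmonizationModel:
    """Everything needed to harmonize tables from known batches."""

    feature_names: list[str]
    batch_labels: list[str]
    covariate_names: list[str]
    grand_mean: np.ndarray          # per feature (batch-size-weighted intercept)
    beta_cov: np.ndarray            # covariates × features
    var_pooled: np.ndarray          # per feature
    gamma_star: np.ndarray          # batches × features (EB-shrunk location)
    delta_star_sq: np.ndarray       # batches × features (EB-shrunk scale²)
    gamma_bar: np.ndarray           # per batch: prior mean of γ
    tau_sq: np.ndarray              # per batch: prior variance of γ
    a_prior: np.ndarray             # per batch: inverse-gamma shape
    b_prior: np.ndarray             # per batch: inverse-gamma scale
    n_iter: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    passthrough: bool = False       # single-batch degenerate fit

    def __post_init__(self) -> None:
        if not self.passthrough and np.any(self.delta_star_sq <= 0):
            raise ValueError("EB-shrunk batch scales must be positive")

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_names": self.feature_names,
            "batch_labels": self.batch_labels,
            "covariate_names": self.covariate_names,
            "passthrough": self.passthrough,
            "n_iter": np.asarray(self.n_iter).tolist(),
        }
        for key in ("grand_mean", "beta_cov", "var_pooled", "gamma_star",
                    "delta_star_sq", "gamma_bar", "tau_sq", "a_prior", "b_prior"):
            doc[key] = np.asarray(getattr(self, key)).tolist()
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        doc = json.loads(Path(path).read_text())
        arrays = {k: np.asarray(doc[k], dtype=float)
                  for k in ("grand_mean", "beta_cov", "var_pooled", "gamma_star",
                            "delta_star_sq", "gamma_bar", "tau_sq",
                            "a_prior", "b_prior")}
        return cls(feature_names=doc["feature_names"],
                   batch_labels=doc["batch_labels"],
                   covariate_names=doc["covariate_names"],
                   n_iter=np.asarray(doc["n_iter"], dtype=int),
                   passthrough=doc["passthrough"], **arrays)


def _as_covariate_matrix(covariates, index) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((len(index), 0)), []
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    cov = covariates.loc[index]
    return cov.to_numpy(dtype=float), list(cov.columns)


def _fit_batch(z_batch: np.ndarray, gamma_hat, delta_hat_sq,
               gamma_bar, tau_sq, a, b):
    """Iterate the parametric EB updates for one batch to convergence.

    γ* is the precision-weighted compromise between the raw batch mean and
    the batch-level prior mean; δ*² is the inverse-gamma posterior mode given
    the residual sum of squares around the current γ*.
    """
    n_k = z_batch.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta_hat_sq.copy()
    for it in range(1, EB_MAX_ITER + 1):
        g_new = (n_k * tau_sq * gamma_hat + d_old * gamma_bar) / (n_k * tau_sq + d_old)
        ss = np.sum((z_batch - g_new[None, :]) ** 2, axis=0)
        d_new = (b + 0.5 * ss) / (n_k / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-30)),
                     np.max(np.abs(d_new - d_old) / d_old))
        g_old, d_old = g_new, d_new
        if change < EB_TOL:
            break
    return g_old, d_old, it


def fit_combat(table: FeatureTable, covariates=None) -> HarmonizationModel:
    """Fit parametric ComBat on one feature table.

    Parameters
    ----------
    table
        FeatureTable whose ``batch`` series defines the site/scanner batches.
    covariates
        Optional DataFrame/Series (indexed like the table) of biological
        covariates to preserve, e.g. age. The design must be full rank.
    """
    x = table.values                       # n × p
    n, p = x.shape
    batches = pd.Categorical(table.batch)
    levels = list(batches.categories)
    counts = pd.Series(table.batch).value_counts()

    cov, cov_names = _as_covariate_matrix(covariates, table.ids)
    if len(levels) < 2:
        warnings.warn("single batch: ComBat degenerates to a pass-through",
                      stacklevel=2)
        return HarmonizationModel(
            feature_names=table.feature_names, batch_labels=levels,
            covariate_names=cov_names, grand_mean=np.zeros(p),
            beta_cov=np.zeros((cov.shape[1], p)), var_pooled=np.ones(p),
            gamma_star=np.zeros((1, p)), delta_star_sq=np.ones((1, p)),
            gamma_bar=np.zeros(1), tau_sq=np.ones(1),
            a_prior=np.ones(1), b_prior=np.ones(1), passthrough=True)
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"each batch needs >= 3 participants; too small: {small}")

    onehot = np.zeros((n, len(levels)))
    onehot[np.arange(n), batches.codes] = 1.0
    design = np.hstack([onehot, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design: covariates confounded with batch "
                         "or collinear")

    beta_hat, *_ = np.linalg.lstsq(design, x, rcond=None)
    batch_coef = beta_hat[: len(levels)]            # K × p
    beta_cov = beta_hat[len(levels):]               # q × p
    weights = counts.reindex(levels).to_numpy(dtype=float) / n
    grand_mean = weights @ batch_coef               # p

    resid = x - design @ beta_hat
    var_pooled = np.mean(resid**2, axis=0)
    if np.any(var_pooled <= 0):
        j = int(np.flatnonzero(var_pooled <= 0)[0])
        raise ValueError(f"feature {table.feature_names[j]} has zero pooled variance")

    stand_mean = grand_mean[None, :] + cov @ beta_cov
    z = (x - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_star = np.empty((len(levels), p))
    delta_star_sq = np.empty((len(levels), p))
    gamma_bar = np.empty(len(levels))
    tau_sq = np.empty(len(levels))
    a_prior = np.empty(len(levels))
    b_prior = np.empty(len(levels))
    n_iter = np.empty(len(levels), dtype=int)

    for k, lev in enumerate(levels):
        zk = z[batches.codes == k]
        gamma_hat = zk.mean(axis=0)
        delta_hat_sq = zk.var(axis=0, ddof=1)
        gamma_bar[k] = gamma_hat.mean()
        tau_sq[k] = gamma_hat.var(ddof=1)
        m = delta_hat_sq.mean()
        s2 = delta_hat_sq.var(ddof=1)
        a_prior[k] = (2 * s2 + m**2) / s2
        b_prior[k] = (m * s2 + m**3) / s2
        gamma_star[k], delta_star_sq[k], n_iter[k] = _fit_batch(
            zk, gamma_hat, delta_hat_sq, gamma_bar[k], tau_sq[k],
            a_prior[k], b_prior[k])

    return HarmonizationModel(
        feature_names=table.feature_names, batch_labels=levels,
        covariate_names=cov_names, grand_mean=grand_mean, beta_cov=beta_cov,
        var_pooled=var_pooled, gamma_star=gamma_star,
        delta_star_sq=delta_star_sq, gamma_bar=gamma_bar, tau_sq=tau_sq,
        a_prior=a_prior, b_prior=b_prior, n_iter=n_iter)


def apply_combat(model: HarmonizationModel, table: FeatureTable,
                 covariates=None) -> FeatureTable:
    """Harmonize a table with a fitted model; unseen batches are rejected."""
    if table.feature_names != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    if model.passthrough:
        return FeatureTable(table.data.copy(), table.batch.copy(), table.modality)
    unseen = set(table.batch) - set(model.batch_labels)
    if unseen:
        raise ValueError(f"batches not seen during fit: {sorted(unseen)}")
    cov, cov_names = _as_covariate_matrix(covariates, table.ids)
    if cov_names != model.covariate_names:
        raise ValueError("covariate columns do not match the fitted model")

    x = table.values
    codes = pd.Categorical(table.batch, categories=model.batch_labels).codes
    stand_mean = model.grand_mean[None, :] + cov @ model.beta_cov
    z = (x - stand_mean) / np.sqrt(model.var_pooled)[None, :]
    z_adj = (z - model.gamma_star[codes]) / np.sqrt(model.delta_star_sq)[codes]
    x_adj = z_adj * np.sqrt(model.var_pooled)[None, :] + stand_mean
    return FeatureTable(pd.DataFrame(x_adj, index=table.ids,
                                     columns=model.feature_names),
                        table.batch.copy(), table.modality)


def harmonize_table(table: FeatureTable, covariates=None
                    ) -> tuple[FeatureTable, HarmonizationModel]:
    """Convenience fit-then-apply on one table."""
    model = fit_combat(table, covariates)
    return apply_combat(model, table, covariates), model
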