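"""Parametric empirical-Bayes (ComBat-style) batch harmonisation.

Removes slice-thickness batch effects from radiomics feature tables while
preserving the biological covariates (age, gender). The location-scale model
is

    y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

with per-batch location gamma and scale delta shrunk towards parametric
priors (normal for gamma, inverse-gamma for delta^2) by empirical Bayes.
Strict train-then-apply semantics: the fitted :class:`ComBatModel` is
serialisable and applying it never updates its parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

BATCH_EDGES_MM = (2.0, 4.0)


class HarmonisationError(ValueError):
    pass


def assign_batch(slice_thickness_mm: float) -> int:
    """Slice-thickness batch: 1 if <2 mm, 2 if [2,4) mm, 3 if >=4 mm."""
    t = float(slice_thickness_mm)
    if not np.isfinite(t) or t <= 0:
        raise HarmonisationError(f"slice thickness must be positive, got {t}")
    if t < BATCH_EDGES_MM[0]:
        return 1
    if t < BATCH_EDGES_MM[1]:
        return 2
    return 3


@dataclass
class ComBatModel:
    """Fitted harmonisation parameters for train-then-apply use."""

    feature_ids: list[str]
    batch_levels: list
    covariate_names: list[str]
    alpha: np.ndarray          # (p,) grand intercept per feature
    beta: np.ndarray           # (c, p) covariate coefficients
    sigma: np.ndarray          # (p,) pooled residual scale
    gamma_star: np.ndarray     # (b, p) EB batch locations
    delta_star: np.ndarray     # (b, p) EB batch scales (>0)
    priors: dict = field(default_factory=dict)
    version: str = "1"

    def to_json(self, path=None) -> str:
        obj = {
            "version": self.version,
            "feature_ids": self.feature_ids,
            "batch_levels": [int(b) if isinstance(b, (int, np.integer)) else b
                             for b in self.batch_levels],
            "covariate_names": self.covariate_names,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "priors": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.priors.items()},
        }
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ComBatModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            feature_ids=obj["feature_ids"],
            batch_levels=obj["batch_levels"],
            covariate_names=obj["covariate_names"],
            alpha=np.asarray(obj["alpha"]),
            beta=np.asarray(obj["beta"]),
            sigma=np.asarray(obj["sigma"]),
            gamma_star=np.asarray(obj["gamma_star"]),
            delta_star=np.asarray(obj["delta_star"]),
            priors=obj.get("priors", {}),
            version=obj.get("version", "1"),
        )


def _design(batches: np.ndarray, levels, cov: np.ndarray):
    onehot = np.column_stack([(batches == b).astype(float) for b in levels])
    return np.column_stack([onehot, cov]) if cov.size else onehot


def _validate(table: pd.DataFrame, batches, covariates):
    y = table.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise HarmonisationError("feature table contains non-finite values")
    batches = np.asarray(batches)
    if len(batches) != len(table):
        raise HarmonisationError("batch vector length mismatch")
    cov = (covariates.to_numpy(dtype=np.float64)
           if covariates is not None and covariates.shape[1] > 0
           else np.empty((len(table), 0)))
    return y, batches, cov


def combat_fit(
    table: pd.DataFrame,
    batches,
    covariates: pd.DataFrame | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
):
    """Fit the harmonisation model on training data and return
    ``(ComBatModel, harmonised training table)``.

    Each batch needs at least 2 subjects; zero-variance features are rejected
    by name.
    """
    y, batches, cov = _validate(table, batches, covariates)
    n, p = y.shape
    var0 = y.var(axis=0)
    zero = [c for c, v in zip(table.columns, var0) if v <= 1e-12]
    if zero:
        raise HarmonisationError(f"zero-variance features cannot be harmonised: {zero[:10]}")
    levels = sorted(pd.unique(batches).tolist())
    counts = {b: int((batches == b).sum()) for b in levels}
    singles = [b for b, c in counts.items() if c < 2]
    if singles:
        raise HarmonisationError(f"batches with fewer than 2 subjects: {singles}")

    X = _design(batches, levels, cov)
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    nb = len(levels)
    batch_int = bhat[:nb]                      # per-batch intercepts
    beta = bhat[nb:]                           # covariate coefficients
    w = np.array([counts[b] / n for b in levels])
    alpha = w @ batch_int                      # grand intercept
    fitted = X @ bhat
    sigma2 = ((y - fitted) ** 2).mean(axis=0)
    sigma = np.sqrt(sigma2)
    if np.any(sigma <= 1e-12):
        bad = [c for c, s in zip(table.columns, sigma) if s <= 1e-12]
        raise HarmonisationError(f"features with zero residual variance: {bad[:10]}")

    z = (y - alpha[None, :] - cov @ beta) / sigma[None, :]

    gamma_hat = np.zeros((nb, p))
    delta2_hat = np.zeros((nb, p))
    for i, b in enumerate(levels):
        zb = z[batches == b]
        gamma_hat[i] = zb.mean(axis=0)
        # population variance, consistent with the population-scaled sigma;
        # a single batch then has delta-hat exactly 1 and harmonisation is
        # the identity
        delta2_hat[i] = zb.var(axis=0, ddof=0)

    # method-of-moments parametric priors per batch
    gamma_bar = gamma_hat.mean(axis=1)
    tau2_bar = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    # degenerate scale prior (all features share one batch variance): the
    # inverse-gamma prior collapses to a point mass at m
    degen = s2 <= 1e-12 * np.maximum(m**2, 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(degen, np.inf, (2.0 * s2 + m**2) / s2)
        theta = np.where(degen, np.inf, (m * s2 + m**3) / s2)

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for i, b in enumerate(levels):
        zb = z[batches == b]
        ni = counts[b]
        g = gamma_hat[i].copy()
        d2 = delta2_hat[i].copy()
        for _ in range(max_iter):
            g_new = (ni * tau2_bar[i] * gamma_hat[i] + d2 * gamma_bar[i]) / (
                ni * tau2_bar[i] + d2
            )
            ssq = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            if degen[i]:
                d2_new = np.full(p, m[i])
            else:
                d2_new = (theta[i] + 0.5 * ssq) / (ni / 2.0 + lam[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g) / (np.abs(g) + 1e-8)),
                np.max(np.abs(d2_new - d2) / (np.abs(d2) + 1e-8)),
            )
            g, d2 = g_new, d2_new
            if change < tol:
                break
        gamma_star[i] = g
        delta2_star[i] = d2

    model = ComBatModel(
        feature_ids=list(table.columns),
        batch_levels=levels,
        covariate_names=list(covariates.columns) if covariates is not None else [],
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta2_star),
        priors={
            "gamma_bar": gamma_bar, "tau2_bar": tau2_bar,
            "lambda": lam, "theta": theta,
        },
    )
    return model, combat_apply(model, table, batches, covariates)


def combat_apply(
    model: ComBatModel,
    table: pd.DataFrame,
    batches,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Harmonise new data with stored training parameters only."""
    if list(table.columns) != model.feature_ids:
        table = table[model.feature_ids]
    y, batches, cov = _validate(table, batches, covariates)
    unseen = sorted(set(pd.unique(batches)) - set(model.batch_levels))
    if unseen:
        raise HarmonisationError(f"unseen batch levels: {unseen}")
    if cov.shape[1] != len(model.covariate_names):
        raise HarmonisationError(
            f"expected covariates {model.covariate_names}, got {cov.shape[1]} columns"
        )
    cov_part = cov @ model.beta
    z = (y - model.alpha[None, :] - cov_part) / model.sigma[None, :]
    out = np.empty_like(y)
    for i, b in enumerate(model.batch_levels):
        sel = batches == b
        if not sel.any():
            continue
        out[sel] = (
            (z[sel] - model.gamma_star[i][None, :])
            * (model.sigma / model.delta_star[i])[None, :]
            + model.alpha[None, :]
            + cov_part[sel]
        )
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def batch_mixing_score(table: pd.DataFrame, batches) -> float:
    """Mean silhouette coefficient of batch labels on standardised features.

    Near 0 (or negative) means batches are well mixed; values towards 1 mean
    the batches form separate clusters in feature space.
    """
    batches = np.asarray(batches)
    if len(pd.unique(batches)) < 2:
        raise HarmonisationError("batch mixing score needs at least 2 batches")
    x = table.to_numpy(dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd <= 1e-12] = 1.0
    return float(silhouette_score((x - mu) / sd, batches))
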