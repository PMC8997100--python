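"""Empirical-Bayes ComBat harmonization of feature tables across batches.

ComBat models each feature g measured in batch i, sample j as

    y_gij = alpha_g + gamma_ig + delta_ig * eps_gij

with additive (location) batch effects gamma and multiplicative (scale)
effects delta.  Features are first standardized by the grand mean and
pooled variance; batch means and variances of the standardized data are
then shrunk toward common priors across features — a normal prior for the
location effects and an inverse-gamma prior for the scale effects, with
hyperparameters estimated by moments ("parametric" mode) or by weighting
with the empirical density of the other features' estimates
("non-parametric" mode).  The adjusted data subtract gamma*, divide by
delta* and restore the original scale.

In the pairwise reproducibility pipeline the two scans of a pair form the
two batches (160 VOI samples each); phantom cartridges are identical across
scans, so no covariates are preserved.  Zero-variance features cannot be
standardized and are passed through unadjusted (and reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable

__all__ = ["CombatModel", "fit_combat", "apply_combat", "harmonize_pair"]


@dataclass
class CombatModel:
    """Fitted ComBat parameters for a set of batches.

    ``gamma_star``/``delta2_star`` are the EB-shrunken per-batch additive
    effects and squared multiplicative effects on the standardized scale;
    ``alpha``/``var_pooled`` restore the original scale.
    """

    feature_names: list[str]
    batch_labels: list[str]
    alpha: np.ndarray  # (n_features,) grand mean
    var_pooled: np.ndarray  # (n_features,) pooled residual variance
    gamma_star: np.ndarray  # (n_batches, n_features)
    delta2_star: np.ndarray  # (n_batches, n_features), > 0
    gamma_bar: np.ndarray  # (n_batches,) location-prior means
    tau2_bar: np.ndarray  # (n_batches,) location-prior variances
    a_prior: np.ndarray  # (n_batches,) inverse-gamma shape
    b_prior: np.ndarray  # (n_batches,) inverse-gamma scale
    constant_features: list[str] = field(default_factory=list)
    parametric: bool = True

    def to_json_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "batch_labels": self.batch_labels,
            "alpha": self.alpha.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "gamma_bar": self.gamma_bar.tolist(),
            "tau2_bar": self.tau2_bar.tolist(),
            "a_prior": self.a_prior.tolist(),
            "b_prior": self.b_prior.tolist(),
            "constant_features": self.constant_features,
            "parametric": self.parametric,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CombatModel":
        return cls(
            feature_names=list(d["feature_names"]),
            batch_labels=list(d["batch_labels"]),
            alpha=np.asarray(d["alpha"], dtype=float),
            var_pooled=np.asarray(d["var_pooled"], dtype=float),
            gamma_star=np.asarray(d["gamma_star"], dtype=float),
            delta2_star=np.asarray(d["delta2_star"], dtype=float),
            gamma_bar=np.asarray(d["gamma_bar"], dtype=float),
            tau2_bar=np.asarray(d["tau2_bar"], dtype=float),
            a_prior=np.asarray(d["a_prior"], dtype=float),
            b_prior=np.asarray(d["b_prior"], dtype=float),
            constant_features=list(d["constant_features"]),
            parametric=bool(d["parametric"]),
        )


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (2.0 * s2 + m * m) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _eb_iterate(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    *,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled posterior-mode updates for one batch (parametric EB)."""
    n = z.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sum2 = ((z - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def _eb_nonparametric(
    z: np.ndarray, gamma_hat: np.ndarray, delta2_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo EB: integrate each feature's posterior over the other
    features' empirical (gamma_hat, delta2_hat) values."""
    n, G = z.shape
    gamma_star = np.empty(G)
    delta2_star = np.empty(G)
    for g in range(G):
        others = np.arange(G) != g
        g_cand = gamma_hat[others]
        d_cand = delta2_hat[others]
        resid2 = ((z[:, g][:, None] - g_cand[None, :]) ** 2).sum(axis=0)
        log_lh = -0.5 * n * np.log(2.0 * np.pi * d_cand) - resid2 / (2.0 * d_cand)
        w = np.exp(log_lh - log_lh.max())
        w_sum = w.sum()
        gamma_star[g] = (g_cand * w).sum() / w_sum
        delta2_star[g] = (d_cand * w).sum() / w_sum
    return gamma_star, delta2_star


def fit_combat(
    tables: Sequence[FeatureTable],
    batch_labels: Sequence[str] | None = None,
    *,
    parametric: bool = True,
) -> CombatModel:
    """Fit ComBat across the given feature tables (one batch per table by
    default, i.e. per scan).

    Requires >= 2 batches with >= 2 samples each.  Zero-variance features
    (no residual variance after removing batch means) are excluded from the
    model and later passed through unadjusted.
    """
    tables = list(tables)
    if batch_labels is None:
        batch_labels = [t.scan_id for t in tables]
    batch_labels = [str(b) for b in batch_labels]
    if len(set(batch_labels)) < 2:
        raise ValueError(
            "ComBat needs at least 2 batches; a single batch has nothing to harmonize"
        )
    cols = list(tables[0].frame.columns)
    for t in tables[1:]:
        if list(t.frame.columns) != cols:
            raise ValueError("all tables must share the same feature registry")

    # stack samples, grouped by batch
    uniq = sorted(set(batch_labels))
    mats = {u: [] for u in uniq}
    for t, b in zip(tables, batch_labels):
        mats[b].append(t.values)
    X_parts = [np.vstack(mats[u]) for u in uniq]
    for u, part in zip(uniq, X_parts):
        if part.shape[0] < 2:
            raise ValueError(f"batch {u!r} has fewer than 2 samples")
    X = np.vstack(X_parts)  # (N, G)
    n_per = np.array([p.shape[0] for p in X_parts])
    N = X.shape[0]
    starts = np.concatenate([[0], np.cumsum(n_per)])
    batch_slices = [slice(starts[i], starts[i + 1]) for i in range(len(uniq))]

    batch_means = np.vstack([X[s].mean(axis=0) for s in batch_slices])  # (B, G)
    alpha = (n_per[:, None] * batch_means).sum(axis=0) / N
    resid = X.copy()
    for s, bm in zip(batch_slices, batch_means):
        resid[s] -= bm
    var_pooled = (resid ** 2).sum(axis=0) / N

    keep = var_pooled > 0
    constant_features = [c for c, k in zip(cols, keep) if not k]
    Z = np.full_like(X, np.nan)
    Z[:, keep] = (X[:, keep] - alpha[keep]) / np.sqrt(var_pooled[keep])

    B, Gk = len(uniq), int(keep.sum())
    gamma_star = np.zeros((B, len(cols)))
    delta2_star = np.ones((B, len(cols)))
    gamma_bar = np.zeros(B)
    tau2_bar = np.zeros(B)
    a_prior = np.zeros(B)
    b_prior = np.zeros(B)
    for i, s in enumerate(batch_slices):
        z = Z[s][:, keep]
        g_hat = z.mean(axis=0)
        d_hat = z.var(axis=0, ddof=1)
        gamma_bar[i] = g_hat.mean()
        tau2_bar[i] = g_hat.var(ddof=1) if Gk > 1 else 1.0
        if Gk > 1 and d_hat.var(ddof=1) > 0:
            a_prior[i] = _aprior(d_hat)
            b_prior[i] = _bprior(d_hat)
        else:  # degenerate prior: no shrinkage possible
            a_prior[i] = 2.0
            b_prior[i] = max(d_hat.mean(), 1e-12)
        if parametric:
            g_star, d2_star = _eb_iterate(
                z, g_hat, d_hat, gamma_bar[i], tau2_bar[i], a_prior[i], b_prior[i]
            )
        else:
            g_star, d2_star = _eb_nonparametric(z, g_hat, d_hat)
        gamma_star[i, keep] = g_star
        delta2_star[i, keep] = np.maximum(d2_star, 1e-12)

    return CombatModel(
        feature_names=cols,
        batch_labels=uniq,
        alpha=alpha,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2_bar=tau2_bar,
        a_prior=a_prior,
        b_prior=b_prior,
        constant_features=constant_features,
        parametric=parametric,
    )


def apply_combat(
    model: CombatModel,
    tables: Sequence[FeatureTable],
    batch_labels: Sequence[str] | None = None,
) -> list[FeatureTable]:
    """Adjust feature tables with a fitted model: y* = sqrt(var) (z - gamma*) / delta* + alpha.

    Batches must have been seen at fit time.  Output tables keep the shape,
    VOI index and feature order of the input; constant features pass
    through unchanged.
    """
    tables = list(tables)
    if batch_labels is None:
        batch_labels = [t.scan_id for t in tables]
    batch_labels = [str(b) for b in batch_labels]
    unknown = sorted(set(batch_labels) - set(model.batch_labels))
    if unknown:
        raise ValueError(f"batch label(s) {unknown} were not seen at fit time")

    keep = model.var_pooled > 0
    sd = np.sqrt(model.var_pooled[keep])
    out = []
    for t, b in zip(tables, batch_labels):
        if list(t.frame.columns) != model.feature_names:
            raise ValueError("table registry does not match the fitted model")
        i = model.batch_labels.index(b)
        X = t.values.copy()
        z = (X[:, keep] - model.alpha[keep]) / sd
        z_adj = (z - model.gamma_star[i, keep]) / np.sqrt(model.delta2_star[i, keep])
        X[:, keep] = z_adj * sd + model.alpha[keep]
        frame = pd.DataFrame(X, index=t.frame.index, columns=t.frame.columns)
        out.append(FeatureTable(scan_id=t.scan_id, arm=t.arm, frame=frame))
    return out


def harmonize_pair(
    ta: FeatureTable, tb: FeatureTable, *, parametric: bool = True
) -> tuple[FeatureTable, FeatureTable]:
    """Two-batch ComBat for one scan pair (the per-pair scenario default)."""
    model = fit_combat([ta, tb], parametric=parametric)
    out = apply_combat(model, [ta, tb])
    return out[0], out[1]
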