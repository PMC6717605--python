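"""Regularized linear discriminant analysis with a shared covariance.

Both classes are modelled as Gaussians with class-specific means and one
pooled covariance, regularized by blending toward a scaled identity:

    Sigma_reg = (1 - lambda) * Sigma_pooled + lambda * nu * I,

where ``nu`` is the mean of the pooled diagonal variances.  Posterior
class probabilities are exact Gaussian posteriors under this model; the
decision function is linear in the features.  Features are z-scored with
training-split statistics stored on the model, so applying the model to a
held-out set leaks no information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .core import ConfigError, DataError

__all__ = ["RldaModel", "fit_rlda", "predict_proba", "select_shrinkage"]


@dataclass
class RldaModel:
    classes: np.ndarray  # sorted class labels, impaired class last
    means: np.ndarray  # (2, p) class means in standardized space
    covariance: np.ndarray  # (p, p) regularized pooled covariance
    shrinkage: float
    priors: np.ndarray  # (2,)
    feature_mean: np.ndarray  # (p,) standardization offset
    feature_scale: np.ndarray  # (p,) standardization scale
    feature_names: tuple = ()
    _chol: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not np.allclose(self.priors.sum(), 1.0):
            raise DataError("class priors must sum to 1")
        if self._chol is None:
            self._chol = linalg.cholesky(self.covariance, lower=True)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_json(self) -> str:
        payload = {
            "classes": self.classes.tolist(),
            "means": self.means.tolist(),
            "covariance": self.covariance.tolist(),
            "shrinkage": self.shrinkage,
            "priors": self.priors.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "feature_names": list(self.feature_names),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "RldaModel":
        d = json.loads(s)
        return cls(
            classes=np.array(d["classes"]),
            means=np.array(d["means"]),
            covariance=np.array(d["covariance"]),
            shrinkage=float(d["shrinkage"]),
            priors=np.array(d["priors"]),
            feature_mean=np.array(d["feature_mean"]),
            feature_scale=np.array(d["feature_scale"]),
            feature_names=tuple(d["feature_names"]),
        )


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
    return mean, scale


def _pooled_covariance(X: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    n, p = X.shape
    scatter = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        d = Xc - Xc.mean(axis=0)
        scatter += d.T @ d
    dof = max(n - len(classes), 1)
    return scatter / dof


def select_shrinkage(features: np.ndarray, labels: np.ndarray) -> float:
    """Analytic (Ledoit-Wolf) shrinkage toward the scaled identity.

    Computed on class-centered training data so the between-class mean
    shift does not inflate the estimate.  Behaves as expected at the
    extremes: ~0 for well-conditioned n >> p data, bounded away from 0
    when p > n.
    """
    from sklearn.covariance import ledoit_wolf

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    centered = np.empty_like(X)
    for c in np.unique(y):
        mask = y == c
        centered[mask] = X[mask] - X[mask].mean(axis=0)
    _, lam = ledoit_wolf(centered, assume_centered=True)
    return float(np.clip(lam, 0.0, 1.0))


def fit_rlda(
    features: np.ndarray,
    labels: Sequence[int],
    shrinkage: Optional[float] = None,
    priors: Optional[Sequence[float]] = None,
    feature_names: Sequence[str] = (),
) -> RldaModel:
    """Fit the shared-covariance regularized discriminant.

    ``shrinkage=None`` selects lambda analytically; explicit values must lie
    in [0, 1].  ``priors=None`` uses training-class frequencies.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise DataError("features must be a 2-D array")
    if len(X) != len(y):
        raise DataError("features/labels length mismatch")
    if not np.isfinite(X).all():
        raise DataError("non-finite feature values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DataError(f"need exactly 2 classes in training data, got {len(classes)}")
    if counts.min() < 2:
        raise DataError("need at least 2 examples per class")
    if shrinkage is not None and not (0.0 <= shrinkage <= 1.0):
        raise ConfigError(f"shrinkage must be in [0, 1], got {shrinkage}")

    mean, scale = _standardize_params(X)
    Z = (X - mean) / scale
    if shrinkage is None:
        shrinkage = select_shrinkage(Z, y)
    sigma = _pooled_covariance(Z, y, classes)
    p = Z.shape[1]
    nu = float(np.trace(sigma)) / p
    if nu <= 0.0:
        nu = 1.0  # all features constant; fall back to identity metric
    sigma_reg = (1.0 - shrinkage) * sigma + shrinkage * nu * np.eye(p)
    # guarantee positive definiteness even at shrinkage ~ 0 on rank-deficient data
    jitter = 1e-10 * nu
    sigma_reg = sigma_reg + jitter * np.eye(p)

    means = np.vstack([Z[y == c].mean(axis=0) for c in classes])
    if priors is None:
        pri = counts / counts.sum()
    else:
        pri = np.asarray(priors, dtype=np.float64)
        if len(pri) != 2 or (pri <= 0).any():
            raise ConfigError("priors must be 2 positive values")
        pri = pri / pri.sum()
    return RldaModel(
        classes=classes,
        means=means,
        covariance=sigma_reg,
        shrinkage=float(shrinkage),
        priors=pri,
        feature_mean=mean,
        feature_scale=scale,
        feature_names=tuple(feature_names),
    )


def decision_scores(model: RldaModel, features: np.ndarray) -> np.ndarray:
    """Log posterior-odds of the impaired (last) class vs the other."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise DataError(
            f"feature dimension mismatch: model has {model.n_features}, "
            f"input has {X.shape[1]}"
        )
    Z = (X - model.feature_mean) / model.feature_scale
    L = model._chol
    # delta_k(x) = x' S^-1 mu_k - 0.5 mu_k' S^-1 mu_k + log pi_k
    W = linalg.cho_solve((L, True), model.means.T)  # (p, 2)
    lin = Z @ W
    const = -0.5 * np.sum(model.means.T * W, axis=0) + np.log(model.priors)
    scores = lin + const
    return scores[:, 1] - scores[:, 0]


def predict_proba(model: RldaModel, features: np.ndarray) -> np.ndarray:
    """Posterior probability of the impaired (larger-label) class per row."""
    s = decision_scores(model, features)
    # numerically stable logistic
    out = np.empty_like(s)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    e = np.exp(s[~pos])
    out[~pos] = e / (1.0 + e)
    return out
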