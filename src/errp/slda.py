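"""Shrinkage linear discriminant analysis.

Classical two-class LDA becomes ill-conditioned when the feature dimension
approaches the trial count, the usual regime for waveform ERP features.  The
pooled within-class covariance S is therefore shrunk toward a scaled
identity,

    Sigma(gamma) = (1 - gamma) S + gamma (trace(S)/d) I,

with the shrinkage intensity gamma chosen by the analytic Ledoit-Wolf
formula (clipped to [0, 1]); it can also be fixed manually.  With balanced
classes the decision rule is the sign of w.x - b with w = Sigma^{-1}
(mu_errp - mu_nonerrp) and b placing the boundary midway between the
projected class means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ERRP, NONERRP

__all__ = ["SLDAModel", "estimate_shrunk_covariance", "train_slda", "predict_slda"]


@dataclass
class SLDAModel:
    mean_nonerrp: np.ndarray
    mean_errp: np.ndarray
    covariance: np.ndarray  # pooled, shrunk
    gamma: float
    w: np.ndarray  # projection Sigma^{-1} (mu1 - mu0)
    bias: float
    priors: tuple[float, float] = (0.5, 0.5)

    @property
    def n_features(self) -> int:
        return len(self.w)


def ledoit_wolf_gamma(Xc: np.ndarray) -> float:
    """Analytic optimal shrinkage intensity toward (trace(S)/d) I.

    ``Xc`` holds centered samples (rows).  Returns the estimated intensity
    clipped to [0, 1]; 0 when S is already proportional to the identity.
    """
    n, d = Xc.shape
    S = (Xc.T @ Xc) / n
    mu = np.trace(S) / d
    # squared Frobenius distance of S from its shrinkage target, per dimension
    delta2 = float(np.sum((S - mu * np.eye(d)) ** 2)) / d
    if delta2 <= 0:
        return 0.0
    # E ||x x^T - S||^2_F / n estimates the variance of the sample covariance
    sq_norms = np.einsum("ij,ij->i", Xc, Xc)
    beta2 = (float(np.sum(sq_norms**2)) / n - float(np.sum(S * S))) / (n * d)
    beta2 = min(max(beta2, 0.0), delta2)
    return beta2 / delta2


def estimate_shrunk_covariance(Xc: np.ndarray, gamma: float | None = None) -> tuple[np.ndarray, float]:
    """Shrunk covariance of centered samples and the intensity used.

    With ``gamma`` None the Ledoit-Wolf estimate is used.  The result is
    symmetric positive definite whenever gamma > 0, even for d > n.
    """
    Xc = np.asarray(Xc, dtype=float)
    if Xc.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    n, d = Xc.shape
    S = (Xc.T @ Xc) / n
    if gamma is None:
        gamma = ledoit_wolf_gamma(Xc)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    mu = np.trace(S) / d
    sigma = (1.0 - gamma) * S + gamma * mu * np.eye(d)
    return sigma, float(gamma)


def train_slda(X: np.ndarray, labels: np.ndarray, gamma: float | None = None) -> SLDAModel:
    """Fit shrinkage LDA on trials x features with ErrP/NonErrP labels.

    The covariance is pooled over both classes after removing each class's
    own mean.  Equal priors are assumed (classes are balanced upstream).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    idx0 = labels == NONERRP
    idx1 = labels == ERRP
    if not idx0.any() or not idx1.any():
        raise ValueError("both classes must be present")
    mu0 = X[idx0].mean(axis=0)
    mu1 = X[idx1].mean(axis=0)
    Xc = np.vstack([X[idx0] - mu0, X[idx1] - mu1])
    sigma, g = estimate_shrunk_covariance(Xc, gamma)
    try:
        w = np.linalg.solve(sigma, mu1 - mu0)
    except np.linalg.LinAlgError:
        # the analytic intensity can be exactly 0 in degenerate tiny-sample
        # cases (e.g. two samples per class center to +/- pairs), leaving a
        # singular covariance; fall back to the minimum-norm solution
        w = np.linalg.pinv(sigma, hermitian=True) @ (mu1 - mu0)
    bias = float(w @ (mu0 + mu1) / 2.0)
    return SLDAModel(mu0, mu1, sigma, g, w, bias)


def predict_slda(model: SLDAModel, X: np.ndarray) -> np.ndarray:
    """Labels by the sign of w.x - b; exact ties break to NonErrP."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected n x {model.n_features} features, got {X.shape}")
    score = X @ model.w - model.bias
    return np.where(score > 0, ERRP, NONERRP)
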