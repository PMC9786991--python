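"""Fisher linear discriminant analysis for the permutation engine.

Implements the classical multi-class DFA: discriminant vectors solve the
generalized eigenproblem ``Sb v = lambda Sw v`` (between- vs pooled
within-class scatter) and are scaled so discriminant scores have unit pooled
within-class variance.  Classification uses the Gaussian discriminant score
with the pooled covariance.  Determinism matters inside permutation loops,
so sign conventions and tie-breaks are fixed: each discriminant vector has
its largest-magnitude entry positive, and classification ties go to the
first class label in sorted order.

A singular pooled covariance (possible on degenerate permutation resamples)
triggers a small ridge (eps = 1e-8 * trace/d) with a warning instead of an
abort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import SchemaError

RIDGE_EPS = 1e-8


@dataclass
class LDAModel:
    class_labels: list
    class_means: np.ndarray          # k x d
    pooled_within_cov: np.ndarray    # d x d (unbiased, df = n - k)
    discriminant_vectors: np.ndarray  # d x min(k-1, d)
    priors: np.ndarray               # k
    within_sd: np.ndarray            # d, sqrt(diag(pooled_within_cov))
    ridge_applied: bool = False

    @property
    def n_discriminants(self) -> int:
        return self.discriminant_vectors.shape[1]


def fit_lda(X: np.ndarray, labels, priors: str = "proportional") -> LDAModel:
    """Fit a Fisher LDA.

    Requires >= 2 classes with >= 2 observations each.  ``priors`` is
    ``"proportional"`` (training frequencies; the convention of the classic
    implementation this mirrors) or ``"equal"``.  Upstream balancing makes
    the two coincide in practice.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(labels) != X.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = sorted(set(labels.tolist()))
    k, (n, d) = len(classes), X.shape
    if k < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([np.sum(labels == c) for c in classes])
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 observations")

    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    Sw = np.zeros((d, d))
    for c, mu in zip(classes, means):
        Xi = X[labels == c] - mu
        Sw += Xi.T @ Xi
    Sw /= n - k

    ridge = False
    # within-class scatter must be positive definite for the eigenproblem
    if np.linalg.matrix_rank(Sw) < d or np.linalg.cond(Sw) > 1e12:
        eps = RIDGE_EPS * max(np.trace(Sw), 1.0) / d
        Sw = Sw + eps * np.eye(d)
        ridge = True
        warnings.warn("singular pooled within-class covariance; ridge applied")

    grand = (counts @ means) / n
    Sb = np.zeros((d, d))
    for cnt, mu in zip(counts, means):
        diff = (mu - grand)[:, None]
        Sb += cnt * (diff @ diff.T)
    Sb /= max(n - k, 1)

    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_df = min(k - 1, d)
    V = evecs[:, order[:n_df]]
    # scale: unit pooled within-class variance of each discriminant score
    for j in range(n_df):
        v = V[:, j]
        s = float(v @ Sw @ v)
        if s > 0:
            V[:, j] = v / np.sqrt(s)
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] *= -1

    pr = counts / n if priors == "proportional" else np.full(k, 1.0 / k)
    if priors not in ("proportional", "equal"):
        raise ValueError("priors must be 'proportional' or 'equal'")
    return LDAModel(
        class_labels=classes,
        class_means=means,
        pooled_within_cov=Sw,
        discriminant_vectors=V,
        priors=pr,
        within_sd=np.sqrt(np.diag(Sw)),
        ridge_applied=ridge,
    )


def discriminant_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Gaussian discriminant score per class: x'S⁻¹mu - mu'S⁻¹mu/2 + log prior."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.class_means.shape[1]:
        raise SchemaError(
            f"X has {X.shape[1]} features, model expects {model.class_means.shape[1]}"
        )
    Sinv_mu = np.linalg.solve(model.pooled_within_cov, model.class_means.T)  # d x k
    lin = X @ Sinv_mu
    const = -0.5 * np.einsum("kd,dk->k", model.class_means, Sinv_mu)
    return lin + const + np.log(model.priors)


def classify(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels; ties broken deterministically to the first label."""
    scores = discriminant_scores(model, X)
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum
    return np.asarray(model.class_labels, dtype=object)[idx]


def accuracy(predicted, truth) -> float:
    """Percentage of matching labels (0-100)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("length mismatch")
    if len(predicted) == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return 100.0 * float(np.mean(predicted == truth))


def standardized_coefficients(model: LDAModel) -> np.ndarray:
    """Per-variable standardized coefficients, one column per discriminant.

    Raw discriminant vectors scaled by the pooled within-class standard
    deviation of each variable, making "highest coefficient" comparisons
    invariant to the variables' units.  With two classes only DF1 exists.
    """
    return model.discriminant_vectors * model.within_sd[:, None]


def raw_coefficients(model: LDAModel) -> np.ndarray:
    return model.discriminant_vectors.copy()
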