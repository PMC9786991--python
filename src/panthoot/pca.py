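"""PCA dimension reduction with the study's two component-count heuristics.

Acoustic feature tables mix units (seconds, hertz, element counts), so the
default is standardized (correlation-matrix) PCA; covariance-matrix PCA is
available via ``standardize=False``.  Downstream discriminant analyses use
the component scores rather than raw features, with the component count
chosen by either

* ``select_components_cap`` — the smaller of (a) the number of observations
  in the smallest test-factor category and (b) the number of components
  needed to reach 90 % cumulative explained variance; or
* ``select_components_scree`` — the Cattell scree elbow, operationalised as
  the point of maximum perpendicular distance from the chord joining the
  first and last scree points (an alternative max-second-difference rule is
  available via ``method="second_diff"``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SchemaError


@dataclass
class PCAModel:
    """Fitted principal-component model.

    ``loadings`` has one orthonormal column per component; ``explained_frac``
    is the per-component fraction of total variance (non-increasing);
    ``eigenvalues`` are the variances of the scores.  The sign of each
    component is fixed so its largest-magnitude loading is positive, making
    permutation runs reproducible.
    """

    feature_names: list[str]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_frac: np.ndarray
    center: np.ndarray
    scale: np.ndarray | None
    n_selected: int
    heuristic: str = "all"
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_frac": self.explained_frac.tolist(),
            "center": self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "n_selected": self.n_selected,
            "heuristic": self.heuristic,
            "dropped_constant": self.dropped_constant,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            loadings=np.asarray(d["loadings"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            explained_frac=np.asarray(d["explained_frac"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            scale=None if d["scale"] is None else np.asarray(d["scale"], dtype=float),
            n_selected=d["n_selected"],
            heuristic=d["heuristic"],
            dropped_constant=d.get("dropped_constant", []),
        )


def fit_pca(
    X: np.ndarray,
    feature_names: list[str] | None = None,
    standardize: bool = True,
) -> PCAModel:
    """Fit PCA by eigendecomposition of the correlation (or covariance) matrix.

    Constant columns are dropped with a warning when standardizing (their
    correlation is undefined).  Missing values are a precondition error —
    complete-case filtering belongs upstream.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 observations")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite values")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]

    sd = X.std(axis=0, ddof=1)
    dropped: list[str] = []
    if standardize and np.any(sd == 0):
        dropped = [feature_names[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(f"dropping constant column(s) before standardized PCA: {dropped}")
        keep = sd > 0
        X = X[:, keep]
        feature_names = [f for f, k in zip(feature_names, keep) if k]
        sd = sd[keep]

    center = X.mean(axis=0)
    Xc = X - center
    scale = None
    if standardize:
        scale = sd
        Xc = Xc / scale
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1

    total = eigvals.sum()
    frac = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAModel(
        feature_names=list(feature_names),
        loadings=eigvecs,
        eigenvalues=eigvals,
        explained_frac=frac,
        center=center,
        scale=scale,
        n_selected=eigvecs.shape[1],
        dropped_constant=dropped,
    )


def select_components_cap(
    model: PCAModel, smallest_category_n: int, variance_target: float = 0.90
) -> int:
    """min(smallest test-factor category size, #components reaching 90 % variance)."""
    if smallest_category_n < 1:
        raise ValueError("smallest_category_n must be >= 1")
    cum = np.cumsum(model.explained_frac)
    reached = np.flatnonzero(cum >= variance_target - 1e-12)
    k90 = int(reached[0]) + 1 if len(reached) else model.n_components
    return min(smallest_category_n, k90)


def select_components_scree(model: PCAModel, method: str = "distance") -> int:
    """Cattell scree elbow on the eigenvalue profile.

    ``distance`` (default): index maximizing perpendicular distance from the
    chord joining the first and last scree points, ties broken toward fewer
    components.  ``second_diff``: index maximizing the discrete second
    difference of the scree.
    """
    m = model.n_components
    if m < 3:
        warnings.warn("scree elbow undefined for < 3 components; returning all")
        return m
    y = model.eigenvalues
    x = np.arange(1, m + 1, dtype=float)
    if method == "distance":
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        norm = np.hypot(dx, dy)
        d = np.abs(dy * x - dx * y + x[-1] * y[0] - x[0] * y[-1]) / norm
        inner = d[1:-1]
        return int(np.argmax(inner)) + 2  # +2: skip first point, 1-based index
    if method == "second_diff":
        d2 = y[:-2] - 2 * y[1:-1] + y[2:]
        return int(np.argmax(d2)) + 2
    raise ValueError(f"unknown scree method {method!r}")


def transform(model: PCAModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Project observations onto the model's components.

    Returns the score matrix truncated to ``n_components`` (default:
    ``model.n_selected``).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"X has {X.shape[1]} columns, model expects {len(model.feature_names)}"
        )
    k = model.n_selected if n_components is None else n_components
    Xc = X - model.center
    if model.scale is not None:
        Xc = Xc / model.scale
    return Xc @ model.loadings[:, :k]
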