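"""Low-dimensional views: PCA embedding with best-fit plane, and a
Fisher-discriminant plane with an orthogonalized healthy-anchor axis.

The case–control view is a 3-D PCA of the standardized variable matrix
(eigenvalues of the covariance via SVD).  The pre/post intervention view is
a 2-D plane whose horizontal axis u is the (ridge-regularized) Fisher
linear discriminant between pre- and post-intervention rows and whose
vertical axis v is the healthy-control-to-pre-intervention center vector
with its component along u removed, both normalized to unit length.
Classification accuracy on the plane is resubstitution accuracy of
thresholding the u-coordinate at the midpoint of the two class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class EmbeddingResult:
    """PCA axes, spectrum and scores."""

    components: np.ndarray  # (n_components, p), rows unit length
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    variance_explained: np.ndarray  # fractions for returned components
    scores: np.ndarray  # (n, n_components)
    group_centers: Dict[str, np.ndarray] = field(default_factory=dict)
    column_names: Optional[Sequence[str]] = None

    def to_dict(self) -> dict:
        return {
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "group_centers": {g: c.tolist() for g, c in self.group_centers.items()},
            "columns": list(self.column_names) if self.column_names is not None else None,
        }


def pca_svd(
    matrix,
    n_components: int = 3,
    labels: Optional[Sequence] = None,
) -> EmbeddingResult:
    """PCA of a complete standardized matrix via singular value decomposition.

    Columns are centered; the covariance eigenvalues are the squared
    singular values divided by (n − 1); scores are projections onto the top
    right-singular vectors; variance explained is each eigenvalue over the
    trace.  Missing entries are rejected — impute first.
    """
    columns = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing entries; impute before PCA")
    n, p = X.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} rows, got {n}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    components = Vt[:n_components]
    scores = Xc @ components.T

    centers: Dict[str, np.ndarray] = {}
    if labels is not None:
        lab = np.asarray(labels)
        for g in pd.unique(lab):
            centers[str(g)] = scores[lab == g].mean(axis=0)

    return EmbeddingResult(
        components=components,
        eigenvalues=eigenvalues,
        variance_explained=eigenvalues[:n_components] / total,
        scores=scores,
        group_centers=centers,
        column_names=columns,
    )


@dataclass
class PlaneFit:
    point: np.ndarray  # centroid, on the plane
    normal: np.ndarray  # unit normal
    basis: np.ndarray  # (2, 3) in-plane orthonormal directions
    degenerate: bool = False


def best_fit_plane(scores) -> PlaneFit:
    """Least-squares plane through 3-D points: centroid + top-2 principal span.

    The normal is the least-variance principal direction.  Collinear point
    sets (rank < 2) are flagged degenerate.
    """
    P = np.asarray(scores, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 points in 3-D")
    centroid = P.mean(axis=0)
    _, s, Vt = np.linalg.svd(P - centroid, full_matrices=False)
    degenerate = s[1] <= s[0] * 1e-12
    return PlaneFit(point=centroid, normal=Vt[2], basis=Vt[:2], degenerate=degenerate)


def fisher_direction(X, labels, ridge: Optional[float] = None) -> np.ndarray:
    """Regularized Fisher linear discriminant direction, unit length.

    w ∝ (S_w + λI)⁻¹ (m₂ − m₁) with S_w the pooled within-class scatter.
    λ defaults to 1e-3 · trace(S_w)/p, which keeps the solve well-posed when
    the variable count exceeds the per-class sample size; λ=0 requests the
    unregularized solve and raises if S_w is singular.  Sign convention: the
    second class in sorted label order projects to the larger mean.
    """
    X = np.asarray(X, dtype=float)
    lab = np.asarray(labels)
    classes = sorted(pd.unique(lab).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    X1, X2 = X[lab == classes[0]], X[lab == classes[1]]
    if len(X1) < 2 or len(X2) < 2:
        raise ValueError("each class needs at least 2 rows")
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    Sw = (X1 - m1).T @ (X1 - m1) + (X2 - m2).T @ (X2 - m2)
    p = X.shape[1]
    lam = 1e-3 * np.trace(Sw) / p if ridge is None else float(ridge)
    if lam < 0:
        raise ValueError("ridge must be >= 0")
    A = Sw + lam * np.eye(p)
    try:
        w = np.linalg.solve(A, m2 - m1)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; pass a positive ridge"
        ) from None
    if lam == 0 and np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; pass a positive ridge"
        )
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant: identical class means")
    w = w / norm
    if (m2 - m1) @ w < 0:
        w = -w
    return w


@dataclass
class FisherPlaneResult:
    """Fisher plane: axes, projections, threshold and accuracy."""

    u: np.ndarray  # horizontal unit axis (Fisher direction, pre -> post)
    v: np.ndarray  # vertical unit axis (orthogonalized healthy-anchor)
    coords_pre: np.ndarray  # (n_pre, 2)
    coords_post: np.ndarray  # (n_post, 2)
    center_healthy: np.ndarray  # (2,)
    center_pre: np.ndarray
    center_post: np.ndarray
    threshold: float
    accuracy: float
    ridge: float

    def to_dict(self) -> dict:
        return {
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "centers": {
                "healthy": self.center_healthy.tolist(),
                "pre": self.center_pre.tolist(),
                "post": self.center_post.tolist(),
            },
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "ridge": self.ridge,
        }


def classification_accuracy(scores, labels, threshold: float) -> float:
    """Fraction of rows on the correct side of the threshold.

    The class with the larger projected mean claims scores above the
    threshold.  Rows exactly at the threshold go to the class whose
    projected mean is nearer (the higher class under exact equidistance,
    deterministically).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    classes = sorted(pd.unique(lab).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    mean0, mean1 = s[lab == classes[0]].mean(), s[lab == classes[1]].mean()
    hi, lo = (classes[1], classes[0]) if mean1 >= mean0 else (classes[0], classes[1])
    hi_mean, lo_mean = max(mean0, mean1), min(mean0, mean1)
    pred = np.where(s > threshold, hi, lo)
    at = s == threshold
    if at.any():
        tie_class = hi if abs(hi_mean - threshold) <= abs(lo_mean - threshold) else lo
        pred = pred.astype(object)
        pred[at] = tie_class
    return float(np.mean(pred == lab))


def fisher_plane(
    X_pre,
    X_post,
    center_healthy,
    ridge: Optional[float] = None,
) -> FisherPlaneResult:
    """Project pre/post rows and group centers onto the Fisher plane.

    u is the Fisher direction between pre and post rows (post projects
    higher); v is the healthy-center-to-pre-center vector minus its
    projection onto u, normalized.  Classification thresholds the
    u-coordinate at the midpoint of the two projected class means;
    accuracy is resubstitution over the pre/post rows.
    """
    X_pre = np.asarray(X_pre, dtype=float)
    X_post = np.asarray(X_post, dtype=float)
    c_h = np.asarray(center_healthy, dtype=float)
    if X_pre.shape[1] != X_post.shape[1] or c_h.shape[0] != X_pre.shape[1]:
        raise ValueError("pre, post and healthy center must share columns")

    X = np.vstack([X_pre, X_post])
    lab = np.array([0] * len(X_pre) + [1] * len(X_post))
    u = fisher_direction(X, lab, ridge)
    # recover the lambda actually used for reporting
    m1 = X_pre.mean(axis=0)
    Sw_trace = float(
        ((X_pre - m1) ** 2).sum() + ((X_post - X_post.mean(axis=0)) ** 2).sum()
    )
    lam = 1e-3 * Sw_trace / X.shape[1] if ridge is None else float(ridge)

    c_pre = X_pre.mean(axis=0)
    a = c_pre - c_h
    resid = a - (a @ u) * u
    nr = np.linalg.norm(resid)
    if nr < 1e-12:
        raise ValueError(
            "healthy-to-pre vector is parallel to the Fisher axis: vertical "
            "axis is degenerate"
        )
    v = resid / nr

    basis = np.stack([u, v])
    coords_pre = X_pre @ basis.T
    coords_post = X_post @ basis.T
    center_pre = c_pre @ basis.T
    center_post = X_post.mean(axis=0) @ basis.T
    center_h = c_h @ basis.T

    s = X @ u
    threshold = 0.5 * (s[lab == 0].mean() + s[lab == 1].mean())
    accuracy = classification_accuracy(s, lab, threshold)

    return FisherPlaneResult(
        u=u,
        v=v,
        coords_pre=coords_pre,
        coords_post=coords_post,
        center_healthy=center_h,
        center_pre=center_pre,
        center_post=center_post,
        threshold=float(threshold),
        accuracy=accuracy,
        ridge=lam,
    )
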