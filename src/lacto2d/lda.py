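"""Linear discriminant analysis via the between/within scatter trace ratio.

With N samples in C classes, the between-class and within-class scatter
matrices are

    S_B = (1/N) * sum_i N_i (xbar_i - xbar)(xbar_i - xbar)^T
    S_W = (1/N) * sum_i sum_j (x_ij - xbar_i)(x_ij - xbar_i)^T

and the projection V maximizes the trace ratio
tr(V^T S_B V) / tr(V^T S_W V).  The classic closed form — top-m
generalized eigenvectors of (S_W + ridge*I)^(-1) S_B — maximizes the
related ratio-trace objective and can be strictly suboptimal for the
trace ratio when m > 1, so it is used only to initialize the standard
trace-ratio iteration (solve the symmetric eigenproblem of
S_B - lambda * S_W at the current ratio lambda until lambda converges),
which is globally optimal.  With many more wavelengths than samples S_W
is singular, hence the ridge (default 1e-6 * trace(S_W)/n).
Classification assigns the label of the nearest projected class mean,
ties broken by class order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import Lacto2dError, NumericalError


@dataclass
class LabeledSpectralMatrix:
    """Feature matrix X (N x n) with class labels and class statistics."""

    X: np.ndarray
    y: np.ndarray
    classes: tuple[str, ...]
    class_counts: np.ndarray
    class_means: np.ndarray  # C x n
    grand_mean: np.ndarray  # n

    @classmethod
    def build(cls, X: np.ndarray, y) -> "LabeledSpectralMatrix":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise Lacto2dError("X must be N x n with one label per row")
        classes = tuple(sorted({str(v) for v in y}))
        counts = np.array([np.sum(y == c) for c in classes])
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        return cls(
            X=X,
            y=y,
            classes=classes,
            class_counts=counts,
            class_means=means,
            grand_mean=X.mean(axis=0),
        )


@dataclass
class LDAModel:
    """Fitted projection plus projected class means."""

    V: np.ndarray  # n x m
    classes: tuple[str, ...]
    projected_means: np.ndarray  # C x m
    ridge: float
    feature_space: str = "visnir"

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "classes": list(self.classes),
            "V": self.V.tolist(),
            "projected_means": self.projected_means.tolist(),
            "ridge": self.ridge,
            "feature_space": self.feature_space,
        }


def scatter_matrices(d: LabeledSpectralMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Between-class S_B and within-class S_W, both 1/N-normalized."""
    if len(d.classes) < 2:
        raise Lacto2dError("scatter matrices need >= 2 classes")
    n_total = d.X.shape[0]
    n_feat = d.X.shape[1]
    s_b = np.zeros((n_feat, n_feat))
    s_w = np.zeros((n_feat, n_feat))
    for c, count, mean in zip(d.classes, d.class_counts, d.class_means):
        dm = mean - d.grand_mean
        s_b += count * np.outer(dm, dm)
        resid = d.X[d.y == c] - mean
        s_w += resid.T @ resid
    s_b /= n_total
    s_w /= n_total
    # enforce exact symmetry against accumulation round-off
    return (s_b + s_b.T) / 2.0, (s_w + s_w.T) / 2.0


def trace_ratio(V: np.ndarray, s_b: np.ndarray, s_w: np.ndarray) -> float:
    """The objective tr(V^T S_B V) / tr(V^T S_W V)."""
    num = float(np.trace(V.T @ s_b @ V))
    den = float(np.trace(V.T @ s_w @ V))
    if den == 0:
        raise NumericalError("within-class trace is zero for this projection")
    return num / den


def _trace_ratio_refine(
    V: np.ndarray,
    s_b: np.ndarray,
    s_w_reg: np.ndarray,
    m: int,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Iterate V <- top-m eigenvectors of S_B - lambda*S_W until the ratio converges.

    lambda is the current trace ratio; each step cannot decrease it, and the
    fixed point is the global trace-ratio maximizer.
    """
    n = s_b.shape[0]
    lam = np.trace(V.T @ s_b @ V) / np.trace(V.T @ s_w_reg @ V)
    for _ in range(max_iter):
        _, vecs = linalg.eigh(s_b - lam * s_w_reg, subset_by_index=[n - m, n - 1])
        V = vecs[:, ::-1]
        new_lam = np.trace(V.T @ s_b @ V) / np.trace(V.T @ s_w_reg @ V)
        if abs(new_lam - lam) <= tol * max(1.0, abs(lam)):
            lam = new_lam
            break
        lam = new_lam
    return V


def fit_lda(
    d: LabeledSpectralMatrix,
    m: int | None = None,
    ridge: float | None = None,
    feature_space: str = "visnir",
) -> LDAModel:
    """Fit the discriminant projection.

    m defaults to C - 1 (2 for the three freshness classes); ridge defaults
    to 1e-6 * trace(S_W)/n.  Eigenvector signs are fixed by making each
    column's largest-magnitude entry positive so artifacts reproduce.
    """
    n_classes = len(d.classes)
    if m is None:
        m = n_classes - 1
    if not 1 <= m <= n_classes - 1:
        raise Lacto2dError(f"m must be in [1, {n_classes - 1}], got {m}")
    s_b, s_w = scatter_matrices(d)
    n_feat = s_w.shape[0]
    if ridge is None:
        ridge = 1e-6 * np.trace(s_w) / n_feat
    if ridge < 0:
        raise Lacto2dError("ridge must be >= 0")
    # the optimum lies in the span of the total scatter (outside it the
    # numerator vanishes while the ridge still penalizes), so reduce to that
    # subspace before solving — essential when wavelengths >> samples
    total_vals, total_vecs = linalg.eigh(s_b + s_w)
    keep = total_vals > 1e-12 * max(total_vals.max(), 1.0)
    if keep.sum() < m:
        raise NumericalError("data span has lower rank than the requested m")
    Q = total_vecs[:, keep]
    s_b_r = Q.T @ s_b @ Q
    s_w_reg_r = Q.T @ s_w @ Q + ridge * np.eye(Q.shape[1])
    try:
        eigvals, eigvecs = linalg.eigh(s_b_r, s_w_reg_r)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "S_W + ridge*I is singular; increase the ridge parameter"
        ) from exc
    order = np.argsort(eigvals)[::-1][:m]
    V = eigvecs[:, order]
    V = Q @ _trace_ratio_refine(V, s_b_r, s_w_reg_r, m)
    # unit columns + sign convention, so artifacts reproduce exactly
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return LDAModel(
        V=V,
        classes=d.classes,
        projected_means=d.class_means @ V,
        ridge=float(ridge),
        feature_space=feature_space,
    )


def classify_lda(x: np.ndarray, model: LDAModel) -> str:
    """Label of the nearest projected class mean (Euclidean); first class wins ties."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != model.V.shape[0]:
        raise Lacto2dError(
            f"feature vector has {x.size} entries; model expects {model.V.shape[0]}"
        )
    z = x @ model.V
    dists = np.linalg.norm(model.projected_means - z, axis=1)
    return model.classes[int(np.argmin(dists))]


def classify_lda_batch(X: np.ndarray, model: LDAModel) -> np.ndarray:
    """Vectorized nearest-projected-mean labels for an N x n matrix."""
    Z = np.asarray(X, dtype=float) @ model.V
    d2 = ((Z[:, None, :] - model.projected_means[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.array([model.classes[i] for i in idx], dtype=object)
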