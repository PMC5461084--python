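"""Support vector data description (SVDD): one-class hypersphere classifier.

SVDD fits the smallest hypersphere enclosing (most of) the target training
spectra in RBF-kernel feature space, by solving the dual quadratic program

    minimize   sum_ij alpha_i alpha_j K(x_i, x_j)
    subject to sum_i alpha_i = 1,  0 <= alpha_i <= C

(for an RBF kernel K(x, x) = 1, so the linear dual term is constant). The
tradeoff coefficient C bounds each dual weight: lowering C forces training
points outside the sphere and shrinks the description, while the kernel
width s controls its compactness in feature space. A spectrum z is accepted
as target iff its squared kernel distance to the sphere centre,

    d^2(z) = 1 - 2 sum_i alpha_i K(x_i, z) + sum_ij alpha_i alpha_j K(x_i, x_j),

does not exceed the squared radius R^2 (boundary inclusive). R^2 is read off
the unbounded support vectors (alpha strictly between 0 and C), which sit
exactly on the sphere at the dual optimum.

The QP is solved by sequential minimal optimization: pairwise weight
transfers that preserve the simplex constraint, with most-violating-pair
working-set selection and a KKT-gap stopping rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .raster import LabelRaster, MultibandRaster

__all__ = ["SVDDModel", "rbf_kernel", "fit_svdd", "decide", "decision_distances",
           "classify_raster"]

TARGET_CODE = 1
OUTLIER_CODE = 0


def rbf_kernel(x: np.ndarray, y: np.ndarray, s: float) -> float:
    """Gaussian kernel K(x, y) = exp(-||x - y||^2 / s^2).

    Symmetric, equal to 1 at x = y, strictly decreasing in ||x - y||;
    larger kernel width s makes distant spectra look more similar.
    """
    if s <= 0:
        raise ValueError(f"kernel width s must be > 0, got {s}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"spectrum length mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / s**2))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, s: float) -> np.ndarray:
    return np.exp(-cdist(A, B, "sqeuclidean") / s**2)


@dataclass
class SVDDModel:
    """Fitted SVDD hypersphere.

    ``alphas``/``X`` hold every training point carrying dual weight (the
    exact solver support); ``support_mask`` flags weights above
    ``alpha_tol``, the support vectors proper. ``scaler`` is the per-band
    (mean, std) z-score transform estimated from the training set and
    applied to every spectrum at prediction time.
    """

    X: np.ndarray              # (m, p) standardized spectra with alpha > 0
    alphas: np.ndarray         # (m,) dual weights, sum to 1
    C: float
    s: float
    R2: float
    center_term: float         # sum_ij alpha_i alpha_j K(x_i, x_j)
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    alpha_tol: float = 1e-6
    info: dict = field(default_factory=dict)

    @property
    def support_mask(self) -> np.ndarray:
        return self.alphas > self.alpha_tol

    @property
    def support_vectors(self) -> np.ndarray:
        return self.X[self.support_mask]

    @property
    def n_bounded(self) -> int:
        return int(np.sum(self.alphas >= self.C - self.alpha_tol))

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def standardize(self, Z: np.ndarray) -> np.ndarray:
        return (np.asarray(Z, dtype=float) - self.scaler_mean) / self.scaler_std

    # -- JSON round-trip ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alphas": self.alphas.tolist(),
            "support_vectors": self.X.tolist(),
            "C": self.C,
            "s": self.s,
            "R2": self.R2,
            "center_term": self.center_term,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "alpha_tol": self.alpha_tol,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SVDDModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            X=np.asarray(d["support_vectors"], dtype=float),
            alphas=np.asarray(d["alphas"], dtype=float),
            C=d["C"], s=d["s"], R2=d["R2"], center_term=d["center_term"],
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_std=np.asarray(d["scaler_std"], dtype=float),
            alpha_tol=d["alpha_tol"],
        )


def _smo(K: np.ndarray, C: float, tol: float, max_iter: int) -> tuple[np.ndarray, int]:
    """Minimize alpha^T K alpha on the scaled simplex {sum=1, 0<=a<=C}.

    Most-violating-pair SMO: transfer weight from the active coordinate
    with the largest gradient to the one with the smallest until the KKT
    gap falls below ``tol``.
    """
    n = K.shape[0]
    alpha = np.full(n, 1.0 / n)
    if n == 1:
        return alpha, 0
    g = 2.0 * (K @ alpha)
    eps = 1e-14
    it = 0
    for it in range(max_iter):
        up = alpha < C - eps
        dn = alpha > eps
        if not up.any() or not dn.any():  # all weights pinned at a bound
            break
        i = int(np.flatnonzero(up)[np.argmin(g[up])])
        j = int(np.flatnonzero(dn)[np.argmax(g[dn])])
        gap = g[j] - g[i]
        if gap <= tol:
            break
        eta = 2.0 * (K[i, i] + K[j, j] - 2.0 * K[i, j])
        step = gap / eta if eta > eps else np.inf
        step = min(step, C - alpha[i], alpha[j])
        alpha[i] += step
        alpha[j] -= step
        g += 2.0 * step * (K[:, i] - K[:, j])
    return alpha, it


def fit_svdd(
    targets,
    C: float,
    s: float,
    *,
    standardize: bool = True,
    tol: float = 1e-8,
    alpha_tol: float = 1e-6,
    max_iter: int = 100_000,
) -> SVDDModel:
    """Fit the SVDD dual on target-only training spectra.

    ``targets`` may be a :class:`~svddmap.sampling.SampleSet` or an
    ``(n, p)`` array. Requires ``C >= 1/n`` (else the simplex constraint is
    infeasible) and ``s > 0``. With ``standardize=True`` (default) spectra
    are z-scored per band using training statistics, so the kernel-width
    bounds used by the parameter search are unit-independent.
    """
    X = np.atleast_2d(np.asarray(getattr(targets, "spectra", targets), dtype=float))
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one training sample")
    if s <= 0:
        raise ValueError(f"kernel width s must be > 0, got {s}")
    if C < 1.0 / n - 1e-12:
        raise ValueError(
            f"C={C} infeasible: the simplex constraint needs C >= 1/n = {1.0 / n:.6g}"
        )
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Xs = (X - mean) / std

    K = _kernel_matrix(Xs, Xs, s)
    alpha, n_iter = _smo(K, min(C, 1.0), tol, max_iter)

    keep = alpha > 0
    Xk, ak = Xs[keep], alpha[keep]
    Kk = K[np.ix_(keep, keep)]
    center_term = float(ak @ Kk @ ak)
    d2 = 1.0 - 2.0 * (Kk @ ak) + center_term
    unbounded = (ak > alpha_tol) & (ak < C - alpha_tol)
    if np.any(unbounded):
        R2 = float(np.max(d2[unbounded]))
    else:
        bounded = ak >= C - alpha_tol
        # degenerate case: every SV at its bound; use a stable aggregate
        R2 = float(np.mean(d2[bounded])) if np.any(bounded) else float(np.max(d2))
    return SVDDModel(
        X=Xk, alphas=ak, C=float(C), s=float(s), R2=max(R2, 0.0),
        center_term=center_term, scaler_mean=mean, scaler_std=std,
        alpha_tol=alpha_tol, info={"n_train": n, "smo_iterations": n_iter},
    )


def decision_distances(model: SVDDModel, Z: np.ndarray) -> np.ndarray:
    """Squared kernel distance from the sphere centre for each row of Z."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.n_features:
        raise ValueError(
            f"spectrum length {Z.shape[1]} != model dimension {model.n_features}"
        )
    Kz = _kernel_matrix(model.standardize(Z), model.X, model.s)
    return 1.0 - 2.0 * (Kz @ model.alphas) + model.center_term


def decide(model: SVDDModel, z: np.ndarray) -> tuple[str, float]:
    """Classify one spectrum: ("target"|"outlier", squared kernel distance).

    Boundary inclusive: d^2 = R^2 is accepted, so support vectors on the
    sphere are targets.
    """
    d2 = float(decision_distances(model, np.asarray(z, dtype=float)[np.newaxis])[0])
    return ("target" if d2 <= model.R2 else "outlier", d2)


def classify_raster(
    model: SVDDModel,
    raster: MultibandRaster,
    *,
    unknown_code: int = -1,
    chunk: int = 65536,
) -> LabelRaster:
    """Per-pixel SVDD decision over a raster.

    Returns a binary label map (1 = target, 0 = outlier); nodata pixels map
    to ``unknown_code``.
    """
    if raster.n_bands != model.n_features:
        raise ValueError(
            f"raster has {raster.n_bands} bands, model expects {model.n_features}"
        )
    h, w = raster.shape
    flat = raster.values.reshape(raster.n_bands, -1).T
    out = np.full(h * w, OUTLIER_CODE, dtype=np.int64)
    valid = raster.valid_mask().ravel()
    idx = np.flatnonzero(valid)
    for start in range(0, len(idx), chunk):
        sel = idx[start : start + chunk]
        d2 = decision_distances(model, flat[sel])
        out[sel] = np.where(d2 <= model.R2, TARGET_CODE, OUTLIER_CODE)
    out[~valid] = unknown_code
    return LabelRaster(
        out.reshape(h, w),
        {TARGET_CODE: "target", OUTLIER_CODE: "outlier"},
        unknown_code=unknown_code,
    )
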