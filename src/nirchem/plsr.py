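"""Partial least squares regression via NIPALS, implemented from scratch.

Single-response PLS1: X is centered (and optionally autoscaled), y centered;
components are extracted by NIPALS deflation and collapsed into a regression
coefficient vector mapping raw X to y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PlsrModel",
    "fit_plsr",
    "predict_plsr",
    "choose_components",
    "save_plsr",
    "load_plsr",
]


@dataclass
class PlsrModel:
    n_components: int
    x_weights: np.ndarray    # (p, A)
    x_scores: np.ndarray     # (n, A)
    x_loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray   # (A,)
    coef: np.ndarray         # (p,), maps raw X to y
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    autoscale: bool = True


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int,
             autoscale: bool = True) -> PlsrModel:
    """Fit PLS1 by NIPALS.

    ``autoscale`` divides every X column by its training standard deviation
    (columns with zero variance are left unscaled).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X rows must match y length")
    if n < 2:
        raise ValueError("need at least 2 samples")
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise ValueError(
            f"n_components must be in [1, {max_a}] for X of shape {X.shape}"
        )
    if np.ptp(y) == 0:
        raise ValueError("y is constant; PLSR target is degenerate")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    x_scale = np.where(x_sd > 0, x_sd, 1.0) if autoscale else np.ones(p)
    y_mean = float(y.mean())

    E = (X - x_mean) / x_scale
    f = y - y_mean

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual X carries no covariance with y; stop early
            W, T, P, q = W[:, :a], T[:, :a], P[:, :a], q[:a]
            n_components = a
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, T, P, q = W[:, :a], T[:, :a], P[:, :a], q[:a]
            n_components = a
            break
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
    if n_components == 0:
        raise ValueError("no usable PLS component (X uncorrelated with y)")

    # B = W (P' W)^-1 q in scaled coordinates
    b_scaled = W @ np.linalg.solve(P.T @ W, q)
    coef = b_scaled / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return PlsrModel(n_components, W, T, P, q, coef, intercept,
                     x_mean, x_scale, y_mean, autoscale)


def predict_plsr(m: PlsrModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != m.coef.size:
        raise ValueError(
            f"expected shape (n, {m.coef.size}), got {X.shape}"
        )
    return m.intercept + X @ m.coef


def choose_components(X: np.ndarray, y: np.ndarray, max_components: int,
                      n_folds: int = 5, seed: int = 0,
                      tolerance: float = 0.02,
                      autoscale: bool = True) -> int:
    """Pick the smallest component count whose k-fold CV RMSE is within
    ``tolerance`` (relative) of the global minimum."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n_folds < 2 or n_folds > n:
        raise ValueError("n_folds must be in [2, n_samples]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    rmse = np.full(max_components, np.inf)
    for a in range(1, max_components + 1):
        sq = []
        for k in range(n_folds):
            test = folds[k]
            train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            a_eff = min(a, min(train.size - 1, X.shape[1]))
            m = fit_plsr(X[train], y[train], a_eff, autoscale=autoscale)
            sq.append((predict_plsr(m, X[test]) - y[test]) ** 2)
        rmse[a - 1] = float(np.sqrt(np.mean(np.concatenate(sq))))
    best = float(rmse.min())
    ok = np.where(rmse <= best * (1.0 + tolerance))[0]
    return int(ok[0]) + 1


def save_plsr(m: PlsrModel, path: str | Path) -> None:
    doc = {
        "n_components": m.n_components,
        "coef": m.coef.tolist(),
        "intercept": m.intercept,
        "x_mean": m.x_mean.tolist(),
        "x_scale": m.x_scale.tolist(),
        "y_mean": m.y_mean,
        "autoscale": m.autoscale,
        "x_weights": m.x_weights.tolist(),
        "x_loadings": m.x_loadings.tolist(),
        "y_loadings": m.y_loadings.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_plsr(path: str | Path) -> PlsrModel:
    doc = json.loads(Path(path).read_text())
    return PlsrModel(
        n_components=doc["n_components"],
        x_weights=np.array(doc["x_weights"]),
        x_scores=np.zeros((0, doc["n_components"])),
        x_loadings=np.array(doc["x_loadings"]),
        y_loadings=np.array(doc["y_loadings"]),
        coef=np.array(doc["coef"]),
        intercept=doc["intercept"],
        x_mean=np.array(doc["x_mean"]),
        x_scale=np.array(doc["x_scale"]),
        y_mean=doc["y_mean"],
        autoscale=doc["autoscale"],
    )
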