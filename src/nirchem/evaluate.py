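"""Repeated random-split evaluation harness and the five test-set metrics
(R, R^2, MSE, RMSE, MAE)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metrics",
    "SplitPlan",
    "EvalDistribution",
    "split_data",
    "metrics",
    "repeated_evaluation",
    "summarize",
    "boxplot_stats",
    "DEFAULT_FRACTIONS",
]

#: train / validation / test fractions.
DEFAULT_FRACTIONS = (0.60, 0.10, 0.30)

METRIC_NAMES = ("mse", "rmse", "mae", "r", "r2")


@dataclass(frozen=True)
class Metrics:
    """Test-split performance in target units.

    ``r2`` is the square of the Pearson correlation (the headline value);
    ``r2_ss`` is the 1 - SSres/SStot variant, emitted alongside.
    """

    r: float
    r2: float
    mse: float
    rmse: float
    mae: float
    r2_ss: float

    def as_dict(self) -> dict[str, float]:
        return {"mse": self.mse, "rmse": self.rmse, "mae": self.mae,
                "r": self.r, "r2": self.r2}


@dataclass(frozen=True)
class SplitPlan:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train.tolist()), set(self.validation.tolist()),
                 set(self.test.tolist())]
        n = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != n:
            raise ValueError("split parts must be disjoint")


@dataclass
class EvalDistribution:
    records: list[Metrics]
    seeds: list[int]
    method: str
    n_failed: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([m.as_dict() for m in self.records])
        df.insert(0, "seed", self.seeds)
        return df


def _part_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of n * fractions."""
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(v)) for v in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - v for s, v in zip(sizes, raw)])  # biggest remainder first
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_data(n: int, fractions: Sequence[float] = DEFAULT_FRACTIONS,
               seed: int = 0) -> SplitPlan:
    """Random train/validation/test partition, reproducible per seed."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    sizes = _part_sizes(n, fractions)
    if min(sizes) < 1:
        raise ValueError(
            f"n={n} too small for fractions {fractions}: empty part"
        )
    perm = np.random.default_rng(seed).permutation(n)
    n_tr, n_val, _ = sizes
    return SplitPlan(
        train=np.sort(perm[:n_tr]),
        validation=np.sort(perm[n_tr:n_tr + n_val]),
        test=np.sort(perm[n_tr + n_val:]),
        fractions=fractions,
        seed=seed,
    )


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Compute R, R^2, MSE, RMSE and MAE on a test split."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred need equal nonzero lengths")
    err = y_pred - y_true
    mse = float(np.mean(err ** 2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(err)))
    # std (not ptp) guards against variance underflow for near-equal values
    if np.std(y_true) == 0:
        raise ValueError("y_true is constant; correlation undefined")
    if np.std(y_pred) == 0:
        raise ValueError("y_pred is constant; correlation undefined")
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2_ss = 1.0 - float(np.sum(err ** 2)) / sstot
    return Metrics(r=r, r2=r * r, mse=mse, rmse=rmse, mae=mae, r2_ss=r2_ss)


def repeated_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    pipeline: Callable,
    n_iter: int = 500,
    base_seed: int = 0,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    method: str = "",
) -> EvalDistribution:
    """Run ``pipeline`` over ``n_iter`` random splits and collect test metrics.

    ``pipeline(X_train, y_train, X_val, y_val, seed)`` must return a
    prediction function ``f(X) -> y_hat`` and be deterministic given its seed.
    Failed iterations are recorded and excluded from the distribution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    records, seeds = [], []
    failures: list[tuple[int, str]] = []
    for i in range(1, n_iter + 1):
        seed = base_seed + i
        plan = split_data(y.size, fractions, seed=seed)
        try:
            predict_fn = pipeline(X[plan.train], y[plan.train],
                                  X[plan.validation], y[plan.validation],
                                  seed)
            m = metrics(y[plan.test], predict_fn(X[plan.test]))
            if not all(np.isfinite(v) for v in m.as_dict().values()):
                raise ValueError("non-finite metric")
        except Exception as exc:  # noqa: BLE001 - campaign must survive
            failures.append((seed, str(exc)))
            continue
        records.append(m)
        seeds.append(seed)
    return EvalDistribution(records, seeds, method,
                            n_failed=len(failures), failures=failures)


def summarize(d: EvalDistribution) -> pd.DataFrame:
    """Mean +/- SD, quartiles and the best-training row (minimal test MSE).

    Rows: mean, sd, q1, median, q3, best. Columns: the five metrics. The
    seed of the best iteration is stored in ``df.attrs["best_seed"]``.
    """
    if not d.records:
        raise ValueError("empty distribution")
    df = pd.DataFrame([m.as_dict() for m in d.records])
    best_i = int(df["mse"].idxmin())
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1) if len(df) > 1 else df.mean() * 0.0,
            "q1": df.quantile(0.25),
            "median": df.quantile(0.50),
            "q3": df.quantile(0.75),
            "best": df.iloc[best_i],
        }
    ).T
    out = out[list(METRIC_NAMES)]
    out.attrs["best_seed"] = d.seeds[best_i]
    out.attrs["method"] = d.method
    out.attrs["n_failed"] = d.n_failed
    return out


def boxplot_stats(d: EvalDistribution) -> dict:
    """Whisker/quartile statistics per metric, for box-plot export."""
    df = pd.DataFrame([m.as_dict() for m in d.records])
    stats = {}
    for col in df.columns:
        v = df[col].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = v[(v >= lo) & (v <= hi)]
        stats[col] = {
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": float(inliers.min()),
            "whisker_high": float(inliers.max()),
            "outliers": [float(x) for x in v[(v < lo) | (v > hi)]],
        }
    return stats
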