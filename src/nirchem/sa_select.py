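"""Simulated-annealing search over fixed-size wavelength subsets.

The objective of a subset is the validation MSE of a small MLP (by default
the 2-layer radbas/logsig structure used for selection) trained on the
subset's columns with one fixed seed and one fixed inner train/validation
split. Objective values are memoized, making the objective a deterministic
function of the subset, as annealing theory assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .neuralnet import (AnnConfig, TrainingError, init_network, network_mse,
                        train_network)
from .spectra import SpectraSet, WavelengthGrid

__all__ = [
    "SaConfig",
    "WavelengthSubset",
    "SELECTION_ANN",
    "acceptance_probability",
    "propose_neighbor",
    "sa_select_wavelengths",
    "make_ann_objective",
]

#: Default objective network for wavelength selection: two hidden layers of
#: 13 and 23 neurons with radbas / logsig transfers, incremental training.
SELECTION_ANN = AnnConfig(
    n_layers=2,
    neurons=(13, 23),
    transfer=("radbas", "logsig"),
    train_method="trains",
    learn_method="learnh",
)


@dataclass(frozen=True)
class SaConfig:
    """Annealing schedule. ``t_init=None`` sets the initial temperature to the
    standard deviation of the objective over 20 random subsets."""

    subset_size: int = 4
    t_init: float | None = None
    cooling: float = 0.95
    steps_per_temp: int = 20
    t_min: float = 1e-4
    seed: int = 0
    #: probability of a local refinement swap (incoming index drawn within
    #: ``local_radius`` grid steps of a selected one) instead of the uniform
    #: global swap; spectra are spatially correlated, so local moves make
    #: hill-climbing effective once a region is found.
    local_swap_prob: float = 0.5
    local_radius: int = 5

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling must be in (0, 1)")
        if self.t_min <= 0:
            raise ValueError("t_min must be > 0")
        if self.t_init is not None and self.t_init <= self.t_min:
            raise ValueError("t_init must exceed t_min")
        if self.steps_per_temp < 1:
            raise ValueError("steps_per_temp must be >= 1")
        if not 0.0 <= self.local_swap_prob <= 1.0:
            raise ValueError("local_swap_prob must be in [0, 1]")


@dataclass
class WavelengthSubset:
    """A selected subset: sorted unique grid indices plus the MSE that earned
    them and the accepted-move trace of the search."""

    indices: tuple[int, ...]
    wavelengths: tuple[float, ...]
    objective: float
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("subset indices must be unique")
        if tuple(sorted(idx)) != idx:
            raise ValueError("subset indices must be sorted")
        if self.objective < 0:
            raise ValueError("objective must be >= 0")
        self.indices = idx
        self.wavelengths = tuple(float(w) for w in self.wavelengths)


def acceptance_probability(delta: float, t: float) -> float:
    """Metropolis rule: 1 for improving moves, exp(-delta/t) otherwise."""
    if t <= 0:
        raise ValueError("temperature must be > 0")
    if delta <= 0:
        return 1.0
    return math.exp(-delta / t)


def propose_neighbor(current: tuple[int, ...], n_grid: int,
                     rng: np.random.Generator) -> tuple[int, ...]:
    """Swap one selected index for one unselected index, uniformly at random."""
    current = tuple(current)
    if len(current) >= n_grid:
        raise ValueError("no unselected indices available for a swap")
    out = current[rng.integers(len(current))]
    selected = set(current)
    pool = [i for i in range(n_grid) if i not in selected]
    incoming = pool[rng.integers(len(pool))]
    return tuple(sorted(set(current) - {out} | {incoming}))


def _propose_local(current: tuple[int, ...], n_grid: int, radius: int,
                   rng: np.random.Generator) -> tuple[int, ...]:
    """Swap one selected index for an unselected one near a selected index."""
    selected = set(current)
    out = current[rng.integers(len(current))]
    anchor = current[rng.integers(len(current))]
    lo, hi = max(0, anchor - radius), min(n_grid - 1, anchor + radius)
    pool = [i for i in range(lo, hi + 1) if i not in selected]
    if not pool:
        return propose_neighbor(current, n_grid, rng)
    incoming = pool[rng.integers(len(pool))]
    return tuple(sorted(selected - {out} | {incoming}))


def make_ann_objective(
    s: SpectraSet,
    target: np.ndarray,
    ann: AnnConfig = SELECTION_ANN,
    inner_seed: int = 0,
    val_fraction: float = 0.2,
    max_epochs: int = 25,
    lr: float = 0.15,
    patience: int = 6,
):
    """Deterministic, memoized subset objective: inner-validation MSE of
    ``ann`` trained on the subset's wavelength columns.

    The inner split and every training seed are fixed, so the objective is a
    pure function of the subset.
    """
    target = np.asarray(target, dtype=float).ravel()
    if target.size != s.n_samples:
        raise ValueError("target length must equal sample count")
    n = s.n_samples
    rng = np.random.default_rng(inner_seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    cache: dict[tuple[int, ...], float] = {}

    def objective(indices: tuple[int, ...]) -> float:
        key = tuple(sorted(int(i) for i in indices))
        if key in cache:
            return cache[key]
        X = s.intensities[:, key]
        net = init_network(ann, n_in=len(key), n_out=1, seed=inner_seed)
        try:
            net, _ = train_network(
                net, X[train_idx], target[train_idx],
                val=(X[val_idx], target[val_idx]),
                max_epochs=max_epochs, lr=lr, seed=inner_seed,
                patience=patience,
            )
            mse = network_mse(net, X[val_idx], target[val_idx])
        except TrainingError:
            mse = float("inf")
        cache[key] = mse
        return mse

    objective.cache = cache  # type: ignore[attr-defined]
    return objective


def sa_select_wavelengths(
    s: SpectraSet,
    target: np.ndarray,
    sa: SaConfig,
    ann: AnnConfig = SELECTION_ANN,
    objective=None,
    objective_kwargs: dict | None = None,
) -> WavelengthSubset:
    """Metropolis walk with geometric cooling over fixed-size subsets.

    Returns the best-ever subset. ``objective`` may be supplied directly
    (tests use exhaustive oracles); otherwise the memoized ANN objective is
    built from ``ann``.
    """
    n_grid = len(s.grid)
    if sa.subset_size > n_grid:
        raise ValueError("subset_size exceeds grid length")
    if objective is None:
        objective = make_ann_objective(s, target, ann,
                                       **(objective_kwargs or {}))
    if sa.subset_size == n_grid:
        full = tuple(range(n_grid))
        return WavelengthSubset(full, tuple(s.grid.values), objective(full))

    rng = np.random.default_rng(sa.seed)
    current = tuple(sorted(rng.choice(n_grid, size=sa.subset_size,
                                      replace=False).tolist()))
    current_obj = objective(current)
    best, best_obj = current, current_obj

    t = sa.t_init
    if t is None:
        # probe random subsets to scale the schedule; the probes are paid
        # for, so the walk starts from the best one seen
        probe_objs = []
        for _ in range(20):
            probe = tuple(sorted(rng.choice(
                n_grid, size=sa.subset_size, replace=False).tolist()))
            probe_objs.append((objective(probe), probe))
        finite = [p for p, _ in probe_objs if math.isfinite(p)]
        t = float(np.std(finite)) if len(finite) > 1 else 1.0
        t = max(t, 10.0 * sa.t_min)
        probe_best, probe_pos = min(probe_objs, key=lambda x: x[0])
        if probe_best < current_obj:
            current, current_obj = probe_pos, probe_best
        if current_obj < best_obj:
            best, best_obj = current, current_obj

    history: list[dict] = [{"step": 0, "temperature": t,
                            "objective": current_obj, "best": best_obj,
                            "accepted": True}]
    step = 0
    while t > sa.t_min:
        for _ in range(sa.steps_per_temp):
            step += 1
            if rng.random() < sa.local_swap_prob:
                cand = _propose_local(current, n_grid, sa.local_radius, rng)
            else:
                cand = propose_neighbor(current, n_grid, rng)
            cand_obj = objective(cand)
            delta = cand_obj - current_obj
            accepted = (math.isfinite(cand_obj)
                        and rng.random() < acceptance_probability(delta, t))
            if accepted:
                current, current_obj = cand, cand_obj
                if cand_obj < best_obj:
                    best, best_obj = cand, cand_obj
            history.append({"step": step, "temperature": t,
                            "objective": current_obj, "best": best_obj,
                            "accepted": accepted})
        t *= sa.cooling

    return WavelengthSubset(
        indices=best,
        wavelengths=tuple(float(s.grid.values[i]) for i in best),
        objective=best_obj,
        history=history,
    )
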