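"""Imperialist competitive algorithm over a mixed integer/categorical space,
used to tune the five structural parameters of the MLP.

Countries are encoded as tuples with one slot per dimension. The classic
continuous moves are adapted to the mixed space: during assimilation each
colony slot moves toward the imperialist's slot with probability
min(1, beta * U), U ~ Uniform(0, 1) — integer slots step a uniform random
amount toward the imperialist, categorical slots copy the imperialist's
value. Revolution re-randomizes a colony wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .neuralnet import (LEARN_METHODS, TRAIN_METHODS, TRANSFER_CATALOG,
                        AnnConfig, TrainingError, init_network, network_mse,
                        train_network)
from .spectra import SpectraSet

__all__ = [
    "IcaConfig",
    "IntDim",
    "CatDim",
    "Country",
    "ica_optimize",
    "ann_search_space",
    "decode_ann",
    "tune_ann",
]


@dataclass(frozen=True)
class IntDim:
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("empty integer range")

    def sample(self, rng: np.random.Generator):
        return int(rng.integers(self.lo, self.hi + 1))


@dataclass(frozen=True)
class CatDim:
    choices: tuple

    def __post_init__(self) -> None:
        if not self.choices:
            raise ValueError("empty categorical set")
        object.__setattr__(self, "choices", tuple(self.choices))

    def sample(self, rng: np.random.Generator):
        return self.choices[rng.integers(len(self.choices))]


@dataclass(frozen=True)
class IcaConfig:
    n_countries: int = 50
    n_imperialists: int = 5
    max_decades: int = 100
    revolution_rate: float = 0.2
    beta: float = 2.0
    zeta: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_imperialists < self.n_countries:
            raise ValueError("need 1 <= n_imperialists < n_countries")
        if not 0.0 <= self.revolution_rate <= 1.0:
            raise ValueError("revolution_rate must be in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must be in [0, 1]")


@dataclass
class Country:
    position: tuple
    cost: float
    role: str = "colony"         # "imperialist" | "colony"
    empire: int = -1


def _sample_position(space: Sequence, rng: np.random.Generator) -> tuple:
    return tuple(dim.sample(rng) for dim in space)


def _assimilate(pos: tuple, imp: tuple, space: Sequence, beta: float,
                rng: np.random.Generator) -> tuple:
    out = list(pos)
    for k, dim in enumerate(space):
        if out[k] == imp[k]:
            continue
        if rng.random() >= min(1.0, beta * rng.random()):
            continue
        if isinstance(dim, IntDim):
            diff = imp[k] - out[k]
            step = int(rng.integers(1, abs(diff) + 1))
            out[k] = out[k] + int(np.sign(diff)) * step
        else:
            out[k] = imp[k]
    return tuple(out)


def ica_optimize(cost: Callable[[tuple], float], space: Sequence,
                 cfg: IcaConfig) -> tuple[tuple, list[dict]]:
    """Minimize ``cost`` over the mixed space; returns (best position, history).

    History rows carry decade, best_cost, mean_cost, n_empires, and the id of
    the empire a colony was taken from during competition.
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(cfg.seed)
    memo: dict[tuple, float] = {}

    def eval_pos(pos: tuple) -> float:
        if pos not in memo:
            c = float(cost(pos))
            if np.isnan(c):
                raise ValueError(f"non-finite cost at position {pos!r}")
            memo[pos] = c
        return memo[pos]

    countries = [Country(p, eval_pos(p))
                 for p in (_sample_position(space, rng)
                           for _ in range(cfg.n_countries))]
    countries.sort(key=lambda c: c.cost)
    imperialists = countries[:cfg.n_imperialists]
    colonies = countries[cfg.n_imperialists:]
    for i, imp in enumerate(imperialists):
        imp.role, imp.empire = "imperialist", i

    # initial colony distribution proportional to normalized imperialist power
    costs = np.array([imp.cost for imp in imperialists], dtype=float)
    finite_max = costs[np.isfinite(costs)].max(initial=0.0)
    norm = finite_max - np.where(np.isfinite(costs), costs, finite_max)
    if norm.sum() <= 0:
        shares = np.full(len(imperialists), 1.0 / len(imperialists))
    else:
        shares = norm / norm.sum()
    n_col = len(colonies)
    counts = np.floor(shares * n_col).astype(int)
    counts[0] += n_col - counts.sum()  # remainder to the strongest empire
    # every empire starts with at least one colony when there are enough,
    # so no empire collapses before competition has actually played out
    if n_col >= len(imperialists):
        for e in range(len(counts)):
            while counts[e] == 0:
                donor = int(np.argmax(counts))
                if counts[donor] <= 1:
                    break
                counts[donor] -= 1
                counts[e] += 1
    j = 0
    for e, k in enumerate(counts):
        for _ in range(k):
            colonies[j].role, colonies[j].empire = "colony", e
            j += 1

    best_pos = imperialists[0].position
    best_cost = imperialists[0].cost
    history: list[dict] = []
    stall = 0  # decades without best-cost improvement under a single empire

    def empires_alive() -> list[int]:
        return sorted({c.empire for c in countries if c.role == "imperialist"})

    for decade in range(cfg.max_decades):
        alive = empires_alive()
        # converged: one empire left and its search has gone quiet
        if len(alive) <= 1 and stall >= 40:
            break
        prev_best = best_cost
        imp_of = {c.empire: c for c in countries if c.role == "imperialist"}

        # assimilation + revolution
        for c in countries:
            if c.role != "colony":
                continue
            if rng.random() < cfg.revolution_rate:
                c.position = _sample_position(space, rng)
            else:
                c.position = _assimilate(c.position, imp_of[c.empire].position,
                                         space, cfg.beta, rng)
            c.cost = eval_pos(c.position)
            if c.cost < best_cost:
                best_cost, best_pos = c.cost, c.position

        # position exchange: a colony that beats its imperialist takes over
        for e in alive:
            imp = imp_of[e]
            members = [c for c in countries if c.role == "colony" and c.empire == e]
            if members:
                champ = min(members, key=lambda c: c.cost)
                if champ.cost < imp.cost:
                    champ.role, imp.role = "imperialist", "colony"
                    imp_of[e] = champ

        # imperialistic competition
        moved_from = None
        alive = empires_alive()
        if len(alive) > 1:
            imp_of = {c.empire: c for c in countries if c.role == "imperialist"}
            totals = {}
            for e in alive:
                members = [c for c in countries
                           if c.role == "colony" and c.empire == e]
                mean_col = float(np.mean([c.cost for c in members])) if members \
                    else imp_of[e].cost
                totals[e] = imp_of[e].cost + cfg.zeta * mean_col
            weakest = max(alive, key=lambda e: totals[e])
            weak_members = [c for c in countries
                            if c.role == "colony" and c.empire == weakest]
            if weak_members:
                prize = max(weak_members, key=lambda c: c.cost)
            else:
                # empire with no colonies collapses: its imperialist is the prize
                prize = imp_of[weakest]
                prize.role = "colony"
            bidders = [e for e in alive if e != weakest]
            tc = np.array([totals[e] for e in bidders])
            power = tc.max() - tc
            p = power / power.sum() if power.sum() > 0 \
                else np.full(len(bidders), 1.0 / len(bidders))
            winner = bidders[int(np.argmax(p - rng.uniform(0, 1, len(bidders))))]
            prize.empire = winner
            moved_from = weakest

        if len(empires_alive()) <= 1:
            stall = stall + 1 if best_cost >= prev_best else 0
        history.append({
            "decade": decade,
            "best_cost": best_cost,
            "mean_cost": float(np.mean([c.cost for c in countries])),
            "n_empires": len(empires_alive()),
            "moved_from": moved_from,
            "n_imperialists": sum(c.role == "imperialist" for c in countries),
            "n_colonies": sum(c.role == "colony" for c in countries),
        })

    return best_pos, history


# ---------------------------------------------------------------------------
# ANN structure tuning
# ---------------------------------------------------------------------------

MAX_HIDDEN_LAYERS = 3
MAX_NEURONS = 25


def ann_search_space(transfer_choices: tuple[str, ...] | None = None) -> list:
    """Mixed space over the five tunable parameters.

    Slots: n_layers, neurons x3, transfer x3, train_method, learn_method.
    Slots beyond n_layers are carried but ignored by :func:`decode_ann`.
    """
    transfers = tuple(transfer_choices or sorted(TRANSFER_CATALOG))
    return (
        [IntDim(1, MAX_HIDDEN_LAYERS)]
        + [IntDim(1, MAX_NEURONS)] * MAX_HIDDEN_LAYERS
        + [CatDim(transfers)] * MAX_HIDDEN_LAYERS
        + [CatDim(tuple(TRAIN_METHODS)), CatDim(tuple(LEARN_METHODS))]
    )


def decode_ann(position: tuple) -> AnnConfig:
    n_layers = int(position[0])
    neurons = tuple(int(v) for v in position[1:1 + n_layers])
    transfer = tuple(position[1 + MAX_HIDDEN_LAYERS:
                              1 + MAX_HIDDEN_LAYERS + n_layers])
    return AnnConfig(n_layers=n_layers, neurons=neurons, transfer=transfer,
                     train_method=position[-2], learn_method=position[-1])


def make_ann_cost(s: SpectraSet, target: np.ndarray, inner_seed: int = 0,
                  val_fraction: float = 0.2, max_epochs: int = 150,
                  lr: float = 0.05):
    """Country cost: inner-validation MSE of the decoded config, trained on a
    fixed split with a fixed seed, memoized per decoded config. Divergent
    training costs +inf."""
    target = np.asarray(target, dtype=float).ravel()
    n = s.n_samples
    rng = np.random.default_rng(inner_seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X = s.intensities
    cache: dict[AnnConfig, float] = {}

    def cost(position: tuple) -> float:
        cfg = decode_ann(position)
        if cfg in cache:
            return cache[cfg]
        net = init_network(cfg, n_in=X.shape[1], n_out=1, seed=inner_seed)
        try:
            net, _ = train_network(net, X[train_idx], target[train_idx],
                                   val=(X[val_idx], target[val_idx]),
                                   max_epochs=max_epochs, lr=lr,
                                   seed=inner_seed)
            mse = network_mse(net, X[val_idx], target[val_idx])
            if not np.isfinite(mse):
                mse = float("inf")
        except TrainingError:
            mse = float("inf")
        cache[cfg] = mse
        return mse

    cost.cache = cache  # type: ignore[attr-defined]
    return cost


def tune_ann(s: SpectraSet, target: np.ndarray, cfg: IcaConfig,
             space: Sequence | None = None,
             cost: Callable[[tuple], float] | None = None,
             max_epochs: int = 150) -> tuple[AnnConfig, list[dict]]:
    """Tune the MLP structure for the given (selected-wavelength) spectra."""
    if space is None:
        space = ann_search_space()
    if cost is None:
        cost = make_ann_cost(s, target, inner_seed=cfg.seed,
                             max_epochs=max_epochs)
    best_pos, history = ica_optimize(cost, space, cfg)
    return decode_ann(best_pos), history
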