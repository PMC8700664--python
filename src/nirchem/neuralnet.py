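"""Multilayer perceptron with a MATLAB-style catalog of transfer functions
and training methods.

The network is a stack of hidden layers, each with its own transfer function
from the catalog, followed by a linear output layer. Inputs and targets are
min-max scaled to [-1, 1] using statistics of the training split only; the
scaling is stored on the network and inverted at prediction time.

Training methods
----------------
``traingd``
    Full-batch gradient descent with a fixed learning rate.
``traincgb``
    Full-batch nonlinear conjugate gradient with Powell-Beale restarts.
``trains``
    Random-order incremental (per-sample) updates. The per-sample update rule
    is selected by ``learn_method``: ``learnh`` applies an error-driven
    outer-product step with weight decay, ``learnsom`` the same step without
    decay. Under the batch methods ``learn_method`` is recorded but inert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

try:  # optional JIT for the per-sample incremental trainer
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "AnnConfig",
    "Network",
    "TrainRecord",
    "TrainingError",
    "transfer",
    "transfer_derivative",
    "init_network",
    "train_network",
    "predict",
    "network_mse",
    "save_network",
    "load_network",
    "TRANSFER_CATALOG",
    "TRAIN_METHODS",
    "LEARN_METHODS",
]

_NETINV_EPS = 1e-12
_NETINV_CLIP = 1e12


def _netinv(x):
    z = np.where(np.abs(x) < _NETINV_EPS,
                 np.where(x < 0, -_NETINV_EPS, _NETINV_EPS), x)
    return np.clip(1.0 / z, -_NETINV_CLIP, _NETINV_CLIP)


def _netinv_deriv(x):
    z = np.where(np.abs(x) < _NETINV_EPS,
                 np.where(x < 0, -_NETINV_EPS, _NETINV_EPS), x)
    return np.clip(-1.0 / (z * z), -_NETINV_CLIP, 0.0)


# name -> (f(x), f'(x)); derivatives of the piecewise-linear / step functions
# are taken as 0 at their corners (the MATLAB convention).
TRANSFER_CATALOG: dict[str, tuple[Callable, Callable]] = {
    "logsig": (lambda x: expit(x),
               lambda x: expit(x) * (1.0 - expit(x))),
    "tansig": (lambda x: np.tanh(x),
               lambda x: 1.0 - np.tanh(x) ** 2),
    "purelin": (lambda x: np.asarray(x, dtype=float),
                lambda x: np.ones_like(x, dtype=float)),
    "radbas": (lambda x: np.exp(-np.square(x)),
               lambda x: -2.0 * x * np.exp(-np.square(x))),
    "satlins": (lambda x: np.clip(x, -1.0, 1.0),
                lambda x: ((x > -1.0) & (x < 1.0)).astype(float)),
    "hardlim": (lambda x: (x >= 0).astype(float),
                lambda x: np.zeros_like(x, dtype=float)),
    "tribas": (lambda x: np.maximum(0.0, 1.0 - np.abs(x)),
               lambda x: np.where(np.abs(x) < 1.0, -np.sign(x), 0.0)),
    "netinv": (_netinv, _netinv_deriv),
}

TRAIN_METHODS = ("traingd", "traincgb", "trains")
LEARN_METHODS = ("learnh", "learnsom")


class TrainingError(RuntimeError):
    """Non-finite loss encountered during training."""


def transfer(name: str, x):
    """Evaluate a catalog transfer function element-wise."""
    try:
        f, _ = TRANSFER_CATALOG[name]
    except KeyError:
        raise ValueError(
            f"unknown transfer function {name!r}; "
            f"catalog: {sorted(TRANSFER_CATALOG)}"
        ) from None
    return f(np.asarray(x, dtype=float))


def transfer_derivative(name: str, x):
    try:
        _, df = TRANSFER_CATALOG[name]
    except KeyError:
        raise ValueError(f"unknown transfer function {name!r}") from None
    return df(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class AnnConfig:
    """The five ICA-tunable structural parameters of the MLP."""

    n_layers: int
    neurons: tuple[int, ...]
    transfer: tuple[str, ...]
    train_method: str = "traingd"
    learn_method: str = "learnh"

    def __post_init__(self) -> None:
        object.__setattr__(self, "neurons", tuple(int(n) for n in self.neurons))
        object.__setattr__(self, "transfer", tuple(self.transfer))
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if len(self.neurons) != self.n_layers or len(self.transfer) != self.n_layers:
            raise ValueError("neurons and transfer must have n_layers entries")
        if any(n < 1 for n in self.neurons):
            raise ValueError("every layer needs >= 1 neuron")
        for t in self.transfer:
            if t not in TRANSFER_CATALOG:
                raise ValueError(f"unknown transfer function {t!r}")
        if self.train_method not in TRAIN_METHODS:
            raise ValueError(f"train_method must be one of {TRAIN_METHODS}")
        if self.learn_method not in LEARN_METHODS:
            raise ValueError(f"learn_method must be one of {LEARN_METHODS}")


@dataclass
class TrainRecord:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_reason: str = ""


@dataclass
class Network:
    """MLP weights plus the scaling fitted at train time."""

    config: AnnConfig
    weights: list[np.ndarray]   # per layer, shape (n_prev, n_units)
    biases: list[np.ndarray]    # per layer, shape (n_units,)
    n_in: int
    n_out: int
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    y_min: float | None = None
    y_max: float | None = None

    @property
    def fitted(self) -> bool:
        return self.x_min is not None

    def copy(self) -> "Network":
        return Network(self.config, [w.copy() for w in self.weights],
                       [b.copy() for b in self.biases], self.n_in, self.n_out,
                       None if self.x_min is None else self.x_min.copy(),
                       None if self.x_max is None else self.x_max.copy(),
                       self.y_min, self.y_max)

    # transfer name per layer including the linear output layer
    @property
    def layer_transfers(self) -> tuple[str, ...]:
        return tuple(self.config.transfer) + ("purelin",)


def init_network(cfg: AnnConfig, n_in: int, n_out: int, seed: int) -> Network:
    """Reproducible uniform(-0.5, 0.5) weight initialization."""
    if n_in < 1 or n_out < 1:
        raise ValueError("n_in and n_out must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [n_in, *cfg.neurons, n_out]
    weights = [rng.uniform(-0.5, 0.5, size=(sizes[i], sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[i + 1])
              for i in range(len(sizes) - 1)]
    return Network(cfg, weights, biases, n_in, n_out)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def _fit_scaling(net: Network, X: np.ndarray, y: np.ndarray) -> None:
    net.x_min = X.min(axis=0)
    net.x_max = X.max(axis=0)
    net.y_min = float(y.min())
    net.y_max = float(y.max())


def _scale_x(net: Network, X: np.ndarray) -> np.ndarray:
    span = np.where(net.x_max > net.x_min, net.x_max - net.x_min, 1.0)
    return 2.0 * (X - net.x_min) / span - 1.0


def _scale_y(net: Network, y: np.ndarray) -> np.ndarray:
    span = net.y_max - net.y_min if net.y_max > net.y_min else 1.0
    return 2.0 * (y - net.y_min) / span - 1.0


def _unscale_y(net: Network, ys: np.ndarray) -> np.ndarray:
    span = net.y_max - net.y_min if net.y_max > net.y_min else 1.0
    return (ys + 1.0) * span / 2.0 + net.y_min


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward(net: Network, Xs: np.ndarray):
    """Forward pass in scaled space; returns (activations, pre-activations)."""
    acts = [Xs]
    pres = []
    a = Xs
    for W, b, t in zip(net.weights, net.biases, net.layer_transfers):
        z = a @ W + b
        pres.append(z)
        a = TRANSFER_CATALOG[t][0](z)
        acts.append(a)
    return acts, pres


def _loss_and_grads(net: Network, Xs: np.ndarray, ys: np.ndarray):
    """Mean-squared-error loss and its gradients w.r.t. weights and biases."""
    n = Xs.shape[0]
    acts, pres = _forward(net, Xs)
    err = acts[-1][:, 0] - ys
    loss = float(np.mean(err ** 2))
    delta = (2.0 / n) * err[:, None]  # dL/d(output activation)
    gw, gb = [], []
    for li in range(len(net.weights) - 1, -1, -1):
        t = net.layer_transfers[li]
        dz = delta * TRANSFER_CATALOG[t][1](pres[li])
        gw.append(acts[li].T @ dz)
        gb.append(dz.sum(axis=0))
        if li > 0:
            delta = dz @ net.weights[li].T
    return loss, gw[::-1], gb[::-1]


def _flatten(ws, bs):
    return np.concatenate([w.ravel() for w in ws] + [b.ravel() for b in bs])


def _unflatten_into(net: Network, theta: np.ndarray) -> None:
    pos = 0
    for w in net.weights:
        w[...] = theta[pos:pos + w.size].reshape(w.shape)
        pos += w.size
    for b in net.biases:
        b[...] = theta[pos:pos + b.size]
        pos += b.size


def _scaled_mse(net: Network, Xs: np.ndarray, ys: np.ndarray) -> float:
    acts, _ = _forward(net, Xs)
    return float(np.mean((acts[-1][:, 0] - ys) ** 2))


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

def _train_gd(net, Xs, ys, val, max_epochs, lr, patience, record):
    best = (_val_or_train(net, Xs, ys, val), net.copy())
    stall = 0
    for epoch in range(max_epochs):
        loss, gw, gb = _loss_and_grads(net, Xs, ys)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        for W, g in zip(net.weights, gw):
            W -= lr * g
        for b, g in zip(net.biases, gb):
            b -= lr * g
        stall, best, stop = _bookkeep(net, Xs, ys, val, record, best, stall,
                                      patience)
        if stop:
            record.stop_reason = "early_stop"
            break
    else:
        record.stop_reason = "max_epochs"
    return best[1]


def _train_cgb(net, Xs, ys, val, max_epochs, patience, record):
    """Nonlinear CG (Polak-Ribiere) with the Powell-Beale restart test."""
    theta = _flatten(net.weights, net.biases)

    def f_and_g(t):
        _unflatten_into(net, t)
        loss, gw, gb = _loss_and_grads(net, Xs, ys)
        return loss, _flatten(gw, gb)

    loss, g = f_and_g(theta)
    d = -g
    best = (_val_or_train(net, Xs, ys, val), net.copy())
    stall = 0
    for epoch in range(max_epochs):
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        gd = float(g @ d)
        if gd >= 0:  # not a descent direction: restart
            d, gd = -g, -float(g @ g)
            if gd == 0:
                record.stop_reason = "converged"
                break
        alpha = _backtrack(f_and_g, theta, loss, g, d, gd)
        if alpha == 0.0:
            record.stop_reason = "line_search_failed"
            break
        theta = theta + alpha * d
        new_loss, new_g = f_and_g(theta)
        # Powell-Beale restart: successive gradients far from orthogonal
        if abs(float(new_g @ g)) >= 0.2 * float(new_g @ new_g):
            d = -new_g
        else:
            beta = float(new_g @ (new_g - g)) / max(float(g @ g), 1e-300)
            d = -new_g + max(beta, 0.0) * d
        loss, g = new_loss, new_g
        stall, best, stop = _bookkeep(net, Xs, ys, val, record, best, stall,
                                      patience)
        if stop:
            record.stop_reason = "early_stop"
            break
    else:
        record.stop_reason = record.stop_reason or "max_epochs"
    return best[1]


def _backtrack(f_and_g, theta, loss, g, d, gd, max_halvings=30):
    """Armijo backtracking line search; returns step length (0 on failure)."""
    alpha = 1.0
    for _ in range(max_halvings):
        new_loss, _ = f_and_g(theta + alpha * d)
        if np.isfinite(new_loss) and new_loss <= loss + 1e-4 * alpha * gd:
            return alpha
        alpha *= 0.5
    return 0.0


# integer codes for the jitted kernel, order matters
_TRANSFER_CODES = {"logsig": 0, "tansig": 1, "purelin": 2, "radbas": 3,
                   "satlins": 4, "hardlim": 5, "tribas": 6, "netinv": 7}


@_njit(cache=True)
def _tf(code, x):  # pragma: no cover - exercised through the kernel
    if code == 0:
        return 1.0 / (1.0 + np.exp(-x))
    if code == 1:
        return np.tanh(x)
    if code == 2:
        return x
    if code == 3:
        return np.exp(-x * x)
    if code == 4:
        return min(1.0, max(-1.0, x))
    if code == 5:
        return 1.0 if x >= 0.0 else 0.0
    if code == 6:
        return max(0.0, 1.0 - abs(x))
    z = x
    if abs(z) < 1e-12:
        z = 1e-12 if z >= 0 else -1e-12
    v = 1.0 / z
    return min(1e12, max(-1e12, v))


@_njit(cache=True)
def _dtf(code, x):  # pragma: no cover - exercised through the kernel
    if code == 0:
        s = 1.0 / (1.0 + np.exp(-x))
        return s * (1.0 - s)
    if code == 1:
        t = np.tanh(x)
        return 1.0 - t * t
    if code == 2:
        return 1.0
    if code == 3:
        return -2.0 * x * np.exp(-x * x)
    if code == 4:
        return 1.0 if -1.0 < x < 1.0 else 0.0
    if code == 5:
        return 0.0
    if code == 6:
        if abs(x) < 1.0:
            return -1.0 if x > 0 else 1.0
        return 0.0
    z = x
    if abs(z) < 1e-12:
        z = 1e-12 if z >= 0 else -1e-12
    return max(-1e12, min(0.0, -1.0 / (z * z)))


@_njit(cache=True)
def _trains_epoch_jit(theta, sizes, w_off, b_off, codes, X, y, order, lr,
                      decay, acts, pres, deltas):  # pragma: no cover
    n_layers = sizes.shape[0] - 1
    ok = True
    for oi in range(order.shape[0]):
        i = order[oi]
        for j in range(sizes[0]):
            acts[0, j] = X[i, j]
        # forward
        for li in range(n_layers):
            n_in, n_out = sizes[li], sizes[li + 1]
            w0, b0 = w_off[li], b_off[li]
            for k in range(n_out):
                z = theta[b0 + k]
                for j in range(n_in):
                    z += acts[li, j] * theta[w0 + j * n_out + k]
                pres[li, k] = z
                acts[li + 1, k] = _tf(codes[li], z)
        err = acts[n_layers, 0] - y[i]
        if not np.isfinite(err):
            ok = False
            break
        # backward: deltas w.r.t. activations
        deltas[n_layers, 0] = 2.0 * err
        for li in range(n_layers - 1, -1, -1):
            n_in, n_out = sizes[li], sizes[li + 1]
            w0, b0 = w_off[li], b_off[li]
            if li > 0:
                for j in range(n_in):
                    s = 0.0
                    for k in range(n_out):
                        s += (deltas[li + 1, k] * _dtf(codes[li], pres[li, k])
                              * theta[w0 + j * n_out + k])
                    deltas[li, j] = s
            for k in range(n_out):
                dz = deltas[li + 1, k] * _dtf(codes[li], pres[li, k])
                for j in range(n_in):
                    idx = w0 + j * n_out + k
                    theta[idx] -= lr * acts[li, j] * dz + decay * theta[idx]
                theta[b0 + k] -= lr * dz
    return ok


def _run_trains_epoch(net, Xs, ys, order, lr, decay, epoch):
    """One random-order pass over the training set, JIT-ed when available."""
    if _HAVE_NUMBA:
        sizes = np.array([net.n_in, *net.config.neurons, net.n_out],
                         dtype=np.int64)
        codes = np.array([_TRANSFER_CODES[t] for t in net.layer_transfers],
                         dtype=np.int64)
        theta = _flatten(net.weights, net.biases)
        # _flatten layout: all weight blocks, then all bias blocks
        w_off = np.zeros(sizes.size - 1, dtype=np.int64)
        b_off = np.zeros(sizes.size - 1, dtype=np.int64)
        pos = 0
        for li in range(sizes.size - 1):
            w_off[li] = pos
            pos += int(sizes[li] * sizes[li + 1])
        for li in range(sizes.size - 1):
            b_off[li] = pos
            pos += int(sizes[li + 1])
        width = int(sizes.max())
        acts = np.zeros((sizes.size, width))
        pres = np.zeros((sizes.size - 1, width))
        deltas = np.zeros((sizes.size, width))
        ok = _trains_epoch_jit(theta, sizes, w_off, b_off, codes, Xs, ys,
                               order.astype(np.int64), lr, decay,
                               acts, pres, deltas)
        if not ok:
            raise TrainingError(f"non-finite error at epoch {epoch}")
        _unflatten_into(net, theta)
        return
    for i in order:
        x_i = Xs[i:i + 1]
        acts, pres = _forward(net, x_i)
        err = acts[-1][0, 0] - ys[i]
        if not np.isfinite(err):
            raise TrainingError(f"non-finite error at epoch {epoch}")
        delta = np.array([[2.0 * err]])
        for li in range(len(net.weights) - 1, -1, -1):
            t = net.layer_transfers[li]
            dz = delta * TRANSFER_CATALOG[t][1](pres[li])
            if li > 0:
                delta = dz @ net.weights[li].T
            net.weights[li] -= lr * (acts[li].T @ dz) + decay * net.weights[li]
            net.biases[li] -= lr * dz[0]


def _train_incremental(net, Xs, ys, val, max_epochs, lr, patience, record,
                       rng, decay):
    """Random-order per-sample updates (``trains``)."""
    n = Xs.shape[0]
    best = (_val_or_train(net, Xs, ys, val), net.copy())
    stall = 0
    for epoch in range(max_epochs):
        _run_trains_epoch(net, Xs, ys, rng.permutation(n), lr, decay, epoch)
        stall, best, stop = _bookkeep(net, Xs, ys, val, record, best, stall,
                                      patience)
        if stop:
            record.stop_reason = "early_stop"
            break
    else:
        record.stop_reason = "max_epochs"
    return best[1]


def _val_or_train(net, Xs, ys, val):
    if val is not None:
        return _scaled_mse(net, val[0], val[1])
    return _scaled_mse(net, Xs, ys)


def _bookkeep(net, Xs, ys, val, record, best, stall, patience):
    train_mse = _scaled_mse(net, Xs, ys)
    if not np.isfinite(train_mse):
        raise TrainingError(f"non-finite loss at epoch {len(record.train_mse)}")
    record.train_mse.append(train_mse)
    score = train_mse
    if val is not None:
        score = _scaled_mse(net, val[0], val[1])
        record.val_mse.append(score)
    if score < best[0]:
        best = (score, net.copy())
        stall = 0
    else:
        stall += 1
    return stall, best, stall >= patience


def train_network(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    max_epochs: int = 1000,
    lr: float = 0.05,
    patience: int = 20,
    seed: int = 0,
    weight_decay: float = 1e-4,
) -> tuple[Network, TrainRecord]:
    """Train a network; returns (best-validation network, TrainRecord).

    Stops at ``max_epochs`` or when the monitored MSE (validation when a
    split is given, else training) has not improved for ``patience`` epochs.
    The weights achieving the best monitored MSE are returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if X.shape[1] != net.n_in:
        raise ValueError(f"X has {X.shape[1]} columns, network expects {net.n_in}")
    record = TrainRecord()
    if max_epochs == 0:
        record.stop_reason = "max_epochs"
        return net, record

    net = net.copy()
    _fit_scaling(net, X, y)
    Xs, ys = _scale_x(net, X), _scale_y(net, y)
    val_s = None
    if val is not None:
        Xv = np.asarray(val[0], dtype=float)
        yv = np.asarray(val[1], dtype=float).ravel()
        val_s = (_scale_x(net, Xv), _scale_y(net, yv))

    method = net.config.train_method
    if method == "traingd":
        best_net = _train_gd(net, Xs, ys, val_s, max_epochs, lr, patience,
                             record)
    elif method == "traincgb":
        best_net = _train_cgb(net, Xs, ys, val_s, max_epochs, patience, record)
    else:  # trains
        rng = np.random.default_rng(seed)
        decay = weight_decay if net.config.learn_method == "learnh" else 0.0
        best_net = _train_incremental(net, Xs, ys, val_s, max_epochs, lr,
                                      patience, record, rng, decay)
    return best_net, record


def predict(net: Network, X: np.ndarray) -> np.ndarray:
    """Forward pass returning predictions in original target units."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_in:
        raise ValueError(f"expected shape (n, {net.n_in}), got {X.shape}")
    if not net.fitted:
        raise ValueError("network has no fitted scaling; train it first")
    acts, _ = _forward(net, _scale_x(net, X))
    return _unscale_y(net, acts[-1][:, 0])


def network_mse(net: Network, X: np.ndarray, y: np.ndarray) -> float:
    """Mean squared prediction error in original units."""
    y = np.asarray(y, dtype=float).ravel()
    pred = predict(net, X)
    return float(np.mean((pred - y) ** 2))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_network(net: Network, path: str | Path) -> None:
    doc = {
        "config": {
            "n_layers": net.config.n_layers,
            "neurons": list(net.config.neurons),
            "transfer": list(net.config.transfer),
            "train_method": net.config.train_method,
            "learn_method": net.config.learn_method,
        },
        "n_in": net.n_in,
        "n_out": net.n_out,
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "x_min": None if net.x_min is None else net.x_min.tolist(),
        "x_max": None if net.x_max is None else net.x_max.tolist(),
        "y_min": net.y_min,
        "y_max": net.y_max,
    }
    Path(path).write_text(json.dumps(doc))


def load_network(path: str | Path) -> Network:
    doc = json.loads(Path(path).read_text())
    cfg = AnnConfig(
        n_layers=doc["config"]["n_layers"],
        neurons=tuple(doc["config"]["neurons"]),
        transfer=tuple(doc["config"]["transfer"]),
        train_method=doc["config"]["train_method"],
        learn_method=doc["config"]["learn_method"],
    )
    return Network(
        cfg,
        [np.array(w) for w in doc["weights"]],
        [np.array(b) for b in doc["biases"]],
        doc["n_in"], doc["n_out"],
        None if doc["x_min"] is None else np.array(doc["x_min"]),
        None if doc["x_max"] is None else np.array(doc["x_max"]),
        doc["y_min"], doc["y_max"],
    )
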