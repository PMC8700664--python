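"""Train/predict pipeline factories consumed by the evaluation harness."""

from __future__ import annotations

import numpy as np

from .neuralnet import AnnConfig, init_network, predict, train_network
from .plsr import choose_components, fit_plsr, predict_plsr

__all__ = ["make_ann_pipeline", "make_plsr_pipeline"]


def make_ann_pipeline(cfg: AnnConfig, max_epochs: int = 500, lr: float = 0.05,
                      restarts: int = 3):
    """Pipeline that trains ``cfg`` with ``restarts`` seed-dependent
    initializations, early-stops each on the validation split, and keeps the
    restart with the best validation MSE."""
    from .neuralnet import network_mse

    def pipeline(X_tr, y_tr, X_val, y_val, seed):
        best, best_val = None, np.inf
        for k in range(restarts):
            sub_seed = seed * 1000 + k
            net = init_network(cfg, n_in=X_tr.shape[1], n_out=1, seed=sub_seed)
            net, _ = train_network(net, X_tr, y_tr, val=(X_val, y_val),
                                   max_epochs=max_epochs, lr=lr, seed=sub_seed)
            v = network_mse(net, X_val, y_val)
            if v < best_val:
                best_val, best = v, net
        return lambda X: predict(best, X)

    return pipeline


def make_plsr_pipeline(n_components: int | None = None,
                       max_components: int = 10, autoscale: bool = True):
    """Pipeline fitting PLSR on train+validation (PLSR has no early stopping;
    the validation rows would otherwise be wasted). With ``n_components``
    unset, the count is chosen by seeded cross-validation on that data."""

    def pipeline(X_tr, y_tr, X_val, y_val, seed):
        X = np.vstack([X_tr, X_val])
        y = np.concatenate([np.ravel(y_tr), np.ravel(y_val)])
        cap = min(max_components, X.shape[1], X.shape[0] - 1)
        a = n_components if n_components is not None else \
            choose_components(X, y, cap, n_folds=5, seed=seed,
                              autoscale=autoscale)
        m = fit_plsr(X, y, min(a, cap), autoscale=autoscale)
        return lambda Xq: predict_plsr(m, Xq)

    return pipeline
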