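"""A small fully connected network with Adam, trained in plain numpy.

Supports ReLU hidden layers, inverted dropout, mean-squared-error regression
and (class-weighted) softmax cross-entropy classification, early stopping on
a validation split, and a reduce-on-plateau learning-rate schedule.  All
randomness (init, splits, dropout) is driven by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrainConfig:
    lr: float = 1e-3
    max_epochs: int = 1000
    patience: int = 50
    val_frac: float = 0.2
    seed: int = 0
    dropout: float = 0.0
    # reduce-on-plateau schedule
    plateau_factor: float = 0.5
    plateau_window: int = 20
    min_lr: float = 1e-5
    class_weights: np.ndarray | None = None


@dataclass
class FitReport:
    epochs_run: int = 0
    best_epoch: int = 0
    train_loss: float = np.inf
    val_loss: float = np.inf
    history: list[tuple[float, float]] = field(default_factory=list)


class MLP:
    """Fully connected net: linear layers with ReLU between them."""

    def __init__(self, widths: list[int], seed: int = 0):
        self.widths = list(widths)
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            # standard uniform fan-in init
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, fan_out))

    def forward(
        self, X: np.ndarray, dropout: float = 0.0, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Return (output, cache); dropout > 0 requires an rng (training mode)."""
        cache = []
        a = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < last:
                h_act = np.maximum(z, 0.0)
                if dropout > 0.0 and rng is not None:
                    keep = rng.random(h_act.shape) >= dropout
                    h_act = h_act * keep / (1.0 - dropout)
                    cache.append((a, z, keep))
                else:
                    cache.append((a, z, None))
                a = h_act
            else:
                cache.append((a, z, None))
                a = z
        return a, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(np.atleast_2d(np.asarray(X, float)))
        return out

    def backward(self, cache: list, dout: np.ndarray, dropout: float = 0.0
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        grad = dout
        for i in range(len(self.W) - 1, -1, -1):
            a_in, z, keep = cache[i]
            gW[i] = a_in.T @ grad
            gb[i] = grad.sum(axis=0)
            if i > 0:
                grad = grad @ self.W[i].T
                _, z_prev, keep_prev = cache[i - 1]
                if keep_prev is not None:
                    grad = grad * keep_prev / (1.0 - dropout)
                grad = grad * (z_prev > 0)
        return gW, gb

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.W] + [b.copy() for b in self.b]

    def set_weights(self, flat: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [w.copy() for w in flat[:k]]
        self.b = [b.copy() for b in flat[k:]]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _split(n: int, val_frac: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n))) if val_frac > 0 and n > 2 else 0
    return idx[n_val:], idx[:n_val]


def train_regression(
    net: MLP, X: np.ndarray, Y: np.ndarray, cfg: TrainConfig,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitReport:
    """Full-batch Adam on MSE with early stopping and plateau LR decay."""
    X = np.asarray(X, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    rng = np.random.default_rng(cfg.seed)
    tr, va = split if split is not None else _split(X.shape[0], cfg.val_frac, rng)
    if va.size == 0:
        tr, va = np.arange(X.shape[0]), np.arange(X.shape[0])
    opt = _Adam(net.W + net.b, cfg.lr)
    report = FitReport()
    best = net.get_weights()
    best_val = np.inf
    since_improve = 0
    since_plateau = 0
    for epoch in range(1, cfg.max_epochs + 1):
        out, cache = net.forward(X[tr], dropout=cfg.dropout, rng=rng)
        diff = out - Y[tr]
        loss = float(np.mean(diff**2))
        dout = 2.0 * diff / diff.size
        gW, gb = net.backward(cache, dout, dropout=cfg.dropout)
        opt.step(net.W + net.b, gW + gb)

        val_out, _ = net.forward(X[va])
        val_loss = float(np.mean((val_out - Y[va]) ** 2))
        report.history.append((loss, val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best = net.get_weights()
            report.best_epoch = epoch
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
        if since_plateau >= cfg.plateau_window and opt.lr > cfg.min_lr:
            opt.lr = max(opt.lr * cfg.plateau_factor, cfg.min_lr)
            since_plateau = 0
        if since_improve >= cfg.patience:
            break
    net.set_weights(best)
    report.epochs_run = epoch
    report.train_loss = loss
    report.val_loss = best_val
    return report


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_classifier(
    net: MLP, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitReport:
    """Full-batch Adam on class-weighted cross-entropy; early stopping on
    validation accuracy."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n_classes = net.widths[-1]
    w = cfg.class_weights if cfg.class_weights is not None else np.ones(n_classes)
    rng = np.random.default_rng(cfg.seed)
    tr, va = split if split is not None else _split(X.shape[0], cfg.val_frac, rng)
    if va.size == 0:
        tr, va = np.arange(X.shape[0]), np.arange(X.shape[0])
    opt = _Adam(net.W + net.b, cfg.lr)
    report = FitReport()
    best = net.get_weights()
    best_acc = -np.inf
    since_improve = 0
    since_plateau = 0
    onehot = np.eye(n_classes)[y]
    sw = w[y]  # per-sample weights
    for epoch in range(1, cfg.max_epochs + 1):
        logits, cache = net.forward(X[tr], dropout=cfg.dropout, rng=rng)
        p = _softmax(logits)
        eps = 1e-12
        loss = float(-np.sum(sw[tr] * np.log(p[np.arange(tr.size), y[tr]] + eps)) / sw[tr].sum())
        dlogits = (p - onehot[tr]) * sw[tr][:, None] / sw[tr].sum()
        gW, gb = net.backward(cache, dlogits, dropout=cfg.dropout)
        opt.step(net.W + net.b, gW + gb)

        val_logits, _ = net.forward(X[va])
        val_acc = float(np.mean(val_logits.argmax(axis=1) == y[va]))
        report.history.append((loss, -val_acc))
        if val_acc > best_acc + 1e-12:
            best_acc = val_acc
            best = net.get_weights()
            report.best_epoch = epoch
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
        if since_plateau >= cfg.plateau_window and opt.lr > cfg.min_lr:
            opt.lr = max(opt.lr * cfg.plateau_factor, cfg.min_lr)
            since_plateau = 0
        if since_improve >= cfg.patience:
            break
    net.set_weights(best)
    report.epochs_run = epoch
    report.train_loss = loss
    report.val_loss = -best_acc
    return report
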