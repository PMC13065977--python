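"""Parametric embedding ψ: a feed-forward approximation of the t-SNE map.

t-SNE has no out-of-sample transform, so a small network (150 -> 128 -> 64
-> 2, ReLU after the hidden layers) is trained by MSE to reproduce the
embedding coordinates of the training colonies.  Simulated and
structure-predicted phenotypes can then be projected into the frozen
experimental morphospace.  Agreement between a predicted and a true point
cloud is scored with the Jensen-Shannon divergence between their KDE
densities on a shared grid (natural log, so the maximum is ln 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import MLP, FitReport, TrainConfig, train_regression
from .records import PhenotypeVector

_WIDTHS = [150, 128, 64, 2]


@dataclass
class EmbeddingNet:
    """Trained ψ plus its training configuration and fit report.

    Coordinates are standardized internally during training; ``project``
    returns values on the original embedding scale.
    """

    net: MLP
    coord_mean: np.ndarray
    coord_scale: np.ndarray
    training_config: TrainConfig
    fit_report: FitReport

    def save(self, path: str) -> None:
        np.savez_compressed(
            path if path.endswith(".npz") else path + ".npz",
            *self.net.W,
            *self.net.b,
            coord_mean=self.coord_mean,
            coord_scale=self.coord_scale,
        )
        base = path[:-4] if path.endswith(".npz") else path
        cfg = self.training_config
        with open(base + ".json", "w") as fh:
            json.dump(
                {
                    "widths": self.net.widths,
                    "lr": cfg.lr,
                    "max_epochs": cfg.max_epochs,
                    "patience": cfg.patience,
                    "val_frac": cfg.val_frac,
                    "seed": cfg.seed,
                    "epochs_run": self.fit_report.epochs_run,
                    "val_loss": self.fit_report.val_loss,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str) -> "EmbeddingNet":
        base = path[:-4] if path.endswith(".npz") else path
        data = np.load(base + ".npz")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        net = MLP(meta["widths"])
        k = len(net.W)
        flat = [data[f"arr_{i}"] for i in range(2 * k)]
        net.set_weights(flat)
        cfg = TrainConfig(
            lr=meta["lr"], max_epochs=meta["max_epochs"], patience=meta["patience"],
            val_frac=meta["val_frac"], seed=meta["seed"],
        )
        rep = FitReport(epochs_run=meta["epochs_run"], val_loss=meta["val_loss"])
        return cls(net=net, coord_mean=data["coord_mean"], coord_scale=data["coord_scale"],
                   training_config=cfg, fit_report=rep)


def train_embedding(
    vectors: np.ndarray | list[PhenotypeVector],
    tsne_coords: np.ndarray,
    config: TrainConfig | None = None,
) -> EmbeddingNet:
    """Fit ψ to (scaled phenotype vector, t-SNE coordinate) pairs.

    80/20 train/validation split, Adam (lr 0.001), MSE loss, up to 1000
    epochs with early stopping (patience 50) and a reduce-on-plateau
    learning-rate schedule; deterministic given the config seed.
    """
    X = _as_matrix(vectors)
    Y = np.asarray(tsne_coords, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("vectors and coordinates must have matching row counts")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training rows")
    cfg = config or TrainConfig()
    mean = Y.mean(axis=0)
    scale = Y.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    net = MLP(_WIDTHS, seed=cfg.seed)
    report = train_regression(net, X, (Y - mean) / scale, cfg)
    return EmbeddingNet(net=net, coord_mean=mean, coord_scale=scale,
                        training_config=cfg, fit_report=report)


def project(embedding: EmbeddingNet, vector: np.ndarray | PhenotypeVector) -> np.ndarray:
    """Project one or more 150-d vectors to 2-D morphospace coordinates."""
    X = _as_matrix(vector)
    if X.shape[1] != _WIDTHS[0]:
        raise ValueError(f"input must have {_WIDTHS[0]} features, got {X.shape[1]}")
    out = embedding.net.predict(X) * embedding.coord_scale + embedding.coord_mean
    return out[0] if X.shape[0] == 1 and not isinstance(vector, (list, np.ndarray)) else out


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, PhenotypeVector):
        return vectors.values[None, :]
    if isinstance(vectors, list) and vectors and isinstance(vectors[0], PhenotypeVector):
        return np.stack([v.values for v in vectors])
    arr = np.asarray(vectors, float)
    return arr[None, :] if arr.ndim == 1 else arr


def jsd_density(
    pred_coords: np.ndarray,
    true_coords: np.ndarray,
    grid_size: int = 128,
    bandwidth_factor: float = 1.0,
) -> float:
    """Jensen-Shannon divergence between the KDE densities of two clouds.

    Both densities are evaluated on one shared grid with the bandwidth of
    the true cloud; natural-log base, so the value lies in [0, ln 2].
    """
    P = np.asarray(pred_coords, float)
    Q = np.asarray(true_coords, float)
    allpts = np.vstack([P, Q])
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo, hi = lo - 0.05 * span, hi + 0.05 * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    mx, my = np.meshgrid(gx, gy)
    grid = np.column_stack([mx.ravel(), my.ravel()])
    # isotropic Gaussian KDE with one shared bandwidth (Scott's rule on the
    # true cloud), so the two densities are directly comparable
    h_bw = bandwidth_factor * Q.shape[0] ** (-1.0 / 6.0) * float(Q.std(axis=0).mean())
    h_bw = max(h_bw, 1e-9)

    from scipy.spatial.distance import cdist
    from scipy.special import logsumexp

    def _density(pts: np.ndarray) -> np.ndarray:
        # normalized in log space so widely separated clouds don't underflow
        d2 = cdist(grid, pts, "sqeuclidean")
        logp = logsumexp(-0.5 * d2 / h_bw**2, axis=1)
        return np.exp(logp - logsumexp(logp))

    p = _density(P)
    q = _density(Q)
    m = 0.5 * (p + q)

    def _kl(a, b):
        nz = a > 0
        return float(np.sum(a[nz] * np.log(a[nz] / b[nz])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def evaluate_embedding(
    embedding: EmbeddingNet,
    vectors: np.ndarray | list[PhenotypeVector],
    true_coords: np.ndarray,
) -> dict:
    """Score ψ against true coordinates: JSD plus per-point errors."""
    X = _as_matrix(vectors)
    Y = np.asarray(true_coords, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("vectors and coordinates must have matching row counts")
    pred = project(embedding, X)
    err = np.linalg.norm(pred - Y, axis=1)
    return {
        "jsd": jsd_density(pred, Y),
        "per_point_error": err,
        "median_error": float(np.median(err)),
        "mean_error": float(err.mean()),
    }
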