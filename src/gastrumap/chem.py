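"""Structure-to-phenotype prediction and teratogenicity scoring.

A two-stage model maps a 768-d molecular embedding to a 150-d phenotype:

1. a classifier (768 -> 512 -> 256 -> clusters, ReLU + dropout, linear
   output) trained with class-weighted cross-entropy (extra weight on
   failure-mode clusters), 5-fold cross-validation with early stopping on
   validation accuracy, final assignments from fold-averaged logits;
2. per-cluster ridge regressions predicting the residual between the
   cluster-mean phenotype and the observed one; the prediction is
   cluster mean + predicted residual.

Molecular embeddings come from a pluggable backend.  The shipped
deterministic fallback hashes character 3-grams of the SMILES string into
4096 bins and projects them to 768-d with a seeded Gaussian random matrix;
a transformer backend hook exists for externally supplied weights.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .nn import MLP, TrainConfig, train_classifier
from .records import CompoundRecord, PhenotypeVector

EMBED_DIM = 768
_HASH_BINS = 4096
_PROJECTIONS: dict[int, np.ndarray] = {}


def _projection(seed: int) -> np.ndarray:
    if seed not in _PROJECTIONS:
        rng = np.random.default_rng(seed)
        _PROJECTIONS[seed] = rng.normal(0.0, 1.0 / np.sqrt(_HASH_BINS), (_HASH_BINS, EMBED_DIM))
    return _PROJECTIONS[seed]


def embed_molecule(smiles: str, backend: str = "fallback", seed: int = 0) -> np.ndarray:
    """Embed a SMILES string into a 768-d vector.

    ``fallback`` is fully deterministic per (smiles, seed) and needs no
    external weights; ``transformer`` requires a pretrained chemistry
    language model, which must be supplied by the user.
    """
    if not smiles:
        raise ValueError("SMILES string must be non-empty")
    if backend == "fallback":
        counts = np.zeros(_HASH_BINS)
        padded = f"^{smiles}$"
        for i in range(len(padded) - 2):
            gram = padded[i : i + 3]
            idx = int.from_bytes(hashlib.md5(gram.encode()).digest()[:4], "little") % _HASH_BINS
            counts[idx] += 1.0
        return counts @ _projection(seed)
    if backend == "transformer":
        raise RuntimeError(
            "the transformer backend requires externally supplied pretrained "
            "weights; use backend='fallback' for a deterministic, "
            "dependency-free embedding"
        )
    raise ValueError(f"unknown backend {backend!r}; available: fallback, transformer")


@dataclass
class PredictorConfig:
    lr: float = 1e-3
    max_epochs: int = 300
    patience: int = 30
    n_folds: int = 5
    holdout_frac: float = 0.1
    dropout: float = 0.3
    ridge_alpha: float = 1.0
    failure_weight: float = 3.0  # cost-sensitive weight on failure clusters
    seed: int = 0


@dataclass
class StructureModel:
    """Trained two-stage structure-to-phenotype model."""

    fold_models: list[MLP]
    cluster_ids: list[int]
    cluster_means: dict[int, np.ndarray]
    ridges: dict[int, Ridge | None]
    holdout_ids: list[str]
    training_ids: list[str]
    failure_clusters: set[int]
    config: PredictorConfig

    def logits(self, embeddings: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(embeddings, float))
        return np.mean([m.predict(X) for m in self.fold_models], axis=0)


def train_structure_model(
    records: list[CompoundRecord],
    config: PredictorConfig | None = None,
    failure_clusters: set[int] | None = None,
) -> StructureModel:
    """Train the classifier (5-fold, fold-averaged logits) and ridge stages.

    Ten percent of the compounds are held out (seeded) as a blind test set
    and never touched during training.  Ridge residual models are fit per
    cluster on all training compounds of that cluster; a single-member
    cluster degenerates to a zero-residual model with a warning.
    """
    cfg = config or PredictorConfig()
    labeled = [r for r in records if r.cluster_label is not None]
    classes = sorted({r.cluster_label for r in labeled})
    if len(classes) < 2:
        raise ValueError("need at least 2 clusters to train")
    failure = failure_clusters or set()
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(labeled))
    n_hold = int(round(cfg.holdout_frac * len(labeled)))
    hold_idx = set(order[:n_hold].tolist())
    train_recs = [labeled[i] for i in range(len(labeled)) if i not in hold_idx]
    hold_recs = [labeled[i] for i in sorted(hold_idx)]
    if len(train_recs) < cfg.n_folds:
        raise ValueError("too few compounds for the requested fold count")

    class_index = {c: i for i, c in enumerate(classes)}
    X = np.stack([r.embedding for r in train_recs])
    y = np.array([class_index[r.cluster_label] for r in train_recs])
    weights = np.array([cfg.failure_weight if c in failure else 1.0 for c in classes])

    fold_models: list[MLP] = []
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    for fold, (tr, va) in enumerate(kf.split(X)):
        net = MLP([EMBED_DIM, 512, 256, len(classes)], seed=cfg.seed + 100 + fold)
        tc = TrainConfig(
            lr=cfg.lr, max_epochs=cfg.max_epochs, patience=cfg.patience,
            seed=cfg.seed + fold, dropout=cfg.dropout, class_weights=weights,
        )
        # early stopping monitors the fold-out split
        train_classifier(net, X, y, tc, split=(tr, va))
        fold_models.append(net)

    cluster_means: dict[int, np.ndarray] = {}
    ridges: dict[int, Ridge | None] = {}
    for c in classes:
        members = [r for r in train_recs if r.cluster_label == c]
        if not members:
            members = [r for r in labeled if r.cluster_label == c]
        phen = np.stack([r.centroid_phenotype.values for r in members])
        cluster_means[c] = phen.mean(axis=0)
        if len(members) < 2:
            warnings.warn(
                f"cluster {c} has a single member; ridge degenerates to zero residual",
                stacklevel=2,
            )
            ridges[c] = None
            continue
        emb = np.stack([r.embedding for r in members])
        resid = phen - cluster_means[c]
        model = Ridge(alpha=cfg.ridge_alpha)
        model.fit(emb, resid)
        ridges[c] = model

    return StructureModel(
        fold_models=fold_models,
        cluster_ids=classes,
        cluster_means=cluster_means,
        ridges=ridges,
        holdout_ids=[r.compound_id for r in hold_recs],
        training_ids=[r.compound_id for r in train_recs],
        failure_clusters=failure,
        config=cfg,
    )


def predict_phenotype(
    model: StructureModel,
    embedding: np.ndarray,
    embedding_net=None,
    morphospace_model=None,
) -> tuple[PhenotypeVector, int, np.ndarray | None]:
    """Predict (phenotype vector, cluster, morphospace coordinate).

    Cluster = argmax of fold-averaged logits; phenotype = cluster mean +
    that cluster's ridge residual; the coordinate is computed when a
    parametric embedding net is supplied (and the region is available via
    ``morphospace.assign_region`` on the returned coordinate).
    """
    emb = np.asarray(embedding, float).ravel()
    if emb.size != EMBED_DIM:
        raise ValueError(f"embedding must be {EMBED_DIM}-d")
    logits = model.logits(emb[None, :])[0]
    cluster = model.cluster_ids[int(np.argmax(logits))]
    pheno = model.cluster_means[cluster].copy()
    ridge = model.ridges.get(cluster)
    if ridge is not None:
        pheno = pheno + ridge.predict(emb[None, :])[0]
    vec = PhenotypeVector(pheno, provenance="predicted")
    coord = None
    if embedding_net is not None:
        from .embedding import project

        coord = np.atleast_2d(project(embedding_net, pheno))[0]
    return vec, cluster, coord


@dataclass
class PredictionMetrics:
    rmse: float
    cosine_similarity: float
    frac_within_1sd: float | None


def score_prediction(
    pred: PhenotypeVector, replicates: list[PhenotypeVector]
) -> PredictionMetrics:
    """Score a predicted phenotype against a compound's replicate profiles.

    RMSE and cosine similarity are computed against the replicate mean;
    ``frac_within_1sd`` is the fraction of the 150 features whose prediction
    lies within one replicate standard deviation of the replicate mean
    (undefined with a single replicate).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    R = np.stack([r.values for r in replicates])
    mean = R.mean(axis=0)
    p = pred.values
    rmse = float(np.sqrt(np.mean((p - mean) ** 2)))
    denom = np.linalg.norm(p) * np.linalg.norm(mean)
    cos = float(p @ mean / denom) if denom > 0 else 0.0
    frac = None
    if R.shape[0] >= 2:
        sd = R.std(axis=0, ddof=1)
        ok = np.abs(p - mean) <= sd
        frac = float(ok.mean())
    return PredictionMetrics(rmse=rmse, cosine_similarity=cos, frac_within_1sd=frac)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    balanced_accuracy: float
    precision: float
    sensitivity: float
    specificity: float


def confusion_metrics(calls: list[bool], truth: list[bool]) -> ConfusionSummary:
    """Binary confusion counts and the five derived fractions."""
    if len(calls) == 0 or len(calls) != len(truth):
        raise ValueError("calls and truth must be non-empty and aligned")
    c = np.asarray(calls, bool)
    t = np.asarray(truth, bool)
    tp = int(np.sum(c & t))
    fp = int(np.sum(c & ~t))
    fn = int(np.sum(~c & t))
    tn = int(np.sum(~c & ~t))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return ConfusionSummary(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / len(calls),
        balanced_accuracy=0.5 * (sens + spec),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        sensitivity=sens,
        specificity=spec,
    )
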