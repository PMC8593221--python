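"""The twin network, contrastive loss and training loop.

Two identical fully connected subnetworks share one set of weights W and map
a pair of scaled expression vectors (X1, X2) into a low-dimensional
embedding.  A distance layer computes the Euclidean distance

    D_w(X1, X2) = sqrt( sum_i (f(X1)_i - f(X2)_i)^2 )

and the contrastive loss, with Y = 1 for a same-type pair,

    L(Y, D_w) = Y * 1/2 * D_w^2 + (1 - Y) * 1/2 * max(0, margin - D_w)^2

pulls similar pairs together and pushes dissimilar pairs apart up to the
margin.  The default subnetwork is input -> 512 -> 512 -> 32 with rectified
linear hidden units and dropout 0.5 after each hidden layer (training mode
only); inference is deterministic.

The forward/backward passes and the RMSprop update are implemented directly
on numpy arrays: the network is small (a few hundred thousand parameters at
typical gene-panel sizes) and dense matrix products dominate, so this keeps
the training loop dependency-light, single-threaded-reproducible, and easy
to verify against finite differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import PairSet, ScaledMatrix

logger = logging.getLogger(__name__)

_DIST_EPS = 1e-12  # guards the sqrt gradient at zero distance during training


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the shared subnetwork."""

    input_dim: int
    hidden_widths: tuple[int, ...] = (512, 512)
    embedding_dim: int = 32
    dropout_rate: float = 0.5
    activation: str = "relu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_widths", tuple(self.hidden_widths))
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_dim, *self.hidden_widths, self.embedding_dim]

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum(i * o + o for i, o in zip(sizes[:-1], sizes[1:]))


@dataclass
class TrainConfig:
    """Optimization settings for contrastive training.

    ``margin`` is the distance beyond which dissimilar pairs incur no loss;
    ``accuracy_threshold`` is the distance below which a pair is called
    same-type when computing Siamese accuracy (the 0.5 default sits at
    margin/2).
    """

    margin: float = 1.0
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    optimizer: str = "rmsprop"
    accuracy_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.accuracy_threshold <= 0:
            raise ValueError("accuracy_threshold must be > 0")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainedModel:
    """Shared subnetwork weights plus everything needed to reuse them."""

    spec: NetworkSpec
    weights: list[tuple[np.ndarray, np.ndarray]]
    gene_space: tuple[str, ...] | None = None
    config: TrainConfig | None = None
    history: pd.DataFrame | None = None
    best_epoch: int | None = None

    def copy_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(W.copy(), b.copy()) for W, b in self.weights]


@dataclass
class EmbeddingMatrix:
    """Cells x embedding_dim coordinates, linked to source cell ids."""

    values: np.ndarray
    cell_ids: list[str]


def build_network(spec: NetworkSpec, seed: int = 0) -> TrainedModel:
    """Initialize the shared subnetwork reproducibly (Glorot-uniform)."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return TrainedModel(spec=spec, weights=weights)


# ---------------------------------------------------------------------------
# forward / backward


def _forward(
    model: TrainedModel,
    X: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Forward pass; in training mode applies inverted dropout after each
    hidden activation and returns the caches needed for backprop."""
    p = model.spec.dropout_rate
    n_layers = len(model.weights)
    h = X
    caches = []
    for i, (W, b) in enumerate(model.weights):
        z = h @ W + b
        if i < n_layers - 1:
            a = np.maximum(z, 0.0)
            mask = None
            if train and p > 0.0:
                mask = (rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
        else:
            a, mask = z, None
        caches.append((h, z, mask))
        h = a
    return h, caches


def _backward(model: TrainedModel, caches, grad_out: np.ndarray):
    """Backprop a gradient w.r.t. the embedding through the subnetwork."""
    n_layers = len(model.weights)
    grads = [None] * n_layers
    g = grad_out
    for i in range(n_layers - 1, -1, -1):
        h, z, mask = caches[i]
        if i < n_layers - 1:
            if mask is not None:
                g = g * mask
            g = g * (z > 0)
        W, _ = model.weights[i]
        grads[i] = (h.T @ g, g.sum(axis=0))
        if i > 0:
            g = g @ W.T
    return grads


def embed(model: TrainedModel, x: "ScaledMatrix | np.ndarray") -> EmbeddingMatrix:
    """Map scaled expression vectors into the embedding space.

    Deterministic: dropout is disabled, identical input gives identical
    output.  If *x* is a ScaledMatrix its gene order must match the model's
    gene space exactly.
    """
    if isinstance(x, ScaledMatrix):
        if model.gene_space is not None and tuple(x.gene_ids) != tuple(model.gene_space):
            raise ValueError(
                "query gene space does not match the model's; run "
                "align_to_gene_space on the counts before scaling"
            )
        values, cell_ids = x.values, list(x.cell_ids)
    else:
        values = np.asarray(x, dtype=np.float64)
        cell_ids = [str(i) for i in range(values.shape[0])]
    if values.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"input has {values.shape[1]} genes but the network expects "
            f"{model.spec.input_dim}; run align_to_gene_space first"
        )
    out, _ = _forward(model, values, train=False)
    return EmbeddingMatrix(out, cell_ids)


def pair_distance(e1: np.ndarray, e2: np.ndarray) -> np.ndarray | float:
    """Euclidean distance between embedding vectors (or row-paired matrices)."""
    e1 = np.asarray(e1, dtype=np.float64)
    e2 = np.asarray(e2, dtype=np.float64)
    if e1.shape != e2.shape:
        raise ValueError(f"dimension mismatch: {e1.shape} vs {e2.shape}")
    d = np.sqrt(((e1 - e2) ** 2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


def contrastive_loss(y, d, margin: float = 1.0):
    """Mean contrastive loss over pairs; Y=1 means the pair is same-type."""
    y = np.asarray(y, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if margin <= 0:
        raise ValueError("margin must be > 0")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("pair labels must be 0 or 1")
    per_pair = y * 0.5 * d**2 + (1.0 - y) * 0.5 * np.maximum(0.0, margin - d) ** 2
    return float(np.mean(per_pair))


def siamese_accuracy(labels, distances, threshold: float = 0.5) -> float:
    """Fraction of pairs where (D < threshold) agrees with (Y = 1).

    The comparison is strict: a pair sitting exactly at the threshold is
    called different-type.
    """
    labels = np.asarray(labels)
    distances = np.asarray(distances, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("cannot compute accuracy of zero pairs")
    if labels.shape != distances.shape:
        raise ValueError("labels and distances must have equal length")
    return float(np.mean((distances < threshold) == (labels == 1)))


# ---------------------------------------------------------------------------
# training


class _RMSProp:
    """Keras-style RMSprop: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, params_like, lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [
            (np.zeros_like(W), np.zeros_like(b)) for W, b in params_like
        ]

    def step(self, weights, grads) -> None:
        for i, ((W, b), (gW, gb), (cW, cb)) in enumerate(
            zip(weights, grads, self.cache)
        ):
            cW *= self.rho
            cW += (1 - self.rho) * gW**2
            cb *= self.rho
            cb += (1 - self.rho) * gb**2
            W -= self.lr * gW / (np.sqrt(cW) + self.eps)
            b -= self.lr * gb / (np.sqrt(cb) + self.eps)


def _batch_loss_and_grads(model, Xa, Xb, y, margin, rng):
    """One Siamese forward/backward: both branches share weights, so the
    per-branch gradients are summed."""
    ea, ca = _forward(model, Xa, train=True, rng=rng)
    eb, cb = _forward(model, Xb, train=True, rng=rng)
    diff = ea - eb
    d = np.sqrt(np.maximum(_DIST_EPS, (diff**2).sum(axis=1)))
    hinge = np.maximum(0.0, margin - d)
    per_pair = y * 0.5 * d**2 + (1.0 - y) * 0.5 * hinge**2
    loss = float(per_pair.mean())
    # dL/d(ea) = [Y - (1-Y) * hinge / D] * diff / n
    coef = (y - (1.0 - y) * hinge / d)[:, None] / len(y)
    ga = _backward(model, ca, coef * diff)
    gb = _backward(model, cb, -coef * diff)
    grads = [(gWa + gWb, gba + gbb) for (gWa, gba), (gWb, gbb) in zip(ga, gb)]
    return loss, grads


def _pairset_distances(model, x_values, pairs: PairSet) -> np.ndarray:
    emb, _ = _forward(model, x_values, train=False)
    return np.sqrt(((emb[pairs.idx_a] - emb[pairs.idx_b]) ** 2).sum(axis=1))


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    np.savez(
        Path(path),
        **{f"W{i}": W for i, (W, _) in enumerate(model.weights)},
        **{f"b{i}": b for i, (_, b) in enumerate(model.weights)},
    )


def load_checkpoint(path: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    with np.load(Path(path)) as z:
        n = sum(1 for k in z.files if k.startswith("W"))
        return [(z[f"W{i}"].copy(), z[f"b{i}"].copy()) for i in range(n)]


def train(
    model: TrainedModel,
    x: ScaledMatrix,
    train_pairs: PairSet,
    val_pairs: PairSet,
    cfg: TrainConfig,
    checkpoint_dir: str | Path | None = None,
) -> TrainedModel:
    """Contrastive training with per-epoch checkpointing and best-epoch
    selection.

    Each epoch shuffles the pair order, runs minibatch RMSprop updates, then
    evaluates (in inference mode) the Siamese accuracy on the train and
    validation pair sets.  Weights are saved every epoch when a checkpoint
    directory is given.  The returned model carries the weights of the epoch
    with the highest validation accuracy (ties broken toward the earliest
    epoch), the full history, and the selected epoch number.

    Fully reproducible from ``cfg.seed``, which drives both the shuffling
    and the dropout masks.
    """
    if model.gene_space is not None and tuple(x.gene_ids) != tuple(model.gene_space):
        raise ValueError("scaled matrix gene order does not match the model gene space")
    values = np.asarray(x.values, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    opt = _RMSProp(model.weights, lr=cfg.learning_rate)
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)

    n_pairs = len(train_pairs)
    history_rows = []
    best_acc = -np.inf
    best_weights = model.copy_weights()
    best_epoch = 0

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n_pairs)
        epoch_losses = []
        for start in range(0, n_pairs, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            Xa = values[train_pairs.idx_a[sel]]
            Xb = values[train_pairs.idx_b[sel]]
            y = train_pairs.labels[sel].astype(np.float64)
            loss, grads = _batch_loss_and_grads(model, Xa, Xb, y, cfg.margin, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; try a smaller "
                    f"learning rate (current {cfg.learning_rate})"
                )
            opt.step(model.weights, grads)
            epoch_losses.append(loss)

        train_d = _pairset_distances(model, values, train_pairs)
        val_d = _pairset_distances(model, values, val_pairs)
        train_acc = siamese_accuracy(train_pairs.labels, train_d, cfg.accuracy_threshold)
        val_acc = siamese_accuracy(val_pairs.labels, val_d, cfg.accuracy_threshold)
        history_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "train_acc": train_acc,
                "val_acc": val_acc,
            }
        )
        if ckpt is not None:
            save_checkpoint(model, ckpt / f"epoch_{epoch:04d}.npz")
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.copy_weights()
            best_epoch = epoch

    model.weights = best_weights
    model.best_epoch = best_epoch
    model.config = cfg
    model.history = pd.DataFrame(history_rows)
    if model.gene_space is None:
        model.gene_space = tuple(x.gene_ids)
    logger.info(
        "training done: best epoch %d, val accuracy %.3f", best_epoch, best_acc
    )
    if ckpt is not None:
        model.history.to_csv(ckpt / "history.tsv", sep="\t", index=False)
    return model
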