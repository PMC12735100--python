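"""Split protocol, momentum-SGD training loop, and model evaluation.

The split follows the two-stage protocol: 80% of the data is set aside for
training and 20% for testing, then the training part is split again 80/20
into train and validation, yielding 64% / 16% / 20% overall. Both stages use
per-class stratification by default (floor rounding, remainder to train), so
even a 177-sample class keeps proportional representation in every
partition.

Training minimizes cross-entropy with stochastic gradient descent with
momentum (SGDM) at a constant learning rate — defaults: 30 epochs, batch
size 128, learning rate 0.01, momentum 0.9, weight decay 1e-4. An optional
class-aware sampler composes each mini-batch with a near-uniform class mix,
which counteracts the strong class imbalance; it is off by default. Given a
seed, shuffling, sampling and initialization are fully deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .architecture import MACNeXt, PredictionBatch, save_checkpoint
from .config import TrainConfig
from .evaluation import ConfusionMatrix, MetricsReport, evaluate_predictions

__all__ = [
    "ArrayDataset",
    "SplitAssignment",
    "split_dataset",
    "train_model",
    "evaluate_model",
    "TrainLog",
]

PARTITIONS = ("train", "val", "test")


@dataclass
class ArrayDataset:
    """In-memory labeled image set: (N, C, H, W) float32 in [0, 1]."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels must have matching length")
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise ValueError("label index exceeds class_names")

    def __len__(self) -> int:
        return int(self.images.shape[0])


@dataclass
class SplitAssignment:
    """Per-sample partition labels in {train, val, test}."""

    partition: np.ndarray  # array of strings
    stratified: bool = True

    def indices(self, name: str) -> np.ndarray:
        if name not in PARTITIONS:
            raise ValueError(f"unknown partition {name!r}")
        return np.nonzero(self.partition == name)[0]

    def counts(self) -> dict[str, int]:
        return {p: int((self.partition == p).sum()) for p in PARTITIONS}


def _two_stage_sizes(n: int, cfg: TrainConfig) -> tuple[int, int, int]:
    """Floor-then-remainder-to-train rounding of the two-stage 80/20 split."""
    n_test = int(np.floor(n * cfg.test_fraction + 1e-9))
    n_trainval = n - n_test
    val_of_trainval = cfg.val_fraction / (cfg.train_fraction + cfg.val_fraction)
    n_val = int(np.floor(n_trainval * val_of_trainval + 1e-9))
    n_train = n_trainval - n_val
    return n_train, n_val, n_test


def split_dataset(labels: np.ndarray, config: TrainConfig, class_names=None) -> SplitAssignment:
    """Deterministic, stratified-by-default train/val/test assignment."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    rng = np.random.default_rng(config.seed)
    partition = np.empty(n, dtype=object)
    if config.stratified:
        for c in np.unique(labels):
            idx = np.nonzero(labels == c)[0]
            if idx.size < 5:
                name = class_names[c] if class_names is not None else c
                raise ValueError(
                    f"class {name!r} has only {idx.size} samples; "
                    "stratified splitting needs at least 5"
                )
            idx = rng.permutation(idx)
            n_train, n_val, n_test = _two_stage_sizes(idx.size, config)
            partition[idx[:n_test]] = "test"
            partition[idx[n_test : n_test + n_val]] = "val"
            partition[idx[n_test + n_val :]] = "train"
    else:
        idx = rng.permutation(n)
        n_train, n_val, n_test = _two_stage_sizes(n, config)
        partition[idx[:n_test]] = "test"
        partition[idx[n_test : n_test + n_val]] = "val"
        partition[idx[n_test + n_val :]] = "train"
    return SplitAssignment(partition.astype(str), stratified=config.stratified)


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def to_csv(self, path: str | Path) -> None:
        if not self.epochs:
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.epochs[0]))
            writer.writeheader()
            writer.writerows(self.epochs)


def _softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = nn.softmax(logits, axis=1)
    m = y.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.mean(np.log(p[np.arange(m), y] + eps)))
    d = p.copy()
    d[np.arange(m), y] -= 1.0
    return loss, d / m


def _balanced_order(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round-robin over classes so every batch holds a near-uniform class mix."""
    classes = np.unique(labels)
    pools = [rng.permutation(np.nonzero(labels == c)[0]).tolist() for c in classes]
    n = labels.shape[0]
    order = []
    k = 0
    while len(order) < n:
        pool = pools[k % len(pools)]
        if pool:
            order.append(pool.pop())
        k += 1
        if all(not p for p in pools):
            break
    return np.asarray(order, dtype=np.int64)


def _sgdm_step(model: MACNeXt, velocity: list[np.ndarray], cfg: TrainConfig) -> None:
    for p, v in zip(model.parameters(), velocity):
        g = p.grad
        if cfg.weight_decay:
            g = g + cfg.weight_decay * p.data
        v *= cfg.momentum
        v -= cfg.learning_rate * g
        p.data += v


def _partition_metrics(model: MACNeXt, x: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    """Inference-mode mean loss and accuracy."""
    losses, correct = [], 0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward_logits(xb, training=False)
        loss, _ = _softmax_xent(logits, yb)
        losses.append(loss * yb.size)
        correct += int((logits.argmax(axis=1) == yb).sum())
    n = x.shape[0]
    return float(np.sum(losses) / n), correct / n


def recalibrate_batchnorm(model: MACNeXt, images: np.ndarray, batch_size: int = 128) -> None:
    """Replace BN running statistics with population statistics.

    Runs the given images forward in training mode with frozen weights and
    sets every BN layer's running mean/variance to the simple average of the
    per-batch statistics. Mini-batch running averages lag the weights during
    optimization; evaluating with population statistics removes that lag
    (the convention of ``BatchNormalizationStatistics="population"`` in the
    protocol's reference training environment).
    """
    bns = [
        layer
        for mod in model.modules()
        for layer in mod.layers()
        if isinstance(layer, nn.BatchNorm2d)
    ]
    sums = [None] * len(bns)
    n_batches = 0
    saved = [(bn.momentum,) for bn in bns]
    try:
        for i in range(0, images.shape[0], batch_size):
            for bn in bns:
                bn.momentum = 1.0  # running stats := this batch's stats
            model.forward_logits(images[i : i + batch_size], training=True)
            n_batches += 1
            for j, bn in enumerate(bns):
                pair = np.stack([bn.running_mean, bn.running_var])
                sums[j] = pair if sums[j] is None else sums[j] + pair
    finally:
        for bn, (mom,) in zip(bns, saved):
            bn.momentum = mom
    for bn, s in zip(bns, sums):
        bn.running_mean = (s[0] / n_batches).astype(np.float32)
        bn.running_var = (s[1] / n_batches).astype(np.float32)


def train_model(
    model: MACNeXt,
    dataset: ArrayDataset,
    split: SplitAssignment,
    config: TrainConfig,
    out_dir: str | Path | None = None,
) -> TrainLog:
    """Momentum-SGD training with a per-epoch train/val log.

    Writes ``log.csv`` plus final- and best-validation checkpoints when
    ``out_dir`` is given.
    """
    if len(dataset) != split.partition.shape[0]:
        raise ValueError("dataset and split sizes differ")
    if int(dataset.labels.max()) + 1 > model.config.num_classes:
        raise ValueError(
            f"dataset has {int(dataset.labels.max()) + 1} classes but the model "
            f"emits {model.config.num_classes}"
        )
    tr_idx = split.indices("train")
    va_idx = split.indices("val")
    if tr_idx.size == 0:
        raise ValueError("training partition is empty")
    x_tr, y_tr = dataset.images[tr_idx], dataset.labels[tr_idx]
    x_va, y_va = dataset.images[va_idx], dataset.labels[va_idx]

    rng = np.random.default_rng(config.seed)
    velocity = [np.zeros_like(p.data) for p in model.parameters()]
    log = TrainLog()
    best_val = -np.inf
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, config.epochs + 1):
        if config.balanced_batches:
            order = _balanced_order(y_tr, rng)
        else:
            order = rng.permutation(y_tr.shape[0])
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, order.size, config.batch_size):
            sel = order[i : i + config.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            logits = model.forward_logits(xb, training=True)
            loss, dlogits = _softmax_xent(logits, yb)
            model.zero_grad()
            model.backward(dlogits)
            _sgdm_step(model, velocity, config)
            ep_loss += loss * yb.size
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        train_loss = ep_loss / order.size
        train_acc = ep_correct / order.size
        if va_idx.size:
            val_loss, val_acc = _partition_metrics(model, x_va, y_va, config.batch_size)
        else:
            val_loss, val_acc = float("nan"), float("nan")
        log.append(
            epoch=epoch,
            train_loss=train_loss,
            train_acc=train_acc,
            val_loss=val_loss,
            val_acc=val_acc,
        )
        if out_dir is not None:
            if va_idx.size and val_acc >= best_val:
                best_val = val_acc
                save_checkpoint(model, out_dir / "best.ckpt")
    recalibrate_batchnorm(model, x_tr, config.batch_size)
    if out_dir is not None:
        save_checkpoint(model, out_dir / "final.ckpt")
        log.to_csv(out_dir / "log.csv")
    return log


def evaluate_model(
    model: MACNeXt,
    dataset: ArrayDataset,
    split: SplitAssignment,
    partition: str = "test",
    batch_size: int = 64,
) -> tuple[ConfusionMatrix, MetricsReport, PredictionBatch]:
    """Inference over one partition; feeds the evaluation module verbatim."""
    idx = split.indices(partition)
    if idx.size == 0:
        raise ValueError(f"partition {partition!r} is empty")
    pred = model.predict(dataset.images[idx], batch_size=batch_size)
    names = dataset.class_names
    truth = [names[i] for i in dataset.labels[idx]]
    predicted = [names[i] for i in pred.predicted_label]
    cm, report = evaluate_predictions(truth, predicted, names)
    return cm, report, pred
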