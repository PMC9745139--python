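"""Training loop: per-class binary cross-entropy with masked pixels.

Each pixel's classification is treated as a set of independent binary
problems, one per class: the network emits one logit plane per class,
the loss is the mean binary cross-entropy between the sigmoid
probabilities and the one-hot targets,

    BCE = -(1/m) * sum_i [ y_i * log(p_i) + (1 - y_i) * log(1 - p_i) ]

averaged over valid pixel-class elements. Unlabeled pixels (label 0) and
tile padding are masked out of both the loss and the reported accuracy.
At prediction time the per-class probabilities are fused by argmax. A
softmax cross-entropy alternative sits behind ``TrainConfig.loss``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Tensor
from .nn import autograd as ag
from .network import (
    DualBranchUNet,
    NetConfig,
    PlainUNet,
    build_dual_branch,
    build_plain_unet,
    build_single_branch,
)
from .preprocess import Tile, TileSet, mosaic_labels
from .types import ClassScheme, LabelMap

__all__ = [
    "TrainConfig",
    "one_hot_encode",
    "bce_loss",
    "Adam",
    "train_model",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Training protocol.

    Defaults follow the full-scale protocol (batch 4, up to 600 epochs,
    Adam at 1e-4, optional step decay at epoch 100); desk-scale runs pass
    smaller ``max_epochs`` and a proportionally larger ``lr`` explicitly.
    """

    batch_size: int = 4
    max_epochs: int = 600
    lr: float = 1e-4
    lr_schedule: str = "constant"  # constant | step
    step_epoch: int = 100
    step_factor: float = 0.1
    optimizer: str = "adam"
    loss: str = "bce"  # bce | softmax
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.lr_schedule not in ("constant", "step"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.loss not in ("bce", "softmax"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "step" and epoch >= self.step_epoch:
            return self.lr * self.step_factor
        return self.lr


def one_hot_encode(labels: np.ndarray, n_classes: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One binary plane per class plus a validity mask.

    ``labels`` uses ids ``1..n_classes`` with 0 = unlabeled; plane ``k``
    (0-based) is hot where ``labels == k + 1``. Label 0 yields an all-zero
    column and ``mask = False``, so it never contributes to the loss.
    Accepts ``H x W`` or ``N x H x W``; the class axis is inserted first
    after the batch axis.
    """
    labels = np.asarray(labels)
    squeeze = labels.ndim == 2
    if squeeze:
        labels = labels[None]
    n, h, w = labels.shape
    planes = np.zeros((n, n_classes, h, w), dtype=np.float32)
    for k in range(n_classes):
        planes[:, k] = labels == k + 1
    mask = labels > 0
    if squeeze:
        return planes[0], mask[0]
    return planes, mask


def bce_loss(logits, targets: np.ndarray, mask: np.ndarray):
    """Masked mean binary cross-entropy, fused with the sigmoid.

    ``logits`` may be a plain array (returns a float) or an autograd
    tensor (returns a scalar tensor for backpropagation). ``mask``
    must broadcast against the logits; an empty mask is an error.
    """
    if isinstance(logits, Tensor):
        return ag.bce_with_logits(logits, targets, mask)
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    m = np.broadcast_to(np.asarray(mask, dtype=np.float64), z.shape)
    total = m.sum()
    if total == 0:
        raise ValueError("empty mask: no valid elements to average over")
    elem = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float((elem * m).sum() / total)


class Adam:
    """Adam with bias correction (the usual defaults)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        # float64 moments: squared gradients overflow float32 range
        self.m = [np.zeros(p.data.shape) for p in self.params]
        self.v = [np.zeros(p.data.shape) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bias1)
                       / (np.sqrt(v / bias2) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _tile_inputs(tile: Tile) -> tuple[np.ndarray, np.ndarray | None]:
    pca = np.ascontiguousarray(
        tile.pca.transpose(2, 0, 1), dtype=np.float32)
    art = None
    if tile.artificial is not None:
        art = np.ascontiguousarray(
            tile.artificial.transpose(2, 0, 1), dtype=np.float32)
    return pca, art


def _is_dual(model) -> bool:
    return isinstance(model, DualBranchUNet)


def _forward_tiles(model, tiles: list[Tile]) -> Tensor:
    pcas, arts = [], []
    for t in tiles:
        pca, art = _tile_inputs(t)
        pcas.append(pca)
        arts.append(art)
    x_pca = Tensor(np.stack(pcas))
    if _is_dual(model):
        if any(a is None for a in arts):
            raise ValueError("dual-branch model needs tiles with an "
                             "artificial-feature input")
        return model(x_pca, Tensor(np.stack(arts)))
    return model(x_pca)


def _batch_targets(tiles: list[Tile], n_classes: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    labels = np.stack([t.labels for t in tiles])
    planes, label_mask = one_hot_encode(labels, n_classes)
    valid = np.stack([t.valid_mask() for t in tiles])
    return planes, label_mask & valid


def train_model(
    model,
    train: TileSet,
    config: TrainConfig,
    val: TileSet | None = None,
    verbose: bool = False,
):
    """Train a network on a tile set with the configured protocol.

    Tiles are shuffled each epoch with a seeded generator; the optimizer
    is Adam at ``config.lr`` (with the optional step decay). The history
    records per-epoch mean loss and masked pixel accuracy (plus
    validation loss/accuracy when a validation set is given), and the
    parameters with the best validation (else training) loss are restored
    at the end. A non-finite loss aborts with the offending epoch.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    n_classes = model.config.n_classes
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.lr)
    history: list[dict] = []
    best_loss = np.inf
    best_state = None

    for epoch in range(config.max_epochs):
        model.train()
        optimizer.lr = config.lr_at(epoch)
        order = rng.permutation(len(train))
        losses, correct, total = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[start:start + config.batch_size]]
            planes, mask = _batch_targets(batch, n_classes)
            logits = _forward_tiles(model, batch)
            if config.loss == "bce":
                loss = ag.bce_with_logits(logits, planes, mask[:, None])
            else:
                loss = ag.softmax_cross_entropy(logits, planes, mask)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            pred = logits.data.argmax(axis=1) + 1
            truth = np.stack([t.labels for t in batch])
            correct += int(((pred == truth) & mask).sum())
            total += int(mask.sum())
        record = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / max(total, 1),
            "lr": optimizer.lr,
        }
        monitor = record["loss"]
        if val is not None and len(val) > 0:
            val_loss, val_acc = evaluate_loss(model, val, config)
            record["val_loss"], record["val_accuracy"] = val_loss, val_acc
            monitor = val_loss
        history.append(record)
        if monitor < best_loss:
            best_loss = monitor
            best_state = copy.deepcopy(model.state_dict())
        if verbose:
            print(f"epoch {epoch:3d}  loss {record['loss']:.4f}  "
                  f"acc {record['accuracy']:.4f}")
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def evaluate_loss(model, tiles: TileSet, config: TrainConfig
                  ) -> tuple[float, float]:
    """Mean loss and masked pixel accuracy without updating weights."""
    model.eval()
    n_classes = model.config.n_classes
    losses, correct, total = [], 0, 0
    for start in range(0, len(tiles), config.batch_size):
        batch = tiles.tiles[start:start + config.batch_size]
        planes, mask = _batch_targets(batch, n_classes)
        logits = _forward_tiles(model, batch)
        if config.loss == "bce":
            loss = ag.bce_with_logits(logits, planes, mask[:, None])
        else:
            loss = ag.softmax_cross_entropy(logits, planes, mask)
        losses.append(float(loss.data))
        pred = logits.data.argmax(axis=1) + 1
        truth = np.stack([t.labels for t in batch])
        correct += int(((pred == truth) & mask).sum())
        total += int(mask.sum())
    model.train()
    return float(np.mean(losses)), correct / max(total, 1)


def predict(
    model,
    tiles: TileSet,
    scheme: ClassScheme | None = None,
    batch_size: int = 4,
) -> LabelMap:
    """Per-pixel class maps: argmax over per-class sigmoid probabilities,
    tiles mosaicked back by origin with padding stripped."""
    model.eval()
    per_tile: list[np.ndarray] = []
    tile_list = list(tiles)
    for start in range(0, len(tile_list), batch_size):
        batch = tile_list[start:start + batch_size]
        logits = _forward_tiles(model, batch)
        probs = ag.sigmoid(logits.data)
        pred = probs.argmax(axis=1).astype(np.int32) + 1
        per_tile.extend(pred)
    model.train()
    shape = tiles.scene_shape
    if shape is None:
        h = max(t.origin[0] + t.valid[0] for t in tile_list)
        w = max(t.origin[1] + t.valid[1] for t in tile_list)
        shape = (h, w)
    labels = mosaic_labels(tile_list, per_tile, shape)
    if scheme is None:
        scheme = ClassScheme.generic(model.config.n_classes)
    return LabelMap(labels, scheme)


# ---------------------------------------------------------------------------
# checkpoints

_BUILDERS = {
    "single": build_single_branch,
    "dual": build_dual_branch,
    "plain": build_plain_unet,
}


def save_checkpoint(model, path) -> None:
    path = Path(path)
    kind = ("dual" if isinstance(model, DualBranchUNet)
            else "plain" if isinstance(model, PlainUNet) else "single")
    meta = {"kind": kind, "config": model.config.to_dict()}
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **model.state_dict())


def load_checkpoint(path):
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg = NetConfig.from_dict(meta["config"])
    if meta["kind"] == "plain":
        model = build_plain_unet(cfg)
    elif meta["kind"] == "dual":
        model = build_dual_branch(cfg)
    else:
        model = build_single_branch(cfg)
    model.load_state_dict(state)
    return model
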