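"""Training and inference for the segmentation models.

The training recipe follows the study regime: Adam with a constant
learning rate, plain (unweighted) cross-entropy over the three categories,
shuffling every epoch, mini-batches of 10, and optionally several
replicate runs with identical hyper-parameters but different seeds.  The
full-scale profile (64 base filters, 15 epochs, lr 1e-4) matches that
regime; the desk profile (16 base filters, 5 epochs, lr 1e-3) is a
CPU-sized configuration for phantom experiments and carries no claim about
full-scale behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ..core import Category, LabelMap, as_categories
from ..dataset import TILE_OFFSETS, TILE_SIZE, TileSet, reassemble
from .layers import Adam, cross_entropy, softmax
from .models import SegModel, SegNetStyle, UNet


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 15
    batch_size: int = 10
    loss: str = "cross-entropy"
    shuffle_each_epoch: bool = True
    seed: int = 0
    base_filters: int = 64
    encoder_depth: int = 4

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.encoder_depth < 1:
            raise ValueError("epochs, batch_size and encoder_depth must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "cross-entropy":
            raise ValueError("only cross-entropy loss is supported")


def paper_profile(seed: int = 0) -> TrainConfig:
    """The full-scale training regime (64 filters, 15 epochs, lr 1e-4)."""
    return TrainConfig(seed=seed)


def desk_profile(seed: int = 0, epochs: int = 5) -> TrainConfig:
    """CPU-sized profile for phantom experiments."""
    return TrainConfig(
        base_filters=16, epochs=epochs, learning_rate=1e-3, seed=seed
    )


def build_unet(config: TrainConfig) -> UNet:
    """U-Net with depth-4 encoder and doubled filters per pooling stage."""
    return UNet(
        base_filters=config.base_filters, depth=config.encoder_depth, seed=config.seed
    )


def build_segnet(config: TrainConfig) -> SegNetStyle:
    """SegNet-style encoder-decoder with max-pooling-index unpooling."""
    return SegNetStyle(
        base_filters=config.base_filters, depth=config.encoder_depth, seed=config.seed
    )


def tiles_to_arrays(
    pairs: Sequence[tuple[np.ndarray, LabelMap | np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (image, label) tile pairs into training arrays.

    Images (H, W, 3) uint8 become float32 in [0, 1] with shape
    ``(n, 3, H, W)``; labels become an int64 class grid ``(n, H, W)``.
    """
    if not pairs:
        raise ValueError("empty tile collection")
    xs = np.stack(
        [np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0 for img, _ in pairs]
    )
    ys = np.stack([as_categories(lab).astype(np.int64) for _, lab in pairs])
    return xs, ys


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_accuracy: float = float("nan")


def _batched_accuracy(model: SegModel, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    correct = 0
    for i in range(0, x.shape[0], batch):
        xb = np.ascontiguousarray(x[i : i + batch].transpose(1, 0, 2, 3))
        pred = model.forward(xb).argmax(axis=0)
        correct += int((pred == y[i : i + batch]).sum())
    return correct / y.size


def train(
    model: SegModel,
    train_pairs: Sequence[tuple[np.ndarray, LabelMap | np.ndarray]],
    val_pairs: Sequence[tuple[np.ndarray, LabelMap | np.ndarray]] | None,
    config: TrainConfig,
) -> tuple[SegModel, list[EpochRecord]]:
    """Train in place with Adam + cross-entropy; returns per-epoch history."""
    x, y = tiles_to_arrays(train_pairs)
    xv = yv = None
    if val_pairs:
        xv, yv = tiles_to_arrays(val_pairs)
    opt = Adam(lr=config.learning_rate)
    rng = np.random.default_rng([config.seed, 3])
    n = x.shape[0]
    history: list[EpochRecord] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = np.ascontiguousarray(x[idx].transpose(1, 0, 2, 3))
            logits = model.forward(xb)
            loss, grad = cross_entropy(logits, y[idx])
            model.backward(grad)
            opt.step(model.parameters())
            losses.append(loss)
        rec = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)))
        if xv is not None:
            rec.val_accuracy = _batched_accuracy(model, xv, yv, config.batch_size)
        history.append(rec)
    return model, history


def train_replicates(
    architecture: str,
    train_pairs,
    val_pairs,
    config: TrainConfig,
    n_replicates: int = 3,
) -> list[tuple[SegModel, list[EpochRecord]]]:
    """Train several replicates with identical hyper-parameters.

    Replicate ``r`` uses ``seed + r`` for initialization and shuffling, so
    results can be reported as mean ± SD across runs.
    """
    builders = {"u-net": build_unet, "segnet-style": build_segnet}
    if architecture not in builders:
        raise ValueError(f"unknown architecture {architecture!r}")
    out = []
    for r in range(n_replicates):
        cfg = replace(config, seed=config.seed + r)
        model = builders[architecture](cfg)
        out.append(train(model, train_pairs, val_pairs, cfg))
    return out


def predict_tile(model: SegModel, image: np.ndarray) -> LabelMap:
    """Argmax class labels for one (H, W, 3) uint8 tile.

    ``np.argmax`` returns the lowest class index on exact ties.
    """
    x = np.ascontiguousarray(
        np.asarray(image, dtype=np.float32).transpose(2, 0, 1)[:, None] / 255.0
    )
    labels = model.forward(x).argmax(axis=0)[0]
    return LabelMap(labels.astype(np.uint8))


def predict_full(model: SegModel, tiles: TileSet) -> LabelMap:
    """Predict each 224x224 tile and reassemble the 224x896 label map."""
    if len(tiles.tiles) != len(TILE_OFFSETS) or set(tiles.offsets) != set(TILE_OFFSETS):
        raise ValueError(
            f"need exactly {len(TILE_OFFSETS)} tiles at offsets {TILE_OFFSETS}"
        )
    preds = [as_categories(predict_tile(model, t)) for t in tiles.tiles]
    assembled = reassemble(TileSet(tiles=preds, offsets=tiles.offsets))
    return LabelMap(assembled)


__all__ = [
    "EpochRecord",
    "TrainConfig",
    "build_segnet",
    "build_unet",
    "desk_profile",
    "paper_profile",
    "predict_full",
    "predict_tile",
    "tiles_to_arrays",
    "train",
    "train_replicates",
]
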