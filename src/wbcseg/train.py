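"""Training, inference and evaluation wiring.

The full-scale optimization protocol is Adam with learning rate 1e-4,
batch size 8 and 200 epochs, minimizing pixelwise BCE or focal loss on
(image, mask) pairs.  Per-epoch train/validation losses and
validation Dice are logged; the checkpoint with the best validation Dice
is kept.  Everything is a deterministic function of the seeds.

A desk-scale profile (width 1/8, side 64, 200 synthetic images, up to 20
epochs, learning rate 1e-3) runs the identical code path in minutes on one
CPU core.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .losses import FocalParams, get_loss
from .metrics import MetricsReport, dice, evaluate_dataset
from .model import NetworkConfig, SegmentationNet
from .postprocess import CleanupConfig, binarize, morph_cleanup


@dataclass
class TrainConfig:
    """Optimization protocol knobs (defaults: Adam, lr 1e-4, batch 8,
    200 epochs, BCE loss)."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    loss: str = "bce"
    focal: FocalParams = field(default_factory=FocalParams)
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: str | None = None
    optimizer: str = "adam"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("bce", "focal"):
            raise ValueError(f"loss must be 'bce' or 'focal', got {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if isinstance(self.focal, dict):
            self.focal = FocalParams(**self.focal)


def _to_batch(pairs) -> tuple[np.ndarray, np.ndarray]:
    """(image HWC [0,1], mask HW) pairs -> NCHW images and N1HW masks."""
    imgs = np.stack([np.transpose(np.asarray(im, np.float32), (2, 0, 1))
                     for im, _ in pairs])
    masks = np.stack([np.asarray(mk, np.float32)[None] for _, mk in pairs])
    return imgs, masks


def _val_metrics(model, images, masks, loss_fn) -> tuple[float, float]:
    with nn.no_grad():
        losses, dices = [], []
        for i in range(images.shape[0]):
            out = model(nn.Tensor(images[i:i + 1]))
            losses.append(loss_fn(out, masks[i:i + 1]).item())
            dices.append(dice(out.data[0, 0] >= 0.5, masks[i, 0] > 0.5))
    return float(np.mean(losses)), float(np.mean(dices))


def train(model: SegmentationNet, train_pairs, val_pairs,
          config: TrainConfig | None = None):
    """Fit ``model``; returns ``(model, history)`` with the model restored
    to its best-validation-Dice parameters.

    ``history`` is a list of per-epoch dicts (train_loss, val_loss,
    val_dice).  Raises on an empty training set and aborts with a
    diagnostic if the loss turns non-finite.
    """
    config = config or TrainConfig()
    train_pairs, val_pairs = list(train_pairs), list(val_pairs)
    if not train_pairs:
        raise ValueError("training set is empty")
    loss_fn = get_loss(config.loss, config.focal)
    images, masks = _to_batch(train_pairs)
    val_images, val_masks = (_to_batch(val_pairs) if val_pairs
                             else (None, None))
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    n = images.shape[0]
    history = []
    best = {"val_dice": -1.0, "state": None, "epoch": -1}
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            out = model(nn.Tensor(images[idx]))
            loss = loss_fn(out, masks[idx])
            if not math.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss {loss.item()} at epoch {epoch}, "
                    f"batch starting {start}; aborting")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            batch_losses.append(loss.item())
        entry = {"epoch": epoch, "train_loss": float(np.mean(batch_losses))}
        model.eval()
        if val_images is not None:
            vloss, vdice = _val_metrics(model, val_images, val_masks, loss_fn)
            entry["val_loss"], entry["val_dice"] = vloss, vdice
            if vdice > best["val_dice"]:
                best = {"val_dice": vdice, "state": model.state_dict(),
                        "epoch": epoch}
        history.append(entry)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
        if config.checkpoint_dir:
            ckdir = Path(config.checkpoint_dir)
            ckdir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, ckdir / "best.npz")
            (ckdir / "history.json").write_text(json.dumps(history, indent=2))
    model.eval()
    return model, history


def predict(model: SegmentationNet, images,
            cleanup: CleanupConfig | None = None, batch_size: int = 8):
    """Forward -> threshold -> morphological cleanup, per image.

    ``images`` is a list of H×W×3 arrays in [0,1]; returns a list of
    binary H×W masks.  Evaluation-mode statistics make the result
    batch-order invariant per image.
    """
    cleanup = cleanup or CleanupConfig()
    images = list(images)
    model.eval()
    masks = []
    with nn.no_grad():
        for start in range(0, len(images), batch_size):
            chunk = images[start:start + batch_size]
            x = np.stack([np.transpose(np.asarray(im, np.float32), (2, 0, 1))
                          for im in chunk])
            out = model(nn.Tensor(x)).data[:, 0]
            for prob in out:
                masks.append(morph_cleanup(binarize(prob, cleanup.threshold),
                                           cleanup))
    return masks


def evaluate(model: SegmentationNet, test_pairs,
             cleanup: CleanupConfig | None = None,
             report_prefix=None) -> MetricsReport:
    """Predict on a test set and score against ground truth; optionally
    writes ``<prefix>.csv`` and ``<prefix>.json`` reports."""
    test_pairs = list(test_pairs)
    if not test_pairs:
        raise ValueError("test set is empty")
    preds = predict(model, [im for im, _ in test_pairs], cleanup)
    report = evaluate_dataset(preds, [mk for _, mk in test_pairs])
    if report_prefix is not None:
        report.to_csv(str(report_prefix) + ".csv")
        report.to_json(str(report_prefix) + ".json")
    return report


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: SegmentationNet, path) -> None:
    """Native .npz of all parameters and buffers, with a JSON sidecar
    recording the NetworkConfig."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    model.config.save(path.with_suffix(".json"))


def load_checkpoint(path) -> SegmentationNet:
    path = Path(path)
    config = NetworkConfig.load(path.with_suffix(".json"))
    model = SegmentationNet(config)
    archive = np.load(path if path.suffix else path.with_suffix(".npz"))
    model.load_state_dict({k: archive[k] for k in archive.files})
    model.eval()
    return model


# ---------------------------------------------------------------------
# desk-scale profile
# ---------------------------------------------------------------------

def desk_profile(seed: int = 0, loss: str = "bce", epochs: int = 20):
    """Named desk-scale configuration: width-1/8 network at side 64 with a
    200-image synthetic dataset and at most 20 epochs at lr 1e-3."""
    from .synthetic import SceneConfig
    if epochs > 20:
        raise ValueError("the desk profile caps epochs at 20")
    net = NetworkConfig(input_side=64, width_multiplier=1 / 8)
    tr = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=epochs,
                     loss=loss, seed=seed)
    scene = SceneConfig(side=64, seed=seed)
    return net, tr, scene, 200
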