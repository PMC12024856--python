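"""Training loop, evaluation and prediction.

Optimises the soft Dice loss with Adam, monitors a validation metric
(pixel accuracy by default, Dice optionally), keeps the best-epoch
checkpoint, and stops early once the monitor has not improved — by more
than a 1e-6 margin — for ``early_stop_patience`` consecutive epochs.
Weight initialisation, shuffling and augmentation are all seeded.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from ._autograd import Tensor, no_grad
from .data import (
    AugmentationConfig,
    DatasetManifest,
    Sample,
    _read_gray,
    augment,
    load_sample,
    normalize,
    write_mask,
)
from .metrics import (
    ConfusionCounts,
    MetricConfig,
    MetricsRow,
    accuracy,
    binarize,
    confusion_counts,
    dice_coefficient,
    dice_loss,
    write_metrics_table,
)
from .model import ModelConfig, SegmentationNet, build_model

IMPROVEMENT_DELTA = 1e-6


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 100
    optimizer: str = "adam"               # {"adam", "sgd"}
    monitor: str = "val_accuracy"         # {"val_accuracy", "val_dice"}
    seed: int = 0
    device: str = "cpu"
    augment: bool = True
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError(f"learning rate must be positive, got {self.learning_rate}")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("early_stop_patience must not exceed max_epochs")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer: {self.optimizer!r}")
        if self.monitor not in ("val_accuracy", "val_dice"):
            raise ValueError(f"unknown monitor: {self.monitor!r}")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if isinstance(raw.get("augmentation"), dict):
            aug = dict(raw["augmentation"])
            if isinstance(aug.get("sharpness_range"), list):
                aug["sharpness_range"] = tuple(aug["sharpness_range"])
            raw["augmentation"] = AugmentationConfig(**aug)
        return cls(**raw)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_dice: float
    val_accuracy: float
    seconds: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_monitor: float = -np.inf
    checkpoint_path: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "records": [asdict(r) for r in self.records],
            "best_epoch": self.best_epoch,
            "best_monitor": self.best_monitor,
            "checkpoint_path": self.checkpoint_path,
        }, indent=2))


class EarlyStopper:
    """Best-so-far tracking with a patience window.

    An epoch counts as an improvement only if its monitor value exceeds the
    best seen so far by more than ``delta``; the run stops once ``patience``
    consecutive epochs have failed to improve.
    """

    def __init__(self, patience: int, delta: float = IMPROVEMENT_DELTA):
        self.patience = patience
        self.delta = delta
        self.best = -np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, value: float) -> bool:
        """Register one epoch's monitor value; returns True if it improved."""
        self.epoch += 1
        if value > self.best + self.delta:
            self.best = float(value)
            self.best_epoch = self.epoch
            return True
        return False

    @property
    def should_stop(self) -> bool:
        return self.epoch - self.best_epoch >= self.patience


# ---------------------------------------------------------------------------
# optimisers
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[nn.Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


class SGD:
    def __init__(self, params: list[nn.Parameter], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.buf[i] = self.momentum * self.buf[i] + p.grad
            p.data -= (self.lr * self.buf[i]).astype(np.float32)


def _make_optimizer(cfg: TrainConfig, model: nn.Module):
    params = model.parameters()
    if cfg.optimizer == "adam":
        return Adam(params, cfg.learning_rate)
    return SGD(params, cfg.learning_rate)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _load_split(manifest: DatasetManifest, split: str) -> list[Sample]:
    return [load_sample(e.image, e.mask, e.id) for e in manifest.split(split)]


def _batch_tensors(samples: list[Sample]) -> tuple[Tensor, np.ndarray]:
    images = np.stack([normalize(s.image) for s in samples])
    masks = np.stack([s.mask for s in samples]).astype(np.float32)
    return Tensor(images), masks


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def evaluate_samples(model: SegmentationNet, samples: list[Sample],
                     mcfg: MetricConfig | None = None
                     ) -> tuple[list[MetricsRow], dict]:
    """Hard Dice/Acc per image plus micro (pooled pixels) and mean aggregates."""
    mcfg = mcfg or MetricConfig()
    if not samples:
        raise ValueError("cannot evaluate an empty split")
    model.eval()
    rows: list[MetricsRow] = []
    pooled = ConfusionCounts()
    with no_grad():
        for s in samples:
            prob = model(Tensor(normalize(s.image)[None])).data[0]
            pred = binarize(prob, mcfg)
            c = confusion_counts(pred, s.mask)
            pooled = pooled + c
            dice = dice_coefficient(c) if (2 * c.tp + c.fp + c.fn) else 1.0
            rows.append(MetricsRow(s.id, dice, accuracy(c)))
    aggregate = {
        "dice_micro": dice_coefficient(pooled),
        "acc_micro": accuracy(pooled),
        "dice_mean": float(np.mean([r.dice for r in rows])),
        "acc_mean": float(np.mean([r.acc for r in rows])),
    }
    return rows, aggregate


def train(model_cfg: ModelConfig | SegmentationNet, manifest: DatasetManifest,
          cfg: TrainConfig, out_dir: str | Path,
          verbose: bool = False) -> tuple[TrainHistory, SegmentationNet]:
    """Fit on the manifest's train split, monitor on val, keep the best epoch."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model_cfg if isinstance(model_cfg, SegmentationNet) \
        else build_model(model_cfg)

    train_samples = _load_split(manifest, "train")
    val_samples = _load_split(manifest, "val")
    if not train_samples or not val_samples:
        raise ValueError(
            f"manifest needs non-empty train and val splits "
            f"(got {len(train_samples)} train / {len(val_samples)} val)")

    rng = np.random.default_rng(cfg.seed)
    optimizer = _make_optimizer(cfg, model)
    mcfg = MetricConfig()
    history = TrainHistory()
    stopper = EarlyStopper(cfg.early_stop_patience)
    ckpt = out_dir / "best.npz"

    for epoch in range(1, cfg.max_epochs + 1):
        t0 = time.time()
        model.train()
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_samples[i] for i in order[start:start + cfg.batch_size]]
            if cfg.augment:
                batch = [augment(s, cfg.augmentation, rng) for s in batch]
            x, y = _batch_tensors(batch)
            model.zero_grad()
            loss = dice_loss(model(x), y, mcfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))

        _, agg = evaluate_samples(model, val_samples, mcfg)
        monitor = agg["acc_micro"] if cfg.monitor == "val_accuracy" \
            else agg["dice_micro"]
        record = EpochRecord(epoch, float(np.mean(losses)),
                             agg["dice_micro"], agg["acc_micro"],
                             time.time() - t0)
        history.records.append(record)
        if verbose:
            print(f"epoch {epoch:4d}  loss {record.train_loss:.4f}  "
                  f"val_dice {record.val_dice:.4f}  val_acc {record.val_accuracy:.4f}")

        if stopper.update(monitor):
            history.best_monitor = stopper.best
            history.best_epoch = epoch
            model.save(ckpt)
            history.checkpoint_path = str(ckpt)
        elif stopper.should_stop:
            break

    history.save(out_dir / "history.json")
    best = SegmentationNet.load(ckpt)
    return history, best


def evaluate(checkpoint: str | Path | SegmentationNet, manifest: DatasetManifest,
             split: str = "test", out_dir: str | Path | None = None) -> dict:
    """Per-image and aggregate metrics for one split; optionally write tables."""
    model = checkpoint if isinstance(checkpoint, SegmentationNet) \
        else SegmentationNet.load(checkpoint)
    samples = _load_split(manifest, split)
    if not samples:
        raise ValueError(f"split {split!r} is empty")
    rows, aggregate = evaluate_samples(model, samples)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_metrics_table(rows, aggregate,
                            out_dir / f"metrics_{split}.csv",
                            out_dir / f"metrics_{split}.json")
    return aggregate


def predict(checkpoint: str | Path | SegmentationNet, image_path: str | Path,
            out_path: str | Path, threshold: float = 0.5) -> dict:
    """Segment one image file and write the binary mask as an 8-bit PNG."""
    model = checkpoint if isinstance(checkpoint, SegmentationNet) \
        else SegmentationNet.load(checkpoint)
    model.eval()
    img = _read_gray(Path(image_path)).astype(np.float32) / 255.0
    with no_grad():
        prob = model(Tensor(normalize(img)[None, None])).data[0, 0]
    mask = binarize(prob, MetricConfig(threshold=threshold))
    write_mask(mask, out_path)
    return {"shape": list(img.shape),
            "foreground_fraction": float(mask.mean())}
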