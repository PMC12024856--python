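"""Procedural OCTA-like angiograms with exact ground-truth vessel masks.

En-face OCTA angiograms show bright, branching, tree-like vessels of mixed
calibre over a dark speckled background with faint capillary texture.  The
generator emulates that statistical character — it is not a physical model
of OCT speckle — so the package can be exercised and validated without any
external data:

* ``generate_vessel_tree`` grows a few random branching walks from the image
  border inward.  Each walk advances in small steps with jittered heading
  (tortuosity), occasionally spawns a child branch, and stamps a disk of the
  current calibre at every step; the calibre shrinks by ``width_decay`` at
  each branching, floored at ``width_min``.  The union of the stamped disks
  is the binary ground truth: per tree it is connected by construction.
* ``render_octa`` turns a mask into an intensity image: multiplicative
  speckle over a dark base, a smooth capillary texture, a blurred bright
  vessel signal, and additive Gaussian noise, clipped to [0, 1].

All randomness flows through the counter-based Philox generator keyed by
``(seed, sample index)``, so datasets are reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import DatasetManifest, ManifestEntry, Sample, write_image, write_mask


@dataclass
class SyntheticConfig:
    size: tuple[int, int] = (304, 304)
    n_trees: int = 3
    branch_prob: float = 0.07          # per-step probability of spawning a child
    width_root: float = 6.0            # calibre of the root vessel (px)
    width_min: float = 1.0
    width_decay: float = 0.72          # calibre multiplier at each branching
    tortuosity: float = 14.0           # per-step heading jitter (degrees)
    speckle_sigma: float = 0.35        # multiplicative background speckle
    background_capillary_density: float = 0.12
    foreground_gain: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if min(self.size) < 8:
            raise ValueError(f"image size too small: {self.size}")
        if self.width_min < 1:
            raise ValueError(f"width_min must be >= 1, got {self.width_min}")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError(f"branch_prob must be in [0, 1], got {self.branch_prob}")


def _rng_for(cfg: SyntheticConfig, index: int = 0) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence((cfg.seed, index))))


def _stamp_disk(mask: np.ndarray, y: float, x: float, radius: float) -> None:
    h, w = mask.shape
    # 0.75 floor: a disk this size always covers the nearest raster pixel,
    # so unit-step walks rasterise to 8-connected chains even at 1 px calibre
    r = max(radius, 0.75)
    y0, y1 = max(int(y - r), 0), min(int(y + r) + 1, h)
    x0, x1 = max(int(x - r), 0), min(int(x + r) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= ((yy - y) ** 2 + (xx - x) ** 2 <= r * r)


def _grow_tree(mask: np.ndarray, rng: np.random.Generator,
               cfg: SyntheticConfig) -> None:
    h, w = mask.shape
    scale = (h + w) / 2.0
    # root on a random border, heading inward
    side = rng.integers(4)
    if side == 0:
        y, x, heading = 0.0, rng.uniform(0, w), rng.uniform(45, 135)
    elif side == 1:
        y, x, heading = float(h - 1), rng.uniform(0, w), rng.uniform(-135, -45)
    elif side == 2:
        y, x, heading = rng.uniform(0, h), 0.0, rng.uniform(-45, 45)
    else:
        y, x, heading = rng.uniform(0, h), float(w - 1), rng.uniform(135, 225)

    max_steps = int(1.6 * scale)
    stack = [(y, x, heading, cfg.width_root, max_steps)]
    while stack:
        y, x, heading, width, budget = stack.pop()
        for _ in range(budget):
            _stamp_disk(mask, y, x, width / 2.0)
            heading += rng.uniform(-cfg.tortuosity, cfg.tortuosity)
            rad = math.radians(heading)
            y += math.sin(rad)
            x += math.cos(rad)
            if not (0 <= y < h and 0 <= x < w):
                break
            if rng.random() < cfg.branch_prob and width > cfg.width_min:
                child_width = max(width * cfg.width_decay, cfg.width_min)
                turn = rng.uniform(25, 60) * (1 if rng.random() < 0.5 else -1)
                stack.append((y, x, heading + turn, child_width,
                              int(budget * 0.5)))
                width = max(width * cfg.width_decay, cfg.width_min)


def generate_vessel_tree(cfg: SyntheticConfig | None = None,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Binary (H, W) vessel mask: union of ``n_trees`` branching walks."""
    cfg = cfg or SyntheticConfig()
    rng = rng if rng is not None else _rng_for(cfg)
    mask = np.zeros(cfg.size, dtype=bool)
    for _ in range(cfg.n_trees):
        _grow_tree(mask, rng, cfg)
    return mask.astype(np.uint8)


def render_octa(mask: np.ndarray, cfg: SyntheticConfig | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Render a [0, 1] angiogram-like intensity image for a vessel mask."""
    cfg = cfg or SyntheticConfig()
    rng = rng if rng is not None else _rng_for(cfg, index=1)
    mask = np.asarray(mask, dtype=np.float32)
    h, w = mask.shape

    base = 0.16
    speckle = base * (1.0 + cfg.speckle_sigma * rng.standard_normal((h, w)))
    capillary = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
    capillary = cfg.background_capillary_density * np.clip(capillary, 0.0, None)
    vessels = cfg.foreground_gain * ndimage.gaussian_filter(mask, sigma=0.7)
    noise = 0.02 * rng.standard_normal((h, w))
    return np.clip(speckle + capillary + vessels + noise, 0.0, 1.0).astype(np.float32)


def generate_sample(cfg: SyntheticConfig, index: int) -> Sample:
    """Deterministic sample ``index`` of the dataset keyed by ``cfg.seed``."""
    rng = _rng_for(cfg, index)
    mask = generate_vessel_tree(cfg, rng)
    image = render_octa(mask, cfg, rng)
    return Sample(image=image, mask=mask, id=f"synth_{index:04d}")


def _split_sizes(n: int) -> tuple[int, int, int]:
    """70/20/10 split: floor for train and test, remainder to val."""
    n_train = int(n * 0.7)
    n_test = int(n * 0.2)
    return n_train, n_test, n - n_train - n_test


def make_dataset(n: int, cfg: SyntheticConfig | None = None,
                 out_dir: str | Path = ".") -> DatasetManifest:
    """Write ``n`` PNG image/mask pairs plus a CSV manifest with a 70/20/10 split."""
    cfg = cfg or SyntheticConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train, n_test, n_val = _split_sizes(n)
    order = _rng_for(cfg, index=1_000_003).permutation(n)  # split stream

    entries = []
    for i in range(n):
        sample = generate_sample(cfg, i)
        img_path = out_dir / f"{sample.id}_img.png"
        msk_path = out_dir / f"{sample.id}_mask.png"
        write_image(sample.image, img_path)
        write_mask(sample.mask, msk_path)
        rank = int(np.where(order == i)[0][0])
        split = ("train" if rank < n_train
                 else "test" if rank < n_train + n_test else "val")
        entries.append(ManifestEntry(sample.id, img_path.name, msk_path.name, split))

    manifest = DatasetManifest(entries=entries, root=out_dir, name="synthetic")
    manifest.save(out_dir / "manifest.csv")
    # re-load so entry paths resolve against the manifest location
    return DatasetManifest.load(out_dir / "manifest.csv")
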