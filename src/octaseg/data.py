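"""Image/mask pairs, dataset manifests, normalisation and augmentation.

Samples are grayscale en-face angiograms in [0, 1] with strictly binary
vessel masks, stored as ordinary 8-bit image files (PNG/BMP/TIFF/JPEG) and
organised by a CSV manifest ``id,image,mask,split`` with disjoint
train/test/val splits.

Augmentation follows the usual recipe for this kind of data: random
rotation, Gaussian noise, random sharpness adjustment and horizontal /
vertical / diagonal flips.  Geometric transforms are applied identically to
image and mask (the mask with nearest-neighbour interpolation so it stays
binary); photometric transforms touch the image only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

MASK_THRESHOLD = 127  # 8-bit binarisation threshold for mask files


class DataError(Exception):
    """Base class for dataset errors."""


class MissingFileError(DataError):
    pass


class UnreadableImageError(DataError):
    pass


class ShapeMismatchError(DataError):
    pass


@dataclass
class Sample:
    """One image/mask pair: image (1, H, W) in [0, 1]; mask (1, H, W) in {0, 1}."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.ndim == 2:
            self.image = self.image[None]
        if self.mask.ndim == 2:
            self.mask = self.mask[None]
        if self.image.shape != self.mask.shape:
            raise ShapeMismatchError(
                f"sample {self.id!r}: image {self.image.shape} vs "
                f"mask {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise DataError(f"sample {self.id!r}: mask is not binary")


@dataclass
class ManifestEntry:
    id: str
    image: Path
    mask: Path
    split: str


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    root: Path
    name: str = "dataset"

    def split(self, name: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == name]

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "image", "mask", "split"])
            for e in self.entries:
                writer.writerow([e.id, str(e.image), str(e.mask), e.split])

    @classmethod
    def load(cls, path: str | Path, *, check_paths: bool = True) -> "DatasetManifest":
        path = Path(path)
        if not path.exists():
            raise MissingFileError(f"manifest not found: {path}")
        root = path.parent
        entries = []
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                img = root / row["image"] if not Path(row["image"]).is_absolute() \
                    else Path(row["image"])
                msk = root / row["mask"] if not Path(row["mask"]).is_absolute() \
                    else Path(row["mask"])
                if check_paths:
                    for p in (img, msk):
                        if not p.exists():
                            raise MissingFileError(f"listed file not found: {p}")
                entries.append(ManifestEntry(row["id"], img, msk, row["split"]))
        return cls(entries=entries, root=root, name=path.stem)


def _read_gray(path: Path) -> np.ndarray:
    if not path.exists():
        raise MissingFileError(f"file not found: {path}")
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"))
    except UnidentifiedImageError as exc:
        raise UnreadableImageError(f"cannot decode image: {path}") from exc


def load_sample(image_path: str | Path, mask_path: str | Path,
                sample_id: str | None = None) -> Sample:
    """Read an image/mask pair; image scaled to [0, 1], mask binarised at 127."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = _read_gray(image_path).astype(np.float32) / 255.0
    msk = (_read_gray(mask_path) > MASK_THRESHOLD).astype(np.uint8)
    if img.shape != msk.shape:
        raise ShapeMismatchError(
            f"image {img.shape} vs mask {msk.shape} for {image_path.name}")
    return Sample(image=img, mask=msk, id=sample_id or image_path.stem)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    arr = np.asarray(mask)
    if arr.ndim == 3:
        arr = arr[0]
    Image.fromarray((arr > 0).astype(np.uint8) * 255, mode="L").save(Path(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as an 8-bit PNG."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[0]
    Image.fromarray(
        np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8), mode="L"
    ).save(Path(path))


def normalize(image: np.ndarray) -> np.ndarray:
    """Per-image standardisation to zero mean / unit variance.

    Constant images map to all zeros.  Not idempotent (re-standardising a
    standardised image recentres it again), and not claimed to be.
    """
    image = np.asarray(image, dtype=np.float32)
    mu = image.mean()
    sd = image.std()
    if sd < 1e-6:   # constant up to float32 rounding
        return np.zeros_like(image)
    return (image - mu) / sd


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    rotation_degrees: float = 15.0          # sampled uniformly in +/- range
    gaussian_noise_sigma: float = 0.02      # fraction of the [0, 1] range
    sharpness_range: tuple[float, float] = (0.5, 2.0)   # unsharp-mask factor
    flip_horizontal: bool = True
    flip_vertical: bool = True
    flip_diagonal: bool = True              # transpose over the main diagonal
    probability: float = 0.5                # per-op application probability

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {self.probability}")


def _rotate_pair(image: np.ndarray, mask: np.ndarray, angle: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    img = _sk_rotate(image, angle, order=1, mode="constant", cval=0.0,
                     preserve_range=True).astype(np.float32)
    msk = _sk_rotate(mask.astype(np.float32), angle, order=0, mode="constant",
                     cval=0.0, preserve_range=True)
    return img, (msk > 0.5).astype(np.uint8)


def _adjust_sharpness(image: np.ndarray, factor: float) -> np.ndarray:
    """Blend with a blurred copy: factor < 1 softens, > 1 sharpens."""
    blurred = ndimage.gaussian_filter(image, sigma=1.0)
    return np.clip(blurred + factor * (image - blurred), 0.0, 1.0)


def augment(sample: Sample, cfg: AugmentationConfig | None = None,
            seed: int | np.random.Generator = 0) -> Sample:
    """Randomly transformed copy of ``sample``; deterministic given the seed."""
    cfg = cfg or AugmentationConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    img, msk = sample.image[0].copy(), sample.mask[0].copy()

    if cfg.flip_horizontal and rng.random() < cfg.probability:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if cfg.flip_vertical and rng.random() < cfg.probability:
        img, msk = img[::-1, :], msk[::-1, :]
    if cfg.flip_diagonal and rng.random() < cfg.probability:
        img, msk = img.T, msk.T
    if cfg.rotation_degrees > 0 and rng.random() < cfg.probability:
        angle = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)
        img, msk = _rotate_pair(img, msk, angle)
    if cfg.sharpness_range and rng.random() < cfg.probability:
        img = _adjust_sharpness(img, rng.uniform(*cfg.sharpness_range))
    if cfg.gaussian_noise_sigma > 0 and rng.random() < cfg.probability:
        img = np.clip(
            img + rng.normal(0.0, cfg.gaussian_noise_sigma, size=img.shape),
            0.0, 1.0).astype(np.float32)

    return Sample(image=np.ascontiguousarray(img, dtype=np.float32),
                  mask=np.ascontiguousarray(msk), id=sample.id)


def split_manifest(entries: list[ManifestEntry],
                   sizes: tuple[int, int, int],
                   seed: int = 0,
                   root: Path | str = ".",
                   name: str = "dataset") -> DatasetManifest:
    """Deterministic seeded split into train/test/val of the given sizes."""
    n_train, n_test, n_val = sizes
    if n_train + n_test + n_val != len(entries):
        raise ValueError(
            f"split sizes {sizes} do not sum to {len(entries)} entries")
    order = np.random.default_rng(seed).permutation(len(entries))
    out = []
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_test:
            split = "test"
        else:
            split = "val"
        out.append(replace(entries[idx], split=split))
    out.sort(key=lambda e: e.id)
    return DatasetManifest(entries=out, root=Path(root), name=name)
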