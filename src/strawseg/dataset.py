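"""Image/mask pair IO, train-validation splitting, and real-folder adaptation.

Masks live on disk as single-channel 8-bit PNGs with the fixed grayscale code
(0 background, 128 ripe, 255 unripe) and in memory as class-index arrays
{0, 1, 2}.  Real photographs (e.g. a StrawDI-style folder of images with
optional annotation masks) are letterboxed to the training resolution with
nearest-neighbor mask resampling so no new label values can appear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError, DataError, FormatError
from .scene import ClassLabelMap

SOURCE, TARGET_UNLABELED, TARGET_LABELED = "source", "target_unlabeled", "target_labeled"


@dataclass
class SamplePair:
    image: np.ndarray              # (H, W, 3) uint8
    target: np.ndarray | None      # (H, W) int class indices {0,1,2}, None if unlabeled
    id: str
    domain: str = SOURCE


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction {self.train_fraction} must be in (0, 1)"
            )


def mask_to_indices(mask: np.ndarray, label_map: ClassLabelMap | None = None) -> np.ndarray:
    """Map grayscale mask values to class indices; stray values are an error."""
    label_map = label_map or ClassLabelMap()
    lut = label_map.value_to_index
    bad = sorted(set(np.unique(mask).tolist()) - set(lut))
    if bad:
        raise FormatError(f"mask contains values {bad} outside {sorted(lut)}")
    target = np.zeros(mask.shape, dtype=np.int64)
    for value, index in lut.items():
        target[mask == value] = index
    return target


def indices_to_mask(target: np.ndarray, label_map: ClassLabelMap | None = None) -> np.ndarray:
    label_map = label_map or ClassLabelMap()
    lut = label_map.index_to_value
    bad = sorted(set(np.unique(target).tolist()) - set(lut))
    if bad:
        raise FormatError(f"target contains class indices {bad} outside {sorted(lut)}")
    mask = np.zeros(target.shape, dtype=np.uint8)
    for index, value in lut.items():
        mask[target == index] = value
    return mask


def load_pair(image_path, mask_path, label_map: ClassLabelMap | None = None) -> SamplePair:
    image = np.asarray(Image.open(image_path).convert("RGB"))
    mask_img = Image.open(mask_path)
    if mask_img.mode != "L":
        raise FormatError(f"{mask_path}: mask must be single-channel, got {mask_img.mode}")
    mask = np.asarray(mask_img)
    if mask.shape != image.shape[:2]:
        raise DataError(f"{mask_path}: mask {mask.shape} vs image {image.shape[:2]}")
    return SamplePair(image=image, target=mask_to_indices(mask, label_map),
                      id=Path(image_path).stem, domain=SOURCE)


def write_mask(target: np.ndarray, path, label_map: ClassLabelMap | None = None) -> None:
    Image.fromarray(indices_to_mask(target, label_map), mode="L").save(path)


def load_manifest(dataset_dir) -> dict:
    with open(Path(dataset_dir) / "manifest.json") as fh:
        return json.load(fh)


def load_dataset(dataset_dir, label_map: ClassLabelMap | None = None,
                 ids: list[str] | None = None) -> list[SamplePair]:
    """Load (a subset of) a generated dataset directory into memory."""
    root = Path(dataset_dir)
    manifest = load_manifest(root)
    wanted = set(ids) if ids is not None else None
    pairs = []
    for entry in manifest["samples"]:
        if wanted is not None and entry["id"] not in wanted:
            continue
        pairs.append(load_pair(root / "images" / f"{entry['id']}.png",
                               root / "masks" / f"{entry['id']}.png", label_map))
    return pairs


def split_dataset(manifest: dict | list, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Deterministic disjoint-exhaustive train/validation split of sample ids.

    |train| = round(train_fraction * n); the permutation depends only on the
    split seed, not on manifest ordering quirks (ids are sorted first).
    """
    samples = manifest["samples"] if isinstance(manifest, dict) else manifest
    ids = sorted(s["id"] if isinstance(s, dict) else str(s) for s in samples)
    if not ids:
        raise DataError("cannot split an empty manifest")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5B117]))
    perm = rng.permutation(len(ids))
    n_train = int(round(spec.train_fraction * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    val = sorted(ids[i] for i in perm[n_train:])
    return train, val


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance (0.299 R + 0.587 G + 0.114 B), rounded half up."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DataError(f"expected (H, W, 3) RGB, got shape {image.shape}")
    lum = image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114
    return np.floor(lum + 0.5).astype(np.uint8)


def letterbox(image: np.ndarray, size: tuple[int, int],
              is_mask: bool = False) -> np.ndarray:
    """Aspect-preserving resize onto a padded canvas (pad 0 / class background).

    Images are resized bilinearly, masks nearest-neighbor so the label set
    can only shrink, never grow.
    """
    th, tw = size
    h, w = image.shape[:2]
    scale = min(th / h, tw / w)
    nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    pil = Image.fromarray(image)
    resized = np.asarray(pil.resize((nw, nh),
                                    Image.NEAREST if is_mask else Image.BILINEAR))
    canvas = np.zeros(size + image.shape[2:], dtype=image.dtype)
    y0, x0 = (th - nh) // 2, (tw - nw) // 2
    canvas[y0:y0 + nh, x0:x0 + nw] = resized
    return canvas


def load_real_folder(images_dir, masks_dir=None, label_map: ClassLabelMap | None = None,
                     size: tuple[int, int] = (224, 224)) -> list[SamplePair]:
    """Adapt a folder of real photographs (masks optional) to training shape.

    Files are paired by stem name.  Pairs without a mask come back with
    ``domain='target_unlabeled'`` and ``target=None`` — exactly what the
    domain-confusion loss consumes.
    """
    if size[0] % 32 or size[1] % 32:
        raise ConfigurationError(f"target size {size} must be divisible by 32")
    img_root = Path(images_dir)
    mask_root = Path(masks_dir) if masks_dir is not None else None
    pairs: list[SamplePair] = []
    for img_path in sorted(img_root.glob("*.png")) + sorted(img_root.glob("*.jpg")):
        image = letterbox(np.asarray(Image.open(img_path).convert("RGB")), size)
        target = None
        domain = TARGET_UNLABELED
        if mask_root is not None:
            mask_path = mask_root / f"{img_path.stem}.png"
            if mask_path.exists():
                raw = np.asarray(Image.open(mask_path).convert("L"))
                target = mask_to_indices(letterbox(raw, size, is_mask=True), label_map)
                domain = TARGET_LABELED
        pairs.append(SamplePair(image=image, target=target, id=img_path.stem, domain=domain))
    return pairs


def pairs_to_arrays(pairs: list[SamplePair]) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack pairs into float32 image batch (scaled to [0,1]) + int target batch."""
    if not pairs:
        raise DataError("no sample pairs to stack")
    images = np.stack([p.image for p in pairs]).astype(np.float32) / 255.0
    if any(p.target is None for p in pairs):
        return images, None
    targets = np.stack([p.target for p in pairs]).astype(np.int64)
    return images, targets
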