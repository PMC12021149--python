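"""Procedural strawberry-plant scenes with pixel-perfect segmentation masks.

A scene is a flat list of 2-D primitives (wall, stems, leaf clusters, fruits,
calyces, flowers), each carrying a depth key and a semantic class.  Rendering
is a painter's algorithm: primitives are rasterized back-to-front and the
topmost primitive covering a pixel decides both its color and its mask label.
Fruits are labeled by ripeness stage (gray 128 = ripe, white 255 = unripe);
every other primitive — including leaves and flowers — is background (0), so
fruit regions hidden behind foliage are *not* labeled, exactly as a
visibility-based compositing mask behaves.

All randomness flows from integer seeds through ``numpy.random.Generator``
(PCG64); identical (config, seed) pairs give bit-identical images and masks.
"""

from __future__ import annotations

import colorsys
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, GenerationError

# Grayscale mask values (fixed constants) and their class-index order for logits.
BACKGROUND, RIPE, UNRIPE = 0, 128, 255
MASK_VALUES = (BACKGROUND, RIPE, UNRIPE)
CLASS_NAMES = ("background", "ripe", "unripe")

#: ripeness stage at or above which a fruit counts as ripe
RIPE_THRESHOLD = 0.5

# Anchor colors for the ripeness gradient (RGB, 8-bit scale).
UNRIPE_GREEN = np.array([110.0, 175.0, 75.0])
RIPE_RED = np.array([200.0, 30.0, 40.0])


@dataclass(frozen=True)
class ClassLabelMap:
    """Bijection between grayscale mask values and class indices."""

    background: int = BACKGROUND
    ripe: int = RIPE
    unripe: int = UNRIPE

    @property
    def value_to_index(self) -> dict[int, int]:
        return {self.background: 0, self.ripe: 1, self.unripe: 2}

    @property
    def index_to_value(self) -> dict[int, int]:
        return {i: v for v, i in self.value_to_index.items()}


def _check_interval(name: str, lo: float, hi: float) -> None:
    if lo > hi:
        raise ConfigurationError(f"{name}: interval min {lo} > max {hi}")


@dataclass(frozen=True)
class RandomizationRanges:
    """Constrained parameter intervals driving plant-to-plant variability.

    Defaults emulate an indoor vertical grow-wall scene: a few gently curved
    stems, several trifoliate leaves per stem, and 2-6 fruits spanning the
    whole green-to-red ripeness gradient so that both fruit classes occur.
    ``leaf_hue`` is in HSV degrees (about 80-140 spans light to dark green);
    ``stem_noise_amp`` is a fraction of image height; angles in radians.
    """

    stem_count: tuple[int, int] = (2, 4)
    stem_noise_amp: tuple[float, float] = (0.01, 0.05)
    leaves_per_stem: tuple[int, int] = (2, 5)
    leaf_scale: tuple[float, float] = (0.8, 1.2)
    leaf_hue: tuple[float, float] = (95.0, 140.0)
    leaf_curl: tuple[float, float] = (0.0, 0.6)
    fruit_count: tuple[int, int] = (2, 6)
    ripeness_stage: tuple[float, float] = (0.0, 1.0)
    fruit_scale: tuple[float, float] = (0.8, 1.3)
    flower_prob: float = 0.3
    camera_t: tuple[float, float] = (0.0, 1.0)
    camera_angle: tuple[float, float] = (-0.15, 0.15)
    brightness: tuple[float, float] = (0.85, 1.15)

    def validate(self) -> None:
        for name in (
            "stem_count", "stem_noise_amp", "leaves_per_stem", "leaf_scale",
            "leaf_hue", "leaf_curl", "fruit_count", "ripeness_stage",
            "fruit_scale", "camera_t", "camera_angle", "brightness",
        ):
            lo, hi = getattr(self, name)
            _check_interval(name, lo, hi)
        if not 0.0 <= self.flower_prob <= 1.0:
            raise ConfigurationError(f"flower_prob {self.flower_prob} outside [0, 1]")
        if self.fruit_count[1] < 2:
            raise ConfigurationError(
                "fruit_count max must be >= 2 so both ripeness classes can appear"
            )
        lo, hi = self.camera_t
        if lo < 0.0 or hi > 1.0:
            raise ConfigurationError("camera_t interval must lie within [0, 1]")
        lo, hi = self.ripeness_stage
        if lo < 0.0 or hi > 1.0:
            raise ConfigurationError("ripeness_stage interval must lie within [0, 1]")


@dataclass(frozen=True)
class LeafSpec:
    t: float
    scale: float
    hue: float
    curl: float
    rotation: float
    depth: float


@dataclass(frozen=True)
class FruitSpec:
    t: float
    scale: float
    stage: float
    depth: float
    side: float  # lateral offset sign/magnitude of the hanging fruit


@dataclass(frozen=True)
class FlowerSpec:
    t: float
    scale: float
    rotation: float
    depth: float


@dataclass(frozen=True)
class StemSpec:
    points: tuple[tuple[float, float], ...]  # polyline control points, world coords
    leaves: tuple[LeafSpec, ...]
    fruits: tuple[FruitSpec, ...]
    flowers: tuple[FlowerSpec, ...]


@dataclass(frozen=True)
class PlantSpec:
    stems: tuple[StemSpec, ...]
    seed: int

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:16]

    def fruit_stages(self) -> list[float]:
        return [f.stage for s in self.stems for f in s.fruits]


@dataclass(frozen=True)
class CameraView:
    """Position ``t`` along a horizontal track plus a roll angle.

    Realized as a similarity transform of the viewport: the track slides the
    view laterally (up to +/-15% of the frame) and the angle rotates it about
    the frame center.
    """

    t: float = 0.5
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ConfigurationError(f"camera t {self.t} outside [0, 1]")


@dataclass
class RenderedSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8, values in {0, 128, 255}
    seed: int
    spec_digest: str


@dataclass(frozen=True)
class DomainShiftParams:
    """Appearance shift emulating a camera/scene change, labels untouched.

    A desk-scale stand-in for real-world target imagery: color cast,
    desaturation, sensor noise (8-bit units), optical blur (pixels), a busier
    background texture and vignetting.  The all-zero/flat setting is an exact
    identity.
    """

    hue_shift: float = -12.0
    saturation_scale: float = 0.75
    gaussian_noise_sd: float = 8.0
    blur_sigma: float = 0.7
    background_texture: str = "photo_like"
    vignette_strength: float = 0.35

    def __post_init__(self) -> None:
        if self.gaussian_noise_sd < 0:
            raise ConfigurationError("gaussian_noise_sd must be >= 0")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")
        if self.background_texture not in ("flat", "speckle", "photo_like"):
            raise ConfigurationError(
                f"unknown background_texture {self.background_texture!r}"
            )

    @classmethod
    def identity(cls) -> "DomainShiftParams":
        return cls(0.0, 1.0, 0.0, 0.0, "flat", 0.0)


# ---------------------------------------------------------------------------
# Fruit classification and coloring
# ---------------------------------------------------------------------------

def classify_fruit(stage: float) -> str:
    """Map a continuous ripeness stage to 'ripe' or 'unripe' (>= 0.5 is ripe)."""
    if not 0.0 <= stage <= 1.0:
        raise ValueError(f"ripeness stage {stage} outside [0, 1]")
    return "ripe" if stage >= RIPE_THRESHOLD else "unripe"


def fruit_mask_value(stage: float) -> int:
    return RIPE if classify_fruit(stage) == "ripe" else UNRIPE


def fruit_color(stage: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Continuous green-to-red ripeness gradient with optional per-fruit jitter.

    ``stage`` 0 gives the unripe green anchor, 1 the ripe red anchor; the
    jitter (when an rng is supplied) perturbs each channel by ~5% to mimic
    natural color variation between individual berries.
    """
    if not 0.0 <= stage <= 1.0:
        raise ValueError(f"ripeness stage {stage} outside [0, 1]")
    base = (1.0 - stage) * UNRIPE_GREEN + stage * RIPE_RED
    if rng is not None:
        base = base + rng.normal(0.0, 6.0, size=3)
    return np.clip(base, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Plant sampling
# ---------------------------------------------------------------------------

_BOTH_CLASS_RETRIES = 20


def _uniform(rng: np.random.Generator, iv: tuple[float, float]) -> float:
    return float(rng.uniform(iv[0], iv[1]))


def _randint(rng: np.random.Generator, iv: tuple[int, int]) -> int:
    return int(rng.integers(iv[0], iv[1] + 1))


def _sample_stages(rng: np.random.Generator, n: int, iv: tuple[float, float]) -> list[float]:
    """Draw n ripeness stages, retrying until both classes are represented."""
    for _ in range(_BOTH_CLASS_RETRIES):
        stages = [_uniform(rng, iv) for _ in range(n)]
        labels = {classify_fruit(s) for s in stages}
        if labels == {"ripe", "unripe"}:
            return stages
    raise GenerationError(
        f"could not draw both ripe and unripe stages from interval {iv} "
        f"within {_BOTH_CLASS_RETRIES} attempts"
    )


def sample_plant(ranges: RandomizationRanges, seed: int) -> PlantSpec:
    """Sample a randomized plant: stem curves plus leaf/fruit/flower attachments.

    Deterministic in (ranges, seed).  Ripeness stages are resampled (bounded
    retry) until at least one fruit falls on each side of the ripe threshold.
    """
    ranges.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    n_stems = _randint(rng, ranges.stem_count)
    n_fruits_total = max(_randint(rng, ranges.fruit_count), 2)
    stages = _sample_stages(rng, n_fruits_total, ranges.ripeness_stage)
    # deal fruits round-robin onto stems so every plant hangs its berries
    fruit_stem = [i % n_stems for i in range(n_fruits_total)]

    stems = []
    n_ctrl = 10
    for si in range(n_stems):
        x0 = float(rng.uniform(0.2, 0.8))
        drift = float(rng.uniform(-0.12, 0.12))
        amp = _uniform(rng, ranges.stem_noise_amp)
        base = np.array([x0, 0.95])
        top = np.array([np.clip(x0 + drift, 0.08, 0.92), 0.22])
        ts = np.linspace(0.0, 1.0, n_ctrl)
        line = base[None, :] * (1 - ts[:, None]) + top[None, :] * ts[:, None]
        # perpendicular bow + per-point jitter, both scaled by the noise amplitude
        bow = np.sin(ts * np.pi) * float(rng.uniform(-1.0, 1.0))
        jitter = rng.normal(0.0, 0.35, n_ctrl)
        jitter[0] = jitter[-1] = 0.0
        line[:, 0] += amp * (bow + jitter)
        points = tuple((float(x), float(y)) for x, y in line)

        leaves = tuple(
            LeafSpec(
                t=float(rng.uniform(0.25, 0.95)),
                scale=_uniform(rng, ranges.leaf_scale),
                hue=_uniform(rng, ranges.leaf_hue),
                curl=_uniform(rng, ranges.leaf_curl),
                rotation=float(rng.uniform(0.0, 2.0 * np.pi)),
                depth=float(rng.uniform(2.0, 3.0)),
            )
            for _ in range(_randint(rng, ranges.leaves_per_stem))
        )
        fruits = tuple(
            FruitSpec(
                t=float(rng.uniform(0.35, 0.9)),
                scale=_uniform(rng, ranges.fruit_scale),
                stage=stages[fi],
                depth=float(rng.uniform(2.0, 3.0)),
                side=float(rng.uniform(-0.03, 0.03)),
            )
            for fi in range(n_fruits_total)
            if fruit_stem[fi] == si
        )
        flowers = tuple(
            FlowerSpec(
                t=float(rng.uniform(0.5, 0.98)),
                scale=float(rng.uniform(0.8, 1.2)),
                rotation=float(rng.uniform(0.0, 2.0 * np.pi)),
                depth=float(rng.uniform(2.0, 3.0)),
            )
            for _ in range(int(rng.random() < ranges.flower_prob))
        )
        stems.append(StemSpec(points=points, leaves=leaves, fruits=fruits, flowers=flowers))

    return PlantSpec(stems=tuple(stems), seed=int(seed))


def sample_view(ranges: RandomizationRanges, seed: int) -> tuple[CameraView, float]:
    """Sample a camera-track position/roll and a brightness factor."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0CA3]))
    view = CameraView(t=_uniform(rng, ranges.camera_t), angle=_uniform(rng, ranges.camera_angle))
    return view, _uniform(rng, ranges.brightness)


# ---------------------------------------------------------------------------
# Primitives and rasterization
# ---------------------------------------------------------------------------

@dataclass
class Primitive:
    """One paintable element: analytic coverage + a coloring rule + depth key."""

    name: str
    class_value: int
    depth: float
    kind: str            # 'wall' | 'polyline' | 'ellipses' | 'disks'
    geom: dict = field(default_factory=dict)
    color: dict = field(default_factory=dict)

    def coverage(self, wx: np.ndarray, wy: np.ndarray) -> np.ndarray:
        if self.kind == "wall":
            return np.ones_like(wx, dtype=bool)
        if self.kind == "polyline":
            pts = np.asarray(self.geom["points"])
            half = self.geom["width"] / 2.0
            p = np.stack([wx, wy], axis=-1)[..., None, :]        # (H,W,1,2)
            a = pts[None, None, :-1, :]                          # (1,1,S,2)
            b = pts[None, None, 1:, :]
            ab = b - a
            denom = np.maximum((ab * ab).sum(-1), 1e-12)
            tt = np.clip(((p - a) * ab).sum(-1) / denom, 0.0, 1.0)
            proj = a + tt[..., None] * ab
            d2 = ((p - proj) ** 2).sum(-1).min(axis=-1)
            return d2 <= half * half
        if self.kind == "ellipses":
            cover = np.zeros_like(wx, dtype=bool)
            for cx, cy, ax, bx, th in self.geom["ellipses"]:
                c, s = np.cos(th), np.sin(th)
                u = c * (wx - cx) + s * (wy - cy)
                v = -s * (wx - cx) + c * (wy - cy)
                cover |= (u / ax) ** 2 + (v / bx) ** 2 <= 1.0
            return cover
        if self.kind == "disks":
            cover = np.zeros_like(wx, dtype=bool)
            for cx, cy, r in self.geom["disks"]:
                cover |= (wx - cx) ** 2 + (wy - cy) ** 2 <= r * r
            return cover
        raise ValueError(f"unknown primitive kind {self.kind}")

    def paint(self, wx: np.ndarray, wy: np.ndarray, cover: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
        """Return an (H, W, 3) float color field; only values under cover are used."""
        h, w = wx.shape
        out = np.zeros((h, w, 3), dtype=np.float64)
        c = self.color
        if self.kind == "wall":
            # vertical gradient + smoothed low-frequency noise for a plaster look
            grad = 1.0 - 0.25 * wy
            noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(h, w) / 24)
            noise = noise / (np.abs(noise).max() + 1e-9)
            shade = np.clip(grad + 0.15 * noise, 0.0, 1.2)
            out[:] = np.asarray(c["base"])[None, None, :] * shade[..., None]
            return out
        base = np.asarray(c["base"], dtype=np.float64)
        cx, cy = c.get("center", (0.5, 0.5))
        r2 = (wx - cx) ** 2 + (wy - cy) ** 2
        extent = c.get("extent", 0.08)
        shade = 1.0 - c.get("falloff", 0.35) * np.clip(r2 / (extent * extent), 0.0, 1.0)
        out[:] = base[None, None, :] * shade[..., None]
        if c.get("speckle", 0.0) > 0.0 and cover.any():
            idx = np.flatnonzero(cover)
            k = max(1, int(len(idx) * 0.04))
            chosen = rng.choice(idx, size=min(k, len(idx)), replace=False)
            flat = out.reshape(-1, 3)
            flat[chosen] *= 1.0 - c["speckle"]
        return out


def _leaf_color(hue_deg: float, value_jitter: float) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb(hue_deg / 360.0, 0.55, np.clip(0.45 + value_jitter, 0.1, 0.9))
    return np.array([r, g, b]) * 255.0


def _stem_point(points: Sequence[tuple[float, float]], t: float) -> np.ndarray:
    pts = np.asarray(points)
    x = np.interp(t, np.linspace(0, 1, len(pts)), pts[:, 0])
    y = np.interp(t, np.linspace(0, 1, len(pts)), pts[:, 1])
    return np.array([x, y])


def build_primitives(spec: PlantSpec) -> list[Primitive]:
    """Expand a PlantSpec into the depth-ordered primitive list of its scene."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0105]))
    prims: list[Primitive] = [
        Primitive("wall", BACKGROUND, 0.0, "wall",
                  color={"base": np.array([126.0, 116.0, 102.0])})
    ]
    for si, stem in enumerate(spec.stems):
        prims.append(Primitive(
            f"stem{si}", BACKGROUND, 1.0 + 0.01 * si, "polyline",
            geom={"points": [list(p) for p in stem.points], "width": 0.014},
            color={"base": np.array([70.0, 105.0, 55.0]) + rng.normal(0, 5, 3),
                   "falloff": 0.0},
        ))
        for li, leaf in enumerate(stem.leaves):
            at = _stem_point(stem.points, leaf.t)
            lobes = []
            for k in (-1, 0, 1):
                ang = leaf.rotation + k * 0.55
                d = 0.052 * leaf.scale
                lc = at + d * np.array([np.cos(ang), np.sin(ang)])
                a_ax = 0.060 * leaf.scale
                b_ax = 0.040 * leaf.scale / (1.0 + leaf.curl)
                lobes.append((float(lc[0]), float(lc[1]), a_ax, b_ax, float(ang)))
            prims.append(Primitive(
                f"stem{si}/leaf{li}", BACKGROUND, leaf.depth, "ellipses",
                geom={"ellipses": lobes},
                color={"base": _leaf_color(leaf.hue, float(rng.normal(0, 0.04))),
                       "center": tuple(at), "extent": 0.11 * leaf.scale,
                       "falloff": 0.45, "speckle": 0.12},
            ))
        for fi, fruit in enumerate(stem.fruits):
            at = _stem_point(stem.points, fruit.t)
            center = at + np.array([fruit.side, 0.075 * fruit.scale])
            a_ax = 0.055 * fruit.scale
            b_ax = 0.070 * fruit.scale
            prims.append(Primitive(
                f"stem{si}/fruit{fi}", fruit_mask_value(fruit.stage), fruit.depth,
                "ellipses",
                geom={"ellipses": [(float(center[0]), float(center[1]), a_ax, b_ax,
                                    float(fruit.side) * 4.0)]},
                color={"base": fruit_color(fruit.stage, rng),
                       "center": tuple(center), "extent": b_ax * 1.4,
                       "falloff": 0.4, "speckle": 0.35},
            ))
            # calyx: little green cap where the berry meets its stem (background class)
            prims.append(Primitive(
                f"stem{si}/calyx{fi}", BACKGROUND, fruit.depth + 1e-3, "ellipses",
                geom={"ellipses": [(float(center[0]), float(center[1] - b_ax * 0.95),
                                    a_ax * 0.55, b_ax * 0.28, 0.0)]},
                color={"base": np.array([60.0, 110.0, 50.0]),
                       "center": tuple(center), "extent": a_ax, "falloff": 0.2},
            ))
        for wi, flower in enumerate(stem.flowers):
            at = _stem_point(stem.points, flower.t)
            pr = 0.016 * flower.scale
            petals = [
                (float(at[0] + 2.1 * pr * np.cos(flower.rotation + 2 * np.pi * k / 5)),
                 float(at[1] + 2.1 * pr * np.sin(flower.rotation + 2 * np.pi * k / 5)),
                 1.4 * pr)
                for k in range(5)
            ]
            prims.append(Primitive(
                f"stem{si}/flower{wi}", BACKGROUND, flower.depth, "disks",
                geom={"disks": petals},
                color={"base": np.array([240.0, 238.0, 228.0]),
                       "center": tuple(at), "extent": 4 * pr, "falloff": 0.25},
            ))
            prims.append(Primitive(
                f"stem{si}/flower{wi}/center", BACKGROUND, flower.depth + 1e-3, "disks",
                geom={"disks": [(float(at[0]), float(at[1]), pr)]},
                color={"base": np.array([235.0, 200.0, 60.0]), "falloff": 0.0},
            ))
    prims.sort(key=lambda p: p.depth)  # stable: ties keep build order
    return prims


def _world_grid(view: CameraView, size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """World coordinates of each pixel center under the camera transform."""
    h, w = size
    ys, xs = np.mgrid[0:h, 0:w]
    qx = (xs + 0.5) / w
    qy = (ys + 0.5) / h
    dx = (view.t - 0.5) * 0.3
    c, s = np.cos(-view.angle), np.sin(-view.angle)
    ux = qx - 0.5 - dx
    uy = qy - 0.5
    wx = c * ux - s * uy + 0.5
    wy = s * ux + c * uy + 0.5
    return wx, wy


def _check_size(size: tuple[int, int]) -> None:
    h, w = size
    if h % 32 or w % 32:
        raise ConfigurationError(f"image size {size} must be divisible by 32")


def render_scene(spec: PlantSpec, view: CameraView, brightness: float = 1.0,
                 size: tuple[int, int] = (224, 224)) -> RenderedSample:
    """Rasterize a plant back-to-front into a paired RGB image and class mask.

    The mask is produced from the *same* transformed geometry as the image: a
    pixel's label is the class of the topmost primitive covering it, so
    occluded fruit regions stay background.
    """
    _check_size(size)
    wx, wy = _world_grid(view, size)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9A147]))
    image = np.zeros(size + (3,), dtype=np.float64)
    mask = np.zeros(size, dtype=np.uint8)
    for prim in build_primitives(spec):
        cover = prim.coverage(wx, wy)
        colors = prim.paint(wx, wy, cover, rng)
        image[cover] = colors[cover]
        mask[cover] = prim.class_value
    image = np.clip(image * brightness, 0.0, 255.0)
    return RenderedSample(
        image=np.round(image).astype(np.uint8),
        mask=mask,
        seed=spec.seed,
        spec_digest=spec.digest(),
    )


# ---------------------------------------------------------------------------
# Domain shift
# ---------------------------------------------------------------------------

def apply_domain_shift(sample: RenderedSample, params: DomainShiftParams,
                       seed: int) -> RenderedSample:
    """Shift the image's appearance; the mask is returned bit-identical.

    Steps (each skipped exactly when its parameter is the identity, so the
    all-zero/flat setting returns the input image unchanged): HSV hue rotation
    and saturation scaling, background texturing restricted to mask==0 pixels,
    Gaussian blur, additive Gaussian sensor noise, and vignetting.
    """
    from skimage import color as skcolor

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5417F]))
    img = sample.image.astype(np.float64) / 255.0
    h, w = sample.mask.shape

    if params.hue_shift != 0.0 or params.saturation_scale != 1.0:
        hsv = skcolor.rgb2hsv(img)
        hsv[..., 0] = np.mod(hsv[..., 0] + params.hue_shift / 360.0, 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * params.saturation_scale, 0.0, 1.0)
        img = skcolor.hsv2rgb(hsv)

    bg = sample.mask == BACKGROUND
    if params.background_texture == "speckle":
        tex = rng.normal(0.0, 0.12, (h, w))
        img[bg] = np.clip(img[bg] * (1.0 + tex[bg][:, None]), 0.0, 1.0)
    elif params.background_texture == "photo_like":
        # low-frequency colored field, as if the wall were cluttered foliage/soil
        field_ = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w, 3)),
                                         sigma=(h / 16, w / 16, 0))
        field_ = field_ / (np.abs(field_).max() + 1e-9)
        tint = np.array([0.35, 0.3, 0.22]) + 0.25 * field_
        img[bg] = np.clip(0.45 * img[bg] + 0.55 * tint[bg], 0.0, 1.0)

    if params.blur_sigma > 0.0:
        img = ndimage.gaussian_filter(img, sigma=(params.blur_sigma, params.blur_sigma, 0))

    if params.gaussian_noise_sd > 0.0:
        img = img + rng.normal(0.0, params.gaussian_noise_sd / 255.0, img.shape)

    if params.vignette_strength > 0.0:
        ys, xs = np.mgrid[0:h, 0:w]
        r2 = ((xs / w - 0.5) ** 2 + (ys / h - 0.5) ** 2) / 0.5
        img = img * (1.0 - params.vignette_strength * r2)[..., None]

    out = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    return RenderedSample(image=out, mask=sample.mask.copy(),
                          seed=sample.seed, spec_digest=sample.spec_digest)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

MANIFEST_VERSION = 1
_VISIBILITY_RETRIES = 20


def _render_one(ranges: RandomizationRanges, sample_seed: int,
                size: tuple[int, int],
                shift: DomainShiftParams | None) -> RenderedSample:
    """One fully seeded sample; retries until both fruit classes are visible."""
    for attempt in range(_VISIBILITY_RETRIES):
        seed_k = int(np.random.SeedSequence([sample_seed, attempt]).generate_state(1)[0] % (2**31))
        spec = sample_plant(ranges, seed_k)
        view, brightness = sample_view(ranges, seed_k)
        sample = render_scene(spec, view, brightness, size)
        values = set(np.unique(sample.mask).tolist())
        if RIPE in values and UNRIPE in values:
            if shift is not None:
                sample = apply_domain_shift(sample, shift, seed_k)
            return sample
    raise GenerationError(
        f"sample seed {sample_seed}: no view with both fruit classes visible "
        f"after {_VISIBILITY_RETRIES} attempts"
    )


def generate_samples(n: int, ranges: RandomizationRanges, seed: int,
                     size: tuple[int, int] = (224, 224),
                     shift: DomainShiftParams | None = None) -> list[RenderedSample]:
    """In-memory batch generation; each sample seeded from a spawned child seed."""
    ranges.validate()
    _check_size(size)
    children = np.random.SeedSequence(seed).spawn(n)
    return [
        _render_one(ranges, int(child.generate_state(1)[0] % (2**31)), size, shift)
        for child in children
    ]


def generate_dataset(n: int, ranges: RandomizationRanges, seed: int, out_dir,
                     shift: DomainShiftParams | None = None,
                     size: tuple[int, int] = (224, 224)) -> dict:
    """Write n image/mask PNG pairs plus a JSON manifest; returns the manifest.

    Layout: ``out_dir/images/{id}.png`` (RGB), ``out_dir/masks/{id}.png``
    (grayscale 0/128/255), ``out_dir/manifest.json``.  Per-sample seeds are
    spawned from the root seed (numpy SeedSequence), so generation is
    reproducible and each sample is independently re-derivable.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, ranges, seed, size, shift)
    entries = []
    for i, sample in enumerate(samples):
        sid = f"{i:06d}"
        Image.fromarray(sample.image, mode="RGB").save(out / "images" / f"{sid}.png")
        Image.fromarray(sample.mask, mode="L").save(out / "masks" / f"{sid}.png")
        values, counts = np.unique(sample.mask, return_counts=True)
        entries.append({
            "id": sid,
            "seed": sample.seed,
            "spec_digest": sample.spec_digest,
            "class_pixel_counts": {str(int(v)): int(c) for v, c in zip(values, counts)},
        })
    manifest = {
        "version": MANIFEST_VERSION,
        "root_seed": int(seed),
        "size": list(size),
        "ranges": asdict(ranges),
        "domain_shift": asdict(shift) if shift is not None else None,
        "samples": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
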