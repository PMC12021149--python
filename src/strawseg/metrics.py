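"""Per-class Dice Similarity Coefficient evaluation and report rendering.

DSC for a class is 2|X∩Y| / (|X| + |Y|) where X and Y are the predicted and
true pixel sets of that class.  Dataset-level scores are micro-averaged by
default: the three counts are pooled over every evaluated image before the
ratio is taken, so the score is independent of image ordering; a per-image
macro mean is available by flag.  When a class is absent from both prediction
and truth (|X| + |Y| = 0) the coefficient is defined as 1.0 — agreed absence
counts as perfect agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import SamplePair, pairs_to_arrays
from .errors import DataError
from .scene import CLASS_NAMES


@dataclass
class EvalReport:
    dsc: dict[str, float]                 # class name -> DSC in [0, 1]
    n_images: int
    pixel_counts: dict[str, dict[str, int]]  # class -> {pred, true, intersection}
    average: str = "micro"
    config_digest: str = ""
    history: dict = field(default_factory=dict)

    @property
    def fruit_mean(self) -> float:
        return 0.5 * (self.dsc["ripe"] + self.dsc["unripe"])

    def to_json(self) -> str:
        return json.dumps({
            "dsc": self.dsc, "n_images": self.n_images,
            "pixel_counts": self.pixel_counts, "average": self.average,
            "config_digest": self.config_digest,
        }, indent=1, sort_keys=True)

    def to_table(self) -> str:
        """Text table in the Ripe / Unripe / Background row layout."""
        lines = [f"{'Class':<12}{'DSC (%)':>10}"]
        for name in ("ripe", "unripe", "background"):
            lines.append(f"{name.capitalize():<12}{100.0 * self.dsc[name]:>10.1f}")
        return "\n".join(lines)


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray, label) -> float:
    """DSC of one class between two index (or grayscale-value) masks."""
    pred_mask, true_mask = np.asarray(pred_mask), np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"shape mismatch {pred_mask.shape} vs {true_mask.shape}")
    x = pred_mask == label
    y = true_mask == label
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / denom


def _class_counts(pred: np.ndarray, true: np.ndarray, index: int) -> tuple[int, int, int]:
    x = pred == index
    y = true == index
    return int(x.sum()), int(y.sum()), int((x & y).sum())


def evaluate(net, params, pairs: list[SamplePair], average: str = "micro",
             batch_size: int = 16) -> EvalReport:
    """Run the segmenter over labeled pairs and score per-class DSC.

    ``average='micro'`` pools pixel counts over all images (default);
    ``'macro'`` averages per-image DSC values instead.
    """
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")
    if not pairs:
        raise DataError("evaluation dataset is empty")
    if any(p.target is None for p in pairs):
        raise DataError("evaluation requires labeled pairs (found target=None)")

    pooled = {name: [0, 0, 0] for name in CLASS_NAMES}
    per_image: dict[str, list[float]] = {name: [] for name in CLASS_NAMES}
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        images, targets = pairs_to_arrays(chunk)
        preds = net.predict(params, images)
        for b in range(len(chunk)):
            for idx, name in enumerate(CLASS_NAMES):
                px, py, pi = _class_counts(preds[b], targets[b], idx)
                pooled[name][0] += px
                pooled[name][1] += py
                pooled[name][2] += pi
                per_image[name].append(dice_coefficient(preds[b], targets[b], idx))

    dsc = {}
    for name in CLASS_NAMES:
        if average == "micro":
            px, py, pi = pooled[name]
            dsc[name] = 1.0 if px + py == 0 else 2.0 * pi / (px + py)
        else:
            dsc[name] = float(np.mean(per_image[name]))
    counts = {name: {"pred": pooled[name][0], "true": pooled[name][1],
                     "intersection": pooled[name][2]} for name in CLASS_NAMES}
    return EvalReport(dsc=dsc, n_images=len(pairs), pixel_counts=counts,
                      average=average)
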