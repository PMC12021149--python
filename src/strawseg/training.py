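"""Joint-loss training with domain-adaptation batches, plus the dataset-size
scaling study.

Each optimization step draws a labeled source (synthetic) batch and an
unlabeled target batch, computes the joint objective — weighted CE + Dice on
the source predictions, squared MMD between pooled bottleneck features of the
two domains — and applies an AdamW update with cosine learning-rate decay.
Everything is seeded, so two runs with the same config produce identical loss
histories and checkpoints.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from autograd import value_and_grad

from .dataset import SamplePair, pairs_to_arrays
from .errors import ConfigurationError, DataError
from .losses import LossWeights, joint_loss, median_heuristic_bandwidths
from .metrics import EvalReport, evaluate
from .model import ModelConfig, SwinUNet


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  The full-scale default trains for 400 epochs;
    desk presets use ~30."""

    epochs: int = 400
    batch_size: int = 8
    target_batch_size: int = 8
    optimizer: str = "adamw"
    learning_rate: float = 3e-4
    weight_decay: float = 0.01
    schedule: str = "cosine"  # or "constant"
    seed: int = 0
    eval_every: int = 5       # epochs between validation passes (0 = never)
    checkpoint_dir: str | None = None
    allow_no_target: bool = False  # lambda forced to 0 when target pool empty
    # "fit first, then align": the domain weight is held at 0 for the first
    # `domain_delay_frac` of all steps, then ramped linearly to its full value
    # over the next `domain_ramp_frac`.
    domain_delay_frac: float = 0.5
    domain_ramp_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1 or self.target_batch_size < 1:
            raise ConfigurationError("batch sizes must be >= 1")
        if self.optimizer != "adamw":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("cosine", "constant"):
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")
        if not 0.0 <= self.domain_delay_frac <= 1.0:
            raise ConfigurationError("domain_delay_frac must be in [0, 1]")
        if self.domain_ramp_frac < 0.0:
            raise ConfigurationError("domain_ramp_frac must be >= 0")


@dataclass
class TrainResult:
    params: dict                 # best-validation parameters (or final)
    final_params: dict
    history: list[dict]          # per-step loss breakdowns + eval records
    best_val: EvalReport | None


@dataclass
class ScalingResult:
    """Rows of the dataset-size study: (n_train, DSC ripe, DSC unripe)."""

    rows: list[tuple[int, float, float]] = field(default_factory=list)

    def to_table(self) -> str:
        lines = [f"{'No. of Images':<15}{'DSC (Ripe)':>12}{'DSC (Unripe)':>14}"]
        for n, r, u in self.rows:
            lines.append(f"{n:<15}{100 * r:>12.2f}{100 * u:>14.2f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps([{"n_train": n, "dsc_ripe": r, "dsc_unripe": u}
                           for n, r, u in self.rows], indent=1)


# ---------------------------------------------------------------------------
# Parameter-tree utilities and AdamW
# ---------------------------------------------------------------------------

def tree_leaves(tree):
    """Depth-first (path, array) pairs of a nested dict/list parameter tree."""
    out = []

    def walk(node, path):
        if isinstance(node, dict):
            for k in sorted(node):
                walk(node[k], path + (k,))
        elif isinstance(node, (list, tuple)):
            for i, v in enumerate(node):
                walk(v, path + (i,))
        else:
            out.append((path, node))

    walk(tree, ())
    return out


def tree_get(tree, path):
    for k in path:
        tree = tree[k]
    return tree


def tree_set(tree, path, value):
    for k in path[:-1]:
        tree = tree[k]
    tree[path[-1]] = value


class AdamW:
    """Decoupled weight-decay Adam over a nested parameter tree."""

    def __init__(self, params, lr=3e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01):
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.t = 0
        self.m = {p: np.zeros_like(v) for p, v in tree_leaves(params)}
        self.v = {p: np.zeros_like(v) for p, v in tree_leaves(params)}

    def step(self, params, grads, lr_scale: float = 1.0):
        self.t += 1
        b1, b2 = self.betas
        lr = self.lr * lr_scale
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for path, g in tree_leaves(grads):
            g = np.asarray(g, dtype=np.float32)
            p = tree_get(params, path)
            m = self.m[path] = b1 * self.m[path] + (1 - b1) * g
            v = self.v[path] = b2 * self.v[path] + (1 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            tree_set(params, path,
                     (p - lr * (update + self.wd * p)).astype(np.float32))
        return params


def _lr_scale(schedule: str, step: int, total: int) -> float:
    if schedule == "constant" or total <= 1:
        return 1.0
    return 0.5 * (1.0 + float(np.cos(np.pi * step / max(total - 1, 1))))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, config: ModelConfig, params: dict) -> None:
    """Single .npz holding the config echo plus every parameter leaf."""
    arrays = {"/".join(map(str, p)): v for p, v in tree_leaves(params)}
    cfg = asdict(config)
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> tuple[SwinUNet, dict]:
    with np.load(path, allow_pickle=False) as data:
        cfg_raw = json.loads(str(data["__config__"]))
        for key in ("image_size", "depths", "num_heads"):
            cfg_raw[key] = tuple(cfg_raw[key])
        config = ModelConfig(**cfg_raw)
        net = SwinUNet(config)
        params = net.init_params(0)
        for path_key in data.files:
            if path_key == "__config__":
                continue
            parts = tuple(int(p) if p.isdigit() else p for p in path_key.split("/"))
            tree_set(params, parts, data[path_key].astype(np.float32))
    return net, params


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(net: SwinUNet, params: dict, source_pairs: list[SamplePair],
          target_images: np.ndarray | None, loss_weights: LossWeights,
          config: TrainConfig, val_pairs: list[SamplePair] | None = None,
          log_path=None, progress: bool = False) -> TrainResult:
    """Optimize the joint objective; returns best-validation parameters.

    ``target_images`` is an (M, H, W, 3) float batch pool of unlabeled
    target-domain images (None or empty only with domain_weight 0 or
    ``allow_no_target``).  Validation DSC is computed every ``eval_every``
    epochs and at the end; the checkpoint with the highest fruit-class mean
    DSC is retained.
    """
    if not source_pairs:
        raise DataError("no labeled source pairs to train on")
    lam = loss_weights.domain_weight
    n_target = 0 if target_images is None else len(target_images)
    if lam > 0.0 and n_target == 0:
        if not config.allow_no_target:
            raise ConfigurationError(
                "domain_weight > 0 but the target pool is empty "
                "(set allow_no_target to fall back to supervised training)")
        import warnings

        warnings.warn("empty target pool: domain term disabled (lambda -> 0)")
        lam = 0.0
    use_mmd = lam > 0.0
    weights = LossWeights(**{**asdict(loss_weights), "domain_weight": lam})

    images, targets = pairs_to_arrays(source_pairs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7124]))
    n = len(source_pairs)
    steps_per_epoch = max(1, n // config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    opt = AdamW(params, lr=config.learning_rate, weight_decay=config.weight_decay)

    # Freeze RBF bandwidths once from the initial feature distributions so the
    # kernel is a fixed function during optimization.
    if use_mmd and weights.mmd_kernel == "rbf" and weights.rbf_bandwidths is None:
        k = min(16, n)
        kt = min(16, n_target)
        s0 = net.extract_adaptation_features(params, images[:k])
        t0 = net.extract_adaptation_features(params, target_images[:kt])
        bw = median_heuristic_bandwidths(s0, t0, weights.bandwidth_multipliers)
        weights = LossWeights(**{**asdict(weights), "rbf_bandwidths": bw})

    history: list[dict] = []
    best = {"params": copy.deepcopy(params), "score": -1.0, "report": None}
    log_fh = open(log_path, "w") if log_path else None

    def run_validation(epoch):
        if not val_pairs:
            return None
        report = evaluate(net, params, val_pairs)
        record = {"event": "eval", "epoch": epoch, "dsc": report.dsc}
        history.append(record)
        if log_fh:
            log_fh.write(json.dumps(record) + "\n")
        if report.fruit_mean > best["score"]:
            best.update(params=copy.deepcopy(params), score=report.fruit_mean,
                        report=report)
        return report

    step = 0
    epoch_iter = range(config.epochs)
    if progress:
        from tqdm import tqdm

        epoch_iter = tqdm(epoch_iter, desc="epochs")
    for epoch in epoch_iter:
        order = rng.permutation(n)
        for s in range(steps_per_epoch):
            idx = order[s * config.batch_size:(s + 1) * config.batch_size]
            xb, yb = images[idx], targets[idx]
            tb = None
            if use_mmd:
                tidx = rng.integers(0, n_target, config.target_batch_size)
                tb = target_images[tidx]
            # The domain term is delayed then ramped in, so the segmenter
            # settles on its task before feature alignment starts to bite;
            # with nonzero weight from step 0 the MMD gradient pins the
            # encoder to trivially aligned (task-useless) features.
            p = step / max(total_steps, 1)
            if config.domain_ramp_frac == 0.0:
                ramp = 0.0 if p < config.domain_delay_frac else 1.0
            else:
                ramp = min(max((p - config.domain_delay_frac)
                               / config.domain_ramp_frac, 0.0), 1.0)
            lam_t = lam * ramp
            step_weights = LossWeights(
                **{**asdict(weights), "domain_weight": lam_t})

            breakdown_box = {}

            def objective(p):
                if use_mmd and lam_t > 0.0:
                    logits, sfeat = net.forward(p, xb, with_features=True)
                    tfeat = net.forward(p, tb, features_only=True)
                else:
                    logits, sfeat, tfeat = net.forward(p, xb), None, None
                total, br = joint_loss(logits, yb, sfeat, tfeat, step_weights)
                breakdown_box.update(br)
                return total

            _, grads = value_and_grad(objective)(params)
            params = opt.step(params, grads,
                              _lr_scale(config.schedule, step, total_steps))
            record = {"event": "step", "epoch": epoch, "step": step,
                      "lambda": lam_t, **breakdown_box}
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            step += 1
        if config.eval_every and (epoch + 1) % config.eval_every == 0:
            run_validation(epoch)

    final_report = run_validation(config.epochs - 1) if val_pairs else None
    if log_fh:
        log_fh.close()
    if best["report"] is None:  # no validation: final params are the result
        best.update(params=copy.deepcopy(params), report=final_report)
    if config.checkpoint_dir:
        ckpt_dir = Path(config.checkpoint_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(ckpt_dir / "best.npz", net.config, best["params"])
        save_checkpoint(ckpt_dir / "final.npz", net.config, params)
    return TrainResult(params=best["params"], final_params=params,
                       history=history, best_val=best["report"])


def scaling_experiment(sizes: list[int], net_config: ModelConfig,
                       pool_pairs: list[SamplePair],
                       eval_pairs: list[SamplePair],
                       loss_weights: LossWeights, train_config: TrainConfig,
                       target_images: np.ndarray | None = None,
                       progress: bool = False) -> ScalingResult:
    """Train from scratch on growing prefixes of a fixed pool; evaluate each
    model on one fixed held-out (typically domain-shifted) set.

    Mirrors the structure of a dataset-size ladder: independent rows, fresh
    initialization per row, identical evaluation data throughout.
    """
    if sizes != sorted(sizes):
        raise ConfigurationError("sizes must be ascending")
    if sizes and sizes[-1] > len(pool_pairs):
        raise ConfigurationError(
            f"largest size {sizes[-1]} exceeds pool of {len(pool_pairs)}")
    result = ScalingResult()
    for row, n in enumerate(sizes):
        net = SwinUNet(net_config)
        params = net.init_params(
            int(np.random.SeedSequence([train_config.seed, row]).generate_state(1)[0]
                % (2 ** 31)))
        res = train(net, params, pool_pairs[:n], target_images, loss_weights,
                    train_config, val_pairs=None, progress=progress)
        report = evaluate(net, res.final_params, eval_pairs)
        result.rows.append((n, report.dsc["ripe"], report.dsc["unripe"]))
    return result
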