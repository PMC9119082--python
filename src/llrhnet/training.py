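"""Dice-loss training protocol: Adam, early stopping, fixed hyperparameters.

The loss is the smoothed soft Dice with squared denominators,

    L(P,G) = 1 - (2 * sum p_ij g_ij + eps) / (sum p_ij^2 + sum g_ij^2 + eps),

computed per image and per foreground class and averaged (the background
channel does not contribute).  ``eps`` keeps the loss finite and equal to 0
when both prediction and target are empty for a class — the case that
otherwise destabilises training on lesion-free slices.

Reference protocol: Adam (lr 0.001, default betas), mini-batch 3, up to 80
epochs, dropout 0.3, random weight initialisation, early stopping on the
validation loss with patience 10, best (lowest validation loss) checkpoint
kept.  Everything — init, data order, dropout — is driven by the config
seed, so identical configs give identical training logs.

``train`` also supports a step-capped mode (``max_steps``) for desk-scale
experiments such as overfit checks and the patch-size sweep.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import metrics
from .assembly import LLRHNet, NetConfig, build
from .global_branch import TransformerConfig, token_count
from .nn import Adam, DTYPE, Tensor, no_grad


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 80
    batch_size: int = 3
    learning_rate: float = 0.001
    dropout: float = 0.3
    epsilon: float = 1e-5
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate < 0:
            raise ValueError("epochs/batch size must be >= 1, learning rate >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0 for numerical stability")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mean_dc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    steps: int = 0
    seed: int = 0
    config_echo: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    """Outcome of a training run: the fitted network, its best weights and
    the per-epoch log.  ``summary()`` renders a small report table."""

    net: LLRHNet
    log: TrainLog
    best_state: dict

    def restore_best(self) -> LLRHNet:
        self.net.load_state_dict(self.best_state)
        return self.net

    def summary(self) -> str:
        lines = ["epoch  train_loss  val_loss  val_mean_dc",
                 "-----  ----------  --------  -----------"]
        for i, (tl, vl, dc) in enumerate(zip(self.log.train_loss,
                                             self.log.val_loss,
                                             self.log.val_mean_dc), start=1):
            lines.append(f"{i:5d}  {tl:10.4f}  {vl:8.4f}  {dc:11.4f}")
        lines.append(f"stopped after epoch {self.log.stopped_epoch} "
                     f"({self.log.steps} optimizer steps); "
                     f"best epoch {self.log.best_epoch}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(B,H,W) integer labels -> (B,C,H,W) one-hot float array."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=DTYPE)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def dice_loss(probabilities: Tensor | np.ndarray, target: np.ndarray,
              epsilon: float = 1e-5) -> Tensor:
    """Smoothed soft-Dice loss averaged over foreground classes.

    ``probabilities``: (B,C,H,W) softmax output; ``target``: matching one-hot.
    """
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(
        np.asarray(probabilities))
    g = np.asarray(target, dtype=p.data.dtype)
    if p.data.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {g.shape}")
    inter = (p * Tensor(g)).sum(axis=(2, 3))          # (B,C)
    denom = (p * p).sum(axis=(2, 3)) + Tensor(np.sum(g * g, axis=(2, 3)))
    ratio = (2.0 * inter + epsilon) / (denom + epsilon)
    b, c = g.shape[:2]
    sel = np.ones((b, c), dtype=p.data.dtype)
    sel[:, 0] = 0.0                                   # background excluded
    return ((1.0 - ratio) * Tensor(sel)).sum() * (1.0 / (b * (c - 1)))


def normalize_slice(image: np.ndarray) -> np.ndarray:
    """Per-slice min-max normalisation to [0,1] (constant slices -> 0)."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi - lo < 1e-12:
        return np.zeros_like(image, dtype=DTYPE)
    return ((image - lo) / (hi - lo)).astype(DTYPE)


# ---------------------------------------------------------------------------
# Dataset plumbing
# ---------------------------------------------------------------------------

def arrays_from_manifest(manifest: dict) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Convert an in-memory phantom manifest into per-split arrays.

    Returns ``{"train"/"val"/"test": (images (N,C,H,W), labels (N,H,W))}``
    with per-slice min-max normalised intensities.
    """
    samples = manifest.get("in_memory")
    if samples is None:
        raise ValueError("manifest has no in-memory samples; regenerate first")
    splits: dict[str, list] = {"train": [], "val": [], "test": []}
    for entry, sample in zip(manifest["samples"], samples):
        splits[entry["split"]].append(sample)
    out = {}
    for name, group in splits.items():
        if not group:
            continue
        imgs = []
        for s in group:
            img = s.image if s.image.ndim == 3 else s.image[None]
            imgs.append(np.stack([normalize_slice(ch) for ch in img]))
        out[name] = (np.stack(imgs).astype(DTYPE),
                     np.stack([s.labels for s in group]))
    return out


def mean_foreground_dice(net: LLRHNet, images: np.ndarray, labels: np.ndarray,
                         classes=(1, 2), batch_size: int = 4,
                         use_batch_stats: bool = False) -> float:
    """Mean Dice over samples and foreground classes (empty-empty counts 1)."""
    preds = predict_labels(net, images, batch_size=batch_size,
                           use_batch_stats=use_batch_stats)
    scores = []
    for pred, gt in zip(preds, labels):
        for c in classes:
            scores.append(metrics.dice(pred == c, gt == c))
    return float(np.mean(scores))


def predict_labels(net: LLRHNet, images: np.ndarray, batch_size: int = 4,
                   use_batch_stats: bool = False) -> np.ndarray:
    """Argmax label maps for a stack of images, without building the tape."""
    was_training = net.training
    net.train(use_batch_stats)
    outs = []
    try:
        with no_grad():
            for i in range(0, len(images), batch_size):
                x = Tensor(np.asarray(images[i:i + batch_size], dtype=DTYPE))
                if use_batch_stats:
                    logits = _forward_no_dropout(net, x)
                else:
                    logits = net.logits(x)
                outs.append(logits.data.argmax(axis=1).astype(np.uint8))
    finally:
        net.train(was_training)
    return np.concatenate(outs, axis=0)


def _forward_no_dropout(net: LLRHNet, x: Tensor) -> Tensor:
    """Train-mode (batch-stat) forward with dropout switched off."""
    rates = []
    for _, mod in net.named_modules():
        if mod.__class__.__name__ == "Dropout":
            rates.append((mod, mod.rate))
            mod.rate = 0.0
    try:
        return net.logits(x)
    finally:
        for mod, rate in rates:
            mod.rate = rate


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------

def _epoch_loss(net: LLRHNet, images, labels, n_classes, eps, batch_size) -> float:
    losses = []
    was_training = net.training
    net.eval()
    try:
        with no_grad():
            for i in range(0, len(images), batch_size):
                x = Tensor(np.asarray(images[i:i + batch_size], dtype=DTYPE))
                probs = net.logits(x).softmax(axis=1)
                losses.append(float(dice_loss(
                    probs, one_hot(labels[i:i + batch_size], n_classes), eps).data))
    finally:
        net.train(was_training)
    return float(np.mean(losses))


def train(net_cfg: NetConfig, train_cfg: TrainConfig, dataset: dict,
          max_steps: int | None = None, target_train_dc: float | None = None,
          eval_every: int = 20, verbose: bool = False) -> TrainResult:
    """Fit a network variant on (images, labels) splits with Dice loss + Adam.

    ``dataset`` maps split names to ``(images (N,C,H,W), labels (N,H,W))``;
    a ``train`` split is required.  Without a ``val`` split (step-capped
    desk-scale runs), early stopping is disabled and the final weights are
    the best ones.  ``target_train_dc`` enables periodic training-set Dice
    evaluation with early exit once the target is reached.
    """
    if "train" not in dataset or len(dataset["train"][0]) == 0:
        raise ValueError("training split is empty")
    net_cfg = NetConfig(**{**_cfg_dict(net_cfg), "dropout": train_cfg.dropout})
    net = build(net_cfg, seed=train_cfg.seed)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate)
    order_rng = np.random.default_rng(train_cfg.seed + 1)

    images, labels = dataset["train"]
    n_classes = net_cfg.n_classes
    log = TrainLog(seed=train_cfg.seed,
                   config_echo={"net": _cfg_dict(net_cfg),
                                "train": asdict(train_cfg)})
    best_val = np.inf
    best_state = net.state_dict()
    patience_left = train_cfg.early_stop_patience
    stop = False

    for epoch in range(1, train_cfg.epochs + 1):
        net.train()
        idx = order_rng.permutation(len(images))
        epoch_losses = []
        for i in range(0, len(idx), train_cfg.batch_size):
            batch = idx[i:i + train_cfg.batch_size]
            x = Tensor(np.asarray(images[batch], dtype=DTYPE))
            probs = net.logits(x).softmax(axis=1)
            loss = dice_loss(probs, one_hot(labels[batch], n_classes),
                             train_cfg.epsilon)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged to non-finite loss at epoch {epoch}, "
                    f"step {log.steps + 1}, batch indices {batch.tolist()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(lval)
            log.steps += 1
            if target_train_dc is not None and log.steps % eval_every == 0:
                dc = mean_foreground_dice(net, images, labels,
                                          classes=tuple(range(1, n_classes)))
                if verbose:
                    print(f"step {log.steps}: train mean DC {dc:.4f}")
                if dc >= target_train_dc:
                    stop = True
                    break
            if max_steps is not None and log.steps >= max_steps:
                stop = True
                break
        log.train_loss.append(float(np.mean(epoch_losses)))

        if "val" in dataset and dataset["val"][0].size:
            vl = _epoch_loss(net, *dataset["val"], n_classes,
                             train_cfg.epsilon, train_cfg.batch_size)
            vdc = mean_foreground_dice(net, *dataset["val"],
                                       classes=tuple(range(1, n_classes)))
            log.val_loss.append(vl)
            log.val_mean_dc.append(vdc)
            if vl < best_val:
                best_val, log.best_epoch = vl, epoch
                best_state = net.state_dict()
                patience_left = train_cfg.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    stop = True
            if verbose:
                print(f"epoch {epoch}: train {log.train_loss[-1]:.4f} "
                      f"val {vl:.4f} val DC {vdc:.4f}")
        else:
            log.val_loss.append(float("nan"))
            log.val_mean_dc.append(float("nan"))
            log.best_epoch = epoch
            best_state = net.state_dict()

        log.stopped_epoch = epoch
        if stop:
            break

    return TrainResult(net=net, log=log, best_state=best_state)


def _cfg_dict(cfg: NetConfig) -> dict:
    d = {"variant": cfg.variant, "n_classes": cfg.n_classes,
         "in_channels": cfg.in_channels, "decoder_widths": cfg.decoder_widths,
         "dropout": cfg.dropout, "encoder": cfg.encoder, "plan": cfg.plan,
         "transformer": cfg.transformer}
    return d


# ---------------------------------------------------------------------------
# Patch-size sweep
# ---------------------------------------------------------------------------

def patch_size_sweep(sizes, net_cfg: NetConfig, train_cfg: TrainConfig,
                     dataset: dict, steps: int = 0,
                     eval_split: str = "test") -> list[dict]:
    """One row per admissible patch size: token count, DC, HD, s/step proxy.

    Sizes that do not divide the image dimensions are skipped with a
    warning entry rather than an error.  ``steps = 0`` evaluates the
    freshly initialised model without training (harness check mode).
    """
    if not net_cfg.uses_global_branch:
        raise ValueError("the patch-size sweep requires a variant with a "
                         "global branch (3 or 4)")
    images, labels = dataset[eval_split]
    h, w = images.shape[-2:]
    rows = []
    for p in sizes:
        if h % p or w % p:
            rows.append({"patch_size": int(p), "skipped": True,
                         "reason": f"{p} does not divide {h}x{w}"})
            continue
        base = _cfg_dict(net_cfg)
        tf = base["transformer"]
        tf_kwargs = {"patch_size": int(p), "in_channels": net_cfg.in_channels}
        if tf is not None:
            tf_kwargs.update(embed_width=tf.embed_width, n_layers=tf.n_layers,
                             n_heads=tf.n_heads, mlp_ratio=tf.mlp_ratio,
                             dropout=tf.dropout)
        base["transformer"] = TransformerConfig(**tf_kwargs)
        cfg = NetConfig(**base)
        t0 = time.perf_counter()
        if steps > 0:
            result = train(cfg, train_cfg, dataset, max_steps=steps)
            net = result.net
            sec_per_step = (time.perf_counter() - t0) / max(result.log.steps, 1)
        else:
            net = build(cfg, seed=train_cfg.seed)
            sec_per_step = float("nan")
        preds = predict_labels(net, images)
        dcs, hds = [], []
        for pred, gt in zip(preds, labels):
            for c in range(1, cfg.n_classes):
                dcs.append(metrics.dice(pred == c, gt == c))
                try:
                    hds.append(metrics.hausdorff(pred == c, gt == c))
                except metrics.UndefinedMetricError:
                    pass
        rows.append({
            "patch_size": int(p),
            "n_tokens": token_count(h, w, int(p)),
            "mean_dc": float(np.mean(dcs)),
            "mean_hd": float(np.mean(hds)) if hds else float("nan"),
            "sec_per_step": sec_per_step,
            "skipped": False,
        })
    return rows
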