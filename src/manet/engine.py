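"""Training and evaluation orchestration.

Training follows a fixed protocol: soft Dice loss, Adam at 1e-4 with the
rate cut by 10x every 30 epochs, batch size 4, 80 epochs by default, and
real-time augmentation.  There is no validation split; the checkpoint
kept is the one with the highest test-set Dice observed during training,
which is optimistic model selection by construction (see README).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .errors import ConfigurationError
from .metrics import MaskPair, MetricReport, aggregate
from .network import ArchitectureConfig, MANet, build_model, count_parameters
from .preprocess import AugmentSpec, augment, preprocess_slice
from .synthetic import PhantomSpec, generate_stack


@dataclass
class TrainConfig:
    """Optimization protocol (defaults are the reference training recipe)."""

    lr: float = 1e-4
    lr_decay_gamma: float = 0.1
    lr_decay_every: int = 30
    epochs: int = 80
    batch: int = 4
    seed: int = 0
    variant: str = "manet"
    loss: str = "dice"
    classes: int = 3
    device: str = "cpu"
    dice_smooth: float = 1.0
    augment: AugmentSpec = field(default_factory=AugmentSpec)

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError(f"learning rate must be positive, got {self.lr}")
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if isinstance(self.augment, dict):
            self.augment = AugmentSpec(**self.augment)

    def to_dict(self):
        return asdict(self)


@dataclass
class SliceDataset:
    """In-memory dataset of preprocessed slices ([0,1] floats) and binary masks."""

    images: np.ndarray                 # (n, h, w) in [0, 1]
    masks: np.ndarray                  # (n, h, w) in {0, 1}
    volume_ids: Optional[List] = None  # one id per slice, for volume-mode evaluation
    spacing: Optional[Tuple[float, float]] = None

    def __len__(self):
        return len(self.images)


def make_phantom_dataset(n_slices: int,
                         spec: Optional[PhantomSpec] = None,
                         seed: int = 0,
                         slices_per_volume: Optional[int] = None) -> SliceDataset:
    """Generate, window and normalize a phantom slice dataset."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    raw, masks = generate_stack(spec, n_slices, rng)
    images = np.stack([preprocess_slice(s) for s in raw])
    k = slices_per_volume or spec.slices_per_volume
    vol_ids = [i // k for i in range(n_slices)]
    return SliceDataset(images=images, masks=masks.astype(np.uint8),
                        volume_ids=vol_ids, spacing=spec.spacing)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def dice_loss(pred, target, smooth: float = 1.0):
    """Soft Dice loss, averaged over batch and foreground channels.

    ``pred`` is a probability field (b, c, h, w); ``target`` a binary array
    of the same shape.  Per (batch, channel): 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s).
    With a multi-channel head, channel 0 is the background complement and
    is excluded from the average; a single-channel head is all foreground.
    """
    pred = nn.as_tensor(pred)
    target = np.asarray(target, dtype=pred.data.dtype)
    if pred.shape != target.shape:
        raise ValueError(f"prediction {pred.shape} and target {target.shape} shapes differ")
    t = nn.Tensor(target)
    inter = nn.sum_spatial(nn.mul(pred, t))                       # (b, c)
    denom = nn.add(nn.sum_spatial(pred), target.sum(axis=(2, 3)))  # (b, c)
    dice = nn.div(nn.add(nn.mul(inter, 2.0), smooth), nn.add(denom, smooth))
    b, c = dice.shape
    w = np.zeros((b, c), dtype=pred.data.dtype)
    fg = slice(1, None) if c > 1 else slice(None)
    w[:, fg] = 1.0 / (b * w[:, fg].shape[1])
    mean_fg = nn.tsum(nn.mul(dice, nn.Tensor(w)))
    return nn.add(1.0, nn.mul(mean_fg, -1.0))


def masks_to_targets(masks: np.ndarray, classes: int = 3) -> np.ndarray:
    """Expand (b, h, w) binary tumor masks to the (b, classes, h, w) layout.

    3-class layout: channel 0 background, channel 1 liver (all-zero unless
    liver labels exist), channel 2 tumor.  1-class layout: the tumor mask.
    """
    m = np.asarray(masks)
    if classes == 1:
        return m[:, None].astype(np.float32)
    if classes == 3:
        t = np.zeros((m.shape[0], 3, *m.shape[1:]), dtype=np.float32)
        t[:, 2] = m
        t[:, 0] = 1.0 - m
        return t
    raise ConfigurationError(f"classes must be 1 or 3, got {classes}")


def tumor_channel(classes: int) -> int:
    return 0 if classes == 1 else 2


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """Best-on-test model weights plus provenance."""

    weights: Dict[str, np.ndarray]
    epoch: int
    test_dice: float
    arch: ArchitectureConfig
    train_config: Optional[TrainConfig] = None
    history: List[Dict] = field(default_factory=list)

    def build(self) -> MANet:
        net = build_model(self.arch)
        net.load_state_dict(self.weights)
        return net


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    """Serialize to .npz with the architecture/training configs embedded as YAML."""
    import yaml

    meta = {
        "epoch": int(ckpt.epoch),
        "test_dice": float(ckpt.test_dice),
        "arch": ckpt.arch.to_dict(),
        "train_config": ckpt.train_config.to_dict() if ckpt.train_config else None,
        "history": ckpt.history,
    }
    arrays = {f"w::{k}": v for k, v in ckpt.weights.items()}
    np.savez_compressed(str(path), __meta__=np.frombuffer(
        yaml.safe_dump(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Checkpoint:
    import yaml

    with np.load(str(path)) as z:
        meta = yaml.safe_load(bytes(z["__meta__"]).decode())
        weights = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
    arch = ArchitectureConfig.from_dict({**meta["arch"],
                                         "encoder_widths": tuple(meta["arch"]["encoder_widths"]),
                                         "decoder_widths": tuple(meta["arch"]["decoder_widths"])})
    tc = TrainConfig(**meta["train_config"]) if meta.get("train_config") else None
    return Checkpoint(weights=weights, epoch=meta["epoch"], test_dice=meta["test_dice"],
                      arch=arch, train_config=tc, history=meta.get("history", []))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _batch_inputs(images: np.ndarray) -> np.ndarray:
    """Replicate grayscale slices into the 3-channel input layout."""
    return np.repeat(images[:, None], 3, axis=1).astype(np.float32)


def _mean_test_dice(net: MANet, ds: SliceDataset, classes: int, batch: int = 8) -> float:
    """Mean per-slice tumor Dice at threshold 0.5 (fast, confusion-count based)."""
    ch = tumor_channel(classes)
    dices = []
    for i in range(0, len(ds), batch):
        x = _batch_inputs(ds.images[i:i + batch])
        prob = net.predict(x)[:, ch]
        pred = prob >= 0.5
        truth = ds.masks[i:i + batch].astype(bool)
        for p, t in zip(pred, truth):
            inter = np.count_nonzero(p & t)
            denom = np.count_nonzero(p) + np.count_nonzero(t)
            dices.append(1.0 if denom == 0 else 2.0 * inter / denom)
    return float(np.mean(dices))


def train(model: MANet,
          train_ds: SliceDataset,
          test_ds: SliceDataset,
          cfg: TrainConfig,
          log=None) -> Checkpoint:
    """Run the epoch loop and return the best-on-test checkpoint.

    Fully seeded: weight init is the model's, batch order and augmentation
    draws derive from ``cfg.seed``.  Aborts on a non-finite loss.
    """
    if len(train_ds) == 0 or len(test_ds) == 0:
        raise ValueError("training and test sets must both be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    sched = nn.StepLR(opt, step_size=cfg.lr_decay_every, gamma=cfg.lr_decay_gamma)
    best = None
    history = []
    n = len(train_ds)
    for epoch in range(cfg.epochs):
        sched.set_epoch(epoch)
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for i0 in range(0, n - cfg.batch + 1, cfg.batch):
            idx = order[i0:i0 + cfg.batch]
            imgs, msks = [], []
            for j in idx:
                im, mk = augment(train_ds.images[j], train_ds.masks[j], cfg.augment, rng)
                imgs.append(im)
                msks.append(mk)
            x = _batch_inputs(np.stack(imgs))
            y = masks_to_targets(np.stack(msks), cfg.classes)
            model.zero_grad()
            out = model(x)
            loss = dice_loss(out, y, smooth=cfg.dice_smooth)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch + 1}, batch {nb + 1}; aborting"
                )
            loss.backward()
            opt.step()
            epoch_loss += lval
            nb += 1
        test_dice = _mean_test_dice(model, test_ds, cfg.classes)
        history.append({"epoch": epoch + 1, "lr": sched.lr_at(epoch),
                        "train_loss": epoch_loss / max(nb, 1), "test_dice": test_dice})
        if log is not None:
            log(f"epoch {epoch + 1:3d}/{cfg.epochs}  lr {sched.lr_at(epoch):.1e}  "
                f"loss {epoch_loss / max(nb, 1):.4f}  test dice {test_dice:.4f}")
        if best is None or test_dice > best.test_dice:
            best = Checkpoint(
                weights={k: v.copy() for k, v in model.state_dict().items()},
                epoch=epoch + 1, test_dice=test_dice, arch=model.config,
                train_config=cfg, history=history,
            )
    best.history = history
    return best


def select_best_epoch(history: Sequence[Dict]) -> int:
    """Index (1-based epoch) of the maximal logged test Dice."""
    dices = [h["test_dice"] for h in history]
    return int(np.argmax(dices)) + 1


def evaluate(model: MANet,
             ds: SliceDataset,
             mode: str = "slice",
             classes: int = 3,
             batch: int = 8) -> MetricReport:
    """Binarize the tumor probability at 0.5 and compute the seven metrics."""
    ch = tumor_channel(classes)
    preds = []
    for i in range(0, len(ds), batch):
        x = _batch_inputs(ds.images[i:i + batch])
        preds.append(model.predict(x)[:, ch] >= 0.5)
    pred = np.concatenate(preds).astype(np.uint8)
    pairs = [MaskPair(a, b, ds.spacing) for a, b in zip(pred, ds.masks)]
    return aggregate(pairs, grouping=mode, volume_ids=ds.volume_ids if mode == "volume" else None)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

TABLE5_ROWS = (
    ("unet", "UNet"),
    ("unet_rb", "UNet + RB"),
    ("unet_rb_scag", "UNet + RB + SCAG"),
    ("unet_rb_ca", "UNet + RB + CA"),
    ("unet_rb_sa", "UNet + RB + SA"),
    ("unet_rb_cbam", "UNet + RB + CBAM"),
    ("unet_all_attn", "UNet + SCAG + CA + SA + CBAM"),
    ("manet", "MANet: UNet + RB + SCAG + CA + SA + CBAM"),
)


def run_ablation(variants: Optional[Sequence[str]] = None,
                 cfg: Optional[TrainConfig] = None,
                 arch: Optional[ArchitectureConfig] = None,
                 n_slices: int = 40,
                 phantom: Optional[PhantomSpec] = None,
                 log=None):
    """Build, train (scaled) and evaluate each architecture variant.

    Returns a DataFrame shaped like the ablation table: one row per
    variant with the seven metrics (mean ± std over test slices) plus the
    parameter count.
    """
    import pandas as pd

    names = dict(TABLE5_ROWS)
    variants = list(variants) if variants else [v for v, _ in TABLE5_ROWS]
    unknown = [v for v in variants if v not in names]
    if unknown:
        raise ConfigurationError(f"unknown variants {unknown}; expected among {list(names)}")
    cfg = cfg or TrainConfig(epochs=1)
    base_arch = arch or ArchitectureConfig.reduced(16)
    ds = make_phantom_dataset(n_slices, phantom, seed=cfg.seed)
    from .preprocess import split_dataset

    idx_train, idx_test = split_dataset(list(range(len(ds))), seed=cfg.seed)
    tr = SliceDataset(ds.images[idx_train], ds.masks[idx_train])
    te = SliceDataset(ds.images[idx_test], ds.masks[idx_test])
    rows = []
    for v in variants:
        a = ArchitectureConfig(**{**base_arch.to_dict(), "variant": v,
                                  "out_channels": 1 if cfg.classes == 1 else 3})
        net = build_model(a, seed=cfg.seed)
        ckpt = train(net, tr, te, TrainConfig(**{**cfg.to_dict(), "variant": v}), log=log)
        net.load_state_dict(ckpt.weights)
        report = evaluate(net, te, classes=cfg.classes)
        rows.append({
            "method": names[v], "variant": v,
            "parameters": count_parameters(net),
            **{f"{m}_mean": report.mean[m] for m in report.mean},
            **{f"{m}_std": report.std[m] for m in report.std},
        })
        if log is not None:
            log(f"{names[v]}: dice {report.mean['dice']:.4f}, params {rows[-1]['parameters']}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature visualization
# ---------------------------------------------------------------------------

def minmax_scale(arr: np.ndarray) -> np.ndarray:
    """Map an array onto [0, 1] between its extremes; flat arrays map to 0.5."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.full_like(arr, 0.5, dtype=np.float32)
    return ((arr - lo) / (hi - lo)).astype(np.float32)


def visualize_features(model: MANet,
                       x: np.ndarray,
                       layers: Optional[Sequence[str]] = None,
                       out_dir=None) -> Dict[str, np.ndarray]:
    """Mean-over-channel feature maps, min–max scaled to [0, 1].

    Captures every tagged intermediate of one forward pass (encoder blocks
    before/after channel attention, bridge before/after CBAM, decoder
    upsamples before/after spatial attention, gate maps).  Optionally
    writes 8-bit PNGs to ``out_dir``.
    """
    model.capture = True
    model.captured = {}
    try:
        model.predict(np.asarray(x, dtype=np.float32))
    finally:
        model.capture = False
    captured = model.captured
    if layers:
        missing = [l for l in layers if l not in captured]
        if missing:
            raise KeyError(f"unknown layer selectors {missing}; available: {sorted(captured)}")
        captured = {k: captured[k] for k in layers}
    images = {name: minmax_scale(feat[0].mean(axis=0)) for name, feat in captured.items()}
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, img in images.items():
            iio.imwrite(out / f"{name.replace('.', '_')}.png",
                        (img * 255).round().astype(np.uint8))
    return images
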