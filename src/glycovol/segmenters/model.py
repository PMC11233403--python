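"""UNet segmenter: construction, augmentation, training, prediction."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..io_core import EMImage, SegMask
from ._nn import AdaptiveMoments, Conv, MaxPool2, ReLU, Upsample2, softmax_cross_entropy

_SCHEME_BY_CLASSES = {2: "granules", 6: "locations"}


@dataclass
class SegmenterConfig:
    """Architecture and training-regime parameters.

    ``n_classes`` is 6 (locations) or 2 (granules).  ``optimizer_schedule``
    alternates between Adam and Nadam every ``switch_epochs`` epochs.
    """

    n_classes: int = 2
    depth: int = 3
    base_channels: int = 8
    input_size: int = 256
    epochs: int = 60
    batch_size: int = 1
    learning_rate: float = 3e-3
    switch_epochs: int = 10
    augmentation: dict | None = field(
        default_factory=lambda: {"rot90": True, "mirror": True, "contrast": (0.8, 1.2)}
    )
    class_weights: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in _SCHEME_BY_CLASSES:
            raise ValueError(f"n_classes must be one of {sorted(_SCHEME_BY_CLASSES)}")
        if self.input_size % (1 << self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {1 << self.depth}"
            )


@dataclass
class TrainingReport:
    train_loss: list[float]
    train_accuracy: list[float]
    val_accuracy: list[float]
    final_accuracy: float
    wall_clock_s: float
    config: SegmenterConfig
    warnings: list[str] = field(default_factory=list)


class UNetSegmenter:
    """Encoder–decoder with skip connections and per-pixel softmax output."""

    def __init__(self, config: SegmenterConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        B, D = config.base_channels, config.depth

        self.enc = []
        c_in = 1
        for lvl in range(D):
            c = B << lvl
            self.enc.append([Conv(c_in, c, 3, rng), ReLU(), Conv(c, c, 3, rng), ReLU()])
            c_in = c
        self.pools = [MaxPool2() for _ in range(D)]
        cb = B << D
        self.bottleneck = [Conv(c_in, cb, 3, rng), ReLU(), Conv(cb, cb, 3, rng), ReLU()]
        self.ups = []
        self.dec = []
        c_in = cb
        for lvl in reversed(range(D)):
            c = B << lvl
            self.ups.append([Upsample2(), Conv(c_in, c, 3, rng), ReLU()])
            # after concatenation with the skip the block sees 2c channels
            self.dec.append([Conv(2 * c, c, 3, rng), ReLU(), Conv(c, c, 3, rng), ReLU()])
            c_in = c
        self.head = Conv(c_in, config.n_classes, 1, rng)

    def _layers(self):
        for block in self.enc + [self.bottleneck] + self.ups + self.dec:
            yield from block
        yield self.head

    def parameters(self):
        params = []
        for layer in self._layers():
            params.extend(layer.params)
        return params

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (H, W, 1) float32 in [0, 1] → logits (H, W, n_classes)."""
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                x = layer.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for layer in self.bottleneck:
            x = layer.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            for layer in up:
                x = layer.forward(x)
            self._skip_channels.append(skip.shape[2])
            x = np.concatenate([skip, x], axis=2)
            for layer in dec:
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            for layer in reversed(dec):
                dx = layer.backward(dx)
            dskips.append(dx[:, :, :c_skip])
            dx = dx[:, :, c_skip:]
            for layer in reversed(up):
                dx = layer.backward(dx)
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        # dskips were collected shallow-first; the encoder unwinds deep-first
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dx = pool.backward(dx)
            dx = dx + dskip
            for layer in reversed(block):
                dx = layer.backward(dx)

    def predict_proba(self, pixels: np.ndarray) -> np.ndarray:
        """Per-pixel class distribution (softmax of the logits)."""
        x = (np.asarray(pixels, dtype=np.float32) / 255.0)[..., None]
        logits = self.forward(x)
        z = logits - logits.max(axis=2, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=2, keepdims=True)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, (p, _) in enumerate(self.parameters()):
            arrays[f"p{i}"] = p
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        if cfg.get("augmentation") and "contrast" in cfg["augmentation"]:
            cfg["augmentation"]["contrast"] = tuple(cfg["augmentation"]["contrast"])
        if cfg.get("class_weights"):
            cfg["class_weights"] = tuple(cfg["class_weights"])
        model = cls(SegmenterConfig(**cfg))
        data = np.load(path.with_suffix(".npz"))
        for i, (p, _) in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        return model


def build_segmenter(config: SegmenterConfig) -> UNetSegmenter:
    """Construct an untrained UNet segmenter from its configuration."""
    return UNetSegmenter(config)


def augment(
    image: EMImage, mask: SegMask, spec: dict | None, seed=None
) -> tuple[EMImage, SegMask]:
    """Random co-registered augmentation: rotations, mirroring, contrast.

    The same geometric transform is applied to image and mask; the contrast
    change (linear rescale about mid-gray) touches the image only.
    """
    if spec is None:
        return image, mask
    rng = np.random.default_rng(seed)
    px = image.pixels
    lab = mask.labels
    if spec.get("rot90"):
        k = int(rng.integers(4))
        px = np.rot90(px, k)
        lab = np.rot90(lab, k)
    if spec.get("mirror") and rng.random() < 0.5:
        px = px[:, ::-1]
        lab = lab[:, ::-1]
    if "contrast" in spec:
        lo, hi = spec["contrast"]
        alpha = rng.uniform(lo, hi)
        px = np.clip(128.0 + alpha * (px.astype(np.float64) - 128.0), 0, 255).astype(np.uint8)
    return (
        EMImage(np.ascontiguousarray(px), image.pixel_nm, image.source_id),
        SegMask(np.ascontiguousarray(lab), mask.pixel_nm, mask.scheme),
    )


def pixel_accuracy(pred: SegMask, truth: SegMask) -> float:
    """Fraction of pixels with identical labels; symmetric, 1 iff equal."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.scheme != truth.scheme:
        raise ValueError("masks must share a scheme")
    return float((pred.labels == truth.labels).mean())


def predict_mask(model: UNetSegmenter, image: EMImage) -> SegMask:
    """Arg-max label per pixel; larger images are processed in tiles."""
    size = model.config.input_size
    h, w = image.shape
    scheme = _SCHEME_BY_CLASSES[model.config.n_classes]
    if (h, w) == (size, size):
        labels = model.predict_proba(image.pixels).argmax(axis=2)
    else:
        if h % size or w % size:
            raise ValueError(
                f"image {image.shape} is not the model input size {size} nor tileable by it"
            )
        labels = np.empty((h, w), dtype=np.int64)
        for r in range(0, h, size):
            for c in range(0, w, size):
                tile = image.pixels[r : r + size, c : c + size]
                labels[r : r + size, c : c + size] = model.predict_proba(tile).argmax(axis=2)
    return SegMask(labels.astype(np.uint8), image.pixel_nm, scheme)


def train(
    model: UNetSegmenter,
    dataset: list[tuple[EMImage, SegMask]],
    config: SegmenterConfig | None = None,
    val_dataset: list[tuple[EMImage, SegMask]] | None = None,
) -> TrainingReport:
    """Train by per-pixel cross entropy, alternating Adam and Nadam.

    The optimizer rule switches every ``switch_epochs`` epochs; moment state
    is shared across the switch.  Runs with the same seed, data, and config
    produce identical losses.
    """
    if config is None:
        config = model.config
    if not dataset:
        raise ValueError("empty training dataset")
    warnings: list[str] = []
    present = set()
    for _, m in dataset:
        present.update(np.unique(m.labels).tolist())
    missing = set(range(config.n_classes)) - present
    if missing:
        warnings.append(f"classes absent from all training masks: {sorted(missing)}")

    rng = np.random.default_rng(config.seed + 1)
    opt = AdaptiveMoments(model.parameters(), lr=config.learning_rate)
    losses, accs, val_accs = [], [], []
    t0 = time.perf_counter()
    for epoch in range(config.epochs):
        rule = "adam" if (epoch // config.switch_epochs) % 2 == 0 else "nadam"
        order = rng.permutation(len(dataset))
        epoch_loss, epoch_correct, epoch_pixels = 0.0, 0, 0
        opt.zero_grad()
        pending = 0
        for idx in order:
            img, msk = dataset[idx]
            img, msk = augment(img, msk, config.augmentation, seed=rng.integers(2**31))
            x = (img.pixels.astype(np.float32) / 255.0)[..., None]
            logits = model.forward(x)
            loss, dlogits, probs = softmax_cross_entropy(
                logits, msk.labels, config.class_weights
            )
            model.backward(dlogits)
            epoch_loss += loss
            epoch_correct += int((probs.argmax(axis=2) == msk.labels).sum())
            epoch_pixels += msk.labels.size
            pending += 1
            if pending == config.batch_size:
                opt.step(rule)
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step(rule)
            opt.zero_grad()
        losses.append(epoch_loss / len(dataset))
        accs.append(epoch_correct / epoch_pixels)
        if val_dataset:
            val_accs.append(
                float(
                    np.mean(
                        [
                            pixel_accuracy(predict_mask(model, vi), vm)
                            for vi, vm in val_dataset
                        ]
                    )
                )
            )
    final = float(
        np.mean([pixel_accuracy(predict_mask(model, i), m) for i, m in dataset])
    )
    return TrainingReport(
        train_loss=losses,
        train_accuracy=accs,
        val_accuracy=val_accs,
        final_accuracy=final,
        wall_clock_s=time.perf_counter() - t0,
        config=config,
        warnings=warnings,
    )
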