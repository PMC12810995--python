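"""Needle-guide segmentation with a fixed 2D U-Net.

A small encoder-decoder network (configurable depth, Dice +
cross-entropy loss) segments the dark needle-guide void from
reconstructed magnitude frames.  Inference thresholds the foreground
probability at 0.5; largest-connected-component filtering is available
as an option but off by default.  The module also provides the grouped
train/validation split used for model development.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

__all__ = ["SegConfig", "UNet", "split_dataset", "train_segmenter", "segment",
           "dice_score"]


@dataclass(frozen=True)
class SegConfig:
    """U-Net depth/width and training settings."""

    depth: int = 3
    base_filters: int = 8
    epochs: int = 60
    batch_size: int = 8
    learning_rate: float = 5e-3
    split_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


def split_dataset(items, fraction: float = 0.8, seed: int = 0,
                  key=None) -> tuple[list, list]:
    """Random grouped train/validation split.

    ``key(item)`` names the subject an item belongs to; all items of one
    subject land on the same side of the split (default: every item is
    its own subject).  The split is over subjects, seeded, disjoint and
    exhaustive.
    """
    items = list(items)
    if key is None:
        groups = {i: [it] for i, it in enumerate(items)}
    else:
        groups = defaultdict(list)
        for it in items:
            groups[key(it)].append(it)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two subjects to split")
    rng = np.random.default_rng(seed)
    order = [names[i] for i in rng.permutation(len(names))]
    n_train = int(round(fraction * len(names)))
    n_train = min(max(n_train, 1), len(names) - 1)
    train_names = set(order[:n_train])
    train = [it for g in order[:n_train] for it in groups[g]]
    val = [it for g in order[n_train:] for it in groups[g]]
    assert not train_names.intersection(order[n_train:])
    return train, val


class UNet:
    """Small 2D U-Net: two convs per level, 2x pooling, skip connections."""

    def __init__(self, cfg: SegConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng or np.random.default_rng(cfg.rng_seed)
        f = cfg.base_filters
        self.enc = []
        c_in = 1
        for d in range(cfg.depth):
            c_out = f * 2 ** d
            self.enc.append((nn.Conv2d(rng, c_in, c_out),
                             nn.Conv2d(rng, c_out, c_out)))
            c_in = c_out
        self.dec = []
        for d in reversed(range(cfg.depth - 1)):
            c_skip = f * 2 ** d
            self.dec.append((nn.Conv2d(rng, c_in + c_skip, c_skip),
                             nn.Conv2d(rng, c_skip, c_skip)))
            c_in = c_skip
        self.head = nn.Conv2d(rng, c_in, 1, k=1)

    @property
    def params(self):
        ps = []
        for a, b in self.enc + self.dec:
            ps += a.params + b.params
        return ps + self.head.params

    def forward(self, x: "nn.Tensor") -> "nn.Tensor":
        """Foreground probability map for a (B, H, W, 1) batch."""
        skips = []
        for d, (c1, c2) in enumerate(self.enc):
            x = c2(c1(x).relu()).relu()
            if d < self.cfg.depth - 1:
                skips.append(x)
                x = nn.avg_pool2(x)
        for (c1, c2), skip in zip(self.dec, reversed(skips)):
            x = nn.concat([nn.upsample2(x), skip], axis=3)
            x = c2(c1(x).relu()).relu()
        return self.head(x).sigmoid()

    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        np.savez(path, _config=json.dumps(asdict(self.cfg)), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path, allow_pickle=False) as data:
            model = cls(SegConfig(**json.loads(str(data["_config"]))))
            for i, p in enumerate(model.params):
                p.data[...] = data[f"p{i}"]
        return model


def _dice_ce_loss(prob: "nn.Tensor", target: np.ndarray,
                  pos_weight: float = 8.0) -> "nn.Tensor":
    """Soft Dice + foreground-weighted cross-entropy.

    The guide occupies ~2% of the frame; weighting the foreground term
    keeps early training from collapsing into the all-background optimum
    of the unweighted loss.
    """
    t = nn.Tensor(target)
    eps = 1e-6
    inter = (prob * t).sum()
    dice = 1.0 - (inter * 2.0 + 1.0) / (prob.sum() + t.sum() + 1.0)
    ce = -((prob + eps).log() * t * pos_weight
           + (1.0 - prob + eps).log() * (1.0 - t)).mean()
    return dice + ce


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Hard Dice overlap between two binary masks."""
    p = np.asarray(pred_mask, bool)
    t = np.asarray(true_mask, bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, t).sum() / denom


def train_segmenter(images: np.ndarray, masks: np.ndarray,
                    cfg: SegConfig) -> tuple[UNet, list[float]]:
    """Train the U-Net on paired images and binary masks.

    ``images`` (N, H, W) in [0, 1]; ``masks`` (N, H, W) boolean.
    Deterministic for a fixed config; returns the model and the per-epoch
    mean loss trace.
    """
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if images.shape != masks.shape:
        raise ValueError("images and masks must be paired")
    if masks.sum() == 0:
        raise ValueError("all training masks are empty")
    from .nn.autograd import tune_allocator
    tune_allocator()
    rng = np.random.default_rng(cfg.rng_seed)
    model = UNet(cfg, rng=np.random.default_rng(cfg.rng_seed + 1))
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    trace: list[float] = []
    n = len(images)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, cfg.batch_size):
            ids = order[b0:b0 + cfg.batch_size]
            x = nn.Tensor(images[ids][..., None])
            prob = model.forward(x)
            loss = _dice_ce_loss(prob, masks[ids][..., None])
            if not np.isfinite(loss.data):
                raise RuntimeError("segmentation training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return model, trace


def segment(image: np.ndarray, model: UNet, threshold: float = 0.5,
            largest_component: bool = False) -> np.ndarray:
    """Binary guide mask for one image in [0, 1]; deterministic.

    Thresholds the foreground probability at 0.5; optionally keeps only
    the largest connected component.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("expected a single 2D image")
    from .nn.autograd import no_grad
    with no_grad():
        prob = model.forward(nn.Tensor(image[None, :, :, None])).data[0, ..., 0]
    mask = prob > threshold
    if largest_component and mask.any():
        from scipy.ndimage import label
        labels, n = label(mask)
        if n > 1:
            sizes = np.bincount(labels.ravel())[1:]
            mask = labels == (1 + int(np.argmax(sizes)))
    return mask
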