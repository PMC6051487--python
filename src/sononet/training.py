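"""Training from image-level labels.

Freehand screening video is dominated by background frames, so mini-batches
are composed explicitly rather than drawn i.i.d.: every batch holds the
same number of examples of each standard view (default 2) plus a fixed
block of background frames (default 26; with the clinical 13-view taxonomy
this gives the canonical 52-frame batch).  Optimisation is mini-batch
gradient descent with Nesterov momentum 0.9 and a categorical cross-entropy
loss; the learning rate warms up at 0.01 for 500 iterations, then starts at
0.1 and is divided by 10 each time the validation error plateaus.  Scale
augmentation (random square crop between 174 and 224 pixels rescaled to
224), left-right flips and rotations in ±25° regularise the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .network import Network, _softmax
from .preprocess import Frame, normalise_frame
from .taxonomy import LabelTaxonomy

__all__ = [
    "LabelledDataset",
    "BatchComposition",
    "LRSchedule",
    "AugmentationSpec",
    "TrainingHistory",
    "sample_balanced_batch",
    "augment",
    "lr_at",
    "default_schedule",
    "train",
]


@dataclass
class LabelledDataset:
    """Image-level labelled frames plus the class taxonomy."""

    items: list[tuple[object, int]]  # (frame-like, label index)
    taxonomy: LabelTaxonomy

    def __post_init__(self) -> None:
        K = self.taxonomy.num_classes
        for _, label in self.items:
            if not 0 <= label < K:
                raise ValueError(f"label {label} out of range for K={K}")

    def by_class(self) -> dict[int, list[int]]:
        pools: dict[int, list[int]] = {k: [] for k in
                                       range(self.taxonomy.num_classes)}
        for i, (_, label) in enumerate(self.items):
            pools[label].append(i)
        return pools


@dataclass
class BatchComposition:
    """Fixed per-class counts of a balanced mini-batch."""

    per_foreground_class: int = 2
    background_count: int = 26

    def batch_size(self, num_classes: int) -> int:
        return self.per_foreground_class * (num_classes - 1) + \
            self.background_count


@dataclass
class LRSchedule:
    """Warm-up, initial rate and plateau-driven decay."""

    warmup_lr: float = 0.01
    warmup_iters: int = 500
    initial_lr: float = 0.1
    decay_factor: float = 10.0
    plateau_patience: int = 5

    def __post_init__(self) -> None:
        if not self.warmup_lr < self.initial_lr:
            raise ValueError("warm-up rate must be below the initial rate")
        if self.decay_factor <= 1:
            raise ValueError("decay factor must exceed 1")


def default_schedule(variant: str = "sononet") -> LRSchedule:
    """Shipping schedule per variant; the batch-norm-free smallnet needs a
    gentler initial rate (0.001)."""
    if variant == "smallnet":
        return LRSchedule(warmup_lr=0.0001, initial_lr=0.001)
    return LRSchedule()


@dataclass
class AugmentationSpec:
    """Scale/flip/rotation augmentation parameters (pixels, degrees)."""

    min_crop: int = 174
    max_crop: int = 224
    out_size: int = 224
    flip_lr: bool = True
    rotation_range_deg: tuple[float, float] = (-25.0, 25.0)

    def __post_init__(self) -> None:
        if not self.min_crop <= self.max_crop:
            raise ValueError("min_crop must not exceed max_crop")

    @classmethod
    def for_size(cls, out_size: int) -> "AugmentationSpec":
        """Scale the canonical 174–224 crop range to another input size."""
        return cls(min_crop=max(1, round(out_size * 174 / 224)),
                   max_crop=out_size, out_size=out_size)


def lr_at(schedule: LRSchedule, iteration: int, plateau_events: int) -> float:
    """Learning rate at an iteration given how many plateaus occurred."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    if iteration < schedule.warmup_iters:
        return schedule.warmup_lr
    return schedule.initial_lr / schedule.decay_factor ** plateau_events


def sample_balanced_batch(data: LabelledDataset, comp: BatchComposition,
                          rng: np.random.Generator) -> list[tuple[object, int]]:
    """Draw one balanced mini-batch.

    Exactly ``per_foreground_class`` items of every foreground class and
    ``background_count`` background items; small pools are sampled with
    replacement so the strict composition stays feasible.  The batch order
    is shuffled.
    """
    pools = data.by_class()
    tax = data.taxonomy
    chosen: list[int] = []
    for k in tax.foreground:
        pool = pools[k]
        if not pool:
            raise ValueError(
                f"class {k} ({tax.names[k]}) has no items to sample")
        n = comp.per_foreground_class
        idx = rng.choice(len(pool), size=n, replace=len(pool) < n)
        chosen.extend(pool[i] for i in idx)
    bg_pool = pools[tax.background_index]
    if not bg_pool:
        raise ValueError(
            f"background class {tax.background_index} has no items to sample")
    n = comp.background_count
    idx = rng.choice(len(bg_pool), size=n, replace=len(bg_pool) < n)
    chosen.extend(bg_pool[i] for i in idx)
    order = rng.permutation(len(chosen))
    return [data.items[chosen[i]] for i in order]


def draw_augmentation(spec: AugmentationSpec, h: int, w: int,
                      rng: np.random.Generator):
    """Draw one set of augmentation parameters.

    Returns ``(side, r0, c0, flip, angle)``: crop side uniform on the
    integers ``[min_crop, max_crop]``, crop origin uniform over valid
    positions, flip with probability 1/2 (always False when disabled),
    rotation angle uniform in the configured range.
    """
    side = int(rng.integers(spec.min_crop, spec.max_crop + 1))
    r0 = int(rng.integers(0, h - side + 1))
    c0 = int(rng.integers(0, w - side + 1))
    flip = bool(spec.flip_lr and rng.random() < 0.5)
    lo, hi = spec.rotation_range_deg
    angle = float(rng.uniform(lo, hi))
    return side, r0, c0, flip, angle


def augment(frame, spec: AugmentationSpec, rng: np.random.Generator) -> Frame:
    """Random square crop -> rescale to ``out_size`` -> flip -> rotate.

    Parameters come from :func:`draw_augmentation`.  Rotation uses bilinear
    interpolation with out-of-bounds pixels filled with the image minimum,
    so augmented corners stay as dark as the darkest image content.
    """
    pixels = np.asarray(getattr(frame, "pixels", frame), dtype=np.float64)
    h, w = pixels.shape
    if h < spec.max_crop or w < spec.max_crop:
        raise ValueError(
            f"source {h}x{w} smaller than max crop {spec.max_crop}")
    side, r0, c0, flip, angle = draw_augmentation(spec, h, w, rng)
    out = pixels[r0:r0 + side, c0:c0 + side]
    if side != spec.out_size:
        out = resize(out, (spec.out_size, spec.out_size), order=1,
                     preserve_range=True, anti_aliasing=side > spec.out_size)
    if flip:
        out = out[:, ::-1]
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1,
                             mode="constant", cval=float(out.min()))
    return Frame(np.ascontiguousarray(out), normalised=False,
                 source_id=getattr(frame, "source_id", ""),
                 frame_index=getattr(frame, "frame_index", None))


@dataclass
class TrainingHistory:
    """Per-iteration log: loss, learning rate, validation error when run."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Nesterov:
    """SGD with Nesterov momentum: v <- mu v + g; w <- w - lr (g + mu v)."""

    def __init__(self, net: Network, momentum: float = 0.9) -> None:
        self.momentum = momentum
        self.velocity = {
            (i, name): np.zeros_like(p)
            for i, layer in enumerate(net.layers)
            for name, p in layer.params.items()
        }

    def step(self, net: Network, lr: float) -> None:
        mu = self.momentum
        for i, layer in enumerate(net.layers):
            for name, p in layer.params.items():
                g = layer.grads[name]
                v = self.velocity[(i, name)]
                v *= mu
                v += g
                p -= (lr * (g + mu * v)).astype(p.dtype)


def _prepare_batch(batch, aug_spec, rng, do_augment):
    xs, ys = [], []
    for frame, label in batch:
        f = augment(frame, aug_spec, rng) if do_augment else frame
        f = normalise_frame(f if isinstance(f, Frame)
                            else Frame(np.asarray(f, dtype=np.float64)))
        xs.append(f.pixels.astype(np.float32))
        ys.append(label)
    return np.stack(xs)[:, None], np.asarray(ys)


def _validation_error(net: Network, items, chunk: int = 32) -> float:
    """Fraction of validation frames misclassified (inference mode)."""
    wrong = 0
    frames = [normalise_frame(f if isinstance(f, Frame)
                              else Frame(np.asarray(f, dtype=np.float64)))
              for f, _ in items]
    labels = np.asarray([y for _, y in items])
    for i in range(0, len(frames), chunk):
        x = np.stack([f.pixels.astype(np.float32)
                      for f in frames[i:i + chunk]])[:, None]
        maps = net.forward_maps(x, train=False)
        pred = maps.mean(axis=(2, 3)).argmax(axis=1)
        wrong += int((pred != labels[i:i + chunk]).sum())
    return wrong / len(frames)


def train(net: Network, data: LabelledDataset,
          schedule: LRSchedule | None = None,
          comp: BatchComposition | None = None,
          aug_spec: AugmentationSpec | None = None,
          rng: np.random.Generator | None = None,
          n_iterations: int = 2000,
          val_every: int = 50,
          val_fraction: float = 0.2,
          do_augment: bool = True,
          momentum: float = 0.9) -> tuple[Network, TrainingHistory]:
    """Train a network in place; returns it with the iteration history.

    A stratified ``val_fraction`` of the dataset is held out; the validation
    error is evaluated every ``val_every`` iterations and drives the
    plateau-based learning-rate decay (no new error minimum for
    ``plateau_patience`` consecutive evaluations divides the rate by the
    decay factor).  Training aborts with a diagnostic if the loss turns
    non-finite.
    """
    schedule = default_schedule(net.config.variant) if schedule is None \
        else schedule
    comp = BatchComposition() if comp is None else comp
    rng = np.random.default_rng() if rng is None else rng

    # stratified validation split, keeping at least one training item per class
    pools = data.by_class()
    train_items, val_items = [], []
    for k, pool in pools.items():
        if not pool:
            continue
        pool = list(rng.permutation(pool))
        n_val = min(int(round(len(pool) * val_fraction)), len(pool) - 1)
        val_items.extend(data.items[i] for i in pool[:n_val])
        train_items.extend(data.items[i] for i in pool[n_val:])
    train_data = LabelledDataset(train_items, data.taxonomy)

    if aug_spec is None:
        size = np.asarray(getattr(train_items[0][0], "pixels",
                                  train_items[0][0])).shape
        aug_spec = AugmentationSpec.for_size(min(size))

    opt = _Nesterov(net, momentum=momentum)
    history = TrainingHistory()
    plateau_events = 0
    best_val = np.inf
    evals_since_best = 0

    for it in range(n_iterations):
        lr = lr_at(schedule, it, plateau_events)
        batch = sample_balanced_batch(train_data, comp, rng)
        x, y = _prepare_batch(batch, aug_spec, rng, do_augment)
        maps = net.forward_maps(x, train=True)
        a = maps.mean(axis=(2, 3))
        c = _softmax(a, axis=1)
        b = len(y)
        loss = float(-np.log(np.maximum(c[np.arange(b), y], 1e-12)).mean())
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={loss}; "
                f"lr={lr}")
        ga = c.copy()
        ga[np.arange(b), y] -= 1.0
        ga /= b
        dmaps = np.broadcast_to(
            (ga / (maps.shape[2] * maps.shape[3]))[:, :, None, None],
            maps.shape).astype(maps.dtype)
        net.zero_grad()
        net.backward_from_maps(dmaps, guided=False)
        opt.step(net, lr)

        rec = {"iteration": it, "loss": loss, "lr": lr}
        if val_items and (it + 1) % val_every == 0:
            val_err = _validation_error(net, val_items)
            rec["val_error"] = val_err
            if val_err < best_val - 1e-12:
                best_val = val_err
                evals_since_best = 0
            else:
                evals_since_best += 1
                if evals_since_best >= schedule.plateau_patience:
                    plateau_events += 1
                    evals_since_best = 0
        history.records.append(rec)
    return net, history
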