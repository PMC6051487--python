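"""Synthetic pseudo-ultrasound frames with known labels and boxes.

Every other module is testable against this generator without any clinical
data.  Frames mimic the first-order statistics of B-mode ultrasound: a
smooth tissue-like base intensity, multiplicative speckle, an optional
acoustic shadow band, and a fan-shaped field of view.  Each foreground
class renders one distinctive parametric structure at a random pose —

* ``bar``    — a bright elongated capsule (femur-like bone), bright polarity,
* ``ring``   — a bright elliptical ring (skull-like), bright polarity,
* ``lobes``  — a dark four-lobed ellipse (cardiac-like), dark polarity,
* ``wedge``  — a bright triangular wedge, bright polarity,
* ``spots``  — a cluster of small dark discs, dark polarity —

with a ground-truth box tightly containing the rendered support.
Background frames carry speckle plus 0–3 small distractors of non-class
geometry (dots and thin streaks).  The class polarity drives the expected
saliency sign policy of the localiser.

Everything is deterministic under the supplied random generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .localisation import BoundingBox
from .preprocess import Frame
from .taxonomy import LabelTaxonomy

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "synthetic_taxonomy",
    "generate_dataset",
    "generate_video",
    "save_dataset",
    "load_dataset",
]


@dataclass
class SyntheticSpec:
    """Generator conditions: image geometry, noise levels, class registry."""

    num_foreground_classes: int = 3
    height: int = 224
    width: int = 288
    speckle_strength: float = 0.35
    shadow_probability: float = 0.25
    distractor_range: tuple[int, int] = (0, 3)
    fov_mask: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.num_foreground_classes <= len(_SHAPES):
            raise ValueError(
                f"num_foreground_classes must be in [1, {len(_SHAPES)}]")

    @property
    def num_classes(self) -> int:
        return self.num_foreground_classes + 1

    @property
    def background_label(self) -> int:
        return self.num_foreground_classes


@dataclass
class SyntheticSample:
    """One generated frame with its label and (foreground) box."""

    frame: Frame
    label: int
    gt_box: BoundingBox | None = None


# -- shape renderers -----------------------------------------------------
# each returns (delta image, support mask); delta is added to the base

def _grid(h, w):
    return np.meshgrid(np.arange(h), np.arange(w), indexing="ij")


def _render_bar(rng, h, w):
    s = min(h, w)
    length = rng.uniform(0.36, 0.55) * s
    halfwidth = rng.uniform(0.045, 0.075) * s
    angle = rng.uniform(-60, 60) * np.pi / 180
    cr = rng.uniform(0.3, 0.7) * h
    cc = rng.uniform(0.3, 0.7) * w
    rr, cc_ = _grid(h, w)
    dr, dc = rr - cr, cc_ - cc
    u = dr * np.sin(angle) + dc * np.cos(angle)   # along the bar
    v = dr * np.cos(angle) - dc * np.sin(angle)   # across the bar
    d = np.sqrt(np.maximum(np.abs(u) - length / 2, 0) ** 2 + v ** 2)
    profile = np.clip(1.0 - d / halfwidth, 0, 1)
    mask = profile > 0.15
    return 0.55 * profile, mask


def _render_ring(rng, h, w):
    s = min(h, w)
    a = rng.uniform(0.16, 0.26) * s
    b = a * rng.uniform(0.7, 1.0)
    thick = rng.uniform(0.045, 0.07) * s
    theta = rng.uniform(0, np.pi)
    cr = rng.uniform(0.35, 0.65) * h
    cc = rng.uniform(0.35, 0.65) * w
    rr, cc_ = _grid(h, w)
    dr, dc = rr - cr, cc_ - cc
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    r_ell = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    d = np.abs(r_ell - 1.0) * min(a, b)
    profile = np.clip(1.0 - d / thick, 0, 1)
    mask = profile > 0.15
    return 0.5 * profile, mask


def _render_lobes(rng, h, w):
    """Dark multi-lobed blob: overlapping dark ellipses forming one
    connected chamber-like region (cardiac polarity)."""
    s = min(h, w)
    cr = rng.uniform(0.4, 0.6) * h
    cc = rng.uniform(0.4, 0.6) * w
    rr, cc_ = _grid(h, w)
    n_lobes = int(rng.integers(3, 5))
    mask = np.zeros((h, w), dtype=bool)
    for i in range(n_lobes):
        ang = 2 * np.pi * i / n_lobes + rng.uniform(-0.4, 0.4)
        off = rng.uniform(0.06, 0.11) * s
        pr = cr + off * np.cos(ang)
        pc = cc + off * np.sin(ang)
        a = rng.uniform(0.1, 0.15) * s
        b = a * rng.uniform(0.7, 1.0)
        mask |= ((rr - pr) / a) ** 2 + ((cc_ - pc) / b) ** 2 <= 1.0
    return np.where(mask, -0.38, 0.0), mask


def _render_wedge(rng, h, w):
    s = min(h, w)
    size = rng.uniform(0.3, 0.45) * s
    cr = rng.uniform(0.3, 0.65) * h
    cc = rng.uniform(0.3, 0.7) * w
    rr, cc_ = _grid(h, w)
    dr, dc = rr - cr, cc_ - cc
    inside = (dr > -size / 3) & (dr < 2 * size / 3) & \
        (np.abs(dc) < (dr + size / 3) * 0.6) & \
        (np.abs(dc) + np.abs(dr) < size)
    delta = np.where(inside, 0.45, 0.0)
    return delta, inside


def _render_spots(rng, h, w):
    s = min(h, w)
    n = int(rng.integers(3, 6))
    cr = rng.uniform(0.35, 0.65) * h
    cc = rng.uniform(0.35, 0.65) * w
    spread = 0.16 * s
    rr, cc_ = _grid(h, w)
    delta = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n):
        pr = cr + rng.uniform(-spread, spread)
        pc = cc + rng.uniform(-spread, spread)
        rad = rng.uniform(0.035, 0.06) * s
        disc = (rr - pr) ** 2 + (cc_ - pc) ** 2 <= rad ** 2
        delta[disc] = -0.4
        mask |= disc
    return delta, mask


_SHAPES = [
    ("bar", _render_bar, "bright"),
    ("ring", _render_ring, "bright"),
    ("lobes", _render_lobes, "dark"),
    ("wedge", _render_wedge, "bright"),
    ("spots", _render_spots, "dark"),
]


def synthetic_taxonomy(spec: SyntheticSpec) -> LabelTaxonomy:
    """Taxonomy for a spec: shape classes + background, sign policy from
    polarity (bright structures -> positive saliencies, dark -> negative)."""
    kf = spec.num_foreground_classes
    names = [_SHAPES[k][0] for k in range(kf)] + ["Background"]
    modes = {k: ("positive_only" if _SHAPES[k][2] == "bright"
                 else "negative_only") for k in range(kf)}
    modes[kf] = "both"
    return LabelTaxonomy(names=names, background_index=kf, sign_modes=modes)


# -- frame synthesis -----------------------------------------------------

def _base_field(rng, h, w):
    """Smooth tissue-like intensity in roughly [0.25, 0.55]."""
    coarse = rng.normal(size=(max(h // 16, 2), max(w // 16, 2)))
    field = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]),
                         order=1)[:h, :w]
    field = (field - field.min()) / (np.ptp(field) + 1e-9)
    return 0.25 + 0.3 * field


def _speckle(rng, h, w, strength):
    noise = ndimage.gaussian_filter(rng.normal(size=(h, w)), 0.7)
    noise /= noise.std() + 1e-9
    return 1.0 + strength * noise


def _fov_mask(h, w):
    rr, cc = _grid(h, w)
    apex_r, apex_c = -0.25 * h, w / 2
    dr, dc = rr - apex_r, cc - apex_c
    radius = np.sqrt(dr ** 2 + dc ** 2)
    ang = np.abs(np.arctan2(dc, dr))
    return (ang < np.radians(42)) & (radius < 1.3 * h)


def _add_distractors(rng, img, lo, hi):
    h, w = img.shape
    s = min(h, w)
    rr, cc = _grid(h, w)
    for _ in range(int(rng.integers(lo, hi + 1))):
        kind = rng.integers(0, 2)
        pr = rng.uniform(0.2, 0.8) * h
        pc = rng.uniform(0.2, 0.8) * w
        if kind == 0:  # bright dot
            rad = rng.uniform(0.02, 0.045) * s
            img += 0.3 * np.exp(-(((rr - pr) ** 2 + (cc - pc) ** 2)
                                  / (2 * rad ** 2)))
        else:  # thin streak
            angle = rng.uniform(0, np.pi)
            v = (rr - pr) * np.cos(angle) - (cc - pc) * np.sin(angle)
            u = (rr - pr) * np.sin(angle) + (cc - pc) * np.cos(angle)
            streak = (np.abs(v) < 0.012 * s) & (np.abs(u) < 0.12 * s)
            img += np.where(streak, 0.2, 0.0)
    return img


def _compose(rng, spec: SyntheticSpec, shape_idx: int | None,
             max_tries: int = 50):
    """One frame; returns (pixels in [0, 1], gt box or None)."""
    h, w = spec.height, spec.width
    base = _base_field(rng, h, w)
    fov = _fov_mask(h, w) if spec.fov_mask else np.ones((h, w), bool)
    box = None
    if shape_idx is not None:
        _, render, _ = _SHAPES[shape_idx]
        for attempt in range(max_tries):
            delta, mask = render(rng, h, w)
            if mask.any() and (mask & ~fov).sum() <= 0.01 * mask.sum():
                break
        else:
            raise RuntimeError(
                f"could not place shape {shape_idx} inside the field of "
                f"view after {max_tries} attempts")
        base = base + delta
        rows, cols = np.nonzero(mask)
        box = BoundingBox(int(rows.min()), int(cols.min()),
                          int(rows.max()) + 1, int(cols.max()) + 1)
    else:
        lo, hi = spec.distractor_range
        base = _add_distractors(rng, base, lo, hi)
    img = base * _speckle(rng, h, w, spec.speckle_strength)
    if rng.random() < spec.shadow_probability:
        width = rng.uniform(0.06, 0.15) * w
        # operators keep acoustic shadows off the structure of interest,
        # so the band is drawn clear of the target box
        for _ in range(20):
            c0 = rng.uniform(0.1, 0.8) * w
            if box is None or not (box.cmin - 1.5 * width < c0
                                   < box.cmax + 1.5 * width):
                _, cc = _grid(h, w)
                band = np.exp(-((cc - c0) ** 2) / (2 * width ** 2))
                img = img * (1.0 - 0.35 * band)
                break
    img = np.where(fov, img, 0.02)
    return np.clip(img, 0.0, 1.0), box


def generate_dataset(spec: SyntheticSpec, n_per_class: int, n_background: int,
                     rng: np.random.Generator) -> list[SyntheticSample]:
    """Class-major list of foreground samples followed by background."""
    samples: list[SyntheticSample] = []
    for k in range(spec.num_foreground_classes):
        for i in range(n_per_class):
            pixels, box = _compose(rng, spec, k)
            frame = Frame(pixels, source_id=f"synth_c{k}_{i}")
            samples.append(SyntheticSample(frame, k, box))
    for i in range(n_background):
        pixels, _ = _compose(rng, spec, None)
        frame = Frame(pixels, source_id=f"synth_bg_{i}")
        samples.append(SyntheticSample(frame, spec.background_label, None))
    return samples


def generate_video(spec: SyntheticSpec, script,
                   rng: np.random.Generator,
                   sensor_noise: float = 0.004):
    """Render a freehand-style frame sequence from a dwell script.

    ``script`` is a list of ``(class index or None, length, motion
    amplitude)`` segments.  The camera window drifts over a fixed large
    speckled canvas with per-segment step amplitude (pixels/frame), so the
    frame-to-frame image distance tracks the scripted motion; during a
    dwell the class structure is present at a fixed position in view and
    the amplitude is typically small.  Returns ``(frames, events)`` where
    each dwell event records the true frame interval, a designated freeze
    frame (dwell midpoint), and the ground-truth box in frame coordinates.
    """
    h, w = spec.height, spec.width
    margin = max(8, round(0.3 * min(h, w)))
    big_h, big_w = h + 2 * margin, w + 2 * margin
    canvas = _base_field(rng, big_h, big_w) * \
        _speckle(rng, big_h, big_w, spec.speckle_strength)
    fov = _fov_mask(h, w) if spec.fov_mask else np.ones((h, w), bool)
    pos = np.array([margin, margin], dtype=float)
    frames: list[Frame] = []
    events: list[dict] = []
    t = 0
    for class_idx, length, amplitude in script:
        overlay, box = (None, None)
        if class_idx is not None:
            _, render, _ = _SHAPES[class_idx]
            for _ in range(50):
                overlay, mask = render(rng, h, w)
                if mask.any() and (mask & ~fov).sum() <= 0.01 * mask.sum():
                    break
            else:
                raise RuntimeError("could not place dwell shape in view")
            rows, cols = np.nonzero(mask)
            box = BoundingBox(int(rows.min()), int(cols.min()),
                              int(rows.max()) + 1, int(cols.max()) + 1)
            events.append({
                "class": class_idx, "start": t, "end": t + length,
                "freeze_index": t + length // 2, "gt_box": box,
                "motion_amplitude": amplitude,
            })
        for _ in range(length):
            step = rng.normal(0.0, amplitude, size=2)
            pos = np.clip(pos + step, 0, [big_h - h - 1, big_w - w - 1])
            r, c = int(pos[0]), int(pos[1])
            fr, fc = pos[0] - r, pos[1] - c
            # bilinear sub-pixel window so image distance tracks the
            # scripted motion amplitude smoothly
            view = ((1 - fr) * (1 - fc) * canvas[r:r + h, c:c + w]
                    + (1 - fr) * fc * canvas[r:r + h, c + 1:c + w + 1]
                    + fr * (1 - fc) * canvas[r + 1:r + h + 1, c:c + w]
                    + fr * fc * canvas[r + 1:r + h + 1, c + 1:c + w + 1])
            if overlay is not None:
                view = view + overlay
            view = view + rng.normal(0.0, sensor_noise, size=view.shape)
            view = np.where(fov, view, 0.02)
            frames.append(Frame(np.clip(view, 0, 1),
                                source_id="synthetic_video", frame_index=t))
            t += 1
    return frames, events


# -- on-disk format ------------------------------------------------------

def save_dataset(samples: list[SyntheticSample], outdir) -> None:
    """PNG frames plus ``labels.csv`` and ``boxes.csv`` (half-open coords)."""
    import imageio.v3 as iio
    import pandas as pd

    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    labels, boxes = [], []
    for i, s in enumerate(samples):
        name = f"frame_{i:05d}.png"
        img = np.clip(s.frame.pixels * 255, 0, 255).astype(np.uint8)
        iio.imwrite(outdir / "frames" / name, img)
        labels.append({"filename": name, "label": s.label})
        if s.gt_box is not None:
            b = s.gt_box
            boxes.append({"filename": name, "rmin": b.rmin, "cmin": b.cmin,
                          "rmax": b.rmax, "cmax": b.cmax})
    pd.DataFrame(labels).to_csv(outdir / "labels.csv", index=False)
    pd.DataFrame(boxes).to_csv(outdir / "boxes.csv", index=False)


def load_dataset(path) -> list[SyntheticSample]:
    """Inverse of :func:`save_dataset` (pixels back on the [0, 1] scale)."""
    import imageio.v3 as iio
    import pandas as pd

    path = Path(path)
    labels = pd.read_csv(path / "labels.csv")
    boxes_df = pd.read_csv(path / "boxes.csv") \
        if (path / "boxes.csv").exists() else None
    boxes = {}
    if boxes_df is not None:
        for _, row in boxes_df.iterrows():
            boxes[row["filename"]] = BoundingBox(
                int(row["rmin"]), int(row["cmin"]),
                int(row["rmax"]), int(row["cmax"]))
    samples = []
    for _, row in labels.iterrows():
        pixels = iio.imread(path / "frames" / row["filename"]) / 255.0
        frame = Frame(pixels.astype(np.float64), source_id=row["filename"])
        samples.append(SyntheticSample(frame, int(row["label"]),
                                       boxes.get(row["filename"])))
    return samples
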