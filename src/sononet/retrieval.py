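"""Stream annotation, retrospective frame retrieval, background sampling.

In the intended workflow a trained network watches a freehand screening
video, records the per-class softmax confidence of every frame
(:func:`annotate_stream`), and the frame with the highest confidence for
each standard view is retrieved afterwards (:func:`retrieve_best_frames`).
Background training frames are sampled from stretches of the video where
the probe is moving — frames whose image distance to their predecessor
exceeds a small threshold — because operators hold the probe still around
standard planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Network, classify_frame, forward
from .preprocess import image_distance

__all__ = [
    "ConfidenceTrace",
    "RetrievalResult",
    "annotate_stream",
    "retrieve_best_frames",
    "sample_background_frames",
    "match_freeze_frame",
]


@dataclass
class ConfidenceTrace:
    """Per-frame, per-class softmax confidences over a video."""

    confidences: np.ndarray  # (n_frames, K), rows sum to 1
    frame_indices: np.ndarray  # (n_frames,)
    class_names: list[str] | None = None

    def __len__(self) -> int:
        return len(self.frame_indices)

    def to_csv(self, path) -> None:
        import pandas as pd

        k = self.confidences.shape[1] if len(self) else 0
        names = self.class_names or [f"class_{i}" for i in range(k)]
        df = pd.DataFrame(self.confidences, columns=names)
        df.insert(0, "frame_index", self.frame_indices)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConfidenceTrace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df.iloc[:, 1:].to_numpy(float),
                   df["frame_index"].to_numpy(int),
                   list(df.columns[1:]))


@dataclass
class RetrievalResult:
    """Best frame per class: ``{class index: (frame index, confidence)}``."""

    best: dict[int, tuple[int, float]] = field(default_factory=dict)


def annotate_stream(net: Network, frames) -> tuple[ConfidenceTrace,
                                                   list[tuple[int, float]]]:
    """Classify a frame sequence in order.

    Returns the confidence trace plus one ``(label, confidence)`` pair per
    frame.  A failing frame is recorded (index and error) and skipped; the
    stream continues.
    """
    rows, indices, labels = [], [], []
    errors: list[tuple[int, Exception]] = []
    for i, frame in enumerate(frames):
        idx = getattr(frame, "frame_index", None)
        idx = i if idx is None else idx
        try:
            _, scores = forward(net, frame)
        except Exception as exc:  # record and continue
            errors.append((idx, exc))
            warnings.warn(f"frame {idx} failed: {exc}")
            continue
        rows.append(scores.c)
        indices.append(idx)
        label = int(np.argmax(scores.c))
        labels.append((label, float(scores.c[label])))
    conf = np.array(rows) if rows else np.empty((0, net.config.num_classes))
    trace = ConfidenceTrace(conf, np.asarray(indices, dtype=int))
    trace.errors = errors
    return trace, labels


def retrieve_best_frames(trace: ConfidenceTrace,
                         foreground: list[int] | None = None
                         ) -> RetrievalResult:
    """Per class, the frame with the highest confidence (earliest on ties).

    ``foreground`` restricts retrieval to those class indices; by default
    every class column of the trace is retrieved.
    """
    if len(trace) == 0:
        raise ValueError("cannot retrieve from an empty trace")
    classes = range(trace.confidences.shape[1]) if foreground is None \
        else foreground
    result = RetrievalResult()
    for k in classes:
        col = trace.confidences[:, k]
        row = int(np.argmax(col))  # first maximum = earliest frame
        result.best[k] = (int(trace.frame_indices[row]), float(col[row]))
    return result


def motion_distances(frames) -> np.ndarray:
    """Image distance of each frame to its predecessor (index 0 gets NaN)."""
    out = [np.nan]
    prev = frames[0]
    for f in frames[1:]:
        out.append(image_distance(f, prev))
        prev = f
    return np.asarray(out)


def sample_background_frames(frames, n: int,
                             motion_threshold: float | None = None,
                             exclusion_indices=(),
                             rng: np.random.Generator | None = None,
                             exclusion_halfwidth: int = 0) -> np.ndarray:
    """Sample frame indices from moving parts of a video.

    Eligible frames have distance-to-previous strictly above the threshold
    (default: the 5th percentile of the video's own frame-to-frame
    distances, a self-calibrating notion of "small") and lie outside the
    exclusion windows (each excluded index widened by
    ``exclusion_halfwidth`` on both sides).  If fewer than ``n`` frames are
    eligible, all of them are returned with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n < 0:
        raise ValueError("n must be non-negative")
    d = motion_distances(frames)
    if motion_threshold is None:
        finite = d[np.isfinite(d)]
        motion_threshold = float(np.percentile(finite, 5)) if len(finite) \
            else 0.0
    excluded = set()
    for e in exclusion_indices:
        excluded.update(range(e - exclusion_halfwidth,
                              e + exclusion_halfwidth + 1))
    eligible = np.array([i for i in range(1, len(frames))
                         if d[i] > motion_threshold and i not in excluded],
                        dtype=int)
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} eligible frames for {n} requested")
        return rng.permutation(eligible)
    return rng.choice(eligible, size=n, replace=False)


def match_freeze_frame(frames, still) -> int:
    """Index of the video frame closest to a saved freeze-frame image."""
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    dists = [image_distance(f, still) for f in frames]
    return int(np.argmin(dists))  # first minimum = earliest index
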