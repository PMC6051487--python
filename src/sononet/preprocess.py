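"""Frame preprocessing: cropping, per-image normalisation, image distance.

Raw ultrasound stills and video frames carry vendor overlays outside the
fan-shaped field of view, so the pipeline first crops a fixed 224x288 window
(offsets are configuration — where the logo sits is vendor-specific), then
standardises each image to zero mean and unit variance.  All coordinates are
0-based and row-major; crop windows and bounding boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RawFrame",
    "Frame",
    "CropSpec",
    "crop_frame",
    "normalise_frame",
    "image_distance",
    "read_image",
    "iter_video_frames",
]

#: nominal network input size after cropping
OUT_HEIGHT, OUT_WIDTH = 224, 288


@dataclass
class RawFrame:
    """An un-cropped grayscale image or video frame."""

    pixels: np.ndarray
    source_id: str = ""
    frame_index: int | None = None


@dataclass
class Frame:
    """A cropped (and possibly normalised) network input image ``X``."""

    pixels: np.ndarray
    normalised: bool = False
    source_id: str = ""
    frame_index: int | None = None


@dataclass
class CropSpec:
    """Crop window: fixed output size at a configurable offset."""

    row_offset: int = 0
    col_offset: int = 0
    out_height: int = OUT_HEIGHT
    out_width: int = OUT_WIDTH


def crop_frame(raw: RawFrame, spec: CropSpec) -> Frame:
    """Extract the crop window from a raw frame; values are copied unchanged."""
    pixels = np.asarray(raw.pixels)
    h, w = pixels.shape
    r0, c0 = spec.row_offset, spec.col_offset
    r1, c1 = r0 + spec.out_height, c0 + spec.out_width
    if r0 < 0:
        raise ValueError(f"crop top edge {r0} outside frame (top)")
    if c0 < 0:
        raise ValueError(f"crop left edge {c0} outside frame (left)")
    if r1 > h:
        raise ValueError(f"crop bottom edge {r1} exceeds frame height {h}")
    if c1 > w:
        raise ValueError(f"crop right edge {c1} exceeds frame width {w}")
    return Frame(pixels[r0:r1, c0:c1].astype(np.float64, copy=True),
                 normalised=False, source_id=raw.source_id,
                 frame_index=raw.frame_index)


def normalise_frame(frame: Frame) -> Frame:
    """Standardise to zero mean, unit standard deviation (per image)."""
    pixels = np.asarray(frame.pixels, dtype=np.float64)
    std = pixels.std()
    if std == 0:
        raise ValueError(
            "cannot normalise a constant image (zero standard deviation); "
            "such frames carry no signal and indicate upstream corruption")
    out = (pixels - pixels.mean()) / std
    return Frame(out, normalised=True, source_id=frame.source_id,
                 frame_index=frame.frame_index)


def image_distance(a, b) -> float:
    """Mean squared pixel difference between two equally shaped frames.

    Used for freeze-frame matching (minimum distance over a video) and as
    the probe-motion proxy when sampling background frames.
    """
    pa = np.asarray(getattr(a, "pixels", a), dtype=np.float64)
    pb = np.asarray(getattr(b, "pixels", b), dtype=np.float64)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    return float(np.mean((pa - pb) ** 2))


# -- I/O -----------------------------------------------------------------

def _to_gray(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) -> luma
        arr = arr[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    return arr.astype(np.float64)


def read_image(path) -> RawFrame:
    """Read a PNG/TIFF still as a grayscale raw frame."""
    import imageio.v3 as iio

    return RawFrame(_to_gray(iio.imread(path)), source_id=str(path))


def iter_video_frames(path):
    """Yield grayscale :class:`RawFrame` objects from a video source.

    A directory is treated as a frame sequence (sorted image files), which
    is the package's native video format; container files (MP4/AVI) are
    decoded through imageio when a suitable plugin is installed.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        for i, p in enumerate(files):
            raw = read_image(p)
            yield RawFrame(raw.pixels, source_id=str(path), frame_index=i)
    else:
        import imageio.v3 as iio

        for i, frame in enumerate(iio.imiter(path)):
            yield RawFrame(_to_gray(frame), source_id=str(path), frame_index=i)
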