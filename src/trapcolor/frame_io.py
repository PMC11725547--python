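"""Deterministic frame access and ROI extraction.

Supports numbered image sequences (PNG/TIFF, natural-numeric filename
order) and video containers where an imageio decoder is available.  The
protocol this serves assumes a fixed camera: all frames must share one
size, and the time axis is ``index / fps`` with a constant frame rate.

Pixel conventions (the source material never states them): coordinates
are 0-based with origin at the top-left, ``x`` is the column and ``y``
the row, and all ranges are half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = ["Roi", "FrameRange", "FrameStack", "load_frames", "crop_roi"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest: top-left (x, y), size (width, height)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.x}, {self.y})")
        if self.width < 1 or self.height < 1:
            raise ValueError(f"ROI size must be >= 1, got {self.width}x{self.height}")

    @classmethod
    def parse(cls, text: str) -> "Roi":
        """Parse 'X,Y,W,H'."""
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(f"ROI must be 'X,Y,W,H', got {text!r}")
        return cls(*(int(p) for p in parts))


@dataclass(frozen=True)
class FrameRange:
    """Half-open frame index range [first, last)."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if not 0 <= self.first < self.last:
            raise ValueError(f"need 0 <= first < last, got [{self.first}, {self.last})")

    @classmethod
    def parse(cls, text: str) -> "FrameRange":
        """Parse 'FIRST:LAST'."""
        first, _, last = text.partition(":")
        return cls(int(first), int(last))


@dataclass
class FrameStack:
    """Ordered stack of equally-sized RGB frames with a constant frame rate.

    ``frames`` has shape (N, H, W, 3); timestamps are
    ``(start_index + i) / fps`` relative to the on-disk frame 0.
    """

    frames: np.ndarray
    fps: float
    start_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must have shape (N, H, W, 3), got {self.frames.shape}")
        if len(self.frames) == 0:
            raise ValueError("frame stack is empty")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Timestamps in seconds relative to the analyzed range start."""
        return np.arange(len(self.frames)) / self.fps


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically: frame2 < frame10."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name))


def _list_sequence(directory: Path) -> list[Path]:
    files = [p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES]
    if not files:
        raise FileNotFoundError(f"no image files found in {directory}")
    return sorted(files, key=lambda p: _natural_key(p.name))


def load_frames(path, frame_range: FrameRange | None = None, fps: float = 30.0) -> FrameStack:
    """Load a video file or a directory of numbered images as a FrameStack.

    Frames are returned in index order; ``frame_range`` selects the
    half-open slice [first, last) of the on-disk sequence.  All frames
    must share identical dimensions.
    """
    path = Path(path)
    if path.is_dir():
        files = _list_sequence(path)
        n = len(files)
        rng = frame_range or FrameRange(0, n)
        if rng.last > n:
            raise ValueError(f"frame range [{rng.first}, {rng.last}) exceeds {n} frames")
        frames = [np.asarray(iio.imread(f))[..., :3] for f in files[rng.first : rng.last]]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame sizes in sequence: {sorted(shapes)}")
        return FrameStack(np.stack(frames), fps=fps, start_index=rng.first)
    if not path.is_file():
        raise FileNotFoundError(f"no such video file or image directory: {path}")
    try:
        raw = list(iio.imiter(path))
    except Exception as exc:  # decoder missing or corrupt file
        raise OSError(f"cannot decode video {path}: {exc}") from exc
    n = len(raw)
    if n == 0:
        raise OSError(f"no frames decoded from {path}")
    rng = frame_range or FrameRange(0, n)
    if rng.last > n:
        raise ValueError(f"frame range [{rng.first}, {rng.last}) exceeds {n} frames")
    frames = np.stack([np.asarray(f)[..., :3] for f in raw[rng.first : rng.last]])
    return FrameStack(frames, fps=fps, start_index=rng.first)


def crop_roi(frame: np.ndarray, roi: Roi) -> np.ndarray:
    """Extract the pixel block [y, y+height) x [x, x+width) from a frame.

    ROIs extending past the frame bounds are an error — never silently
    clipped.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[0], frame.shape[1]
    if roi.x + roi.width > w or roi.y + roi.height > h:
        raise ValueError(
            f"ROI {roi} exceeds frame bounds {w}x{h} (width x height)"
        )
    return frame[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width]
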