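"""Per-frame ROI-mean L*A*B* and ΔE time series.

For each frame the pixels inside the region of interest are converted
to L*A*B* individually and then averaged per channel
(convert-then-average — the order matters because the color transform
is nonlinear), and ΔE is the Euclidean distance between each frame's
mean color and the mean color of the first analyzed frame.  The series
round-trips through a fixed-schema CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colorimetry import ReferenceWhite, default_white, delta_e, normalize_frame, rgb_to_lab
from .frame_io import FrameStack, Roi, crop_roi

__all__ = [
    "LabSeries",
    "SeriesSummary",
    "roi_mean_lab",
    "delta_e_series",
    "write_series_csv",
    "read_series_csv",
    "summarize",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["frame", "time_s", "L", "A", "B", "deltaE"]


@dataclass
class LabSeries:
    """Per-frame ROI-mean color trajectory.

    ``deltaE[i]`` is the Euclidean L*A*B* distance between frame i and
    frame 0 of the analyzed range, so ``deltaE[0] == 0`` always.
    """

    time_s: np.ndarray
    L: np.ndarray
    A: np.ndarray
    B: np.ndarray
    deltaE: np.ndarray
    roi: Roi | None = None
    white: ReferenceWhite = field(default_factory=default_white)
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.time_s, self.L, self.A, self.B, self.deltaE)]
        self.time_s, self.L, self.A, self.B, self.deltaE = arrays
        n = len(self.time_s)
        if any(len(a) != n for a in arrays):
            raise ValueError("all series arrays must have equal length")
        if n == 0:
            raise ValueError("series is empty")
        if self.frame_index is None:
            self.frame_index = np.arange(n)

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "time_s": self.time_s,
                "L": self.L,
                "A": self.A,
                "B": self.B,
                "deltaE": self.deltaE,
            }
        )


@dataclass(frozen=True)
class SeriesSummary:
    """Mean and population standard deviation of ΔE over a window."""

    mean: float
    sd: float
    n: int


def roi_mean_lab(frame: np.ndarray, roi: Roi, white: ReferenceWhite | None = None) -> np.ndarray:
    """Mean (L*, A*, B*) over the ROI, converting each pixel first.

    The frame may be 8-bit, 16-bit, or float in [0, 1]; integer frames
    are normalized to unit range before conversion.  Accumulation is in
    double precision; the mean is unweighted.
    """
    sub = normalize_frame(crop_roi(frame, roi))
    lab = rgb_to_lab(sub, white)
    return lab.reshape(-1, 3).mean(axis=0)


def delta_e_series(stack: FrameStack, roi: Roi, white: ReferenceWhite | None = None) -> LabSeries:
    """ΔE of every frame against the first frame of the analyzed range."""
    if white is None:
        white = default_white()
    means = np.array([roi_mean_lab(f, roi, white) for f in stack.frames])
    d = delta_e(means, means[0])
    return LabSeries(
        time_s=stack.times,
        L=means[:, 0],
        A=means[:, 1],
        B=means[:, 2],
        deltaE=np.atleast_1d(d),
        roi=roi,
        white=white,
        frame_index=stack.start_index + np.arange(len(stack)),
    )


def write_series_csv(series: LabSeries, path) -> None:
    """Write the series as CSV with header ``frame,time_s,L,A,B,deltaE``.

    Floats are written with full precision (shortest round-tripping
    repr), so read-back is lossless.
    """
    if len(series) == 0:
        raise ValueError("refusing to write an empty series")
    series.to_frame().to_csv(path, index=False)


def read_series_csv(path) -> LabSeries:
    """Read a series written by :func:`write_series_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {path} is missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"CSV {path} holds no rows")
    return LabSeries(
        time_s=df["time_s"].to_numpy(),
        L=df["L"].to_numpy(),
        A=df["A"].to_numpy(),
        B=df["B"].to_numpy(),
        deltaE=df["deltaE"].to_numpy(),
        frame_index=df["frame"].to_numpy(),
    )


def summarize(series: LabSeries, window: tuple[int, int] | None = None) -> SeriesSummary:
    """Mean and population standard deviation of ΔE over ``window``.

    ``window`` is a half-open index range into the series; the default
    covers the whole series.
    """
    lo, hi = window if window is not None else (0, len(series))
    if not 0 <= lo < hi <= len(series):
        raise ValueError(f"window [{lo}, {hi}) invalid for series of length {len(series)}")
    vals = series.deltaE[lo:hi]
    return SeriesSummary(mean=float(vals.mean()), sd=float(vals.std(ddof=0)), n=hi - lo)


def moving_average(series: LabSeries, width: int) -> LabSeries:
    """Optional temporal smoothing: centered moving average of ΔE and
    channel means (width in frames, odd).  No smoothing is applied by
    default anywhere in the pipeline."""
    if width < 1 or width % 2 == 0:
        raise ValueError("moving-average width must be a positive odd integer")
    if width == 1:
        return series
    kernel = np.ones(width) / width

    def smooth(a: np.ndarray) -> np.ndarray:
        pad = width // 2
        padded = np.pad(a, pad, mode="edge")
        return np.convolve(padded, kernel, mode="valid")

    return LabSeries(
        time_s=series.time_s,
        L=smooth(series.L),
        A=smooth(series.A),
        B=smooth(series.B),
        deltaE=smooth(series.deltaE),
        roi=series.roi,
        white=series.white,
        frame_index=series.frame_index,
    )
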