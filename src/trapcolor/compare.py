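"""Agreement between a ΔE series and a trapped-air-volume trace.

The validation step of the method: if ΔE tracks trapped air volume,
the two curves — which live in different units — should coincide after
min–max normalization and correlate strongly.  Alignment interpolates
both onto the coarser of the two time grids over their overlap;
min–max normalization (rather than z-scoring) is used because it
preserves the saturation plateau shape when units differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import LabSeries
from .trap_sim import TrapTrace

__all__ = ["AlignedPair", "align", "pearson", "spearman", "rms_difference", "report"]


@dataclass
class AlignedPair:
    """ΔE and air volume on a common grid, each min–max normalized to [0, 1]."""

    time_s: np.ndarray
    deltaE_norm: np.ndarray
    volume_norm: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.deltaE_norm) == len(self.volume_norm)):
            raise ValueError("aligned arrays must have equal length")

    def __len__(self) -> int:
        return len(self.time_s)


def _minmax(values: np.ndarray, label: str) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValueError(f"{label} series is constant; min–max normalization undefined")
    return (values - lo) / (hi - lo)


def align(series: LabSeries, trace: TrapTrace) -> AlignedPair:
    """Interpolate ΔE(t) and v_air(t) onto the coarser grid over their
    time overlap and min–max normalize each.

    Raises if the time ranges do not overlap or either curve is
    constant on the overlap.
    """
    t0 = max(series.time_s[0], trace.time_s[0])
    t1 = min(series.time_s[-1], trace.time_s[-1])
    if not t1 > t0:
        raise ValueError(
            f"series [{series.time_s[0]}, {series.time_s[-1]}] and trace "
            f"[{trace.time_s[0]}, {trace.time_s[-1]}] do not overlap"
        )

    def spacing(t: np.ndarray) -> float:
        return float(np.median(np.diff(t))) if len(t) > 1 else np.inf

    coarse = series.time_s if spacing(series.time_s) >= spacing(trace.time_s) else trace.time_s
    grid = coarse[(coarse >= t0) & (coarse <= t1)]
    if len(grid) < 2:
        raise ValueError("fewer than 2 common grid points in the overlap")
    de = np.interp(grid, series.time_s, series.deltaE)
    vol = np.interp(grid, trace.time_s, trace.v_air_ul)
    return AlignedPair(grid, _minmax(de, "deltaE"), _minmax(vol, "volume"))


def pearson(pair: AlignedPair) -> float:
    """Sample Pearson correlation between the aligned curves."""
    if len(pair) < 3:
        raise ValueError(f"need at least 3 aligned points, got {len(pair)}")
    r = stats.pearsonr(pair.deltaE_norm, pair.volume_norm).statistic
    return float(r)


def spearman(pair: AlignedPair) -> float:
    """Spearman rank correlation — useful when the relation is monotone
    but not linear."""
    if len(pair) < 3:
        raise ValueError(f"need at least 3 aligned points, got {len(pair)}")
    return float(stats.spearmanr(pair.deltaE_norm, pair.volume_norm).statistic)


def rms_difference(pair: AlignedPair) -> float:
    """Root-mean-square difference between the normalized curves."""
    return float(np.sqrt(np.mean((pair.deltaE_norm - pair.volume_norm) ** 2)))


def report(pair: AlignedPair, r: float, path=None) -> pd.DataFrame:
    """Comparison record: aligned normalized curves plus the correlation.

    Returns a DataFrame with columns ``time_s, deltaE_norm,
    volume_norm, pearson_r`` (r repeated, so the CSV is self-contained)
    and optionally writes it to ``path``.  Deterministic for fixed
    inputs.
    """
    df = pd.DataFrame(
        {
            "time_s": pair.time_s,
            "deltaE_norm": pair.deltaE_norm,
            "volume_norm": pair.volume_norm,
            "pearson_r": np.full(len(pair), r),
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
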