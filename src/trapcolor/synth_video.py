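"""Seeded synthetic side-view video of a bubble trap filling with air.

Emulates the experimental footage the colorimetric pipeline is built
for: a trap silhouette filled with a dark pink tracer solution (a
potassium-permanganate-like dye) in which a near-white air region grows
downward from the top as air accumulates.  The renderer is pixel-exact
and fully seeded, and every sequence comes with a ground-truth table of
per-frame air fraction and trapped volume, so the whole ΔE pipeline is
testable end-to-end without any real video.

Real footage has structure this fixture does not emulate: meniscus
optics, discrete bubbles, specular highlights, compression artifacts.
The noise model is i.i.d. Gaussian per channel; an optional
multiplicative illumination drift exists to exercise robustness
failure modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .frame_io import FrameStack, Roi
from .trap_sim import TrapTrace

__all__ = ["SyntheticScene", "render_frame", "generate_sequence", "write_sequence"]


@dataclass(frozen=True)
class SyntheticScene:
    """Renderer parameters for the side-view trap scene.

    The trap is the pixel rectangle (trap_x, trap_y, trap_w, trap_h);
    an ``air_fraction`` of a frame paints the top
    ceil(air_fraction * trap_h) rows of that rectangle in ``air_rgb``
    and the rest in ``fluid_rgb``.  ``noise_sd`` is the per-channel
    Gaussian sigma in 8-bit counts; ``illum_gain_per_frame`` is a
    multiplicative gain drift applied as (1+g)^frame before noise.
    """

    width: int = 160
    height: int = 120
    trap_x: int = 40
    trap_y: int = 20
    trap_w: int = 80
    trap_h: int = 80
    fluid_rgb: tuple[int, int, int] = (158, 40, 90)   # dark pink dye
    air_rgb: tuple[int, int, int] = (245, 245, 245)   # near-white air
    background_rgb: tuple[int, int, int] = (205, 205, 205)  # chip body
    noise_sd: float = 2.0
    illum_gain_per_frame: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fluid_rgb", "air_rgb", "background_rgb"):
            rgb = getattr(self, name)
            if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
                raise ValueError(f"{name} must be three 8-bit values, got {rgb}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if (
            self.trap_x < 0
            or self.trap_y < 0
            or self.trap_x + self.trap_w > self.width
            or self.trap_y + self.trap_h > self.height
            or self.trap_w < 1
            or self.trap_h < 1
        ):
            raise ValueError("trap rectangle must lie inside the frame")

    @property
    def trap_roi(self) -> Roi:
        """The ROI covering exactly the trap rectangle."""
        return Roi(self.trap_x, self.trap_y, self.trap_w, self.trap_h)


def render_frame(scene: SyntheticScene, air_fraction: float, frame_index: int = 0) -> np.ndarray:
    """Render one 8-bit RGB frame for a given trapped-air fraction.

    Deterministic for a fixed (scene.seed, frame_index) pair.  Air
    collects at the top of the trap (side view, buoyancy): the top
    ceil(air_fraction * trap_h) trap rows are air-colored.
    """
    if not 0.0 <= air_fraction <= 1.0:
        raise ValueError(f"air_fraction must be in [0, 1], got {air_fraction}")
    img = np.empty((scene.height, scene.width, 3), dtype=float)
    img[:] = scene.background_rgb
    y0, y1 = scene.trap_y, scene.trap_y + scene.trap_h
    x0, x1 = scene.trap_x, scene.trap_x + scene.trap_w
    img[y0:y1, x0:x1] = scene.fluid_rgb
    air_rows = math.ceil(air_fraction * scene.trap_h)
    if air_rows:
        img[y0 : y0 + air_rows, x0:x1] = scene.air_rgb
    if scene.illum_gain_per_frame:
        img *= (1.0 + scene.illum_gain_per_frame) ** frame_index
    if scene.noise_sd > 0:
        rng = np.random.default_rng([scene.seed, frame_index])
        img += rng.normal(0.0, scene.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_sequence(
    scene: SyntheticScene, trace: TrapTrace, fps: float
) -> tuple[FrameStack, pd.DataFrame]:
    """Render one frame per 1/fps sampled from a trap-filling trace.

    The frame count is floor(t_end * fps); the per-frame air fraction
    is the trapped volume at the frame time (linearly interpolated on
    the trace grid) divided by the trap capacity.  Returns the frame
    stack and an aligned ground-truth table with columns
    ``frame, time_s, air_fraction, v_air_ul``.
    """
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")
    if len(trace.time_s) == 0:
        raise ValueError("trace is empty")
    t_end = float(trace.time_s[-1])
    n_frames = int(math.floor(t_end * fps))
    if n_frames < 1:
        raise ValueError(f"trace too short for one frame at {fps} fps")
    times = np.arange(n_frames) / fps
    v_air = np.interp(times, trace.time_s, trace.v_air_ul)
    fractions = np.clip(v_air / trace.capacity_ul, 0.0, 1.0)
    frames = np.stack([render_frame(scene, f, i) for i, f in enumerate(fractions)])
    truth = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "time_s": times,
            "air_fraction": fractions,
            "v_air_ul": v_air,
        }
    )
    return FrameStack(frames, fps=fps), truth


def write_sequence(stack: FrameStack, truth: pd.DataFrame, out_dir, truth_path=None) -> None:
    """Write frames as zero-padded PNGs (lossless, codec-free) plus the
    ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digits = max(5, len(str(len(stack) - 1)))
    for i, frame in enumerate(stack.frames):
        iio.imwrite(out_dir / f"frame_{i:0{digits}d}.png", frame)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
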