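"""Reduced-order (0-D) bubble-trap filling model.

The trap is a buoyancy-driven cylindrical reservoir on the inlet line.
Air arrives as a dispersed phase whose inlet volume fraction follows a
smooth ramp (off until ``t_start``, full value from ``t_full``).  The
trap captures all incoming air while below its capacity; once full,
air passes straight through to the downstream channel.  Two events are
reported in the language used for trap characterization: TEP (trap
entry point — air first enters the trap) and CEP (channel entry point
— air first escapes to the channel, i.e. the trap has saturated).

This is a deliberate desk-scale compartment abstraction of the 3-D
two-phase flow: it conserves air volume exactly and reproduces the
qualitative orderings (faster flow saturates the trap sooner) without
any spatial resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import math

import numpy as np
import pandas as pd

__all__ = [
    "RampSchedule",
    "TrapSpec",
    "TrapTrace",
    "ramp_fraction",
    "simulate_trap",
    "saturation_time",
    "write_trace_csv",
    "read_trace_csv",
]

#: Relative threshold defining when air "begins" to enter/leave.
EVENT_THRESHOLD = 1e-3


@dataclass(frozen=True)
class RampSchedule:
    """Inlet air-fraction ramp: 0 until t_start, phi_final from t_full,
    smoothstep (3u² − 2u³) in between."""

    t_start: float = 1.0
    t_full: float = 3.0
    phi_final: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.t_start < self.t_full:
            raise ValueError(f"need 0 <= t_start < t_full, got {self.t_start}, {self.t_full}")
        if not 0 <= self.phi_final <= 1:
            raise ValueError(f"phi_final must be in [0, 1], got {self.phi_final}")

    @property
    def ramp_integral(self) -> float:
        """Integral of phi(t) dt over [t_start, t_full] (smoothstep mean 1/2)."""
        return 0.5 * self.phi_final * (self.t_full - self.t_start)


@dataclass(frozen=True)
class TrapSpec:
    """Cylindrical trap geometry (mm) and air capacity (µL).

    Default capacity is the geometric cylinder volume pi (d/2)^2 h; a
    different effective capacity may be passed explicitly (a physical
    trap can have plumbing volume beyond the cylinder itself).
    """

    diameter_mm: float = 2.0
    height_mm: float = 4.0
    capacity_ul: float | None = None

    def __post_init__(self) -> None:
        if not (self.diameter_mm > 0 and self.height_mm > 0):
            raise ValueError(f"trap dimensions must be positive, got {self}")
        if self.capacity_ul is not None and not self.capacity_ul > 0:
            raise ValueError(f"capacity must be positive, got {self.capacity_ul}")

    @property
    def geometric_volume_ul(self) -> float:
        """Cylinder volume in µL (1 mm³ = 1 µL)."""
        return math.pi * (self.diameter_mm / 2.0) ** 2 * self.height_mm

    @property
    def capacity(self) -> float:
        return self.capacity_ul if self.capacity_ul is not None else self.geometric_volume_ul


def ramp_fraction(t, schedule: RampSchedule = RampSchedule()):
    """Inlet air volume fraction at time t (s); vectorized over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    u = np.clip((t - schedule.t_start) / (schedule.t_full - schedule.t_start), 0.0, 1.0)
    phi = schedule.phi_final * u * u * (3.0 - 2.0 * u)
    return phi if phi.ndim else float(phi)


@dataclass
class TrapTrace:
    """Time series output of the trap model.

    ``v_air_ul`` is trapped air volume; ``vof_in``/``vof_out`` are the
    air fractions at the trap inlet and outlet.  ``tep``/``cep`` are
    the event times in seconds (``None`` if never reached).
    """

    time_s: np.ndarray
    v_air_ul: np.ndarray
    vof_in: np.ndarray
    vof_out: np.ndarray
    tep: float | None
    cep: float | None
    capacity_ul: float
    q_ul_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "v_air_ul": self.v_air_ul,
                "vof_in": self.vof_in,
                "vof_out": self.vof_out,
            }
        )


def simulate_trap(
    q_ul_min: float,
    schedule: RampSchedule = RampSchedule(),
    spec: TrapSpec = TrapSpec(),
    dt: float = 0.01,
    t_end: float = 30.0,
) -> TrapTrace:
    """Integrate trap filling with explicit Euler steps of size dt.

    dV_air/dt = Q phi(t) eta, with capture efficiency eta = 1 below
    capacity and 0 at capacity; the step crossing capacity captures
    exactly the remaining headroom and routes the excess to the outlet,
    so air volume is conserved to machine precision:
    integral of inflow = trapped volume + integral of outflow.

    Raises a ValueError if dt is large enough that a single full-rate
    step could add more than 5% of capacity (stability guard).
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not t_end > schedule.t_full:
        raise ValueError(f"t_end ({t_end}) must exceed ramp completion ({schedule.t_full})")
    if q_ul_min < 0:
        raise ValueError(f"flow rate must be non-negative, got {q_ul_min}")
    q_ul_s = q_ul_min / 60.0
    capacity = spec.capacity
    max_step_vol = q_ul_s * schedule.phi_final * dt
    if max_step_vol > 0.05 * capacity:
        raise ValueError(
            f"dt={dt} s is unstable: a full-rate step adds {max_step_vol:.3g} µL, "
            f"more than 5% of the {capacity:.3g} µL capacity"
        )

    n = int(round(t_end / dt)) + 1
    time = np.arange(n) * dt
    v_air = np.zeros(n)
    vof_in = np.asarray(ramp_fraction(time, schedule))
    vof_out = np.zeros(n)

    v = 0.0
    for i in range(1, n):
        # inflow over [t_{i-1}, t_i) at the left-endpoint fraction
        inflow = q_ul_s * vof_in[i - 1] * dt
        headroom = capacity - v
        captured = min(inflow, headroom)
        spilled = inflow - captured
        v += captured
        v_air[i] = v
        # outlet fraction over the step, recorded at the right endpoint
        vof_out[i] = vof_in[i - 1] * (spilled / inflow) if inflow > 0 else 0.0

    tep_idx = np.nonzero(v_air > EVENT_THRESHOLD * capacity)[0]
    cep_idx = np.nonzero(vof_out > EVENT_THRESHOLD)[0]
    tep = float(time[tep_idx[0]]) if tep_idx.size else None
    cep = float(time[cep_idx[0]]) if cep_idx.size else None
    return TrapTrace(
        time_s=time,
        v_air_ul=v_air,
        vof_in=vof_in,
        vof_out=vof_out,
        tep=tep,
        cep=cep,
        capacity_ul=capacity,
        q_ul_min=q_ul_min,
    )


def saturation_time(trace: TrapTrace, rel_tol: float = 1e-9) -> float | None:
    """First time the trapped volume reaches capacity; None if not reached."""
    full = np.nonzero(trace.v_air_ul >= trace.capacity_ul * (1.0 - rel_tol))[0]
    return float(trace.time_s[full[0]]) if full.size else None


def write_trace_csv(trace: TrapTrace, path) -> None:
    """CSV with header ``time_s,v_air_ul,vof_in,vof_out`` (full precision)."""
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path, capacity_ul: float | None = None, q_ul_min: float = 0.0) -> TrapTrace:
    """Rebuild a TrapTrace from CSV; events are re-detected from the data."""
    df = pd.read_csv(path)
    required = ["time_s", "v_air_ul", "vof_in", "vof_out"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} is missing columns {missing}")
    v_air = df["v_air_ul"].to_numpy()
    vof_out = df["vof_out"].to_numpy()
    time = df["time_s"].to_numpy()
    cap = capacity_ul if capacity_ul is not None else float(v_air.max())
    tep_idx = np.nonzero(v_air > EVENT_THRESHOLD * cap)[0] if cap > 0 else np.array([])
    cep_idx = np.nonzero(vof_out > EVENT_THRESHOLD)[0]
    return TrapTrace(
        time_s=time,
        v_air_ul=v_air,
        vof_in=df["vof_in"].to_numpy(),
        vof_out=vof_out,
        tep=float(time[tep_idx[0]]) if len(tep_idx) else None,
        cep=float(time[cep_idx[0]]) if len(cep_idx) else None,
        capacity_ul=cap,
        q_ul_min=q_ul_min,
    )
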