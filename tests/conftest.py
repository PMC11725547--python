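import math

import numpy as np
import pytest
from hypothesis import settings

from trapcolor import RampSchedule, SyntheticScene, TrapSpec, default_white

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def white():
    return default_white()


@pytest.fixture
def small_scene():
    """Tiny fast scene for rendering/pipeline tests."""
    return SyntheticScene(width=40, height=30, trap_x=10, trap_y=5, trap_w=20, trap_h=20, seed=11)


@pytest.fixture
def fast_trap():
    """Small-capacity trap that saturates within ~15 s at 50 µL/min, φ=0.2."""
    return TrapSpec(capacity_ul=2.0)


@pytest.fixture
def default_ramp():
    return RampSchedule(t_start=1.0, t_full=3.0, phi_final=0.2)


def straight_line_rgb_to_lab(r, g, b, white):
    """Independent per-pixel oracle: literal scalar transcription of the
    RGB→XYZ matrix product, the piecewise compression and the L*A*B*
    differences, sharing no code with the package implementation."""
    x = 0.4124 * r + 0.3576 * g + 0.1805 * b
    y = 0.2126 * r + 0.7152 * g + 0.0722 * b
    z = 0.0193 * r + 0.1192 * g + 0.9505 * b

    def f(t):
        if t > 0.00886:
            return t ** (1.0 / 3.0)
        return 7.787 * t + 16.0 / 116.0

    fx = f(x / white.x0)
    fy = f(y / white.y0)
    fz = f(z / white.z0)
    return (116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))
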