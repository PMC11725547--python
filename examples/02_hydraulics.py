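"""Channel hydraulics: Reynolds number and bubble rise speed.

Checks that a microchannel at typical perfusion flow rates is far below
the laminar-turbulent transition, and computes how fast an air bubble
of a given size rises relative to the water around it — the mechanism
a buoyancy trap relies on.
"""

import numpy as np

from trapcolor import ChannelSpec, is_laminar, reynolds_rectangular, slip_velocity, stokes_velocity

channel = ChannelSpec(width_mm=1.0, height_mm=0.1)
print("Re = 2 rho Q / ((w + h) mu) for a 1.0 x 0.1 mm channel:")
for q in (50.0, 100.0, 150.0):
    re = reynolds_rectangular(q, channel)
    print(f"  Q = {q:5.0f} uL/min -> Re = {re:.3f}  (laminar: {is_laminar(re)})")
print("Re scales linearly with Q and stays orders of magnitude below the critical 2300.\n")

print("Terminal rise speed of an air bubble in water (Haider-Levenspiel drag):")
for d_um in (10, 50, 100, 500):
    u = slip_velocity(d_um / 1000.0)
    u_st = stokes_velocity(d_um / 1000.0)
    print(f"  d = {d_um:4d} um -> u = {u:9.4f} mm/s   (Stokes closed form: {u_st:9.4f} mm/s)")
print("Small bubbles match the Stokes law; large ones fall below its extrapolation")
print("because drag grows faster than Stokes once the particle Reynolds number is O(1).")
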