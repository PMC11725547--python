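"""Color mathematics: RGB → XYZ → L*A*B* and the ΔE difference.

Converts a few representative pixel colors and prints each stage.  The
dark pink is typical of a permanganate-dyed working fluid; near-white
is what trapped air looks like through the chip.  Their ΔE is the
per-pixel signal the whole method rides on: the larger it is, the more
color change one unit of trapped air produces.
"""

import numpy as np

from trapcolor import default_white, delta_e, rgb_to_lab, rgb_to_xyz

white = default_white()
print(f"reference white (x0, y0, z0) = ({white.x0:.4f}, {white.y0:.4f}, {white.z0:.4f})")

colors = {
    "black": (0.0, 0.0, 0.0),
    "white": (1.0, 1.0, 1.0),
    "dark pink fluid": (158 / 255, 40 / 255, 90 / 255),
    "near-white air": (245 / 255, 245 / 255, 245 / 255),
}
labs = {}
for name, rgb in colors.items():
    xyz = rgb_to_xyz(rgb)
    lab = rgb_to_lab(rgb, white)
    labs[name] = lab
    print(f"{name:16s} RGB={np.round(rgb, 3)}  XYZ={np.round(xyz, 4)}  L*A*B*={np.round(lab, 2)}")

d = delta_e(labs["dark pink fluid"], labs["near-white air"])
print(f"\ndelta-E between fluid and air colors: {d:.2f}")
print("(a fully air-filled trap shifts the ROI mean by this much; a half-filled one by half)")
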