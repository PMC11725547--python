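# Methods

## Color pipeline

The measurement chain is: normalize each 8-bit ROI pixel to [0, 1] (divide
by 255; 16-bit frames divide by 65535), convert RGB → XYZ → L\*A\*B\* per
pixel, average each L\*/A\*/B\* channel over the ROI, and report
ΔE = ‖(L, A, B) − (L₀, A₀, B₀)‖₂ against the first analyzed frame.

Decisions that were genuinely open, and how they were settled:

- **No gamma step by default.** The conversion matrix is applied directly to
  the normalized camera values, treating them as linear RGB. Consumer
  cameras usually emit gamma-encoded sRGB, so an opt-in `linearize=True`
  flag applies the sRGB EOTF first; the default stays with the plain matrix
  because the method is a *relative* measurement (ΔE against frame 0 of the
  same footage), where a monotone per-channel transform changes the scale of
  ΔE but not its tracking behavior.
- **Reference white.** Defaults to the image of unit RGB under the matrix,
  (0.9505, 1.0000, 1.0890) — the white the matrix itself implies
  (numerically D65). Overridable wherever a white is accepted.
- **Branch threshold 0.00886** and linear-branch slope 7.787 with offset
  16/116 are used as given; the two branches meet within 1.3 × 10⁻³, far
  below sensor noise.
- **ΔE is the Euclidean (CIE76) form.** No CIEDE2000 weighting is applied.
- **Convert-then-average.** Averaging RGB first and converting once would
  give a different (wrong, for this protocol) answer on any mixed ROI — a
  black/white half-frame yields L\* = 50 one way and ≈ 76.07 the other; a
  regression test guards the order.
- The first frame *after* range slicing defines (L₀, A₀, B₀), so an analysis
  of frames `a:b` is self-contained.
- Means are unweighted and accumulated in double precision. NaN pixels are
  rejected at load.

## Frame access

Image sequences are ordered by natural-numeric filename sort (`frame2` <
`frame10`). Coordinates are 0-based, origin top-left, x = column,
y = row, all ranges half-open. ROIs that exceed the frame are an error,
never clipped. The time axis is `index / fps` with constant, user-supplied
fps; variable-frame-rate input is out of scope.

## Hydraulics

Re = 2ρQ/((w + h)µ) for a rectangular duct (equivalently ρUD_h/µ with
D_h = 2wh/(w+h)). The quoted constants (ρ in g/mm³, Q in µL/min, w, h in
mm, µ in Pa·s) do not form a coherent unit system, so every input is
converted to SI internally; a test checks invariance against an independent
mm–g–s evaluation to 10⁻¹². Defaults: ρ_c = 0.001 g/mm³,
µ_c = 8.90 × 10⁻⁴ Pa·s, ρ_d = 1.2 × 10⁻⁶ g/mm³, µ_d = 1.81 × 10⁻⁵ Pa·s.

The bubble slip velocity solves the buoyancy–drag balance
(ρ_c − ρ_d) g V = C_D ½ ρ_c u² A for a volume-equivalent sphere, with the
Haider–Levenspiel (1989) correlation
C_D = (24/Re)(1 + A·Re^B) + C/(1 + D/Re), whose A, B, C, D are the standard
sphericity polynomials (sphericity defaults to 1 — small bubbles are
spherical). Damped fixed-point iteration from the Stokes guess, relative
tolerance 10⁻⁸, cap 500 iterations. In the Stokes regime the result matches
u = g d²Δρ/(18µ) within 1% (the residual being the correlation's own
low-Re correction, ≈ 0.16% for a 10 µm bubble).

Wall shear stress is deliberately not implemented: credible values require
the full 3-D flow field, and no analytic surrogate is anchored here.

## Trap-filling model

A 0-D compartment: dV_air/dt = Q·φ(t)·η with capture efficiency η = 1
below capacity and 0 at capacity. φ(t) is 0 until t_start = 1 s, reaches
φ_final at t_full = 3 s, smoothstep (3u² − 2u³) between — a smooth,
monotone stand-in for the gradual introduction of the dispersed phase.
Integration is explicit Euler, dt = 0.01 s by default, with a guard
rejecting steps that could add > 5% of capacity at once. The step that
crosses capacity captures exactly the remaining headroom and routes the
excess to the outlet, so the air balance
∫Qφ dt = V_air + ∫Q·vof_out dt holds to machine precision. Events:
TEP = first t with V_air > 10⁻³ × capacity; CEP = first t with
vof_out > 10⁻³ (the threshold is a modeling choice — "begins to enter" has
no sharper definition). In this model CEP coincides with saturation by
construction.

Default geometry is a 2 mm diameter × 4 mm cylinder, capacity = its
geometric volume ≈ 12.57 µL. A larger effective capacity (e.g. a 50 µL
system-level figure that includes plumbing and reservoir volume) can be
passed explicitly; the geometric default is kept because it is the only
value derivable from the stated geometry. φ_final defaults to 0.2 — a
heavy but plausible air load that exercises the full dynamic range without
saturating the default trap inside a 30 s run.

This abstraction reproduces the qualitative physics (monotone filling,
conservation, earlier TEP/CEP at higher Q, fastest saturation at the
highest flow rate) but none of the spatial detail of a CFD mixture model:
no per-surface fractions, no bubble-scale dynamics, no pressure coupling.

## Synthetic video

Side view (buoyant air collects at the top): the trap rectangle is painted
fluid-colored (default dark pink (158, 40, 90), emulating a
permanganate-dyed solution — a fixture parameter, not a measured value)
with the top ⌈air_fraction · H⌉ rows air-colored (245, 245, 245) on a
neutral chip background. I.i.d. Gaussian noise (default sd 2 counts) is
added per channel and clipped; an optional multiplicative illumination
drift per frame exists only to exercise failure modes and is off by
default. All randomness derives from one explicit seed, keyed per frame,
so a fixed seed reproduces byte-identical PNGs.

Because the ROI mean is linear in the painted-pixel fraction, the expected
ΔE is *exactly* proportional to the rendered air fraction — which is what
makes the fixture a sharp end-to-end oracle: any deviation beyond row
quantization (≤ 1 row of the trap height) and noise indicates a pipeline
defect. Real footage breaks this linearity through meniscus optics,
discrete bubbles, lighting drift and codec artifacts, so passing these
tests validates the pipeline's correctness, not the field accuracy of the
ΔE ↔ volume relationship on any particular rig.

## Comparison

ΔE and volume series are linearly interpolated onto the coarser of the two
grids over their time overlap, then min–max normalized (chosen over
z-scores to preserve plateau shapes when units differ). The headline
statistic is the Pearson correlation; Spearman is available where the
relation is monotone but not linear. Constant series are an error
(normalization undefined), as are overlaps shorter than 2 grid points or
correlations on fewer than 3.

## Problem sizes

Default study conditions: flow rates 50/100/150 µL/min, φ_final = 0.2,
ramp 1 s → 3 s, dt = 0.01 s. The end-to-end validation runs 30 s at 30 fps
(900 frames of 160 × 120 px); event timing runs 150 s traces so the
default trap saturates at all three flow rates. These sizes are chosen so
the full cycle — simulate, render, analyze, compare — completes in seconds
while leaving every quantity of interest resolved well beyond its test
tolerance.

## Known limitations

- The Euclidean ΔE is not perceptually uniform at large differences; it is
  used here as a volume proxy, not a perceptual claim.
- The trap model's hard capacity switch means partial capture regimes
  (bubbles escaping a half-full trap) are not representable.
- The renderer's air/fluid colors are fixture parameters; absolute ΔE
  magnitudes from synthetic runs do not transfer to real dye
  concentrations or lighting.
- Video-container input requires an imageio ffmpeg backend at run time;
  PNG/TIFF sequences are the codec-free, fully deterministic path.
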