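# trapcolor

Colorimetric quantification of air accumulation in microfluidic bubble traps.

Organ-on-a-chip and other perfused microfluidic systems are disrupted by air
bubbles; a passive cylindrical *bubble trap* captures them by buoyancy before
they reach the working zone. `trapcolor` implements a cheap, camera-only way
to measure how much air a trap holds over time: film the trap, average the
color of a region of interest frame by frame in the CIELAB color space, and
track the color difference ΔE against the first frame. Because trapped air
displaces the dyed working fluid with a near-white region, the ROI-mean color
shift is (to first order) proportional to the trapped air volume.

The package is aimed at microfluidics labs who want a desk-scale,
fully-testable version of this workflow: the analysis pipeline, the design
formulas around it, a reduced-order trap-filling model, and a seeded
synthetic-video generator so the whole ΔE ↔ volume claim can be exercised
without any real footage.

## The method

Each ROI pixel is converted RGB → XYZ → L\*A\*B\* and the channels are
averaged **after** conversion (the transform is nonlinear, so the order
matters):

- XYZ = M · (R, G, B)ᵀ with M the CIE 1931 matrix
  `[[0.4124, 0.3576, 0.1805], [0.2126, 0.7152, 0.0722], [0.0193, 0.1192, 0.9505]]`
  applied to RGB normalized to [0, 1];
- L\* = 116 f(y/y₀) − 16, A\* = 500[f(x/x₀) − f(y/y₀)],
  B\* = 200[f(y/y₀) − f(z/z₀)], with f(t) = t^⅓ for t > 0.00886 and
  7.787 t + 16/116 otherwise;
- ΔEᵢ = √((Lᵢ−L₀)² + (Aᵢ−A₀)² + (Bᵢ−B₀)²) against the first analyzed frame.

Around the pipeline:

- **hydraulics** — rectangular-duct Reynolds number Re = 2ρQ/((w+h)µ), the
  laminar criterion (Re < 2300), and the terminal rise (slip) velocity of a
  bubble from a buoyancy–drag balance with the Haider–Levenspiel drag
  correlation;
- **trap_sim** — a 0-D trap-filling model: inlet air fraction ramps from 0 to
  φ over a smoothstep (default 1 s → 3 s), the trap captures all air until
  its capacity, then spills downstream; reports TEP (air first enters the
  trap) and CEP (air first escapes to the channel);
- **synth_video** — a seeded renderer of side-view footage (dark pink fluid,
  near-white air growing from the top, Gaussian sensor noise) with a
  per-frame ground-truth air-fraction table;
- **compare** — aligns a ΔE series with a volume trace on a common time grid,
  min–max normalizes both, and reports the Pearson correlation.

## Worked example

`examples/04_deltae_recovers_volume.py` runs the whole loop — trap model →
synthetic video → ΔE pipeline → comparison — at 50 µL/min, inlet air
fraction 0.2, 30 fps for 30 s, with sensor noise of 2 counts:

```
rendered 900 frames (160x120 px)
final deltaE = 22.46  (trap 37% full)
pearson r (deltaE vs trapped volume): 0.9994
rms gap between min-max normalized curves: 0.0151
```

The ΔE series and the true trapped volume correlate at r = 0.9994 and their
min–max-normalized curves differ by 1.5% RMS: the color readout is an
accurate proxy for the air volume under these conditions. The other examples
print the color-conversion stages (ΔE ≈ 59.9 between the fluid and air
colors), the channel hydraulics (Re = 5.1 at 150 µL/min in a 1 × 0.1 mm
channel — deeply laminar; a 10 µm bubble rises at 0.061 mm/s, within 1% of
the Stokes closed form), and the trap-filling events (TEP 1.73/1.57/1.50 s
and saturation 77.4/39.7/27.1 s at 50/100/150 µL/min — faster flow fills the
trap sooner).

The same workflow is available from the shell:

```bash
trapcolor simulate --q 50 --phi 0.2 --t-end 30 --fps 30 --seed 7 \
    --out frames/ --truth truth.csv
trapcolor analyze --input frames/ --roi 40,20,80,80 --fps 30 --out series.csv
trapcolor simulate-trap --q 50 --phi 0.2 --t-end 30 --out trace.csv
trapcolor compare --deltae series.csv --truth trace.csv --out report.csv
```

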