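# vsf — volume of surgical freedom

Quantitative assessment of surgical access corridors from stereotactic
coordinate measurements.

In anatomical approach studies, the maneuverability of an instrument toward
a deep surgical target has traditionally been summarized as *surgical
freedom*: the area bounded by the extreme positions of the instrument's
proximal end, computed by splitting the bounded points into triangles and
summing their Heron areas.  That metric has well-known defects — the
measured points are never coplanar (tilted triangles overestimate the true
perpendicular cross-section), the result scales with the length of the
probe used to capture the points, and the triangle division itself is an
arbitrary choice that can double-count area on irregular outlines.

The **volume of surgical freedom (VSF)** replaces the planar area with the
volume of an irregular-based cone.  The apex of the cone is the surgical
target structure; the base is the ordered ring of instrument-extrema points
(eight by default, captured sequentially around the corridor perimeter).
For a measurement with apex $P_a$ and extrema $P_1,\dots,P_n$:

1. **Best-fit base plane.**  Fit the plane $Ax + By + Cz + D = 0$
   (unit normal $\mathbf{n} = (A,B,C)$) minimizing the total-least-squares
   objective $\sum_p d_p^2$ with
   $d_p = |A x_p + B y_p + C z_p + D| / \sqrt{A^2+B^2+C^2}$.
   The nonlinear fit is seeded from the *average plane* — the
   orientation-aligned mean of the planes through all $\binom{n}{3}$
   point triples — and verified against the closed-form solution
   (centroid + smallest principal direction).
2. **Height normalization.**  Translate the plane parallel to itself to a
   fixed perpendicular distance $h_{\mathrm{norm}}$ (default 10 mm) from
   the apex.
3. **Apex-ray translation.**  Move each extremum onto that plane along the
   line through the apex, which preserves the cone's cross-sectional shape.
4. **Area.**  Chart the translated ring in 2D on the plane and apply the
   shoelace formula — exact for any simple polygon, convex or not.
5. **Volume.**  $V = \tfrac{1}{3} A h$.

The normalized VSF is probe-length independent: measuring the same corridor
with a longer or shorter instrument scales the extrema along their apex
rays and leaves the result unchanged.  The package also reports the
craniocaudal and mediolateral angles of attack (apex angles between
protocol points 1–5 and 3–7), the legacy Heron-fan area for comparison with
the older literature, per-point probe lengths, replicate aggregation, a
synthetic-measurement generator with a realistic error model, and
spline-smoothed 3D corridor meshes (STL/OBJ/PLY) for visualization.

## Worked example

```python
from vsf import SimulationConfig, add_probe_noise, compute_vsf, make_irregular_corridor

cfg = SimulationConfig(seed=42, base_irregularity=0.2)   # 190 mm probe, 5 mm jitter
corridor = add_probe_noise(make_irregular_corridor(cfg), cfg, seed=43)
r = compute_vsf(corridor, h_norm=10.0)
print(round(r.normalized_vsf, 2), round(r.perp_height, 2),
      round(r.craniocaudal_angle, 2), round(r.legacy_heron_area, 2))
```

prints `56.39 183.12 28.11 5846.48`:

- `normalized_vsf = 56.39` mm³ — the corridor volume re-cut 10 mm from the
  apex; directly comparable across studies regardless of probe length
  (the raw volume at the measured height is 346,268 mm³).
- `perp_height = 183.12` mm — apex-to-base-plane distance actually measured.
- `craniocaudal_angle = 28.11`° — apex angle between protocol points 1 and 5.
- `legacy_heron_area = 5846.48` mm² — the historical metric on the raw,
  non-coplanar points; note it exceeds the planar base area (5,672.93 mm²)
  because the tilted fan triangles overestimate the perpendicular
  cross-section.

The same pipeline is available from the shell:

```bash
vsf simulate --preset noisy --replicates 3 --seed 9 --out corridor.csv
vsf compute --input corridor.csv --output report.csv --mesh-dir meshes/
vsf aggregate --input report.csv --out summary.csv
vsf probe-experiment --preset regular --delta 5
```

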