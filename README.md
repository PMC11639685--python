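# thvforge

Parametric, algorithmic modeling of stented transcatheter heart valves
(THVs) as analysis-suitable NURBS geometry.

A stented THV has three structural families: a wire **frame** (stent) that
anchors the device, a fabric **skirt** that lines the lower frame and seals
against paravalvular leak, and three tissue **leaflets** hung from
**commissural attachments**. `thvforge` turns a small declarative
configuration — a table of cylindrical coordinates (r_c, φ_c, z_c) per
stent cross-section, support-point offset fractions, and curve recipes for
the soft goods — into:

* the stent wireframe: a single clamped cubic NURBS wire whose control
  polygon interleaves the baseline points P_i with tangency support points
  (offset axially by 12.5% of the neighbouring vertical gaps at interior
  junctions, 25% along the chord at the apexes), mirrored across φ = 0 and
  patterned in increments of 2·φ_max about the valve axis;
* a crossing-constraint map: at every junction the two overlapping wires
  contribute three collinear control-point pairs that a beam solver ties
  together, clamping the wires and transferring moment;
* skirt, commissure and leaflet patches as Gordon/loft surfaces over
  bidirectional cubic curve networks, built so that every surface
  interpolates 100% of its defining curves to ~1e-14 mm;
* evaluable structural kernels: beam cross-section frames
  v₂ = v₁ × φ̂_c, v₃ = v₁ × v₂ with twist-free Euler–Rodrigues frame
  propagation; the Lee–Sacks tissue energy
  ψ(I₁,I₄) = c₀/2 (I₁−3) + c₁/2 (w e^{c₂(I₁−3)²} + (1−w) e^{c₃(I₄−1)²} − 1);
  shell–shell and shell–beam penalty-coupling parameters
  α_d = α E H / (h (1−ν²)), α_r = α_d H²/12,
  α_d^sb = α min{shell, beam} branches; and the linear nonlocal contact
  kernel φ'_c(r) = −max(k_c (r_max − r), 0) with its static-friction
  companion;
* geometric QC: n-fold/mirror symmetry deviations, junction collinearity,
  bounding dimensions, and a geometric orifice-area proxy.

Two fixtures ship with the package: **THV-A**, a tall (45 mm) self-expanding
frame with 11 cross-sections and φ_max = 12° (Evolut R-like), and **THV-B**,
a short (20.05 mm) balloon-expandable frame with 8 cross-sections at a
constant 13 mm radius and φ_max = 15° (SAPIEN 3-like).

The intended users are cardiovascular-biomechanics groups building
isogeometric structural or FSI models of TAVR devices who need clean,
symmetric, refinable spline geometry plus the constraint/coupling metadata
those solvers consume.

## Worked example

```python
from thvforge import config, stent, nurbs

cfg = config.thv_a()
wire = stent.build_stent_curve(cfg.profile, cfg.support)
print(len(wire.control_points), nurbs.element_count(wire))
# 31 28            <- 11 baseline + 20 support points; 28 cubic spans
refined = nurbs.h_refine_uniform(wire, 2)
print(nurbs.element_count(refined))
# 112              <- two uniform refinements, geometry unchanged (<=1e-12 mm)
```

The 31 control points are the 11 table rows interleaved with 20 support
points; a clamped cubic with 31 control points has 28 non-degenerate knot
spans (isogeometric elements), and two midpoint refinements quadruple that
to 112 — the analysis discretization for the tall frame (76 for the short
one). `examples/` contains one narrative script per capability
(wireframe, soft goods, full assembly + QC + export, structural kernels);
each prints the numbers it computes and what they mean.

A thin CLI wraps the same API:

```bash
thvforge generate thv-a --out build/ --refine-stent 2
thvforge qc build/thv-a.json
thvforge export build/thv-a.json --format stl --tess-tol 0.05
```

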