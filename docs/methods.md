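# Methods

This note records the geometric model, the construction decisions that were
genuinely open, the numerical choices, and what the tests do and do not
demonstrate.

## Coordinate and unit conventions

Right-handed Cartesian frame; the valve axis is +z with the inflow (base)
plane at z = 0. All lengths are millimetres, all moduli kilopascals
(58 GPa is stored as 5.8e7 kPa), densities g/cm³. Public interfaces take
angles in degrees because the profile tables are written in degrees;
radians are internal. All parametric domains are normalized to [0, 1].

## Spline machinery

All curves and surfaces are clamped B-splines of degree 3 with unit weights;
the only rational construction is the exact circular arc (rational
quadratic, used for the circumcircle utility and to seed the interior
leaflet arc). Evaluation goes through `scipy.interpolate.BSpline` on
homogeneous coordinates so rational and polynomial geometry share one code
path. Knot insertion (Boehm), global interpolation, lofting, the Gordon
construction and an internal Bézier-decomposition degree elevation are
implemented in `nurbs.py`; degree elevation is deliberately not public —
it exists only so the Gordon combination can bring its three constituent
surfaces into one spline space.

Global interpolation uses chord-length parameterization with knots by
parameter averaging — the standard shape-stable choice; the
parameterization is not dictated by the design procedure itself, so it is a
package decision. End-derivative constraints are supported (two extra
control points, derivative collocation rows). Callers may supply explicit
parameters and knots; the network builders rely on this.

## Stent wireframe

One wire's control polygon is P₁, S₁⁺, S₂⁻, P₂, S₂⁺, …, Sₙ⁻, Pₙ: every
interior baseline point sits between its two support points, end points
carry one support each. Two readings of the support rule were possible:

* **Interior supports offset purely axially** (same r_c, φ_c as their
  anchor, z shifted by 12.5% of the vertical gap to the adjacent
  cross-section). This is the single most consequential interpretation in
  the package: it makes each triple (S⁻, P, S⁺) exactly collinear on a
  vertical line *and* maps the supports of one wire exactly onto the
  supports of the crossing wire under mirror + rotation, so junction
  control-point pairs coincide to machine precision. A chord-direction
  alternative breaks both properties and was rejected.
* **Apex supports on the chord** to the single neighbour, scaled so the
  axial offset is 25% of the vertical gap. This produces the diamond apex.
  Exact mirror-symmetric G1 continuity across the apex is impossible with a
  nonzero axial support offset (the two chords meet at an angle in the
  azimuthal direction); the junction is position-continuous with
  mirror-symmetric tangents, and the constraint map records apex groups as
  2-member (single coincident pair) groups, without a collinearity claim.

"Distance between adjacent vertical cross-sections" is read as the z-gap,
matching the vertical d₁–d₃ annotations of the construction figures.

Crossing detection buckets control points on coordinates rounded at 1e-7 mm
(or the user tolerance if coarser) and then merges buckets within the
tolerance, so exact-arithmetic and perturbed inputs group identically. A
junction group is centred on a coincident *baseline* pair and pulls in the
two adjacent support pairs of each wire; a missing partner raises an error
naming the junction.

## Gordon networks and the compatibility pass

A Gordon surface (loft of u-curves + loft of v-curves − tensor interpolation
of the crossing grid) interpolates every network curve **only** when the
network is compatible: u-curve j must pass through crossing (i, j) at the
common parameter u_i, and symmetrically in v. Generic chord-length curves
do not satisfy this, so the builders construct compatibility instead of
hoping for it:

1. Build the defining curves and locate all crossings.
2. Average the per-host crossing parameters into common stations.
3. Re-interpolate each vertical curve through its own defining points plus
   the crossing points, with parameters remapped piecewise-linearly so each
   crossing lands exactly at its station. Horizontal curves get their
   stations for free: symmetric point sequences put the centre crossing at
   exactly u = 0.5 and the corners at 0 and 1.

The re-interpolated curves *are* the network curves (the surface is not an
approximation of something else), and the Gordon combination then
reproduces them to ~1e-14 mm, comfortably inside the 1e-8 mm contract the
tests enforce. The three constituent surfaces are degree-elevated and
knot-merged (union of knot vectors, never re-approximation) before the
control nets are combined; the combination is restricted to unit-weight
networks because the pointwise sum of rational surfaces is not the rational
sum of their control nets. For the same reason the interior leaflet arc
enters the network as a cubic interpolant through seven points sampled on
the exact rational arc (the exact arc remains available to callers).

Intersections are found by a 64-point seeding scan, bounded least squares
on the separation vector, and a Gauss–Newton polish to machine precision;
the default network tolerance is 1e-6 mm.

## Soft-good recipes

The construction figures define the per-valve point lists only partially in
prose (the skirt example reference R₂₄°(P₁), the leaflet edge translations
0.12 / 0.15 mm, the free-edge centre-low vs centre-flat rules, the φ_max/6
commissure edge rotation). Recipes are therefore *data*, not code: each
fixture carries ordered point references (P_i, S_i±) with transform chains
(rotate, reflect, translate, invert-φ, radial/vertical offset), and the
parts the figures leave graphical are flagged `approximated_from_figure` in
the configuration. Specific fixture choices, made once on geometric
plausibility:

* Skirt verticals: the lower wire path (THV-A: P₁–P₄, to the z = 13 mm rim;
  THV-B: the full P₁–P₈ height, since the short frame is lined throughout).
  The rotation family uses one curve per azimuth station (increments of
  φ_max across 120°), giving a non-crossing network; rim curves interpolate
  the family's endpoints with a shared azimuthal parameterization.
* Commissures: central curve from the φ = 0 frame section (THV-A: P₇, S₇⁺,
  S₉⁻, P₉; THV-B: P₅, S₅⁺, S₇⁻, P₇); edges at ±φ_max/6; loft of the three.
* Leaflets: the upper vertical edge is the commissure central curve
  translated by 0.12 / 0.15 mm along +y (the unit normal of the φ = 0 plane,
  toward the leaflet interior); the lower run continues down the frame to a
  corner at φ = 24° / 30°. The vertical edge is a single C²-continuous
  interpolation through the union of the two point runs (after verifying
  the shared junction point within 1e-6 mm) rather than a C⁰ two-piece
  join — same points, smoother network. Free-edge side points sit at
  fractions [0.25, 0.5] of the corner-to-axis line (the design states
  "specified increments" without values); the centre point offsets an
  on-axis point radially along φ = 60° and vertically (−6 mm for the
  centre-low THV-A, 0 for the flat THV-B). Belly and interior-offset
  factors (0.6 × the upper-edge length) were likewise chosen once for
  plausible leaflet curvature. Step-4 offsets are arc-length offsets along
  the host curves.

## Structural kernels

Pointwise evaluators with explicit unit contracts; quadrature and assembly
belong to the consuming solver. The global reference triad for frame
propagation defaults to A₁ = ẑ, A₂ = x̂, A₃ = ŷ (configurable). Frames are
propagated station-to-station by the minimal (Euler–Rodrigues) rotation
between consecutive tangents, then rotated by the per-station angle θ̊ about
the local tangent — this avoids the spurious twist a fixed-reference
construction produces where the centerline turns sharply.

Lee–Sacks: the leaflet is transversely isotropic (c₀ = 117.1375 kPa,
c₁ = 41.4347 kPa, c₂ = 109.7423, c₃ = 132.4545, w = 0.9883, fibers at 45°);
the skirt is the isotropic special case w = 1 (c₁ = 60.3991 kPa,
c₂ = 92.4784), whose I₄ derivative is identically zero. The published
parameter listing prints the anisotropy weight as δ while the energy is
written in w; the package stores it as w. The exponential terms are guarded
by configurable invariant caps (defaults I₁ ≤ 12, I₄ ≤ 4, warn-don't-clamp
silently), the pointwise analogue of a hybrid bound at extreme stretch; the
defaults are package choices, stated values for them are not published.

Penalty parameters use the effective stiffness E_sh = 2 c₀ (1+ν) with
ν = 0.5 (so 3 c₀) for the hyperelastic shells; the shell–beam rule takes
the minimum of the shell and beam branches and reports which governs (for
tissue against the 58 GPa frame the shell branch wins by >10⁴). The beam
cross-section area in the beam branch is the rectangle 0.54 × 0.21 mm².
The static-friction evaluator follows the tangential-slip-since-deployment
form and contains no friction coefficient; the configuration's
μ = 0.2 field is carried as metadata for solvers that post-process friction
limits. Zero tangential separation returns zero force with a warning (limit
convention).

## QC metrics

Symmetry deviations are symmetric nearest-neighbour cloud distances (KD
tree), not index-paired, so patch ordering cannot mask an asymmetry.
Bounding dimensions of an assembly are taken over the stent-wire control
points: the frame defines the device envelope and its control points sit
exactly at the table radii/heights, whereas soft-good *control hulls*
legitimately overshoot the geometry (B-spline interpolation and the Gordon
minus-term push control points outward; the sampled surfaces stay within
the frame radius + 1 mm, which a separate check enforces). The orifice-area
proxy samples each free edge at 512 points, orders the loops by starting
azimuth, projects to the z-plane and applies the shoelace formula
(absolute value on self-intersection, with the top-view convention); it is
a property of the as-built open geometry, not a hemodynamic opening area.

## Problem sizes and determinism

Everything here is deterministic desk-scale geometry: a full valve
assembles in well under a second, and the whole test suite (including both
assemblies, mesh exports and a 10⁴-station frame sweep) runs in seconds.
Property tests use a fixed seed (hypothesis profiles are derandomized by
seeding numpy generators in fixtures). The acceptance script's seed only
drives the random spot-check parameters used to confirm refinement leaves
the geometry unchanged; the reported counts are structural.

## Limitations

* The fixture recipes reproduce the published tables, translations, angles
  and qualitative shapes exactly, but the figure-only point lists are
  approximations; downstream strain fields would differ in detail from the
  original devices even though all stated symmetries and counts match.
* Dynamics are out of scope by design: no beam/shell/solid weak forms, no
  crimping/deployment, no FSI. The kernels are the pointwise ingredients a
  solver would integrate.
* Gordon networks must be unit-weight; trimmed surfaces, T-splines and
  degree elevation are not part of the public surface.
* The skirt's one-third section is built from a single rotated vertical
  family; it is exactly 3-fold symmetric in the assembly but only
  approximately mirror-symmetric within a section unless the vertical
  recipe itself is mirror-symmetric.
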