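# THV-A: tall self-expanding valve (Evolut R-like frame).
# Profile table and material parameters are the published device values;
# the skirt/commissure/leaflet recipes are approximated-from-figure where the
# source text stops short of listing every point (see docs/methods.md).
name: THV-A
profile:
  points:  # [r_c mm, phi_c deg, z_c mm], bottom to top
    - [13.15, 0, 0.00]
    - [12.55, 12, 5.00]
    - [12.20, 0, 9.00]
    - [11.75, 12, 13.00]
    - [11.55, 0, 16.50]
    - [11.00, 12, 20.00]
    - [11.00, 0, 23.50]
    - [12.65, 12, 27.50]
    - [15.20, 0, 32.50]
    - [15.85, 12, 38.50]
    - [14.90, 0, 45.00]
support:
  end_fraction: 0.25
  interior_fraction: 0.125
skirt:
  vertical:  # lower wire path, inflow ring up to the skirt rim
    - {ref: P1}
    - {ref: P2}
    - {ref: P3}
    - {ref: P4}
  span_degrees: 120
commissure:
  central:  # phi = 0 section of the upper frame between P7 and P9
    - {ref: P7}
    - {ref: S7+}
    - {ref: S9-}
    - {ref: P9}
  edge_source: central_curve
leaflet:
  translation_mm: 0.12
  lower_edge:  # continues the vertical edge below the commissure
    - {ref: P6}
    - {ref: P5, transforms: [{rotate_z: 24}]}
  attachment:  # left half up to the phi = 60 center; mirrored by the builder
    - {ref: P5, transforms: [{rotate_z: 24}]}
    - {ref: P4, transforms: [{rotate_z: 30}, {offset: [-0.15, 1.5]}]}
    - {ref: P4, transforms: [{rotate_z: 48}]}
  free_edge:
    mode: center_low
    side_fractions: [0.25, 0.5]
    center_radial_offset_mm: 4.0
    center_vertical_offset_mm: -6.0
    axis_vertical_offset_mm: 0.0
  belly:
    radial_offset_mm: 7.5
    vertical_offset_mm: -15.5
  interior_factor: 0.6
  side_drop_factor: 0.6
  use_arc: true
materials:
  frame: {E_GPa: 58, nu: 0.33, rho_g_cm3: 6.45}
  leaflet:
    c0_kPa: 117.1375
    c1_kPa: 41.4347
    c2: 109.7423
    c3: 132.4545
    w: 0.9883
    fiber_angle_deg: 45
  skirt: {c0_kPa: 117.1375, c1_kPa: 60.3991, c2: 92.4784, w: 1.0}
  shell: {thickness_mm: 0.33, rho_g_cm3: 1.0}
  penalties: {alpha_ss: 1.0e+3, alpha_sb: 1.0e+4, alpha_f: 1.0e+11, mu_friction: 0.2}
  beam_section: {width_mm: 0.54, height_mm: 0.21}
approximated_from_figure: [skirt, commissure, leaflet]
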