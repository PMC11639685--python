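# THV-B: short balloon-expandable valve (SAPIEN 3-like frame).
# Constant 13 mm radius; profile and material values are published; soft-good
# recipes are approximated-from-figure where the source text stops short of
# listing every point (see docs/methods.md).
name: THV-B
profile:
  points:  # [r_c mm, phi_c deg, z_c mm], bottom to top
    - [13.00, 0, 0.00]
    - [13.00, 15, 3.65]
    - [13.00, 0, 6.70]
    - [13.00, 15, 9.70]
    - [13.00, 0, 12.75]
    - [13.00, 15, 15.20]
    - [13.00, 0, 17.60]
    - [13.00, 15, 20.05]
support:
  end_fraction: 0.25
  interior_fraction: 0.125
skirt:
  vertical:  # full-height wire path: the skirt lines the whole short frame
    - {ref: P1}
    - {ref: P2}
    - {ref: P3}
    - {ref: P4}
    - {ref: P5}
    - {ref: P6}
    - {ref: P7}
    - {ref: P8}
  span_degrees: 120
commissure:
  central:  # phi = 0 section between P5 and P7
    - {ref: P5}
    - {ref: S5+}
    - {ref: S7-}
    - {ref: P7}
  edge_source: central_curve
leaflet:
  translation_mm: 0.15
  lower_edge:
    - {ref: P4}
    - {ref: P3, transforms: [{rotate_z: 30}]}
  attachment:
    - {ref: P3, transforms: [{rotate_z: 30}]}
    - {ref: P2, transforms: [{rotate_z: 30}, {offset: [0.0, 1.35]}]}
    - {ref: P2, transforms: [{rotate_z: 45}]}
  free_edge:
    mode: center_flat
    side_fractions: [0.25, 0.5]
    center_radial_offset_mm: 3.5
    center_vertical_offset_mm: 0.0
    axis_vertical_offset_mm: 0.0
  belly:
    radial_offset_mm: 8.0
    vertical_offset_mm: -9.6
  interior_factor: 0.6
  side_drop_factor: 0.6
  use_arc: false
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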