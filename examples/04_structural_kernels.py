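"""Evaluate the structural kernels a solver would call pointwise.

Covers beam section frames along a stent wire, the Lee-Sacks tissue energy,
the effective shell stiffness and penalty-coupling parameters, and the
contact kernel.
"""

import numpy as np

from thvforge import config, kernels, stent

cfg = config.thv_a()
m = cfg.materials

# --- beam cross-section frames along the wire -----------------------------
wire = stent.build_stent_curve(cfg.profile, cfg.support)
frames = kernels.propagate_frames(wire, np.linspace(0, 1, 1000))
print(f"frame field: {len(frames.stations)} stations, "
      f"orthonormality residual {frames.orthonormality_residual():.2e}")
print(f"beam section: {m.beam_section.width_mm} x {m.beam_section.height_mm} mm "
      f"(A = {m.beam_section.area_mm2:.4f} mm^2) along v2/v3")

# --- Lee-Sacks tissue energy ----------------------------------------------
for label, p in (("leaflet", m.leaflet), ("skirt", m.skirt)):
    psi = kernels.lee_sacks_energy(3.1, 1.0, p)
    d1, d4 = kernels.lee_sacks_derivatives(3.1, 1.0, p)
    print(f"{label}: psi(I1=3.1, I4=1) = {psi:.3f} kPa, "
          f"dpsi/dI1 = {d1:.1f}, dpsi/dI4 = {d4:.1f}")
# The skirt model is isotropic (w = 1), so its I4 derivative is identically
# zero; the leaflet model keeps a small transversely isotropic fraction.

# --- penalty coupling parameters ------------------------------------------
E_sh = kernels.effective_shell_stiffness(m.leaflet.c0, nu=0.5)
print(f"effective shell stiffness E_sh = 3 c0 = {E_sh:.4f} kPa")
h = 0.5  # representative local element length, mm
a_d, a_r = kernels.penalty_ss(E_sh, m.shell_thickness_mm, h, 0.5, m.penalties.alpha_ss)
print(f"shell-shell penalties: alpha_d = {a_d:.4g}, alpha_r = {a_r:.4g} "
      f"(ratio H^2/12 = {m.shell_thickness_mm**2 / 12:.6f})")
a_sb, branch = kernels.penalty_sb(
    E_sh, m.shell_thickness_mm, h, 0.5,
    m.frame.E_kPa, m.beam_section.area_mm2, h, m.frame.nu,
    m.penalties.alpha_sb,
)
print(f"shell-beam penalty: alpha_d = {a_sb:.4g} ({branch} branch governs)")
# The min{} rule selects the softer (tissue) scale: stiff enough to tie the
# skirt to the frame without ill-conditioning the tissue equations.

# --- contact kernel --------------------------------------------------------
for r in (0.2, 0.5, 1.0, 2.0):
    print(f"contact kernel at r = {r} mm: "
          f"{kernels.contact_kernel(r, k_c=2.0, r_max_mm=1.0):+.2f}")
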