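"""Pointwise structural kernels for the valve model.

These are the evaluable pieces of the structural formulation: local beam
cross-section frames along the stent wires, minimal-rotation frame
propagation, the Lee-Sacks hyperelastic energy density for pericardial
tissue, the penalty-coupling parameter formulas for shell-shell and
shell-beam interfaces, and the nonlocal contact / static-friction kernels.
Everything here is a pure function of its inputs with explicit unit
contracts (mm, kPa, degrees at the interface); quadrature and assembly
belong to a downstream solver, not to this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nurbs import NurbsCurve

__all__ = [
    "FrameField",
    "phi_hat",
    "section_frame",
    "mapping_operator",
    "rotation_about",
    "propagate_frames",
    "lee_sacks_energy",
    "lee_sacks_derivatives",
    "effective_shell_stiffness",
    "penalty_ss",
    "penalty_sb",
    "contact_kernel",
    "friction_force",
    "DegenerateFrameError",
]


class DegenerateFrameError(ValueError):
    """Tangent parallel to the azimuthal direction: section frame undefined."""


def phi_hat(phi_c_deg: float) -> np.ndarray:
    """Unit azimuthal direction (-sin phi, cos phi, 0) at azimuth ``phi_c_deg``."""
    a = np.radians(phi_c_deg)
    return np.array([-np.sin(a), np.cos(a), 0.0])


def section_frame(curve: NurbsCurve, u: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beam cross-section triad at parameter ``u``.

    v1 is the unit tangent; v2 = v1 x phi_hat (normalized), with phi_hat
    evaluated at the point's own azimuth; v3 = v1 x v2. The rectangular wire
    section extends along v2 (width) and v3 (thickness).
    """
    tangent = curve.derivative(u)
    nt = np.linalg.norm(tangent)
    if nt == 0:
        raise DegenerateFrameError("zero tangent")
    v1 = tangent / nt
    pt = curve.evaluate(u)
    phi = np.degrees(np.arctan2(pt[1], pt[0]))
    ph = phi_hat(phi)
    v2 = np.cross(v1, ph)
    n2 = np.linalg.norm(v2)
    if n2 < 1e-10:
        raise DegenerateFrameError(
            f"tangent parallel to azimuthal direction at u={u}"
        )
    v2 = v2 / n2
    v3 = np.cross(v1, v2)
    return v1, v2, v3 / np.linalg.norm(v3)


def mapping_operator(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto unit vector ``b``.

    Euler-Rodrigues form about the axis a x b; undefined for antiparallel
    inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:
        raise ValueError("rotation undefined for antiparallel vectors")
    v = np.cross(a, b)
    K = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
    )
    return np.eye(3) + K + K @ K / (1.0 + c)


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation by ``angle_deg`` about the unit vector ``axis`` (Rodrigues)."""
    t = np.radians(angle_deg)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


@dataclass(frozen=True)
class FrameField:
    """Orthonormal section triads at a set of stations along a wire."""

    stations: np.ndarray
    v1: np.ndarray  # (n, 3) unit tangents
    v2: np.ndarray
    v3: np.ndarray
    theta_deg: np.ndarray

    def orthonormality_residual(self) -> float:
        res = 0.0
        for a, b in ((self.v1, self.v2), (self.v1, self.v3), (self.v2, self.v3)):
            res = max(res, float(np.abs(np.sum(a * b, axis=1)).max()))
        for a in (self.v1, self.v2, self.v3):
            res = max(res, float(np.abs(np.linalg.norm(a, axis=1) - 1).max()))
        return res


def propagate_frames(
    curve: NurbsCurve,
    stations: np.ndarray,
    theta0_deg: float = 0.0,
    reference_triad: np.ndarray | None = None,
) -> FrameField:
    """Twist-free section triads by sequential minimal rotation.

    The first triad is seeded by mapping the global reference direction A1
    onto the first tangent; each subsequent triad is the previous one mapped
    through the minimal rotation between consecutive tangents, then rotated
    by the per-station angle ``theta0_deg`` about the local tangent. This
    avoids spurious twist where the centerline tangent turns sharply.
    """
    stations = np.asarray(stations, dtype=float)
    if stations.size < 1:
        raise ValueError("at least one station required")
    if reference_triad is None:
        reference_triad = np.eye(3)[[2, 0, 1]]  # A1 = z, A2 = x, A3 = y
    A1, A2, A3 = reference_triad

    tangents = np.atleast_2d(curve.derivative(stations))
    norms = np.linalg.norm(tangents, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero tangent along the centerline")
    t_hat = tangents / norms[:, None]

    v2 = np.empty_like(t_hat)
    v3 = np.empty_like(t_hat)
    lam = mapping_operator(A1, t_hat[0])
    a2, a3 = lam @ A2, lam @ A3
    for i in range(len(stations)):
        if i > 0:
            if np.dot(t_hat[i - 1], t_hat[i]) < -1 + 1e-12:
                raise ValueError(
                    f"antiparallel consecutive tangents at station {i}"
                )
            lam = mapping_operator(t_hat[i - 1], t_hat[i])
            a2, a3 = lam @ a2, lam @ a3
        if theta0_deg != 0.0:
            R = rotation_about(t_hat[i], theta0_deg)
            v2[i], v3[i] = R @ a2, R @ a3
        else:
            v2[i], v3[i] = a2, a3
    return FrameField(
        stations, t_hat, v2, v3, np.full(len(stations), float(theta0_deg))
    )


# ---------------------------------------------------------------------------
# Lee-Sacks constitutive model


def lee_sacks_energy(
    I1: float,
    I4: float,
    params,
    cap_I1: float = 12.0,
    cap_I4: float = 4.0,
) -> float:
    """Lee-Sacks elastic energy density in kPa.

    psi = c0/2 (I1 - 3) + c1/2 (w exp(c2 (I1-3)^2) + (1-w) exp(c3 (I4-1)^2) - 1)

    The exponential terms are evaluated with the invariants capped at
    ``cap_I1`` / ``cap_I4`` (a warning is emitted when a cap engages), the
    pointwise analogue of the hybrid bound used to keep the model stable at
    extreme stretches.
    """
    I1c, I4c = I1, I4
    if I1 > cap_I1 or I4 > cap_I4:
        warnings.warn(
            f"invariants (I1={I1:g}, I4={I4:g}) exceed caps "
            f"({cap_I1:g}, {cap_I4:g}); exponential terms are capped",
            stacklevel=2,
        )
        I1c, I4c = min(I1, cap_I1), min(I4, cap_I4)
    iso = params.c0 / 2.0 * (I1 - 3.0)
    expo = params.c1 / 2.0 * (
        params.w * np.exp(params.c2 * (I1c - 3.0) ** 2)
        + (1.0 - params.w) * np.exp(params.c3 * (I4c - 1.0) ** 2)
        - 1.0
    )
    return float(iso + expo)


def lee_sacks_derivatives(I1: float, I4: float, params) -> tuple[float, float]:
    """Analytic (d psi / d I1, d psi / d I4) in kPa."""
    dI1 = params.c0 / 2.0 + params.c1 * params.w * params.c2 * (I1 - 3.0) * np.exp(
        params.c2 * (I1 - 3.0) ** 2
    )
    dI4 = params.c1 * (1.0 - params.w) * params.c3 * (I4 - 1.0) * np.exp(
        params.c3 * (I4 - 1.0) ** 2
    )
    return float(dI1), float(dI4)


def effective_shell_stiffness(c0_kPa: float, nu: float = 0.5) -> float:
    """Effective Young's modulus from the neo-Hookean shear modulus c0.

    E = 2 c0 (1 + nu); with the incompressible choice nu = 0.5 this is 3 c0.
    """
    if c0_kPa <= 0:
        raise ValueError("c0 must be positive")
    return 2.0 * c0_kPa * (1.0 + nu)


# ---------------------------------------------------------------------------
# penalty coupling


def penalty_ss(
    E_kPa: float, H_mm: float, h_I_mm: float, nu: float, alpha: float
) -> tuple[float, float]:
    """Shell-shell displacement and rotation penalties (alpha_d, alpha_r).

    alpha_d = alpha E H / (h_I (1 - nu^2)); alpha_r = alpha_d H^2 / 12.
    """
    if abs(nu) >= 1:
        raise ZeroDivisionError("nu = +/-1 makes the penalty singular")
    alpha_d = alpha * E_kPa * H_mm / (h_I_mm * (1.0 - nu**2))
    alpha_r = alpha_d * H_mm**2 / 12.0
    return alpha_d, alpha_r


def penalty_sb(
    E_sh_kPa: float,
    H_mm: float,
    h_sh_mm: float,
    nu_sh: float,
    E_be_kPa: float,
    A_mm2: float,
    h_be_mm: float,
    nu_be: float,
    alpha: float,
) -> tuple[float, str]:
    """Shell-beam displacement penalty: alpha * min(shell branch, beam branch).

    Returns the value and which branch ("shell" or "beam") was the minimum;
    taking the softer material's scale keeps the constraint stiff without
    ill-conditioning the stiffer one.
    """
    shell = E_sh_kPa * H_mm / (h_sh_mm * (1.0 - nu_sh**2))
    beam = E_be_kPa * np.sqrt(A_mm2) / (h_be_mm * (1.0 - nu_be**2))
    if shell <= beam:
        return alpha * shell, "shell"
    return alpha * beam, "beam"


# ---------------------------------------------------------------------------
# contact and friction


def contact_kernel(r_mm: float, k_c: float, r_max_mm: float) -> float:
    """Linear nonlocal contact kernel: -max(k_c (r_max - r), 0); never positive."""
    if r_mm < 0:
        raise ValueError("separation must be non-negative")
    return -max(k_c * (r_max_mm - r_mm), 0.0)


def friction_force(
    x_be: np.ndarray,
    x_so: np.ndarray,
    x_be_d: np.ndarray,
    x_so_d: np.ndarray,
    n: np.ndarray,
    n_d: np.ndarray,
    alpha_f: float,
    k_c: float,
    r_max_mm: float,
) -> np.ndarray:
    """Pointwise static-friction force density between frame and wall.

    With r = x_be - x_so and its deployed-state counterpart r_d, the force is
    alpha_f |phi'_c(|r|)| (|(r)_tau| - |(r_d)_tau|) (r)_tau / |(r)_tau|,
    where (.)_tau removes the wall-normal component. It resists tangential
    slip accumulated since deployment, vanishes outside the contact cutoff,
    and is zero (by convention) when the tangential separation vanishes.
    """
    x_be, x_so, x_be_d, x_so_d, n, n_d = (
        np.asarray(v, dtype=float) for v in (x_be, x_so, x_be_d, x_so_d, n, n_d)
    )
    r = x_be - x_so
    rn = float(np.linalg.norm(r))
    if rn >= r_max_mm:
        return np.zeros(3)
    r_d = x_be_d - x_so_d
    r_tau = r - np.dot(r, n) * n
    rd_tau = r_d - np.dot(r_d, n_d) * n_d
    nt = float(np.linalg.norm(r_tau))
    if nt < 1e-14:
        warnings.warn("zero tangential separation: friction force taken as zero")
        return np.zeros(3)
    mag = alpha_f * abs(contact_kernel(rn, k_c, r_max_mm)) * (
        nt - float(np.linalg.norm(rd_tau))
    )
    return mag * r_tau / nt
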