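"""Stent wireframe construction.

The frame is a lattice of identical cubic NURBS wires. One wire is built
from the profile table: the baseline points (where two wires cross in the
finished frame) interleaved with tangency support points, strung bottom to
top as the control polygon of a single clamped cubic curve. The wire is
mirrored across the vertical plane at phi_c = 0 and the pair is rotated
about the valve axis in increments of twice the maximum phi_c to tile the
circumference. Control points that coincide across wires are collected into
a constraint map: in the downstream beam model each such group moves as one
point, which clamps the wires together and carries moment through the
junction; the three collinear control points per interior junction preserve
tangent continuity there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import StentProfile, SupportSpec, support_position
from .nurbs import KnotVector, NurbsCurve, open_uniform_knots, reflect, rotate_z

__all__ = [
    "SupportPoint",
    "ConstraintGroup",
    "ConstraintMap",
    "baseline_points",
    "support_points",
    "build_stent_curve",
    "mirror_curve",
    "pattern_curves",
    "crossing_constraints",
    "TilingError",
    "ConstraintError",
]


class TilingError(ValueError):
    """The rotation increment does not tile the full circumference."""


class ConstraintError(ValueError):
    """An expected wire crossing is missing from the patterned curve set."""


@dataclass(frozen=True)
class SupportPoint:
    anchor_index: int  # 0-based baseline index
    side: str  # "above" | "below"
    position: np.ndarray


@dataclass(frozen=True)
class ConstraintGroup:
    location: np.ndarray
    members: tuple[tuple[int, int], ...]  # (curve id, control-point index)
    collinearity_residual: float  # mm; 0 for exact axial triples


@dataclass(frozen=True)
class ConstraintMap:
    groups: tuple[ConstraintGroup, ...]

    def max_collinearity_residual(self) -> float:
        interior = [g.collinearity_residual for g in self.groups if len(g.members) >= 6]
        return max(interior, default=0.0)


def baseline_points(profile: StentProfile) -> np.ndarray:
    """Cartesian conversion of the profile table, bottom to top."""
    return np.array([p.cartesian() for p in profile.points])


def support_points(profile: StentProfile, spec: SupportSpec) -> list[SupportPoint]:
    """Tangency supports: one per end baseline point, two per interior point."""
    if profile.n_points < 2:
        raise ValueError("profile needs at least two baseline points")
    out: list[SupportPoint] = []
    last = profile.n_points - 1
    for i in range(profile.n_points):
        sides = ["above"] if i == 0 else ["below"] if i == last else ["below", "above"]
        for side in sides:
            out.append(
                SupportPoint(i, side, support_position(profile, spec, i, side))
            )
    return out


def build_stent_curve(profile: StentProfile, spec: SupportSpec) -> NurbsCurve:
    """Single clamped cubic wire: P1, S1+, S2-, P2, S2+, ..., Sn-, Pn."""
    base = baseline_points(profile)
    sup = {(s.anchor_index, s.side): s.position for s in support_points(profile, spec)}
    poly = [base[0], sup[(0, "above")]]
    last = profile.n_points - 1
    for i in range(1, last):
        poly.extend([sup[(i, "below")], base[i], sup[(i, "above")]])
    poly.extend([sup[(last, "below")], base[last]])
    ctrl = np.asarray(poly)
    return NurbsCurve(ctrl, open_uniform_knots(len(ctrl), 3))


def mirror_curve(curve: NurbsCurve) -> NurbsCurve:
    """Second wire of the pair: mirror image across the phi_c = 0 plane."""
    return reflect(curve, 0.0)


def pattern_curves(pair: tuple[NurbsCurve, NurbsCurve], phi_max: float) -> list[NurbsCurve]:
    """Rotational tiling of the wire pair in increments of 2 * phi_max degrees."""
    incr = 2.0 * phi_max
    n = 360.0 / incr
    if abs(n - round(n)) > 1e-9:
        raise TilingError(
            f"increment {incr} degrees does not divide 360 evenly"
        )
    n = int(round(n))
    out = []
    for k in range(n):
        for c in pair:
            out.append(rotate_z(c, incr * k))
    return out


def crossing_constraints(curves: list[NurbsCurve], tol: float = 1e-6) -> ConstraintMap:
    """Group coincident control points across the patterned wires.

    Coincidence is keyed on coordinates rounded at 1e-7 mm (or ``tol`` when
    coarser), so exact-arithmetic inputs and perturbed ones behave the same.
    Each interior junction must collect exactly two wires with three control
    points each (a baseline point plus its two supports); the collinearity
    residual of each wire's triple is recorded.
    """
    key_res = max(tol, 1e-7)
    buckets: dict[tuple, list[tuple[int, int]]] = {}
    for ci, c in enumerate(curves):
        for pi, p in enumerate(c.control_points):
            key = tuple(np.round(p / key_res).astype(np.int64))
            buckets.setdefault(key, []).append((ci, pi))

    # merge buckets that actually coincide within tol (rounding can split)
    pairs: list[list[tuple[int, int]]] = []
    locs: list[np.ndarray] = []
    for members in buckets.values():
        pt = curves[members[0][0]].control_points[members[0][1]]
        for gi, loc in enumerate(locs):
            if np.linalg.norm(pt - loc) <= tol:
                pairs[gi].extend(members)
                break
        else:
            locs.append(pt)
            pairs.append(list(members))

    # a junction is centred on a coincident *baseline* pair (control index a
    # multiple of 3 in the P,S interleaving); its group collects that pair
    # plus the two adjacent support pairs of each wire
    out = []
    pair_lookup = {m: gi for gi, members in enumerate(pairs) for m in members}
    last_idx = len(curves[0].control_points) - 1
    for loc, members in zip(locs, pairs):
        if len(members) < 2:
            continue
        if any(pi % 3 != 0 for _, pi in members):
            continue  # support pairs are folded into their junction group
        is_end = any(pi in (0, last_idx) for _, pi in members)
        if is_end:
            out.append(ConstraintGroup(loc, tuple(sorted(members)), 0.0))
            continue
        full: list[tuple[int, int]] = []
        resid = 0.0
        for ci, pi in members:
            for q in (pi - 1, pi, pi + 1):
                if (ci, q) not in pair_lookup or len(pairs[pair_lookup[(ci, q)]]) < 2:
                    raise ConstraintError(
                        f"support point (curve {ci}, index {q}) at junction "
                        f"{np.round(loc, 6)} has no coincident partner"
                    )
                full.append((ci, q))
            a, b, c3 = (curves[ci].control_points[q] for q in (pi - 1, pi, pi + 1))
            axis = c3 - a
            nn = np.linalg.norm(axis)
            if nn > 0:
                d = (b - a) - np.dot(b - a, axis) / nn**2 * axis
                resid = max(resid, float(np.linalg.norm(d)))
        out.append(ConstraintGroup(loc, tuple(sorted(full)), resid))

    interior_expected = _expected_interior_crossings(curves)
    found = sum(1 for g in out if len(g.members) >= 6)
    if interior_expected is not None and found < interior_expected:
        raise ConstraintError(
            f"expected {interior_expected} interior crossings, found {found}"
        )
    return ConstraintMap(tuple(sorted(out, key=lambda g: (g.location[2], np.arctan2(g.location[1], g.location[0])))))


def _expected_interior_crossings(curves: list[NurbsCurve]) -> int | None:
    # n wires x (n_interior baseline points) / 2 wires per junction
    if not curves:
        return None
    n_ctrl = len(curves[0].control_points)
    if any(len(c.control_points) != n_ctrl for c in curves):
        return None
    n_base = (n_ctrl + 4) // 3  # inverse of 3*n_base - 4 interleaved points
    n_interior = n_base - 2
    return len(curves) * n_interior // 2
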