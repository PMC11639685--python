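"""Soft-good surfaces: skirt, commissural attachments, and leaflets.

The skirt is a Gordon surface over a one-third (120 degree) bidirectional
network: vertical wire-path curves rotated in azimuthal increments, closed
by interpolated top and bottom rim curves. Each commissural attachment is a
loft of a central curve in the phi_c = 0 plane and its two rotated/mirrored
edges. A leaflet is a Gordon surface over vertical edge curves (commissure
section continued down the frame), the free edge, the bottom attachment
edge, a central interior curve setting the belly, and one or two interior
horizontal curves.

Network compatibility is established in a second pass: after the defining
curves are built and their mutual crossings located, each vertical curve is
re-interpolated through its own points plus the crossing points at
network-averaged parameter stations. The Gordon combination then reproduces
every network curve exactly (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import nurbs
from .config import ValveConfig, resolve_recipe
from .nurbs import (
    CurveNetwork,
    NurbsCurve,
    NurbsSurface,
    arc_through_points,
    curve_length,
    gordon_surface,
    interpolate_curve,
    reflect,
    rotate_z,
    translate,
)

__all__ = [
    "SkirtSet",
    "CommissureSet",
    "LeafletCurves",
    "skirt_vertical_curves",
    "skirt_rotate_set",
    "skirt_horizontal_curves",
    "build_skirt",
    "commissure_build",
    "leaflet_upper_edge",
    "leaflet_vertical_edges",
    "free_edge",
    "attachment_edge",
    "central_interior_curve",
    "interior_horizontal_curves",
    "build_leaflet",
    "RecipeError",
]

_PHI60 = np.array([np.cos(np.radians(60.0)), np.sin(np.radians(60.0)), 0.0])


class RecipeError(ValueError):
    """A curve recipe is missing or cannot be resolved."""


# ---------------------------------------------------------------------------
# shared helpers


def _chord_params(points: np.ndarray) -> np.ndarray:
    return nurbs._chord_params(np.asarray(points, dtype=float))


def _param_at_arclength(curve: NurbsCurve, s: float) -> float:
    """Parameter at arc length ``s`` measured from the start of the curve."""
    total = curve_length(curve)
    if not 0 <= s <= total:
        raise ValueError(f"arc length {s:g} outside [0, {total:g}]")
    from scipy import integrate

    def arclen(t):
        if t <= 0:
            return 0.0
        val, _ = integrate.quad(
            lambda u: float(np.linalg.norm(curve.derivative(u))), 0.0, t, limit=100
        )
        return val

    return brentq(lambda t: arclen(t) - s, 0.0, 1.0, xtol=1e-12)


def _param_at_z(curve: NurbsCurve, z: float) -> float:
    """First parameter at which the curve reaches height ``z``."""
    ts = np.linspace(*curve.domain, 257)
    zs = curve.evaluate(ts)[:, 2] - z
    sign = np.sign(zs)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        hit = np.argmin(np.abs(zs))
        if abs(zs[hit]) < 1e-9:
            return float(ts[hit])
        raise ValueError(f"curve does not reach z = {z:g} mm")
    i = idx[0]
    return brentq(lambda t: float(curve.evaluate(t)[2] - z), ts[i], ts[i + 1], xtol=1e-13)


def _rebuild_with_crossings(
    points: np.ndarray,
    crossings: list[tuple[np.ndarray, float, float]],
) -> NurbsCurve:
    """Re-interpolate a curve through its points plus crossing points.

    ``crossings`` holds (point, parameter_on_this_curve, common_parameter)
    tuples; the original points are re-parameterized by the piecewise-linear
    map pinning each crossing at its common network station.
    """
    base_params = _chord_params(points)
    anchors_old = [0.0]
    anchors_new = [0.0]
    extra_pts, extra_old = [], []
    for pt, t_host, t_common in sorted(crossings, key=lambda c: c[1]):
        if t_host < 1e-9 or t_host > 1 - 1e-9:
            continue  # endpoint crossings are already interpolation points
        anchors_old.append(t_host)
        anchors_new.append(t_common)
        if np.linalg.norm(points - pt, axis=1).min() > 1e-9:
            extra_pts.append(pt)
            extra_old.append(t_host)
    anchors_old.append(1.0)
    anchors_new.append(1.0)
    all_pts = list(points)
    all_old = list(base_params)
    for pt, t in zip(extra_pts, extra_old):
        k = int(np.searchsorted(all_old, t))
        all_pts.insert(k, pt)
        all_old.insert(k, t)
    params_new = np.interp(all_old, anchors_old, anchors_new)
    return interpolate_curve(np.asarray(all_pts), params=params_new)


def _network_from_stations(
    u_curves: list[NurbsCurve],
    v_curves: list[NurbsCurve],
    u_stations: np.ndarray,
    v_stations: np.ndarray,
    tol: float = 1e-6,
) -> CurveNetwork:
    """Assemble a network whose crossing parameters are known by construction."""
    u_st = np.asarray(u_stations, dtype=float)
    v_st = np.asarray(v_stations, dtype=float)
    grid = np.empty((len(v_curves), len(u_curves), 3))
    worst = 0.0
    for i, vc in enumerate(v_curves):
        pv = vc.evaluate(v_st)
        for j, uc in enumerate(u_curves):
            pu = uc.evaluate(u_st[i])
            worst = max(worst, float(np.linalg.norm(pu - pv[j])))
            grid[i, j] = (pu + pv[j]) / 2.0
    if worst > tol:
        raise nurbs.NetworkError(
            f"network crossings disagree by {worst:.3e} mm (> {tol:g} mm)"
        )
    return CurveNetwork(
        [c.normalized() for c in u_curves],
        [c.normalized() for c in v_curves],
        u_st,
        v_st,
        grid,
        worst,
    )


# ---------------------------------------------------------------------------
# skirt


@dataclass(frozen=True)
class SkirtSet:
    verticals: list[NurbsCurve]
    bottom: NurbsCurve
    top: NurbsCurve
    network: CurveNetwork
    surface: NurbsSurface


def skirt_vertical_curves(cfg: ValveConfig) -> tuple[NurbsCurve, NurbsCurve]:
    """The two baseline vertical skirt curves (recipe curve and its mirror)."""
    recipe = cfg.skirt.get("vertical")
    if not recipe:
        raise RecipeError("skirt.vertical recipe missing or empty")
    pts = resolve_recipe(recipe, cfg.profile, cfg.support)
    a = interpolate_curve(pts)
    return a, reflect(a, 0.0)


def skirt_rotate_set(
    pair: tuple[NurbsCurve, NurbsCurve], phi_max: float, span_degrees: float = 120.0
) -> list[NurbsCurve]:
    """Non-crossing vertical family: the first curve of the pair rotated in
    increments of phi_max across the one-third span (endpoints inclusive)."""
    n = int(round(span_degrees / phi_max))
    if abs(n * phi_max - span_degrees) > 1e-9:
        raise ValueError("phi_max increments do not tile the skirt span")
    return [rotate_z(pair[0], phi_max * k) for k in range(n + 1)]


def skirt_horizontal_curves(
    cfg: ValveConfig, verticals: list[NurbsCurve] | None = None
) -> tuple[NurbsCurve, NurbsCurve]:
    """Top and bottom rim curves through the vertical-family endpoints."""
    if verticals is None:
        verticals = skirt_rotate_set(
            skirt_vertical_curves(cfg),
            cfg.profile.phi_max,
            float(cfg.skirt.get("span_degrees", 120.0)),
        )
    bottom_pts = np.array([v.evaluate(v.domain[0]) for v in verticals])
    top_pts = np.array([v.evaluate(v.domain[1]) for v in verticals])
    # common azimuthal parameterization keeps the rim curves network-compatible
    u_common = (_chord_params(bottom_pts) + _chord_params(top_pts)) / 2.0
    bottom = interpolate_curve(bottom_pts, params=u_common)
    top = interpolate_curve(top_pts, params=u_common)
    return top, bottom


def build_skirt(cfg: ValveConfig, tol: float = 1e-6) -> SkirtSet:
    """One-third skirt as a Gordon surface over verticals and rim curves."""
    pair = skirt_vertical_curves(cfg)
    span = float(cfg.skirt.get("span_degrees", 120.0))
    verticals = skirt_rotate_set(pair, cfg.profile.phi_max, span)
    top, bottom = skirt_horizontal_curves(cfg, verticals)

    # trim verticals between the rim curves where they extend past them
    trimmed = []
    for v in verticals:
        lo_u, lo_v, *_ = nurbs.intersect_curves(bottom, v, tol=tol)
        hi_u, hi_v, *_ = nurbs.intersect_curves(top, v, tol=tol)
        if lo_v > 1e-9 or hi_v < 1 - 1e-9:
            piece = v
            if hi_v < 1 - 1e-9:
                piece, _ = nurbs.split_curve(piece, hi_v)
            if lo_v > 1e-9:
                _, piece = nurbs.split_curve(piece, lo_v / hi_v if hi_v < 1 else lo_v)
            trimmed.append(piece.normalized())
        else:
            trimmed.append(v)
    bottom_pts = np.array([v.evaluate(0.0) for v in trimmed])
    u_common = (_chord_params(bottom_pts) + _chord_params(
        np.array([v.evaluate(1.0) for v in trimmed])
    )) / 2.0
    net = _network_from_stations(
        [bottom, top], trimmed, u_common, np.array([0.0, 1.0]), tol=tol
    )
    surface = gordon_surface(net, tol=tol)
    return SkirtSet(trimmed, bottom, top, net, surface)


# ---------------------------------------------------------------------------
# commissural attachments


@dataclass(frozen=True)
class CommissureSet:
    central_curve: NurbsCurve
    edge_minus: NurbsCurve
    edge_plus: NurbsCurve
    surface: NurbsSurface
    edge_rotation_deg: float


def commissure_build(cfg: ValveConfig, stent_curve: NurbsCurve | None = None) -> CommissureSet:
    """Commissural attachment: central curve at phi = 0, edges at +/- phi_max/6."""
    recipe = cfg.commissure.get("central")
    if not recipe:
        raise RecipeError("commissure.central recipe missing")
    pts = resolve_recipe(recipe, cfg.profile, cfg.support)
    central = interpolate_curve(pts)
    source = cfg.commissure.get("edge_source", "central_curve")
    angle = cfg.profile.phi_max / 6.0
    if source == "central_curve":
        base = central
    elif source == "stent_segment":
        if stent_curve is None:
            raise RecipeError("edge_source 'stent_segment' needs the stent curve")
        base = _stent_segment(stent_curve, pts[0], pts[-1])
    else:
        raise RecipeError(f"unknown edge source {source!r}")
    edge_plus = rotate_z(base, angle)
    edge_minus = reflect(edge_plus, 0.0)
    surface = nurbs.loft(
        [edge_minus, central, edge_plus], v_params=np.array([0.0, 0.5, 1.0])
    )
    return CommissureSet(central, edge_minus, edge_plus, surface, angle)


def _stent_segment(curve: NurbsCurve, p_lo: np.ndarray, p_hi: np.ndarray) -> NurbsCurve:
    ts = np.linspace(*curve.domain, 2049)
    pts = curve.evaluate(ts)
    t_lo = ts[np.argmin(np.linalg.norm(pts - p_lo, axis=1))]
    t_hi = ts[np.argmin(np.linalg.norm(pts - p_hi, axis=1))]
    lo, hi = sorted((t_lo, t_hi))
    _, rest = nurbs.split_curve(curve, lo)
    seg, _ = nurbs.split_curve(rest, (hi - lo) / (curve.domain[1] - lo))
    return seg


# ---------------------------------------------------------------------------
# leaflet


@dataclass(frozen=True)
class LeafletCurves:
    vertical_left: NurbsCurve
    vertical_right: NurbsCurve
    free_edge: NurbsCurve
    attachment_edge: NurbsCurve
    central_interior: NurbsCurve
    interior_horizontals: list[NurbsCurve]


def leaflet_upper_edge(
    commissure: CommissureSet,
    t_mm: float,
    split_fractions: tuple[float, float] | None = None,
) -> NurbsCurve:
    """Commissure central curve translated off the phi = 0 plane by ``t_mm``.

    The translation direction is the unit normal of the phi = 0 vertical
    plane (+y, toward the leaflet interior). ``split_fractions`` optionally
    extracts a parameter subrange of the central curve first.
    """
    if t_mm < 0:
        raise ValueError("translation must be non-negative")
    curve = commissure.central_curve
    if split_fractions is not None:
        a, b = split_fractions
        if not (0 <= a < b <= 1):
            raise ValueError("split fractions must satisfy 0 <= a < b <= 1")
        if a > 0:
            _, curve = nurbs.split_curve(curve, a)
            curve = curve.normalized()
            b = (b - a) / (1 - a)
        if b < 1:
            curve, _ = nurbs.split_curve(curve, b)
    return translate(curve, [0.0, t_mm, 0.0])


def leaflet_vertical_edges(
    upper_points: np.ndarray, lower_points: np.ndarray, tol: float = 1e-6
) -> tuple[NurbsCurve, NurbsCurve]:
    """Left edge through the upper (commissure) and lower point runs; right
    edge is its mirror across phi = 60. Points are ordered top to bottom and
    must meet at a shared junction point."""
    if len(lower_points) < 2:
        raise ValueError("lower edge needs at least two points")
    gap = float(np.linalg.norm(upper_points[-1] - lower_points[0]))
    if gap > tol:
        raise ValueError(
            f"vertical edge sections do not share an endpoint (gap {gap:.3e} mm)"
        )
    pts = np.vstack([upper_points, lower_points[1:]])
    left = interpolate_curve(pts)
    return left, reflect(left, 60.0)


def free_edge(
    cfg: ValveConfig,
    corner_top: np.ndarray,
    upper_edge_bottom_z: float,
    commissure_top_z: float,
) -> tuple[NurbsCurve, np.ndarray, np.ndarray]:
    """Upper (free) edge of the leaflet; returns (curve, points, center point).

    Side points are sampled on the line from the leaflet corner toward a
    point near the valve axis whose height follows the configured style:
    level with the corners for a flat free edge, at the bottom of the
    commissure section for a center-low design. The central point offsets an
    on-axis point radially along the phi = 60 plane and then vertically.
    """
    style = cfg.leaflet.get("free_edge", {})
    fractions = list(style.get("side_fractions", [0.25, 0.5]))
    if not fractions:
        raise RecipeError("free_edge.side_fractions must not be empty")
    mode = style.get("mode", "center_flat")
    axis_z = upper_edge_bottom_z if mode == "center_low" else corner_top[2]
    axis_z += float(style.get("axis_vertical_offset_mm", 0.0))
    axis_pt = np.array([0.0, 0.0, axis_z])
    side = [corner_top + f * (axis_pt - corner_top) for f in fractions]
    center = (
        np.array([0.0, 0.0, commissure_top_z])
        + float(style.get("center_radial_offset_mm", 0.0)) * _PHI60
        + np.array([0.0, 0.0, float(style.get("center_vertical_offset_mm", 0.0))])
    )
    left_run = [corner_top, *side]
    right_run = [reflect(p, 60.0) for p in reversed(left_run)]
    pts = np.array([*left_run, center, *right_run])
    return interpolate_curve(pts), pts, center


def attachment_edge(cfg: ValveConfig) -> tuple[NurbsCurve, np.ndarray]:
    """Bottom leaflet attachment curve, mirrored across phi = 60."""
    import warnings

    recipe = cfg.leaflet.get("attachment")
    if not recipe or len(recipe) < 2:
        raise RecipeError("leaflet.attachment recipe needs at least two points")
    half = resolve_recipe(recipe, cfg.profile, cfg.support)
    center = half[-1]
    off_plane = abs(float(np.dot(center[:2], [-_PHI60[1], _PHI60[0]])))
    if off_plane > 1e-9:
        warnings.warn(
            f"attachment center point is {off_plane:.2e} mm off the phi=60 plane"
        )
    mirrored = np.array([reflect(p, 60.0) for p in half[-2::-1]])
    pts = np.vstack([half, mirrored])
    return interpolate_curve(pts), pts


def central_interior_curve(
    cfg: ValveConfig,
    free_center: np.ndarray,
    attach_center: np.ndarray,
    commissure_top_z: float,
) -> tuple[NurbsCurve, np.ndarray, float]:
    """Vertical interior curve through the belly; returns (curve, belly, belly param)."""
    belly_cfg = cfg.leaflet.get("belly")
    if not belly_cfg:
        raise RecipeError("leaflet.belly offsets missing")
    belly = (
        np.array([0.0, 0.0, commissure_top_z])
        + float(belly_cfg["radial_offset_mm"]) * _PHI60
        + np.array([0.0, 0.0, float(belly_cfg["vertical_offset_mm"])])
    )
    pts = np.array([free_center, belly, attach_center])
    params = _chord_params(pts)
    quad = interpolate_curve(pts, degree=2, params=params)
    return nurbs._elevate_curve_to(quad, 3), belly, float(params[1])


def interior_horizontal_curves(
    cfg: ValveConfig,
    left: NurbsCurve,
    central: NurbsCurve,
    free_pts: np.ndarray,
    upper_edge_length: float,
    belly: np.ndarray,
    belly_param: float,
) -> list[tuple[NurbsCurve, float, float]]:
    """Interior horizontal curve(s): [(curve, station_on_edges, station_on_central)].

    The upper interior curve offsets the free-edge corner and center points
    down their host curves by ``interior_factor`` times the upper vertical
    edge length, and drops the free-edge side points by ``side_drop_factor``
    times the same length. For a center-low design with ``use_arc`` a second,
    circular interior curve passes through the belly point and the two edge
    points at the belly height.
    """
    factor = float(cfg.leaflet.get("interior_factor", 0.6))
    drop = float(cfg.leaflet.get("side_drop_factor", 0.6))
    if factor <= 0:
        raise RecipeError("interior_factor must be positive")
    s = factor * upper_edge_length
    t_edge = _param_at_arclength(left, s)
    t_cen = _param_at_arclength(central, s)
    p_edge = left.evaluate(t_edge)
    p_cen = central.evaluate(t_cen)
    dz = np.array([0.0, 0.0, -drop * upper_edge_length])
    n_side = (len(free_pts) - 1) // 2 - 1  # side points per half
    drops_left = [free_pts[1 + i] + dz for i in range(n_side)]
    left_run = [p_edge, *drops_left]
    right_run = [reflect(p, 60.0) for p in reversed(left_run)]
    pts = np.array([*left_run, p_cen, *right_run])
    upper = interpolate_curve(pts)
    out = [(upper, t_edge, t_cen)]

    if cfg.leaflet.get("use_arc", False):
        z_arc = belly[2]
        t_arc_edge = _param_at_z(left, z_arc)
        p_arc_edge = left.evaluate(t_arc_edge)
        p_arc_right = reflect(p_arc_edge, 60.0)
        exact = arc_through_points(p_arc_edge, belly, p_arc_right)
        # cubic interpolant through samples of the exact arc keeps the
        # network polynomial; the arc itself is available to callers
        samples = exact.evaluate(np.linspace(0, 1, 7))
        arc_cubic = interpolate_curve(samples, params=np.linspace(0, 1, 7))
        out.append((arc_cubic, t_arc_edge, belly_param))
    return out


def build_leaflet(
    cfg: ValveConfig, commissure: CommissureSet | None = None, tol: float = 1e-6
) -> tuple[NurbsSurface, LeafletCurves]:
    """One leaflet as a Gordon surface over its curve network."""
    if not cfg.leaflet:
        raise RecipeError("no leaflet section in the configuration")
    if commissure is None:
        commissure = commissure_build(cfg)
    t_mm = float(cfg.leaflet.get("translation_mm", 0.0))
    upper = leaflet_upper_edge(commissure, t_mm)
    # defining points of the upper run, top to bottom
    upper_pts = np.array(
        [
            p + np.array([0.0, t_mm, 0.0])
            for p in resolve_recipe(
                cfg.commissure["central"], cfg.profile, cfg.support
            )[::-1]
        ]
    )
    lower_recipe = cfg.leaflet.get("lower_edge")
    if not lower_recipe:
        raise RecipeError("leaflet.lower_edge recipe missing")
    lower_pts = np.vstack(
        [upper_pts[-1:], resolve_recipe(lower_recipe, cfg.profile, cfg.support)]
    )
    left, right = leaflet_vertical_edges(upper_pts, lower_pts)

    corner_top = upper_pts[0]
    fe_curve, fe_pts, fe_center = free_edge(
        cfg, corner_top, upper_pts[-1][2], corner_top[2]
    )
    at_curve, at_pts = attachment_edge(cfg)
    gap = np.linalg.norm(at_pts[0] - left.evaluate(1.0))
    if gap > tol:
        raise nurbs.NetworkError(
            f"attachment edge does not meet the vertical edge (gap {gap:.3e} mm)"
        )
    central, belly, belly_param = central_interior_curve(
        cfg, fe_center, at_pts[len(at_pts) // 2], corner_top[2]
    )
    L_up = curve_length(upper)
    interiors = interior_horizontal_curves(
        cfg, left, central, fe_pts, L_up, belly, belly_param
    )

    # --- compatibility pass: common v-stations on the three vertical curves
    v_interior = [
        ((t_e + t_c) / 2.0) for (_, t_e, t_c) in interiors
    ]
    order = np.argsort(v_interior)
    interiors = [interiors[k] for k in order]
    v_interior = [v_interior[k] for k in order]
    v_stations = np.array([0.0, *v_interior, 1.0])

    left_pts_all = np.vstack([upper_pts, lower_pts[1:]])
    left2 = _rebuild_with_crossings(
        left_pts_all,
        [(c.evaluate(0.0), t_e, v) for (c, t_e, _), v in zip(interiors, v_interior)],
    )
    right2 = reflect(left2, 60.0)
    central_pts = np.array([fe_center, belly, at_pts[len(at_pts) // 2]])
    central2 = _rebuild_with_crossings(
        central_pts,
        [
            (c.evaluate(0.5), t_c, v)
            for (c, _, t_c), v in zip(interiors, v_interior)
        ],
    )

    u_stations = np.array([0.0, 0.5, 1.0])
    u_curves = [fe_curve, *[c for c, *_ in interiors], at_curve]
    net = _network_from_stations(
        u_curves, [left2, central2, right2], u_stations, v_stations, tol=tol
    )
    surface = gordon_surface(net, tol=tol)
    curves = LeafletCurves(
        left2, right2, fe_curve, at_curve, central2, [c for c, *_ in interiors]
    )
    return surface, curves
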