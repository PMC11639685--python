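"""Geometric quality control for generated valve assemblies.

Quantifies the symmetries and regularity the construction promises: n-fold
rotational symmetry about the valve axis, mirror symmetry of components
across vertical planes, collinearity of the wire-junction control-point
triples, overall bounding dimensions, and a geometric orifice-area proxy
(the z-plane projection of the region bounded by the three leaflet free
edges). The orifice proxy is a property of the as-built open geometry, not
a hemodynamic opening area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nurbs
from .assembly import ValveAssembly
from .nurbs import NurbsCurve, NurbsSurface, reflect, rotate_z
from .stent import ConstraintMap

__all__ = [
    "QCReport",
    "check_radial_symmetry",
    "check_mirror_symmetry",
    "check_collinearity",
    "bounding_dims",
    "geometric_orifice_area",
    "element_report",
    "soft_good_envelope_radius",
    "run_qc",
]


def _control_point_cloud(obj) -> np.ndarray:
    if isinstance(obj, ValveAssembly):
        clouds = [c.control_points for c in obj.stent_curves]
        clouds += [s.control_points.reshape(-1, 3) for _, s in obj.patches]
        return np.vstack(clouds)
    if isinstance(obj, NurbsSurface):
        return obj.control_points.reshape(-1, 3)
    if isinstance(obj, NurbsCurve):
        return obj.control_points
    if isinstance(obj, np.ndarray):
        return np.atleast_2d(obj)
    raise TypeError(f"no control points on {type(obj).__name__}")


def _cloud_deviation(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric nearest-neighbour Hausdorff-style distance between clouds."""
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab = tb.query(a)[0].max()
    d_ba = ta.query(b)[0].max()
    return float(max(d_ab, d_ba))


def check_radial_symmetry(obj, n_fold: int) -> float:
    """Deviation (mm) of the geometry from n-fold symmetry about the z-axis."""
    if n_fold < 1:
        raise ValueError("n_fold must be at least 1")
    if n_fold == 1:
        return 0.0
    cloud = _control_point_cloud(obj)
    rotated = rotate_z(cloud, 360.0 / n_fold)
    return _cloud_deviation(cloud, rotated)


def check_mirror_symmetry(obj, plane_phi_deg: float) -> float:
    """Deviation (mm) from mirror symmetry across the vertical plane."""
    cloud = _control_point_cloud(obj)
    mirrored = reflect(cloud, plane_phi_deg)
    return _cloud_deviation(cloud, mirrored)


def check_collinearity(cmap: ConstraintMap) -> float:
    """Largest mid-point-to-line residual (mm) over interior junction triples."""
    return cmap.max_collinearity_residual()


def bounding_dims(obj) -> tuple[float, float]:
    """(height, max diameter) in mm.

    For a full assembly the frame sets the device envelope, so the extent is
    taken over the stent-wire control points, which sit exactly at the
    profile-table radii and heights. For a single curve or surface the
    control hull is used (conservative: it contains the geometry).
    """
    if isinstance(obj, ValveAssembly):
        cloud = np.vstack([c.control_points for c in obj.stent_curves])
    else:
        cloud = _control_point_cloud(obj)
    height = float(cloud[:, 2].max() - cloud[:, 2].min())
    diameter = 2.0 * float(np.hypot(cloud[:, 0], cloud[:, 1]).max())
    return height, diameter


def geometric_orifice_area(free_edges: list[NurbsCurve], n_samples: int = 512) -> float:
    """Area (mm^2) of the z-plane projection bounded by the free edges.

    The free edges are sampled densely, ordered into one closed loop around
    the axis, projected to the z-plane, and integrated by the shoelace
    formula (absolute value, so a mildly self-intersecting projection still
    returns a magnitude).
    """
    if len(free_edges) < 1:
        raise ValueError("at least one free edge required")
    loops = []
    for c in free_edges:
        ts = np.linspace(*c.domain, n_samples)
        loops.append(c.evaluate(ts)[:, :2])
    # order segments by their starting azimuth to walk the loop once
    loops.sort(key=lambda xy: np.arctan2(xy[0, 1], xy[0, 0]))
    poly = np.vstack(loops)
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(area))


def element_report(assembly: ValveAssembly) -> dict:
    return assembly.element_report()


def soft_good_envelope_radius(assembly: ValveAssembly, n: int = 60) -> float:
    """Largest cylindrical radius (mm) of the sampled soft-good surfaces."""
    ts = np.linspace(0.0, 1.0, n)
    r = 0.0
    for _, s in assembly.patches:
        g = s.evaluate_grid(ts, ts)
        r = max(r, float(np.hypot(g[..., 0], g[..., 1]).max()))
    return r


@dataclass(frozen=True)
class QCReport:
    radial_symmetry_mm: float
    mirror_symmetry_mm: float
    collinearity_mm: float
    height_mm: float
    diameter_mm: float
    orifice_area_mm2: float | None
    elements: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        checks = {
            "radial_symmetry_mm": self.radial_symmetry_mm,
            "mirror_symmetry_mm": self.mirror_symmetry_mm,
            "collinearity_mm": self.collinearity_mm,
        }
        return all(
            checks[k] <= tol for k, tol in self.tolerances.items() if k in checks
        )

    def summary(self) -> str:
        lines = [
            f"radial 3-fold symmetry deviation : {self.radial_symmetry_mm:.3e} mm",
            f"soft-good mirror deviation       : {self.mirror_symmetry_mm:.3e} mm",
            f"junction collinearity residual   : {self.collinearity_mm:.3e} mm",
            f"bounding height                  : {self.height_mm:.2f} mm",
            f"max diameter                     : {self.diameter_mm:.2f} mm",
        ]
        if self.orifice_area_mm2 is not None:
            lines.append(
                f"geometric orifice area           : {self.orifice_area_mm2:.1f} mm^2"
            )
        lines.append(f"QC pass: {self.passed}")
        return "\n".join(lines)


_DEFAULT_TOLERANCES = {
    "radial_symmetry_mm": 1e-8,
    "mirror_symmetry_mm": 1e-6,
    "collinearity_mm": 1e-12,
}


def run_qc(assembly: ValveAssembly, tolerances: dict | None = None) -> QCReport:
    """Full QC sweep of an assembly against (configurable) tolerances."""
    tol = dict(_DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    soft = (
        np.vstack(
            [s.control_points.reshape(-1, 3) for _, s in assembly.patches]
        )
        if assembly.patches
        else None
    )
    radial = check_radial_symmetry(soft, 3) if soft is not None else 0.0
    mirror = float("nan")
    if assembly.leaflets:
        mirror = check_mirror_symmetry(assembly.leaflets[0], 60.0)
    height, diameter = bounding_dims(assembly)
    orifice = None
    if assembly.leaflets:
        free_edges = [s.iso_curve("v", 0.0) for s in assembly.leaflets]
        orifice = geometric_orifice_area(free_edges)
    return QCReport(
        radial_symmetry_mm=radial,
        mirror_symmetry_mm=mirror if not np.isnan(mirror) else 0.0,
        collinearity_mm=check_collinearity(assembly.constraints),
        height_mm=height,
        diameter_mm=diameter,
        orifice_area_mm2=orifice,
        elements=assembly.element_report(),
        tolerances=tol,
    )
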