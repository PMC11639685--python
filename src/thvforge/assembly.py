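"""Full-valve assembly, refinement, and interchange formats.

One third of the soft goods (skirt section, leaflet, commissural attachment)
is built from the configuration and replicated at 0/120/240 degrees; the
stent wires are patterned around the full circumference. The assembly
carries the wire crossing-constraint map and the coupling-curve metadata a
downstream structural solver needs: shell-shell penalty curves (the leaflet
attachment and vertical edges, shared with skirt and commissure) and
shell-beam penalty curves (the beam centerlines themselves).

Interchange: a versioned JSON schema that round-trips all NURBS patches,
the constraint map and coupling curves losslessly; tessellated legacy-ASCII
VTK polydata and binary STL for visualization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nurbs, softgoods, stent
from .config import ValveConfig
from .nurbs import NurbsCurve, NurbsSurface, h_refine_uniform, rotate_z
from .stent import ConstraintGroup, ConstraintMap

__all__ = [
    "ValveAssembly",
    "assemble_valve",
    "refine_for_analysis",
    "export_vtk",
    "export_stl",
    "export_json_nurbs",
    "import_json_nurbs",
    "tessellate_surface",
    "AssemblyError",
    "SchemaError",
]

SCHEMA_VERSION = 1


class AssemblyError(ValueError):
    """A required component is missing from the assembly inputs."""


class SchemaError(ValueError):
    """JSON interchange document does not match the expected schema."""


@dataclass
class ValveAssembly:
    name: str
    stent_curves: list[NurbsCurve]
    skirts: list[NurbsSurface]
    leaflets: list[NurbsSurface]
    commissures: list[NurbsSurface]
    constraints: ConstraintMap
    coupling_shell_shell: list[NurbsCurve]
    coupling_shell_beam: list[NurbsCurve]
    beam_section_mm: tuple[float, float]
    config: ValveConfig | None = field(default=None, repr=False, compare=False)

    @property
    def patches(self) -> list[tuple[str, NurbsSurface]]:
        out = []
        for label, group in (
            ("skirt", self.skirts),
            ("leaflet", self.leaflets),
            ("commissure", self.commissures),
        ):
            out.extend((f"{label}_{i}", s) for i, s in enumerate(group))
        return out

    def element_report(self) -> dict:
        stent_counts = [nurbs.element_count(c) for c in self.stent_curves]
        report = {"stent_per_curve": stent_counts}
        for label, group in (
            ("skirt", self.skirts),
            ("leaflet", self.leaflets),
            ("commissure", self.commissures),
        ):
            report[label] = [
                int(np.prod(nurbs.element_count(s))) for s in group
            ]
        return report


def assemble_valve(cfg: ValveConfig) -> ValveAssembly:
    """Build the complete valve from a configuration."""
    if cfg.profile is None:
        raise AssemblyError("configuration has no stent profile")
    wire = stent.build_stent_curve(cfg.profile, cfg.support)
    pair = (wire, stent.mirror_curve(wire))
    wires = stent.pattern_curves(pair, cfg.profile.phi_max)
    cmap = stent.crossing_constraints(wires)

    skirts: list[NurbsSurface] = []
    leaflets: list[NurbsSurface] = []
    commissures: list[NurbsSurface] = []
    ss_curves: list[NurbsCurve] = []
    if cfg.skirt:
        third = softgoods.build_skirt(cfg)
        skirts = [rotate_z(third.surface, 120.0 * k) for k in range(3)]
    if cfg.commissure:
        comm = softgoods.commissure_build(cfg)
        commissures = [rotate_z(comm.surface, 120.0 * k) for k in range(3)]
    if cfg.leaflet:
        if not cfg.commissure:
            raise AssemblyError("leaflets require a commissure definition")
        leaf_surface, leaf_curves = softgoods.build_leaflet(cfg)
        leaflets = [rotate_z(leaf_surface, 120.0 * k) for k in range(3)]
        for k in range(3):
            ss_curves.append(rotate_z(leaf_curves.attachment_edge, 120.0 * k))
            ss_curves.append(rotate_z(leaf_curves.vertical_left, 120.0 * k))
            ss_curves.append(rotate_z(leaf_curves.vertical_right, 120.0 * k))

    section = cfg.materials.beam_section
    return ValveAssembly(
        name=cfg.name,
        stent_curves=wires,
        skirts=skirts,
        leaflets=leaflets,
        commissures=commissures,
        constraints=cmap,
        coupling_shell_shell=ss_curves,
        coupling_shell_beam=list(wires),
        beam_section_mm=(section.width_mm, section.height_mm),
        config=cfg,
    )


def refine_for_analysis(
    assembly: ValveAssembly, stent_levels: int = 2, shell_levels: int = 0
) -> ValveAssembly:
    """Uniform h-refinement of every component; geometry is unchanged."""
    return ValveAssembly(
        name=assembly.name,
        stent_curves=[h_refine_uniform(c, stent_levels) for c in assembly.stent_curves],
        skirts=[h_refine_uniform(s, shell_levels) for s in assembly.skirts],
        leaflets=[h_refine_uniform(s, shell_levels) for s in assembly.leaflets],
        commissures=[
            h_refine_uniform(s, shell_levels) for s in assembly.commissures
        ],
        constraints=assembly.constraints,
        coupling_shell_shell=assembly.coupling_shell_shell,
        coupling_shell_beam=[
            h_refine_uniform(c, stent_levels) for c in assembly.coupling_shell_beam
        ],
        beam_section_mm=assembly.beam_section_mm,
        config=assembly.config,
    )


# ---------------------------------------------------------------------------
# tessellation and mesh export


def tessellate_surface(
    surface: NurbsSurface, tol_mm: float = 0.05, max_doublings: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate within a chordal tolerance; returns (vertices, faces).

    The sampling grid starts at two points per knot span and doubles until
    the measured mid-edge chordal deviation drops below ``tol_mm``.
    """
    if tol_mm <= 0:
        raise ValueError("tessellation tolerance must be positive")
    nu_el, nv_el = nurbs.element_count(surface)
    nu, nv = 2 * nu_el + 1, 2 * nv_el + 1
    for _ in range(max_doublings + 1):
        us = np.linspace(0.0, 1.0, nu)
        vs = np.linspace(0.0, 1.0, nv)
        grid = surface.evaluate_grid(us, vs)
        # chordal deviation at cell centers
        um = (us[:-1] + us[1:]) / 2
        vm = (vs[:-1] + vs[1:]) / 2
        mid_true = surface.evaluate_grid(um, vm)
        mid_lin = (
            grid[:-1, :-1] + grid[1:, :-1] + grid[:-1, 1:] + grid[1:, 1:]
        ) / 4.0
        dev = float(np.linalg.norm(mid_true - mid_lin, axis=2).max())
        if dev <= tol_mm:
            break
        nu, nv = 2 * nu - 1, 2 * nv - 1
    verts = grid.reshape(-1, 3)
    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    return verts, faces


def export_vtk(assembly: ValveAssembly, path, tol_mm: float = 0.05) -> Path:
    """Legacy ASCII VTK polydata: tessellated patches plus wire polylines."""
    path = Path(path)
    all_pts: list[np.ndarray] = []
    polys: list[np.ndarray] = []
    poly_patch: list[int] = []
    lines: list[np.ndarray] = []
    offset = 0
    for pid, (label, surf) in enumerate(assembly.patches):
        v, f = tessellate_surface(surf, tol_mm)
        all_pts.append(v)
        polys.append(f + offset)
        poly_patch.extend([pid] * len(f))
        offset += len(v)
    for c in assembly.stent_curves:
        ts = np.linspace(*c.domain, 65)
        pts = c.evaluate(ts)
        all_pts.append(pts)
        lines.append(np.arange(len(pts)) + offset)
        offset += len(pts)
    pts = np.vstack(all_pts) if all_pts else np.empty((0, 3))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"thvforge assembly {assembly.name}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        n_tri = sum(len(f) for f in polys)
        if n_tri:
            fh.write(f"POLYGONS {n_tri} {4 * n_tri}\n")
            for f in polys:
                for tri in f:
                    fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if lines:
            total = sum(len(l) + 1 for l in lines)
            fh.write(f"LINES {len(lines)} {total}\n")
            for l in lines:
                fh.write(" ".join([str(len(l)), *map(str, l)]) + "\n")
        n_cells = n_tri + len(lines)
        if n_cells:
            fh.write(f"CELL_DATA {n_cells}\nSCALARS patch_id int 1\n")
            fh.write("LOOKUP_TABLE default\n")
            for pid in poly_patch:
                fh.write(f"{pid}\n")
            for _ in lines:
                fh.write("-1\n")
    return path


def export_stl(assembly: ValveAssembly, path, tol_mm: float = 0.05) -> Path:
    """Binary little-endian STL of all tessellated surface patches (mm units)."""
    import trimesh

    meshes = []
    for _, surf in assembly.patches:
        v, f = tessellate_surface(surf, tol_mm)
        meshes.append(trimesh.Trimesh(vertices=v, faces=f, process=False))
    if not meshes:
        raise AssemblyError("assembly has no surface patches to export")
    combined = trimesh.util.concatenate(meshes)
    path = Path(path)
    combined.export(path, file_type="stl")
    return path


# ---------------------------------------------------------------------------
# JSON interchange

_TOP_FIELDS = {
    "schema_version",
    "name",
    "stent_curves",
    "skirts",
    "leaflets",
    "commissures",
    "constraints",
    "coupling_shell_shell",
    "coupling_shell_beam",
    "beam_section_mm",
}


def export_json_nurbs(assembly: ValveAssembly, path) -> Path:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": assembly.name,
        "stent_curves": [c.to_dict() for c in assembly.stent_curves],
        "skirts": [s.to_dict() for s in assembly.skirts],
        "leaflets": [s.to_dict() for s in assembly.leaflets],
        "commissures": [s.to_dict() for s in assembly.commissures],
        "constraints": [
            {
                "location": g.location.tolist(),
                "members": [list(m) for m in g.members],
                "collinearity_residual": g.collinearity_residual,
            }
            for g in assembly.constraints.groups
        ],
        "coupling_shell_shell": [c.to_dict() for c in assembly.coupling_shell_shell],
        "coupling_shell_beam": [c.to_dict() for c in assembly.coupling_shell_beam],
        "beam_section_mm": list(assembly.beam_section_mm),
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def import_json_nurbs(path) -> ValveAssembly:
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError("assembly document must be a JSON object")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {doc.get('schema_version')!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    unknown = set(doc) - _TOP_FIELDS
    if unknown:
        raise SchemaError(f"unknown field(s) in assembly document: {sorted(unknown)}")
    missing = _TOP_FIELDS - set(doc)
    if missing:
        raise SchemaError(f"missing field(s) in assembly document: {sorted(missing)}")
    try:
        groups = tuple(
            ConstraintGroup(
                np.asarray(g["location"], dtype=float),
                tuple(tuple(int(i) for i in m) for m in g["members"]),
                float(g["collinearity_residual"]),
            )
            for g in doc["constraints"]
        )
        return ValveAssembly(
            name=str(doc["name"]),
            stent_curves=[NurbsCurve.from_dict(d) for d in doc["stent_curves"]],
            skirts=[NurbsSurface.from_dict(d) for d in doc["skirts"]],
            leaflets=[NurbsSurface.from_dict(d) for d in doc["leaflets"]],
            commissures=[NurbsSurface.from_dict(d) for d in doc["commissures"]],
            constraints=ConstraintMap(groups),
            coupling_shell_shell=[
                NurbsCurve.from_dict(d) for d in doc["coupling_shell_shell"]
            ],
            coupling_shell_beam=[
                NurbsCurve.from_dict(d) for d in doc["coupling_shell_beam"]
            ],
            beam_section_mm=tuple(float(v) for v in doc["beam_section_mm"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed assembly document: {exc}") from exc
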