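"""Declarative valve configuration: profile tables, recipes, materials.

A valve is described by a YAML document holding (a) the stent profile table
of cylindrical coordinates (r_c in mm, phi_c in degrees, z_c in mm), (b) the
support-point offset fractions, (c) curve recipes for the skirt, commissural
attachments and leaflets as ordered point references plus transforms, and
(d) material and penalty parameters. Two fixtures ship with the package:
THV-A, a tall self-expanding frame patterned on the Evolut R, and THV-B, a
short balloon-expandable frame patterned on the SAPIEN 3.

Units are normalized on load: lengths to mm, moduli to kPa, densities to
g/cm^3, angles in degrees at the interface.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CylPoint",
    "StentProfile",
    "SupportSpec",
    "LeeSacksParams",
    "MaterialSet",
    "ValveConfig",
    "ConfigError",
    "ProfileError",
    "load_config",
    "loads_config",
    "serialize_config",
    "thv_a",
    "thv_b",
    "resolve_point",
    "resolve_recipe",
    "support_position",
]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class ProfileError(ConfigError):
    """Stent profile table is geometrically inadmissible."""


# ---------------------------------------------------------------------------
# profile


@dataclass(frozen=True)
class CylPoint:
    """Cylindrical stent coordinate: radius and height in mm, azimuth in degrees."""

    r_c: float
    phi_c: float
    z_c: float

    def __post_init__(self):
        if not self.r_c > 0:
            raise ProfileError(f"radius must be positive, got {self.r_c}")
        if not (0 <= self.phi_c < 180):
            raise ProfileError(f"phi_c must lie in [0, 180), got {self.phi_c}")
        if not math.isfinite(self.z_c):
            raise ProfileError("z_c must be finite")

    def cartesian(self) -> np.ndarray:
        a = math.radians(self.phi_c)
        return np.array(
            [self.r_c * math.cos(a), self.r_c * math.sin(a), self.z_c]
        )


@dataclass(frozen=True)
class StentProfile:
    """Ordered bottom-to-top stent cross-section table (P1 ... Pn)."""

    points: tuple[CylPoint, ...]

    def __post_init__(self):
        pts = tuple(self.points)
        if len(pts) < 2:
            raise ProfileError("profile needs at least two points")
        z = [p.z_c for p in pts]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise ProfileError("z_c must be strictly increasing bottom to top")
        phis = sorted({p.phi_c for p in pts})
        if phis[0] != 0.0 or len(phis) != 2:
            raise ProfileError(
                "phi_c must alternate between 0 and a single maximum angle"
            )
        expected = [0.0 if i % 2 == 0 else phis[1] for i in range(len(pts))]
        if [p.phi_c for p in pts] != expected:
            raise ProfileError("phi_c must alternate 0, phi_max, 0, ...")
        object.__setattr__(self, "points", pts)

    @property
    def phi_max(self) -> float:
        return max(p.phi_c for p in self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def z_range(self) -> tuple[float, float]:
        return self.points[0].z_c, self.points[-1].z_c


@dataclass(frozen=True)
class SupportSpec:
    """Axial offset fractions for the tangency support points."""

    end_fraction: float = 0.25
    interior_fraction: float = 0.125

    def __post_init__(self):
        for name in ("end_fraction", "interior_fraction"):
            v = getattr(self, name)
            if not (0 < v < 0.5):
                raise ConfigError(f"{name} must lie in (0, 0.5), got {v}")


def support_position(profile: StentProfile, spec: SupportSpec, index: int, side: str) -> np.ndarray:
    """Cartesian position of the support point attached to baseline point ``index``.

    Interior supports are offset purely axially (same r_c, phi_c) by the
    interior fraction of the vertical gap to the adjacent cross-section. End
    supports lie on the chord to the single neighbour, scaled so their axial
    offset equals the end fraction of that vertical gap.
    """
    pts = profile.points
    n = len(pts)
    if not 0 <= index < n:
        raise ConfigError(f"baseline index {index} out of range")
    if side not in ("above", "below"):
        raise ConfigError(f"support side must be 'above' or 'below', got {side!r}")
    p = pts[index]
    is_end = index in (0, n - 1)
    if is_end:
        valid = "above" if index == 0 else "below"
        if side != valid:
            raise ConfigError(
                f"end point P{index + 1} only has a support {valid} it"
            )
        nb = pts[index + 1] if index == 0 else pts[index - 1]
        gap = abs(nb.z_c - p.z_c)
        if gap == 0:
            raise ProfileError("zero vertical gap between adjacent cross-sections")
        return p.cartesian() + spec.end_fraction * (nb.cartesian() - p.cartesian())
    nb = pts[index + 1] if side == "above" else pts[index - 1]
    gap = abs(nb.z_c - p.z_c)
    if gap == 0:
        raise ProfileError("zero vertical gap between adjacent cross-sections")
    dz = spec.interior_fraction * gap * (1 if side == "above" else -1)
    return CylPoint(p.r_c, p.phi_c, p.z_c + dz).cartesian()


# ---------------------------------------------------------------------------
# materials


@dataclass(frozen=True)
class LeeSacksParams:
    """Lee-Sacks strain-energy parameters (moduli in kPa)."""

    c0: float
    c1: float
    c2: float
    c3: float = 0.0
    w: float = 1.0
    fiber_angle_deg: float = 0.0

    def __post_init__(self):
        if min(self.c0, self.c1) <= 0 or min(self.c2, self.c3) < 0:
            raise ConfigError("Lee-Sacks moduli must be positive")
        if not 0 <= self.w <= 1:
            raise ConfigError("anisotropy weight w must lie in [0, 1]")


@dataclass(frozen=True)
class FrameMaterial:
    E_kPa: float  # St. Venant-Kirchhoff modulus
    nu: float
    rho_g_cm3: float


@dataclass(frozen=True)
class BeamSection:
    width_mm: float  # along v2
    height_mm: float  # along v3

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.height_mm


@dataclass(frozen=True)
class PenaltyConfig:
    alpha_ss: float
    alpha_sb: float
    alpha_f: float
    mu_friction: float


@dataclass(frozen=True)
class MaterialSet:
    frame: FrameMaterial
    leaflet: LeeSacksParams
    skirt: LeeSacksParams
    shell_thickness_mm: float
    shell_rho_g_cm3: float
    penalties: PenaltyConfig
    beam_section: BeamSection


# ---------------------------------------------------------------------------
# recipes and point resolution

_REF_RE = re.compile(r"^(?:P(\d+)|S(\d+)([+-]))$")
_TRANSFORM_KEYS = {"invert_phi", "rotate_z", "reflect", "translate", "offset", "z_of"}


class ResolutionError(ConfigError):
    """A point reference cannot be resolved against the profile."""


def _to_cylindrical(pt: np.ndarray) -> tuple[float, float, float]:
    r = math.hypot(pt[0], pt[1])
    phi = math.degrees(math.atan2(pt[1], pt[0]))
    return r, phi, pt[2]


def resolve_point(entry: dict, profile: StentProfile, spec: SupportSpec) -> np.ndarray:
    """Resolve a recipe entry ``{"ref": ..., "transforms": [...]}`` to Cartesian mm.

    References are ``P<i>`` for baseline points and ``S<i>+`` / ``S<i>-`` for
    the support above / below baseline point i (1-based, as in the tables).
    Transforms apply left to right.
    """
    if not isinstance(entry, dict) or "ref" not in entry:
        raise ResolutionError(f"recipe entry must be a dict with 'ref': {entry!r}")
    ref = entry["ref"]
    m = _REF_RE.match(str(ref))
    if not m:
        raise ResolutionError(f"unknown point reference {ref!r}")
    if m.group(1):
        idx = int(m.group(1)) - 1
        if not 0 <= idx < profile.n_points:
            raise ResolutionError(f"baseline index out of range in {ref!r}")
        pt = profile.points[idx].cartesian()
    else:
        idx = int(m.group(2)) - 1
        side = "above" if m.group(3) == "+" else "below"
        pt = support_position(profile, spec, idx, side)

    from . import nurbs  # local import to keep module load order simple

    for op in entry.get("transforms", []) or []:
        if not isinstance(op, dict) or len(op) != 1:
            raise ResolutionError(f"malformed transform {op!r}")
        (key, val), = op.items()
        if key not in _TRANSFORM_KEYS:
            raise ResolutionError(f"unknown transform {key!r}")
        if key == "invert_phi":
            r, phi, z = _to_cylindrical(pt)
            pt = CylPoint(r, 0.0, z).cartesian() if phi == 0 else nurbs.reflect(pt, 0.0)
        elif key == "rotate_z":
            pt = nurbs.rotate_z(pt, float(val))
        elif key == "reflect":
            pt = nurbs.reflect(pt, float(val))
        elif key == "translate":
            pt = pt + np.asarray(val, dtype=float)
        elif key == "offset":
            dr, dz = (float(v) for v in val)
            r, phi, z = _to_cylindrical(pt)
            if r + dr <= 0:
                raise ResolutionError("radial offset collapses the point onto the axis")
            pt = CylPoint(r + dr, phi, z + dz).cartesian()
        elif key == "z_of":
            pt = np.array([0.0, 0.0, pt[2]])
    return pt


def resolve_recipe(recipe: list, profile: StentProfile, spec: SupportSpec) -> np.ndarray:
    """Resolve an ordered recipe into an (n, 3) point array."""
    if not recipe:
        raise ResolutionError("empty recipe")
    return np.array([resolve_point(e, profile, spec) for e in recipe])


# ---------------------------------------------------------------------------
# full config


@dataclass(frozen=True)
class ValveConfig:
    name: str
    profile: StentProfile
    support: SupportSpec
    skirt: dict
    commissure: dict
    leaflet: dict
    materials: MaterialSet
    approximated_from_figure: tuple[str, ...] = ()
    raw: dict = field(default_factory=dict, compare=False, repr=False)


_TOP_KEYS = {
    "name",
    "profile",
    "support",
    "skirt",
    "commissure",
    "leaflet",
    "materials",
    "approximated_from_figure",
}
_SKIRT_KEYS = {"vertical", "span_degrees"}
_COMM_KEYS = {"central", "edge_source"}
_LEAFLET_KEYS = {
    "translation_mm",
    "lower_edge",
    "attachment",
    "free_edge",
    "belly",
    "interior_factor",
    "side_drop_factor",
    "use_arc",
}
_FREE_EDGE_KEYS = {
    "mode",
    "side_fractions",
    "center_radial_offset_mm",
    "center_vertical_offset_mm",
    "axis_vertical_offset_mm",
}


def _check_keys(d: dict, allowed: set, where: str):
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def loads_config(text: str) -> ValveConfig:
    """Parse and validate a YAML valve configuration."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(doc, _TOP_KEYS, "top level")
    for key in ("name", "profile", "materials"):
        if key not in doc:
            raise ConfigError(f"missing required section {key!r}")

    prof_doc = doc["profile"]
    _check_keys(prof_doc, {"points"}, "profile")
    try:
        points = tuple(CylPoint(*[float(v) for v in row]) for row in prof_doc["points"])
        profile = StentProfile(points)
    except (TypeError, ProfileError) as exc:
        raise ProfileError(f"invalid profile table: {exc}") from exc

    sup_doc = doc.get("support", {})
    _check_keys(sup_doc, {"end_fraction", "interior_fraction"}, "support")
    support = SupportSpec(**{k: float(v) for k, v in sup_doc.items()})

    m = doc["materials"]
    _check_keys(
        m,
        {"frame", "leaflet", "skirt", "shell", "penalties", "beam_section"},
        "materials",
    )
    frame = FrameMaterial(
        E_kPa=float(m["frame"]["E_GPa"]) * 1.0e6,
        nu=float(m["frame"]["nu"]),
        rho_g_cm3=float(m["frame"]["rho_g_cm3"]),
    )
    leaf = m["leaflet"]
    leaflet_mat = LeeSacksParams(
        c0=float(leaf["c0_kPa"]),
        c1=float(leaf["c1_kPa"]),
        c2=float(leaf["c2"]),
        c3=float(leaf.get("c3", 0.0)),
        w=float(leaf["w"]),
        fiber_angle_deg=float(leaf.get("fiber_angle_deg", 0.0)),
    )
    sk = m["skirt"]
    skirt_mat = LeeSacksParams(
        c0=float(sk["c0_kPa"]),
        c1=float(sk["c1_kPa"]),
        c2=float(sk["c2"]),
        w=float(sk.get("w", 1.0)),
    )
    pen = m["penalties"]
    materials = MaterialSet(
        frame=frame,
        leaflet=leaflet_mat,
        skirt=skirt_mat,
        shell_thickness_mm=float(m["shell"]["thickness_mm"]),
        shell_rho_g_cm3=float(m["shell"]["rho_g_cm3"]),
        penalties=PenaltyConfig(
            alpha_ss=float(pen["alpha_ss"]),
            alpha_sb=float(pen["alpha_sb"]),
            alpha_f=float(pen["alpha_f"]),
            mu_friction=float(pen.get("mu_friction", 0.2)),
        ),
        beam_section=BeamSection(
            width_mm=float(m["beam_section"]["width_mm"]),
            height_mm=float(m["beam_section"]["height_mm"]),
        ),
    )

    skirt = doc.get("skirt", {})
    _check_keys(skirt, _SKIRT_KEYS, "skirt")
    commissure = doc.get("commissure", {})
    _check_keys(commissure, _COMM_KEYS, "commissure")
    if commissure and commissure.get("edge_source", "central_curve") not in (
        "central_curve",
        "stent_segment",
    ):
        raise ConfigError(
            f"unknown commissure edge_source {commissure['edge_source']!r}"
        )
    leaflet = doc.get("leaflet", {})
    _check_keys(leaflet, _LEAFLET_KEYS, "leaflet")
    if leaflet:
        _check_keys(leaflet.get("free_edge", {}), _FREE_EDGE_KEYS, "leaflet.free_edge")
        mode = leaflet.get("free_edge", {}).get("mode", "center_flat")
        if mode not in ("center_low", "center_flat"):
            raise ConfigError(f"unknown free-edge mode {mode!r}")
        fr = leaflet.get("free_edge", {}).get("side_fractions", [0.25, 0.5])
        if not fr or any(
            not (0 < a < 1) for a in fr
        ) or any(b <= a for a, b in zip(fr, fr[1:])):
            raise ConfigError("side_fractions must be strictly increasing in (0,1)")

    # validate every recipe resolves
    for where, recipe in (
        ("skirt.vertical", skirt.get("vertical")),
        ("commissure.central", commissure.get("central")),
        ("leaflet.lower_edge", leaflet.get("lower_edge")),
        ("leaflet.attachment", leaflet.get("attachment")),
    ):
        if recipe is not None:
            try:
                resolve_recipe(recipe, profile, support)
            except ConfigError as exc:
                raise ConfigError(f"recipe {where}: {exc}") from exc

    return ValveConfig(
        name=str(doc["name"]),
        profile=profile,
        support=support,
        skirt=skirt,
        commissure=commissure,
        leaflet=leaflet,
        materials=materials,
        approximated_from_figure=tuple(doc.get("approximated_from_figure", ())),
        raw=doc,
    )


def load_config(path) -> ValveConfig:
    """Load, validate and unit-normalize a valve configuration file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return loads_config(p.read_text())


def serialize_config(cfg: ValveConfig) -> str:
    """YAML serialization that reproduces the loaded values exactly."""
    return yaml.safe_dump(cfg.raw, sort_keys=False)


def _fixture(name: str) -> ValveConfig:
    text = resources.files("thvforge").joinpath("data", name).read_text()
    return loads_config(text)


def thv_a() -> ValveConfig:
    """Tall self-expanding fixture (Evolut R-like, 11 cross-sections, phi_max 12)."""
    return _fixture("thv_a.yaml")


def thv_b() -> ValveConfig:
    """Short balloon-expandable fixture (SAPIEN 3-like, 8 cross-sections, phi_max 15)."""
    return _fixture("thv_b.yaml")
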