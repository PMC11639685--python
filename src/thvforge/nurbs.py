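"""Degree-3 NURBS curves and surfaces for parametric valve modeling.

All geometry here is clamped (open knot vectors), measured in millimetres,
and non-rational by default (weights of 1); exact circular arcs are the one
rational construction. Evaluation runs through ``scipy.interpolate.BSpline``
in homogeneous coordinates, so rational and polynomial geometry share one
code path. Knot insertion, global interpolation, lofting and the Gordon
construction are implemented here because they are the primitives the whole
valve builder rests on.

Conventions
-----------
* Right-handed Cartesian frame, valve axis along +z, inflow plane at z = 0.
* Public interfaces accept angles in degrees (the profile tables are given
  in degrees); radians are used internally.
* Parametric domains are normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy import integrate, optimize

__all__ = [
    "KnotVector",
    "NurbsCurve",
    "NurbsSurface",
    "CurveNetwork",
    "open_uniform_knots",
    "eval_curve",
    "interpolate_curve",
    "h_refine_uniform",
    "insert_knot",
    "rotate_z",
    "reflect",
    "translate",
    "split_curve",
    "join_curves",
    "intersect_curves",
    "loft",
    "gordon_surface",
    "curve_length",
    "element_count",
    "arc_through_points",
    "NetworkError",
    "IntersectionNotFound",
]


class NetworkError(ValueError):
    """A bidirectional curve network is incompatible (missing or bad crossings)."""


class IntersectionNotFound(ValueError):
    """Two curves do not approach each other within the requested tolerance."""


# ---------------------------------------------------------------------------
# knot vectors


@dataclass(frozen=True)
class KnotVector:
    """Clamped (open) knot vector for a spline of the given degree."""

    values: np.ndarray
    degree: int

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        p = self.degree
        if p < 1:
            raise ValueError("degree must be a positive integer")
        if vals.size < 2 * (p + 1):
            raise ValueError("knot vector too short for degree")
        if np.any(np.diff(vals) < 0):
            raise ValueError("knot values must be nondecreasing")
        if not (np.all(vals[: p + 1] == vals[0]) and np.all(vals[-(p + 1):] == vals[-1])):
            raise ValueError("knot vector must be clamped (end multiplicity degree+1)")
        interior = vals[p + 1: -(p + 1)]
        if interior.size:
            uniq, counts = np.unique(interior, return_counts=True)
            if np.any(counts > p):
                raise ValueError("interior knot multiplicity exceeds degree")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def spans(self) -> np.ndarray:
        """Non-degenerate knot spans as an (m, 2) array."""
        u = np.unique(self.values)
        return np.column_stack([u[:-1], u[1:]])

    def n_elements(self) -> int:
        return len(np.unique(self.values)) - 1

    def greville_abscissae(self) -> np.ndarray:
        p = self.degree
        n = len(self.values) - p - 1
        return np.array([self.values[i + 1: i + p + 1].mean() for i in range(n)])


def open_uniform_knots(n_ctrl: int, degree: int) -> KnotVector:
    """Clamped knot vector with uniformly spaced spans on [0, 1]."""
    if n_ctrl < degree + 1:
        raise ValueError(
            f"need at least degree+1={degree + 1} control points, got {n_ctrl}"
        )
    n_spans = n_ctrl - degree
    interior = np.linspace(0.0, 1.0, n_spans + 1)[1:-1]
    values = np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])
    return KnotVector(values, degree)


def _averaged_knots(params: np.ndarray, n_ctrl: int, degree: int) -> KnotVector:
    """Knot vector by parameter averaging (the standard interpolation choice)."""
    p = degree
    n_interior = n_ctrl - p - 1
    if n_interior < 0:
        raise ValueError("too few control points")
    if n_interior == 0:
        interior = np.empty(0)
    else:
        # average over a sliding window of the parameter list, padded at the
        # ends so derivative-augmented systems stay well conditioned
        m = len(params)
        pad = n_ctrl + 1 - m  # extra rows beyond plain point collocation
        ext = np.concatenate([[params[0]] * max(pad, 0), params])
        interior = np.array(
            [ext[j + 1: j + p + 1].mean() for j in range(1, n_interior + 1)]
        )
    values = np.concatenate([np.zeros(p + 1), interior, np.ones(p + 1)])
    return KnotVector(values, p)


# ---------------------------------------------------------------------------
# curves


@dataclass(frozen=True)
class NurbsCurve:
    """Clamped NURBS curve; ``control_points`` is (n, 3) in mm, weights positive."""

    control_points: np.ndarray
    knots: KnotVector
    weights: np.ndarray | None = None

    def __post_init__(self):
        cp = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if cp.shape[1] != 3:
            raise ValueError("control points must be 3-vectors")
        w = self.weights
        w = np.ones(len(cp)) if w is None else np.asarray(w, dtype=float)
        if w.shape != (len(cp),):
            raise ValueError("one weight per control point required")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        expected = len(self.knots.values) - self.knots.degree - 1
        if len(cp) != expected:
            raise ValueError(
                f"control point count {len(cp)} inconsistent with knots "
                f"(expected {expected})"
            )
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "weights", w)

    # -- basic queries ------------------------------------------------------

    @property
    def degree(self) -> int:
        return self.knots.degree

    @property
    def domain(self) -> tuple[float, float]:
        return self.knots.domain

    @property
    def is_rational(self) -> bool:
        return not np.allclose(self.weights, self.weights[0])

    def _homogeneous(self) -> np.ndarray:
        w = self.weights[:, None]
        return np.hstack([self.control_points * w, w])

    def _spline(self) -> BSpline:
        return BSpline(self.knots.values, self._homogeneous(), self.degree)

    def evaluate(self, u) -> np.ndarray:
        """Point(s) on the curve; scalar u gives a (3,) array."""
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        lo, hi = self.domain
        if np.any(u_arr < lo - 1e-12) or np.any(u_arr > hi + 1e-12):
            raise ValueError(f"parameter outside knot range [{lo}, {hi}]")
        u_arr = np.clip(u_arr, lo, hi)
        hw = self._spline()(u_arr)
        pts = hw[:, :3] / hw[:, 3:4]
        return pts[0] if np.isscalar(u) or np.ndim(u) == 0 else pts

    def derivative(self, u, order: int = 1) -> np.ndarray:
        """Derivative(s) of the point map (quotient rule for rational curves)."""
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        lo, hi = self.domain
        u_arr = np.clip(u_arr, lo, hi)
        sp = self._spline()
        A = sp(u_arr)
        C = A[:, :3] / A[:, 3:4]
        d1 = sp.derivative(1)(u_arr)
        C1 = (d1[:, :3] - C * d1[:, 3:4]) / A[:, 3:4]
        if order == 1:
            out = C1
        elif order == 2:
            d2 = sp.derivative(2)(u_arr)
            out = (d2[:, :3] - 2 * C1 * d1[:, 3:4] - C * d2[:, 3:4]) / A[:, 3:4]
        else:
            raise ValueError("only first and second derivatives supported")
        return out[0] if np.isscalar(u) or np.ndim(u) == 0 else out

    def transformed(self, fn: Callable[[np.ndarray], np.ndarray]) -> "NurbsCurve":
        return replace(self, control_points=fn(self.control_points))

    def reversed(self) -> "NurbsCurve":
        lo, hi = self.domain
        vals = (lo + hi) - self.knots.values[::-1]
        return NurbsCurve(
            self.control_points[::-1].copy(),
            KnotVector(vals, self.degree),
            self.weights[::-1].copy(),
        )

    def normalized(self) -> "NurbsCurve":
        """Affinely reparameterized to the domain [0, 1]."""
        lo, hi = self.domain
        if lo == 0.0 and hi == 1.0:
            return self
        vals = (self.knots.values - lo) / (hi - lo)
        return replace(self, knots=KnotVector(vals, self.degree))

    def to_dict(self) -> dict:
        return {
            "type": "curve",
            "degree": self.degree,
            "knots": self.knots.values.tolist(),
            "control_points": self.control_points.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NurbsCurve":
        return cls(
            np.asarray(d["control_points"], dtype=float),
            KnotVector(np.asarray(d["knots"], dtype=float), int(d["degree"])),
            np.asarray(d["weights"], dtype=float),
        )


def eval_curve(curve: NurbsCurve, u) -> np.ndarray:
    return curve.evaluate(u)


# ---------------------------------------------------------------------------
# low-level spline algebra on homogeneous coefficient arrays


def _boehm_insert(t: np.ndarray, c: np.ndarray, p: int, u: float) -> tuple[np.ndarray, np.ndarray]:
    """Single knot insertion (Boehm); ``c`` is (n, m) coefficients."""
    # span index k with t[k] <= u < t[k+1]
    k = int(np.searchsorted(t, u, side="right") - 1)
    k = min(max(k, p), len(c) - 1)
    new_c = np.empty((len(c) + 1, c.shape[1]))
    new_c[: k - p + 1] = c[: k - p + 1]
    for i in range(k - p + 1, k + 1):
        denom = t[i + p] - t[i]
        a = 0.0 if denom == 0.0 else (u - t[i]) / denom
        new_c[i] = (1.0 - a) * c[i - 1] + a * c[i]
    new_c[k + 1:] = c[k:]
    new_t = np.insert(t, k + 1, u)
    return new_t, new_c


def insert_knot(curve: NurbsCurve, u: float, times: int = 1) -> NurbsCurve:
    """Insert ``u`` into the knot vector ``times`` times; geometry unchanged."""
    lo, hi = curve.domain
    if not (lo < u < hi):
        raise ValueError("knot insertion parameter must be strictly interior")
    t = curve.knots.values.copy()
    c = curve._homogeneous()
    for _ in range(times):
        t, c = _boehm_insert(t, c, curve.degree, u)
    w = c[:, 3]
    return NurbsCurve(c[:, :3] / w[:, None], KnotVector(t, curve.degree), w)


def _refine_knots_once(t: np.ndarray, c: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    mids = np.unique(t)
    mids = (mids[:-1] + mids[1:]) / 2.0
    for u in mids:
        t, c = _boehm_insert(t, c, p, u)
    return t, c


def _bezier_segments(t: np.ndarray, c: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Insert knots until every interior breakpoint has multiplicity p."""
    uniq = np.unique(t)[1:-1]
    for u in uniq:
        mult = int(np.sum(t == u))
        if mult < p:
            for _ in range(p - mult):
                t, c = _boehm_insert(t, c, p, u)
    return t, c


def _elevate_once(t: np.ndarray, c: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Degree-elevate by one via Bezier decomposition (internal use only).

    The result keeps interior breakpoints at multiplicity p+1 (C0 joins in the
    representation); geometry is exact, which is all the surface combination
    machinery needs.
    """
    t, c = _bezier_segments(t, c, p)
    breaks = np.unique(t)
    # after full decomposition segment i owns c[i*p : i*p + p + 1]
    n_seg = len(breaks) - 1
    new_c = []
    for i in range(n_seg):
        seg = c[i * p: i * p + p + 1]
        el = np.empty((p + 2, c.shape[1]))
        el[0] = seg[0]
        el[p + 1] = seg[p]
        for j in range(1, p + 1):
            a = j / (p + 1)
            el[j] = a * seg[j - 1] + (1 - a) * seg[j]
        if i == 0:
            new_c.extend(el)
        else:
            new_c.extend(el[1:])
    q = p + 1
    new_t = [breaks[0]] * (q + 1)
    for b in breaks[1:-1]:
        new_t.extend([b] * q)
    new_t.extend([breaks[-1]] * (q + 1))
    return np.asarray(new_t), np.asarray(new_c), q


def _elevate_curve_to(curve: NurbsCurve, degree: int) -> NurbsCurve:
    """Exact degree elevation of a curve (internal: network compatibility only)."""
    t = curve.knots.values.copy()
    c = curve._homogeneous()
    p = curve.degree
    while p < degree:
        t, c, p = _elevate_once(t, c, p)
    w = c[:, 3]
    return NurbsCurve(c[:, :3] / w[:, None], KnotVector(t, p), w)


def _merge_to_knots(t: np.ndarray, c: np.ndarray, p: int, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert knots so that ``t`` contains every knot of ``target`` (same degree)."""
    interior = target[(target > target[0]) & (target < target[-1])]
    for u in np.unique(interior):
        need = int(np.sum(interior == u)) - int(np.sum(t == u))
        for _ in range(max(need, 0)):
            t, c = _boehm_insert(t, c, p, u)
    return t, c


def _union_knots(knot_lists: list[np.ndarray], p: int) -> np.ndarray:
    """Union (max multiplicity per value) of clamped knot vectors on [0,1]."""
    vals: dict[float, int] = {}
    for t in knot_lists:
        interior = t[(t > t[0]) & (t < t[-1])]
        for u in np.unique(interior):
            vals[float(u)] = max(vals.get(float(u), 0), int(np.sum(interior == u)))
    interior_full = np.concatenate(
        [np.full(m, u) for u, m in sorted(vals.items())] or [np.empty(0)]
    )
    return np.concatenate([np.zeros(p + 1), interior_full, np.ones(p + 1)])


def _make_compatible(curves: Sequence[NurbsCurve]) -> list[NurbsCurve]:
    """Normalize domains and merge knots so all curves share one knot vector."""
    curves = [c.normalized() for c in curves]
    degrees = {c.degree for c in curves}
    if len(degrees) != 1:
        raise ValueError("curves must share a degree for knot merging")
    p = degrees.pop()
    target = _union_knots([c.knots.values for c in curves], p)
    out = []
    for c in curves:
        t, coeff = _merge_to_knots(c.knots.values.copy(), c._homogeneous(), p, target)
        w = coeff[:, 3]
        out.append(NurbsCurve(coeff[:, :3] / w[:, None], KnotVector(t, p), w))
    return out


# ---------------------------------------------------------------------------
# refinement / transforms


def h_refine_uniform(g, levels: int):
    """Split every non-degenerate span at its midpoint, ``levels`` times."""
    if levels < 0:
        raise ValueError("levels must be non-negative")
    if levels == 0:
        return g
    if isinstance(g, NurbsCurve):
        t = g.knots.values.copy()
        c = g._homogeneous()
        for _ in range(levels):
            t, c = _refine_knots_once(t, c, g.degree)
        w = c[:, 3]
        return NurbsCurve(c[:, :3] / w[:, None], KnotVector(t, g.degree), w)
    if isinstance(g, NurbsSurface):
        s = g
        for _ in range(levels):
            s = s._refine_once()
        return s
    raise TypeError(f"cannot refine {type(g).__name__}")


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])


def _reflection(plane_phi_deg: float) -> np.ndarray:
    """Mirror across the vertical plane containing the z-axis at given azimuth."""
    R = _rotation_z(plane_phi_deg)
    M = np.diag([1.0, -1.0, 1.0])
    return R @ M @ R.T


def _apply_pointwise(g, fn: Callable[[np.ndarray], np.ndarray]):
    if isinstance(g, NurbsCurve):
        return g.transformed(fn)
    if isinstance(g, NurbsSurface):
        return g.transformed(fn)
    if isinstance(g, np.ndarray):
        return fn(np.atleast_2d(g))[0] if g.ndim == 1 else fn(g)
    raise TypeError(f"cannot transform {type(g).__name__}")


def rotate_z(g, angle_deg: float):
    """Rigid rotation about the valve (z) axis; angle in degrees."""
    R = _rotation_z(angle_deg)
    return _apply_pointwise(g, lambda P: P @ R.T)


def reflect(g, plane_phi_deg: float):
    """Mirror across the vertical plane at azimuth ``plane_phi_deg`` degrees."""
    M = _reflection(plane_phi_deg)
    return _apply_pointwise(g, lambda P: P @ M.T)


def translate(g, vector):
    v = np.asarray(vector, dtype=float)
    return _apply_pointwise(g, lambda P: P + v)


# ---------------------------------------------------------------------------
# interpolation


def _chord_params(points: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = d.sum()
    if total == 0:
        raise ValueError("all interpolation points coincide")
    p = np.concatenate([[0.0], np.cumsum(d) / total])
    p[-1] = 1.0  # guard against cumsum rounding past the domain end
    return np.clip(p, 0.0, 1.0)


def _basis_matrix(t: np.ndarray, p: int, params: np.ndarray, deriv: int = 0) -> np.ndarray:
    n = len(t) - p - 1
    if deriv == 0:
        return BSpline.design_matrix(params, t, p).toarray()
    M = np.empty((len(params), n))
    for j in range(n):
        coef = np.zeros(n)
        coef[j] = 1.0
        M[:, j] = BSpline(t, coef, p).derivative(deriv)(params)
    return M


def interpolate_curve(
    points,
    degree: int = 3,
    end_tangents: tuple | None = None,
    params: np.ndarray | None = None,
    knots: KnotVector | None = None,
) -> NurbsCurve:
    """Global interpolation with chord-length parameterization.

    ``end_tangents`` is an optional pair of derivative vectors (with respect
    to the normalized parameter) imposed at the two ends. ``params`` may
    supply explicit parameter values, which the surface-network builders use
    to make curve families parametrically compatible, and ``knots`` an
    explicit knot vector (the collocation must then satisfy
    Schoenberg-Whitney, e.g. points sampled at the Greville abscissae).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("at least two interpolation points required")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("coincident consecutive interpolation points")
    if end_tangents is None and pts.shape[0] < degree + 1:
        raise ValueError(
            f"need at least degree+1={degree + 1} points (or end tangents)"
        )
    if params is None:
        params = _chord_params(pts)
    else:
        params = np.asarray(params, dtype=float)
        if params.shape != (len(pts),) or np.any(np.diff(params) <= 0):
            raise ValueError("params must be strictly increasing, one per point")
        params = (params - params[0]) / (params[-1] - params[0])

    if end_tangents is None:
        n_ctrl = len(pts)
        if knots is not None:
            if len(knots.values) - knots.degree - 1 != n_ctrl:
                raise ValueError("explicit knot vector inconsistent with point count")
            kv = knots
        else:
            kv = _averaged_knots(params, n_ctrl, degree)
        A = _basis_matrix(kv.values, degree, params)
        rhs = pts
    else:
        d0, d1 = (np.asarray(v, dtype=float) for v in end_tangents)
        n_ctrl = len(pts) + 2
        ext = np.concatenate([[params[0]], params, [params[-1]]])
        kv = _averaged_knots(ext, n_ctrl, degree)
        A = np.zeros((n_ctrl, n_ctrl))
        rhs = np.zeros((n_ctrl, 3))
        P = _basis_matrix(kv.values, degree, params)
        D = _basis_matrix(kv.values, degree, params[[0, -1]], deriv=1)
        A[0], rhs[0] = P[0], pts[0]
        A[1], rhs[1] = D[0], d0
        A[2:-2], rhs[2:-2] = P[1:-1], pts[1:-1]
        A[-2], rhs[-2] = D[1], d1
        A[-1], rhs[-1] = P[-1], pts[-1]

    try:
        ctrl = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
        raise np.linalg.LinAlgError(
            f"singular interpolation system for {len(pts)} points: {exc}"
        ) from exc
    curve = NurbsCurve(ctrl, kv)
    resid = np.linalg.norm(curve.evaluate(params) - pts, axis=1).max()
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"interpolation residual {resid:.2e} mm exceeds tolerance"
        )
    return curve


# ---------------------------------------------------------------------------
# splitting / joining


def split_curve(curve: NurbsCurve, u: float) -> tuple[NurbsCurve, NurbsCurve]:
    """Split into two clamped curves whose union reproduces the original."""
    lo, hi = curve.domain
    if not (lo < u < hi):
        raise ValueError("split parameter must be strictly interior")
    p = curve.degree
    mult = int(np.sum(curve.knots.values == u))
    c = insert_knot(curve, u, times=p - mult) if mult < p else curve
    t = c.knots.values
    hw = c._homogeneous()
    s = int(np.searchsorted(t, u, side="left"))
    # left piece: control points 0..s-1, knots t[0..s+p-1] + [u]
    left_t = np.concatenate([t[:s], [u] * (p + 1)])
    right_t = np.concatenate([[u] * (p + 1), t[s + p:]])
    left_c, right_c = hw[:s], hw[s - 1:]
    wl, wr = left_c[:, 3], right_c[:, 3]
    left = NurbsCurve(left_c[:, :3] / wl[:, None], KnotVector(left_t, p), wl)
    right = NurbsCurve(right_c[:, :3] / wr[:, None], KnotVector(right_t, p), wr)
    return left.normalized(), right.normalized()


def join_curves(a: NurbsCurve, b: NurbsCurve, tol: float = 1e-6) -> NurbsCurve:
    """C0 join of two curves sharing an endpoint (a's end with b's start)."""
    gap = float(np.linalg.norm(a.evaluate(a.domain[1]) - b.evaluate(b.domain[0])))
    if gap > tol:
        raise ValueError(f"curves do not share an endpoint (gap {gap:.3e} mm)")
    if a.degree != b.degree:
        raise ValueError("joined curves must share a degree")
    p = a.degree
    a, b = a.normalized(), b.normalized()
    # length-weighted parameter split keeps parameterization roughly uniform
    la, lb = curve_length(a), curve_length(b)
    s = la / (la + lb)
    ta = a.knots.values * s
    tb = s + b.knots.values * (1 - s)
    t = np.concatenate([ta[:-1], tb[p + 1:]])  # junction multiplicity p (C0)
    cp = np.vstack([a.control_points, b.control_points[1:]])
    w = np.concatenate([a.weights, b.weights[1:] * (a.weights[-1] / b.weights[0])])
    return NurbsCurve(cp, KnotVector(t, p), w)


# ---------------------------------------------------------------------------
# intersection


def intersect_curves(
    a: NurbsCurve, b: NurbsCurve, tol: float = 1e-6, n_seed: int = 64
) -> tuple[float, float, np.ndarray, float]:
    """Closest-approach pair ``(u, v, point, residual)`` between two curves.

    Coarse sampling on an ``n_seed`` grid seeds a bounded least-squares polish
    of the separation vector. Raises :class:`IntersectionNotFound` when the
    curves stay farther apart than ``tol``.
    """
    ua = np.linspace(*a.domain, n_seed)
    vb = np.linspace(*b.domain, n_seed)
    Pa, Pb = a.evaluate(ua), b.evaluate(vb)
    d2 = np.sum((Pa[:, None, :] - Pb[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)

    def fun(x):
        return a.evaluate(x[0]) - b.evaluate(x[1])

    def jac(x):
        return np.column_stack([a.derivative(x[0]), -b.derivative(x[1])])

    res = optimize.least_squares(
        fun,
        x0=[ua[i], vb[j]],
        jac=jac,
        bounds=([a.domain[0], b.domain[0]], [a.domain[1], b.domain[1]]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    u, v = res.x
    # Gauss-Newton polish to machine precision (least_squares stops early)
    for _ in range(25):
        f = a.evaluate(u) - b.evaluate(v)
        J = np.column_stack([a.derivative(u), -b.derivative(v)])
        JTJ = J.T @ J
        if np.linalg.cond(JTJ) > 1e14:
            break
        du, dv = np.linalg.solve(JTJ, -J.T @ f)
        u2 = min(max(u + du, a.domain[0]), a.domain[1])
        v2 = min(max(v + dv, b.domain[0]), b.domain[1])
        if abs(u2 - u) < 1e-16 and abs(v2 - v) < 1e-16:
            u, v = u2, v2
            break
        u, v = u2, v2
    pa, pb = a.evaluate(u), b.evaluate(v)
    residual = float(np.linalg.norm(pa - pb))
    if residual > tol:
        raise IntersectionNotFound(
            f"closest approach {residual:.3e} mm exceeds tolerance {tol:g} mm"
        )
    return float(u), float(v), (pa + pb) / 2.0, residual


# ---------------------------------------------------------------------------
# surfaces


@dataclass(frozen=True)
class NurbsSurface:
    """Tensor-product NURBS surface; net is (nu, nv, 3), weights (nu, nv)."""

    control_points: np.ndarray
    knots_u: KnotVector
    knots_v: KnotVector
    weights: np.ndarray | None = None

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 3 or cp.shape[2] != 3:
            raise ValueError("control net must have shape (nu, nv, 3)")
        w = self.weights
        w = np.ones(cp.shape[:2]) if w is None else np.asarray(w, dtype=float)
        if w.shape != cp.shape[:2]:
            raise ValueError("weight grid must match the control net")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        nu_exp = len(self.knots_u.values) - self.knots_u.degree - 1
        nv_exp = len(self.knots_v.values) - self.knots_v.degree - 1
        if cp.shape[:2] != (nu_exp, nv_exp):
            raise ValueError(
                f"net shape {cp.shape[:2]} inconsistent with knots "
                f"(expected {(nu_exp, nv_exp)})"
            )
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "weights", w)

    @property
    def degrees(self) -> tuple[int, int]:
        return self.knots_u.degree, self.knots_v.degree

    def _homogeneous(self) -> np.ndarray:
        w = self.weights[:, :, None]
        return np.concatenate([self.control_points * w, w], axis=2)

    def evaluate_grid(self, us, vs) -> np.ndarray:
        """Surface points on the tensor grid ``us`` x ``vs``; (len(us), len(vs), 3)."""
        us = np.atleast_1d(np.asarray(us, dtype=float))
        vs = np.atleast_1d(np.asarray(vs, dtype=float))
        hw = self._homogeneous()  # (nu, nv, 4)
        su = BSpline(self.knots_u.values, hw, self.knots_u.degree)
        mid = su(us)  # (len(us), nv, 4)
        sv = BSpline(self.knots_v.values, np.swapaxes(mid, 0, 1), self.knots_v.degree)
        out = np.swapaxes(sv(vs), 0, 1)  # (len(us), len(vs), 4)
        return out[:, :, :3] / out[:, :, 3:4]

    def evaluate(self, u: float, v: float) -> np.ndarray:
        return self.evaluate_grid([u], [v])[0, 0]

    def iso_curve(self, direction: str, param: float) -> NurbsCurve:
        """Extract the iso-parameter curve at ``param`` along ``direction``.

        ``direction='u'`` fixes u and returns a curve in v, and vice versa.
        """
        hw = self._homogeneous()
        if direction == "u":
            sp = BSpline(self.knots_u.values, hw, self.knots_u.degree)
            coef = sp(param)  # (nv, 4)
            kv = self.knots_v
        elif direction == "v":
            sp = BSpline(self.knots_v.values, np.swapaxes(hw, 0, 1), self.knots_v.degree)
            coef = sp(param)  # (nu, 4)
            kv = self.knots_u
        else:
            raise ValueError("direction must be 'u' or 'v'")
        w = coef[:, 3]
        return NurbsCurve(coef[:, :3] / w[:, None], kv, w)

    def transformed(self, fn: Callable[[np.ndarray], np.ndarray]) -> "NurbsSurface":
        flat = self.control_points.reshape(-1, 3)
        return replace(self, control_points=fn(flat).reshape(self.control_points.shape))

    def _map_rows(self, op) -> "NurbsSurface":
        """Apply a (t, c, p) -> (t, c) spline op along u (rows of the net)."""
        hw = self._homogeneous()
        nu, nv, _ = hw.shape
        t0 = self.knots_u.values
        p = self.knots_u.degree
        t, c = op(t0.copy(), hw.reshape(nu, nv * 4), p)
        c = c.reshape(len(c), nv, 4)
        w = c[:, :, 3]
        return NurbsSurface(
            c[:, :, :3] / w[:, :, None], KnotVector(t, p), self.knots_v, w
        )

    def _swap_uv(self) -> "NurbsSurface":
        return NurbsSurface(
            np.swapaxes(self.control_points, 0, 1),
            self.knots_v,
            self.knots_u,
            np.swapaxes(self.weights, 0, 1),
        )

    def _refine_once(self) -> "NurbsSurface":
        s = self._map_rows(_refine_knots_once)
        s = s._swap_uv()._map_rows(_refine_knots_once)._swap_uv()
        return s

    def to_dict(self) -> dict:
        return {
            "type": "surface",
            "degree_u": self.knots_u.degree,
            "degree_v": self.knots_v.degree,
            "knots_u": self.knots_u.values.tolist(),
            "knots_v": self.knots_v.values.tolist(),
            "control_points": self.control_points.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NurbsSurface":
        return cls(
            np.asarray(d["control_points"], dtype=float),
            KnotVector(np.asarray(d["knots_u"], dtype=float), int(d["degree_u"])),
            KnotVector(np.asarray(d["knots_v"], dtype=float), int(d["degree_v"])),
            np.asarray(d["weights"], dtype=float),
        )


# ---------------------------------------------------------------------------
# loft / Gordon


def _interp_coeffs_1d(params: np.ndarray, degree: int) -> tuple[KnotVector, np.ndarray]:
    """Knots and inverse collocation matrix for interpolation at ``params``."""
    kv = _averaged_knots(params, len(params), degree)
    A = _basis_matrix(kv.values, degree, params)
    return kv, np.linalg.inv(A)


def loft(
    curves: Sequence[NurbsCurve],
    v_params: np.ndarray | None = None,
    degree_v: int | None = None,
) -> NurbsSurface:
    """Skinned surface interpolating each section curve as an iso-v line."""
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("loft needs at least two section curves")
    spread = max(
        float(np.abs(a.control_points - b.control_points).max())
        for a, b in zip(curves[:-1], curves[1:])
        if a.control_points.shape == b.control_points.shape
    ) if all(c.control_points.shape == curves[0].control_points.shape for c in curves) else np.inf
    if spread == 0.0:
        import warnings

        warnings.warn("lofting identical curves produces a degenerate surface")
    compat = _make_compatible(curves)
    hom = np.stack([c._homogeneous() for c in compat], axis=1)  # (nu, nsec, 4)
    if v_params is None:
        # chord-length stations from the average control polygon
        mids = np.stack([c.evaluate(np.linspace(0, 1, 7)).mean(axis=0) for c in compat])
        try:
            v_params = _chord_params(mids)
        except ValueError:
            v_params = np.linspace(0.0, 1.0, len(compat))
    else:
        v_params = np.asarray(v_params, dtype=float)
        v_params = (v_params - v_params[0]) / (v_params[-1] - v_params[0])
    if degree_v is None:
        degree_v = min(3, len(compat) - 1)
    kv_v, Ainv = _interp_coeffs_1d(v_params, degree_v)
    net = np.einsum("js,isk->ijk", Ainv, hom)  # solve per u-row across sections
    w = net[:, :, 3]
    return NurbsSurface(
        net[:, :, :3] / w[:, :, None], compat[0].knots, kv_v, w
    )


@dataclass
class CurveNetwork:
    """Bidirectional curve network: u-curves (constant v) and v-curves (constant u).

    ``u_stations[i]`` is the common parameter at which every u-curve meets
    v-curve ``i``; ``v_stations[j]`` likewise on the v-curves. ``grid[i, j]``
    holds the crossing of v-curve i with u-curve j.
    """

    u_curves: list[NurbsCurve]
    v_curves: list[NurbsCurve]
    u_stations: np.ndarray
    v_stations: np.ndarray
    grid: np.ndarray  # (n_v_curves, n_u_curves, 3)
    max_residual: float

    @classmethod
    def build(
        cls,
        u_curves: Sequence[NurbsCurve],
        v_curves: Sequence[NurbsCurve],
        tol: float = 1e-6,
    ) -> "CurveNetwork":
        u_curves = [c.normalized() for c in u_curves]
        v_curves = [c.normalized() for c in v_curves]
        n_i, n_j = len(v_curves), len(u_curves)
        S = np.empty((n_i, n_j))  # param on u-curve j at v-curve i
        T = np.empty((n_i, n_j))  # param on v-curve i at u-curve j
        G = np.empty((n_i, n_j, 3))
        failures = []
        worst = 0.0
        for i, vc in enumerate(v_curves):
            for j, uc in enumerate(u_curves):
                try:
                    s, t, pt, resid = intersect_curves(uc, vc, tol=tol)
                except IntersectionNotFound as exc:
                    failures.append((i, j, str(exc)))
                    continue
                S[i, j], T[i, j], G[i, j] = s, t, pt
                worst = max(worst, resid)
        if failures:
            pairs = ", ".join(f"(v{i}, u{j})" for i, j, _ in failures)
            raise NetworkError(f"non-intersecting network pairs: {pairs}")
        u_st = S.mean(axis=1)
        v_st = T.mean(axis=0)
        if np.any(np.diff(np.argsort(u_st)) != 1) or np.any(np.diff(u_st) <= 0):
            order = np.argsort(u_st)
            u_st = u_st[order]
            v_curves = [v_curves[k] for k in order]
            G = G[order]
        if np.any(np.diff(v_st) <= 0):
            order = np.argsort(v_st)
            v_st = v_st[order]
            u_curves = [u_curves[k] for k in order]
            G = G[:, order]
        return cls(u_curves, v_curves, u_st, v_st, G, worst)


def gordon_surface(net: CurveNetwork, tol: float = 1e-6) -> NurbsSurface:
    """Gordon construction: loft of u-curves + loft of v-curves − tensor patch.

    Requires a compatible, non-rational network: the surface then interpolates
    every network curve. Parameter u runs along the u-curves, v along the
    v-curves.
    """
    for c in net.u_curves + net.v_curves:
        if not np.allclose(c.weights, 1.0):
            raise NetworkError("Gordon combination requires non-rational curves")
    if net.max_residual > tol:
        raise NetworkError(
            f"network residual {net.max_residual:.3e} mm exceeds {tol:g} mm"
        )
    # stations must be pinned to the ends for the combination to telescope
    u_st, v_st = net.u_stations, net.v_stations

    s1 = loft(net.u_curves, v_params=v_st)  # u along curves, v across
    s2 = loft(net.v_curves, v_params=u_st)._swap_uv()  # now u across, v along
    # tensor-product interpolation of the grid
    du = min(3, len(u_st) - 1)
    dv = min(3, len(v_st) - 1)
    kv_u, Au_inv = _interp_coeffs_1d(np.asarray(u_st), du)
    kv_v, Av_inv = _interp_coeffs_1d(np.asarray(v_st), dv)
    # grid is (n_v_curves=i over u direction, n_u_curves=j over v direction)
    ctrl = np.einsum("ia,jb,abk->ijk", Au_inv, Av_inv, net.grid)
    t = NurbsSurface(ctrl, kv_u, kv_v)

    surfaces = [s1, s2, t]
    signs = [1.0, 1.0, -1.0]
    # unify degrees then knots in both directions; all nets are polynomial
    pu = max(s.knots_u.degree for s in surfaces)
    pv = max(s.knots_v.degree for s in surfaces)

    def elevate_u(s: NurbsSurface, target: int) -> NurbsSurface:
        while s.knots_u.degree < target:
            hw = s._homogeneous()
            nu, nv, _ = hw.shape
            tk2, c2, q = _elevate_once(s.knots_u.values.copy(), hw.reshape(nu, nv * 4), s.knots_u.degree)
            c2 = c2.reshape(len(c2), nv, 4)
            w = c2[:, :, 3]
            s = NurbsSurface(c2[:, :, :3] / w[:, :, None], KnotVector(tk2, q), s.knots_v, w)
        return s

    surfaces = [elevate_u(s, pu) for s in surfaces]
    surfaces = [elevate_u(s._swap_uv(), pv)._swap_uv() for s in surfaces]
    tu = _union_knots([s.knots_u.values for s in surfaces], pu)
    tv = _union_knots([s.knots_v.values for s in surfaces], pv)

    def to_knots(s: NurbsSurface) -> NurbsSurface:
        s = s._map_rows(lambda tk, c, p: _merge_to_knots(tk, c, p, tu))
        s = s._swap_uv()._map_rows(lambda tk, c, p: _merge_to_knots(tk, c, p, tv))._swap_uv()
        return s

    surfaces = [to_knots(s) for s in surfaces]
    combo = sum(
        sgn * s.control_points for sgn, s in zip(signs, surfaces)
    )
    return NurbsSurface(
        combo, KnotVector(tu, pu), KnotVector(tv, pv)
    )


# ---------------------------------------------------------------------------
# measures


def curve_length(curve: NurbsCurve, rel_tol: float = 1e-9) -> float:
    """Arc length by adaptive Gauss quadrature over the knot spans."""
    lo, hi = curve.domain
    breaks = np.unique(curve.knots.values)

    def speed(u):
        d = curve.derivative(np.atleast_1d(u))
        return np.linalg.norm(d, axis=1)

    total, _ = integrate.quad(
        lambda u: float(speed(u)[0]),
        lo,
        hi,
        points=breaks[1:-1] if len(breaks) > 2 else None,
        limit=50 + 10 * len(breaks),
        epsrel=rel_tol,
    )
    return float(total)


def element_count(g):
    """Number of non-degenerate knot spans (per direction for surfaces)."""
    if isinstance(g, NurbsCurve):
        return g.knots.n_elements()
    if isinstance(g, NurbsSurface):
        return g.knots_u.n_elements(), g.knots_v.n_elements()
    raise TypeError(f"no element count for {type(g).__name__}")


def arc_through_points(p1, p2, p3) -> NurbsCurve:
    """Exact rational-quadratic circular arc from p1 through p2 to p3.

    The three points must not be collinear; the arc is the minor circumcircle
    arc (sweep < 180 degrees assumed, which valve interior arcs satisfy).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1, v2 = p2 - p1, p3 - p1
    n = np.cross(v1, v2)
    nn = np.linalg.norm(n)
    if nn < 1e-12 * max(np.linalg.norm(v1), np.linalg.norm(v2)):
        raise ValueError("arc points are collinear")
    n = n / nn
    # circumcenter via perpendicular bisectors in the plane
    a, b, c = np.linalg.norm(p3 - p2), np.linalg.norm(p3 - p1), np.linalg.norm(p2 - p1)
    a2, b2, c2 = a * a, b * b, c * c
    w1 = a2 * (b2 + c2 - a2)
    w2 = b2 * (c2 + a2 - b2)
    w3 = c2 * (a2 + b2 - c2)
    center = (w1 * p1 + w2 * p2 + w3 * p3) / (w1 + w2 + w3)
    r = float(np.linalg.norm(p1 - center))
    u1, u3 = (p1 - center) / r, (p3 - center) / r
    cos_sweep = float(np.clip(np.dot(u1, u3), -1.0, 1.0))
    half = np.arccos(cos_sweep) / 2.0
    w_mid = float(np.cos(half))
    if w_mid <= 1e-9:
        raise ValueError("arc sweep too close to 180 degrees")
    # middle control point: intersection of end tangents
    t1, t3 = np.cross(n, u1), np.cross(n, u3)
    # solve p1 + s*t1 = p3 + q*t3 in the plane (least squares; exact here)
    Amat = np.column_stack([t1, -t3])
    sol, *_ = np.linalg.lstsq(Amat, p3 - p1, rcond=None)
    mid = p1 + sol[0] * t1
    ctrl = np.vstack([p1, mid, p3])
    weights = np.array([1.0, w_mid, 1.0])
    kv = KnotVector(np.array([0.0, 0, 0, 1, 1, 1]), 2)
    return NurbsCurve(ctrl, kv, weights)
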