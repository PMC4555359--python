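"""Parametric 3D refractive-index scenes for blood-cell optical models.

A scene is a piecewise-constant refractive-index field assembled from
geometric parts (ellipsoids, spheres, half-ellipsoid pairs, biconcave discs
and swept tubes).  Each part carries a priority; at any point the scene's
index is that of the highest-priority part containing the point (nucleus
overrides cytoplasm overrides medium).  All lengths are in micrometres, the
coordinate frame is right-handed with the origin at the cell centre and the
z axis along the optical axis of the first view.

The built-in builders reproduce the standard optical models of the six blood
cell types: a biconcave-disc red blood cell and five white-blood-cell models
(lymphocyte, eosinophil, neutrophil, monocyte, basophil) consisting of a
12 μm membrane sphere with internal nuclear parts, plus the two-half-ellipsoid
monocyte used for quantitative verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometricPart",
    "Ellipsoid",
    "HalfEllipsoidPair",
    "BiconcaveDisc",
    "SweptTube",
    "Arc",
    "RefractiveIndexScene",
    "index_at",
    "build_rbc",
    "build_lymphocyte",
    "build_eosinophil",
    "build_neutrophil",
    "build_monocyte_fig1",
    "build_basophil",
    "build_monocyte_edward",
    "build_two_ellipsoid_cell",
    "scene_to_config",
    "scene_from_config",
    "save_scene",
    "load_scene",
    "voxelize",
]

# refractive indices used throughout; only the two-half-ellipsoid monocyte
# values are documented presets, the rest are assumptions (see docs/methods.md)
N_MEDIUM = 1.003
N_CYTOPLASM = 1.37
N_NUCLEUS = 1.39
N_RBC = 1.40

_AXES = {"x": 0, "y": 1, "z": 2}


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def _as_vec3(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"expected finite 3-vector, got {v!r}")
    return a


@dataclass(frozen=True)
class GeometricPart:
    """Base class for homogeneous scene parts.

    Parameters common to every part: ``center`` (μm), ``refractive_index``
    (dimensionless, > 1) and ``priority`` (higher wins where parts overlap).
    """

    center: np.ndarray
    refractive_index: float
    priority: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_vec3(self.center))
        if self.refractive_index <= 1.0:
            raise ValueError(
                f"refractive_index must exceed 1.0, got {self.refractive_index}"
            )

    # --- geometry interface -------------------------------------------------
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (N, 3) array of points (μm)."""
        raise NotImplementedError

    def ray_intervals(
        self, u: np.ndarray, v: np.ndarray, axis: int
    ) -> np.ndarray | None:
        """Analytic ray/part intersection intervals.

        ``u``, ``v`` are flat arrays of the two in-plane coordinates of rays
        parallel to coordinate ``axis`` (the remaining coordinate).  Returns an
        (N, K, 2) array of [t_enter, t_exit] intervals (NaN rows where the ray
        misses), or ``None`` when no closed form exists and the caller should
        fall back to sampled membership.
        """
        return None

    def aabb(self) -> np.ndarray:
        """Axis-aligned bounding box, shape (3, 2)."""
        raise NotImplementedError

    def kind(self) -> str:
        raise NotImplementedError

    def params(self) -> dict:
        raise NotImplementedError


def _ray_plane_coords(u: np.ndarray, v: np.ndarray, axis: int) -> tuple[int, int]:
    """In-plane coordinate indices for rays along ``axis`` (sorted order)."""
    others = [i for i in range(3) if i != axis]
    return others[0], others[1]


@dataclass(frozen=True)
class Ellipsoid(GeometricPart):
    """Axis-aligned or rotated ellipsoid (spheres are the equal-axes case).

    ``rotation_deg`` are intrinsic rotations about x, y, z applied in that
    order, in degrees.
    """

    semi_axes: np.ndarray = field(default_factory=lambda: np.ones(3))
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "semi_axes", _as_vec3(self.semi_axes))
        _check_positive(
            semi_a=self.semi_axes[0], semi_b=self.semi_axes[1], semi_c=self.semi_axes[2]
        )
        rx, ry, rz = (float(r) for r in self.rotation_deg)
        object.__setattr__(self, "rotation_deg", (rx, ry, rz))
        R = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
        A = R @ np.diag(1.0 / self.semi_axes**2) @ R.T
        object.__setattr__(self, "_A", A)

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        q = np.einsum("...i,ij,...j->...", d, self._A, d)
        return q <= 1.0 + 1e-12

    def ray_intervals(self, u, v, axis):
        iu, iv = _ray_plane_coords(u, v, axis)
        d = np.zeros((u.size, 3))
        d[:, iu] = u - self.center[iu]
        d[:, iv] = v - self.center[iv]
        d[:, axis] = -self.center[axis]
        A = self._A
        e = np.zeros(3)
        e[axis] = 1.0
        a = A[axis, axis]
        b = 2.0 * d @ (A @ e)
        c = np.einsum("ni,ij,nj->n", d, A, d) - 1.0
        disc = b * b - 4 * a * c
        out = np.full((u.size, 1, 2), np.nan)
        hit = disc > 0
        sq = np.sqrt(disc[hit])
        out[hit, 0, 0] = (-b[hit] - sq) / (2 * a)
        out[hit, 0, 1] = (-b[hit] + sq) / (2 * a)
        return out

    def aabb(self) -> np.ndarray:
        # support function of an ellipsoid along the coordinate axes
        R = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()
        M = R @ np.diag(self.semi_axes)
        ext = np.sqrt((M**2).sum(axis=1))
        return np.stack([self.center - ext, self.center + ext], axis=1)

    def kind(self) -> str:
        return "sphere" if np.ptp(self.semi_axes) == 0 else "ellipsoid"

    def params(self) -> dict:
        return {
            "semi_axes": [float(s) for s in self.semi_axes],
            "rotation_deg": list(self.rotation_deg),
        }


def sphere(center, radius, refractive_index, priority) -> Ellipsoid:
    return Ellipsoid(
        center=center,
        refractive_index=refractive_index,
        priority=priority,
        semi_axes=(radius, radius, radius),
    )


@dataclass(frozen=True)
class HalfEllipsoidPair(GeometricPart):
    """Two half-ellipsoids sharing the equatorial plane z = center_z.

    The upper half (z ≥ center_z) has semi-axes (a, b, c_top), the lower half
    (a, b, c_bottom).  This is the membrane shape of the two-half-ellipsoid
    monocyte model.
    """

    a: float = 6.0
    b: float = 6.0
    c_top: float = 4.5
    c_bottom: float = 3.5

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_positive(a=self.a, b=self.b, c_top=self.c_top, c_bottom=self.c_bottom)

    def _s2(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """1 - x̄²/a² - ȳ²/b² (clipped at 0)."""
        xb = (x - self.center[0]) / self.a
        yb = (y - self.center[1]) / self.b
        return np.clip(1.0 - xb * xb - yb * yb, 0.0, None)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        z = p[..., 2] - self.center[2]
        c = np.where(z >= 0, self.c_top, self.c_bottom)
        xb = (p[..., 0] - self.center[0]) / self.a
        yb = (p[..., 1] - self.center[1]) / self.b
        q = xb * xb + yb * yb + (z / c) ** 2
        return q <= 1.0 + 1e-12

    def ray_intervals(self, u, v, axis):
        out = np.full((u.size, 1, 2), np.nan)
        if axis == 2:  # chord along z: [-c_bottom·s, +c_top·s] about center_z
            s = np.sqrt(self._s2(u, v))
            hit = s > 0
            out[hit, 0, 0] = self.center[2] - self.c_bottom * s[hit]
            out[hit, 0, 1] = self.center[2] + self.c_top * s[hit]
            return out
        # chord along x or y: single interval from whichever half owns z
        if axis == 0:
            y, z = u, v
            semi, cen = self.a, self.center[0]
            tb = (y - self.center[1]) / self.b
        else:
            x, z = u, v
            semi, cen = self.b, self.center[1]
            tb = (x - self.center[0]) / self.a
        zb = z - self.center[2]
        c = np.where(zb >= 0, self.c_top, self.c_bottom)
        s2 = np.clip(1.0 - tb * tb - (zb / c) ** 2, 0.0, None)
        s = np.sqrt(s2)
        hit = s > 0
        out[hit, 0, 0] = cen - semi * s[hit]
        out[hit, 0, 1] = cen + semi * s[hit]
        return out

    def aabb(self) -> np.ndarray:
        lo = self.center - np.array([self.a, self.b, self.c_bottom])
        hi = self.center + np.array([self.a, self.b, self.c_top])
        return np.stack([lo, hi], axis=1)

    def kind(self) -> str:
        return "half_ellipsoid_pair"

    def params(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c_top": self.c_top,
            "c_bottom": self.c_bottom,
        }


def _biconcave_coeffs(center_thickness: float, edge_thickness: float):
    """Coefficients of the cosine-sum thickness profile.

    h(ρ) = A0 + A1·cos(πρ) + A2·cos(2πρ) on ρ = r/R ∈ [0, 1], constrained to
    h(0) = center_thickness, h(1) = 0 and max h = edge_thickness attained at an
    interior radius.  The constraints fix A1 = t_c/2 and A0 + A2 = t_c/2; the
    dimple condition gives a closed-form A2.
    """
    tc, te = center_thickness, edge_thickness
    a1 = tc / 2.0
    if te == tc:
        # degenerate: flat maximum at the centre
        return tc / 2.0, a1, 0.0
    # solve 2u² − (te − tc/2)·u + tc²/32 = 0 for u = −A2 (take the + root so
    # the interior maximum exists: cos(πρm) = A1/(4u) must be ≤ 1)
    p = te - tc / 2.0
    disc = p * p - tc * tc / 4.0
    if disc < 0:
        raise ValueError("edge_thickness too close to center_thickness/2")
    u = (p + math.sqrt(disc)) / 4.0
    a2 = -u
    a0 = tc / 2.0 - a2
    return a0, a1, a2


@dataclass(frozen=True)
class BiconcaveDisc(GeometricPart):
    """Axisymmetric biconcave disc (red-blood-cell shape), axis along z.

    The axial thickness profile is a cosine sum constrained to the centre
    thickness, the edge (maximum) thickness and zero thickness at the rim.
    """

    diameter: float = 7.7
    center_thickness: float = 1.0
    edge_thickness: float = 2.0

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_positive(
            diameter=self.diameter,
            center_thickness=self.center_thickness,
            edge_thickness=self.edge_thickness,
        )
        if self.edge_thickness < self.center_thickness:
            raise ValueError("edge_thickness must be >= center_thickness")
        object.__setattr__(
            self,
            "_coeffs",
            _biconcave_coeffs(self.center_thickness, self.edge_thickness),
        )

    def thickness_profile(self, r: np.ndarray) -> np.ndarray:
        """Axial thickness h(r) (μm) at in-plane radius r (μm)."""
        a0, a1, a2 = self._coeffs
        rho = np.clip(np.asarray(r, dtype=float) / (self.diameter / 2.0), 0.0, None)
        h = a0 + a1 * np.cos(np.pi * rho) + a2 * np.cos(2 * np.pi * rho)
        return np.where(rho <= 1.0, np.clip(h, 0.0, None), 0.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float) - self.center
        r = np.hypot(p[..., 0], p[..., 1])
        return np.abs(p[..., 2]) <= self.thickness_profile(r) / 2.0

    def ray_intervals(self, u, v, axis):
        if axis != 2:
            return None  # lateral chords have no closed form; sampled
        r = np.hypot(u - self.center[0], v - self.center[1])
        h = self.thickness_profile(r)
        out = np.full((u.size, 1, 2), np.nan)
        hit = h > 0
        out[hit, 0, 0] = self.center[2] - h[hit] / 2.0
        out[hit, 0, 1] = self.center[2] + h[hit] / 2.0
        return out

    def aabb(self) -> np.ndarray:
        R = self.diameter / 2.0
        he = self.edge_thickness / 2.0
        lo = self.center - np.array([R, R, he])
        hi = self.center + np.array([R, R, he])
        return np.stack([lo, hi], axis=1)

    def kind(self) -> str:
        return "biconcave_disc"

    def params(self) -> dict:
        return {
            "diameter": self.diameter,
            "center_thickness": self.center_thickness,
            "edge_thickness": self.edge_thickness,
        }


@dataclass(frozen=True)
class Arc:
    """Circular arc in a plane parallel to x-y, for swept-tube centrelines.

    Angles in degrees, measured from +x towards +y about ``center``.
    """

    center: tuple[float, float, float]
    radius: float
    theta_start_deg: float
    theta_end_deg: float

    def closest_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest point of the arc."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center, dtype=float)
        dx = p[..., 0] - c[0]
        dy = p[..., 1] - c[1]
        dz = p[..., 2] - c[2]
        ang = np.degrees(np.arctan2(dy, dx))
        t0, t1 = self.theta_start_deg, self.theta_end_deg
        # clamp angle into [t0, t1] modulo 360
        rel = (ang - t0) % 360.0
        span = (t1 - t0) % 360.0
        if span == 0.0:
            span = 360.0
        inside = rel <= span
        # distance for the clamped-inside case
        rho = np.hypot(dx, dy)
        d_in = np.hypot(rho - self.radius, dz)
        # endpoint distances (rounded capsule ends)
        e0 = c + self.radius * np.array(
            [math.cos(math.radians(t0)), math.sin(math.radians(t0)), 0.0]
        )
        e1 = c + self.radius * np.array(
            [math.cos(math.radians(t0 + span)), math.sin(math.radians(t0 + span)), 0.0]
        )
        d0 = np.linalg.norm(p - e0, axis=-1)
        d1 = np.linalg.norm(p - e1, axis=-1)
        d_end = np.minimum(d0, d1)
        return np.where(inside, d_in, d_end)


@dataclass(frozen=True)
class SweptTube(GeometricPart):
    """Tube of constant radius swept along one or more circular arcs.

    Used for the U-shaped (one 180° arc) and S-shaped (two joined arcs)
    nuclei.  Ends are rounded (capsule-style), which keeps the solid closed.
    ``center`` shifts the whole arc assembly.
    """

    arcs: tuple[Arc, ...] = ()
    tube_radius: float = 1.5

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_positive(tube_radius=self.tube_radius)
        if not self.arcs:
            raise ValueError("SweptTube needs at least one arc")

    def _distance(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float) - self.center
        d = np.full(p.shape[:-1], np.inf)
        for arc in self.arcs:
            d = np.minimum(d, arc.closest_distance(p))
        return d

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self._distance(points) <= self.tube_radius

    def aabb(self) -> np.ndarray:
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for arc in self.arcs:
            c = np.asarray(arc.center)
            r = arc.radius + self.tube_radius
            lo = np.minimum(lo, c - np.array([r, r, self.tube_radius]))
            hi = np.maximum(hi, c + np.array([r, r, self.tube_radius]))
        return np.stack([self.center + lo, self.center + hi], axis=1)

    def kind(self) -> str:
        return "swept_tube"

    def params(self) -> dict:
        return {
            "tube_radius": self.tube_radius,
            "arcs": [
                {
                    "center": list(a.center),
                    "radius": a.radius,
                    "theta_start_deg": a.theta_start_deg,
                    "theta_end_deg": a.theta_end_deg,
                }
                for a in self.arcs
            ],
        }


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------


@dataclass
class RefractiveIndexScene:
    """Composable piecewise-constant 3D refractive-index field."""

    parts: list[GeometricPart]
    medium_index: float = N_MEDIUM
    bounds: np.ndarray | None = None  # (3, 2) μm
    name: str = ""

    def __post_init__(self) -> None:
        if self.bounds is None and self.parts:
            boxes = np.stack([p.aabb() for p in self.parts])
            lo = boxes[:, :, 0].min(axis=0) - 1.0
            hi = boxes[:, :, 1].max(axis=0) + 1.0
            self.bounds = np.stack([lo, hi], axis=1)
        elif self.bounds is None:
            self.bounds = np.array([[-1.0, 1.0]] * 3)
        else:
            self.bounds = np.asarray(self.bounds, dtype=float).reshape(3, 2)

    def sorted_parts(self) -> list[GeometricPart]:
        """Parts in ascending priority (later entries override earlier)."""
        return sorted(self.parts, key=lambda p: p.priority)

    def index_at(self, points) -> np.ndarray | float:
        return index_at(self, points)


def index_at(scene: RefractiveIndexScene, points) -> np.ndarray | float:
    """Refractive index of the scene at one point or an (..., 3) array."""
    p = np.asarray(points, dtype=float)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    if not np.all(np.isfinite(p)):
        raise ValueError("points must be finite")
    out = np.full(p.shape[:-1], scene.medium_index, dtype=float)
    for part in scene.sorted_parts():
        out[part.contains(p)] = part.refractive_index
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _check_nucleus_inside(
    nuclear_parts: Sequence[GeometricPart],
    membrane: GeometricPart,
    n_surface: int = 2000,
) -> None:
    """Reject nuclear geometry extending outside the membrane part.

    Checks a deterministic quasi-random sample of each nuclear part's
    bounding-box points that belong to the part.
    """
    rng = np.random.default_rng(12345)
    for part in nuclear_parts:
        box = part.aabb()
        pts = rng.uniform(box[:, 0], box[:, 1], size=(8 * n_surface, 3))
        pts = pts[part.contains(pts)]
        if pts.size == 0:
            continue
        ok = membrane.contains(pts)
        if not np.all(ok):
            worst = pts[~ok]
            raise ValueError(
                f"nucleus part {part.kind()} extends outside the membrane "
                f"(e.g. at {worst[0]})"
            )


def build_rbc(
    diameter: float = 7.7,
    center_thickness: float = 1.0,
    edge_thickness: float = 2.0,
    index: float = N_RBC,
    medium_index: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Red blood cell: biconcave disc, 7.7 μm diameter, 1.0/2.0 μm thickness."""
    disc = BiconcaveDisc(
        center=(0, 0, 0),
        refractive_index=index,
        priority=1,
        diameter=diameter,
        center_thickness=center_thickness,
        edge_thickness=edge_thickness,
    )
    return RefractiveIndexScene([disc], medium_index=medium_index, name="rbc")


_MEMBRANE_D = 12.0


def _membrane_sphere(n_cytoplasm: float) -> Ellipsoid:
    return sphere((0, 0, 0), _MEMBRANE_D / 2.0, n_cytoplasm, priority=1)


def build_lymphocyte(
    nucleus_radius: float = 4.5,
    nucleus_center=(0.0, 0.0, 1.0),
    n_cytoplasm: float = N_CYTOPLASM,
    n_nucleus: float = N_NUCLEUS,
    medium_index: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Lymphocyte: eccentric double spheres (12 μm membrane, large nucleus)."""
    mem = _membrane_sphere(n_cytoplasm)
    nuc = sphere(nucleus_center, nucleus_radius, n_nucleus, priority=2)
    _check_nucleus_inside([nuc], mem)
    return RefractiveIndexScene([mem, nuc], medium_index, name="lymphocyte")


def build_eosinophil(
    spheroid_semi_axes=(2.5, 2.0, 2.0),
    spheroid_centers=((-2.7, 0.0, 0.0), (2.7, 0.0, 0.0)),
    n_cytoplasm: float = N_CYTOPLASM,
    n_nucleus: float = N_NUCLEUS,
    medium_index: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Eosinophil: 12 μm sphere with two internal spheroids (bilobed nucleus)."""
    mem = _membrane_sphere(n_cytoplasm)
    lobes = [
        Ellipsoid(
            center=c, refractive_index=n_nucleus, priority=2, semi_axes=spheroid_semi_axes
        )
        for c in spheroid_centers
    ]
    _check_nucleus_inside(lobes, mem)
    return RefractiveIndexScene([mem, *lobes], medium_index, name="eosinophil")


def build_neutrophil(
    spheroid_semi_axes=(2.5, 2.0, 2.0),
    pair_offset_x: float = 2.8,
    within_pair_offset_y: float = 1.2,
    n_cytoplasm: float = N_CYTOPLASM,
    n_nucleus: float = N_NUCLEUS,
    medium_index: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Neutrophil: 12 μm sphere with four spheroids in two connected pairs.

    The two spheroids of each pair overlap (their y-offset is smaller than a
    semi-axis), so the nuclear union has exactly two connected components.
    """
    mem = _membrane_sphere(n_cytoplasm)
    centers = [
        (-pair_offset_x, -within_pair_offset_y, 0.0),
        (-pair_offset_x, +within_pair_offset_y, 0.0),
        (+pair_offset_x, -within_pair_offset_y, 0.0),
        (+pair_offset_x, +within_pair_offset_y, 0.0),
    ]
    lobes = [
        Ellipsoid(
            center=c, refractive_index=n_nucleus, priority=2, semi_axes=spheroid_semi_axes
        )
        for c in centers
    ]
    _check_nucleus_inside(lobes, mem)
    return RefractiveIndexScene([mem, *lobes], medium_index, name="neutrophil")


def build_monocyte_fig1(
    arc_radius: float = 3.0,
    tube_radius: float = 1.5,
    n_cytoplasm: float = N_CYTOPLASM,
    n_nucleus: float = N_NUCLEUS,
    medium_index: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Monocyte (qualitative model): 12 μm sphere with a U-shaped nucleus.

    The U is a 180° circular-arc swept tube in the x-y plane, opening towards
    +y.
    """
    mem = _membrane_sphere(n_cytoplasm)
    u_arc = Arc(center=(0.0, 0.0, 0.0), radius=arc_radius,
                theta_start_deg=180.0, theta_end_deg=360.0)
    nuc = SweptTube(
        center=(0, 0, 0),
        refractive_index=n_nucleus,
        priority=2,
        arcs=(u_arc,),
        tube_radius=tube_radius,
    )
    _check_nucleus_inside([nuc], mem)
    return RefractiveIndexScene([mem, nuc], medium_index, name="monocyte_fig1")


def build_basophil(
    arc_radius: float = 2.0,
    tube_radius: float = 1.5,
    n_cytoplasm: float = N_CYTOPLASM,
    n_nucleus: float = N_NUCLEUS,
    medium_index: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Basophil: 12 μm sphere with an S-shaped nucleus (two joined 180° arcs)."""
    mem = _membrane_sphere(n_cytoplasm)
    upper = Arc(center=(0.0, arc_radius, 0.0), radius=arc_radius,
                theta_start_deg=-90.0, theta_end_deg=90.0)
    lower = Arc(center=(0.0, -arc_radius, 0.0), radius=arc_radius,
                theta_start_deg=90.0, theta_end_deg=270.0)
    nuc = SweptTube(
        center=(0, 0, 0),
        refractive_index=n_nucleus,
        priority=2,
        arcs=(upper, lower),
        tube_radius=tube_radius,
    )
    _check_nucleus_inside([nuc], mem)
    return RefractiveIndexScene([mem, nuc], medium_index, name="basophil")


def build_monocyte_edward(
    membrane_semiaxes_top=(6.0, 6.0, 6.5),
    membrane_semiaxes_bottom=(6.0, 6.0, 3.5),
    nucleus_semiaxes=(3.40, 3.70, 3.00),
    nucleus_center=(0.0, 0.0, 3.00),
    n1: float = N_CYTOPLASM,
    n2: float = N_NUCLEUS,
    nm: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Two-half-ellipsoid monocyte with an ellipsoidal nucleus.

    The cytomembrane is two half-ellipsoids sharing the z = 0 equatorial
    plane; the nucleus is an axis-aligned ellipsoid (default semi-axes
    3.40/3.70/3.00 μm at (0, 0, 3.00) μm, indices 1.37/1.39 in medium 1.003).
    """
    at, bt, ct = (float(s) for s in membrane_semiaxes_top)
    ab, bb, cb = (float(s) for s in membrane_semiaxes_bottom)
    if (at, bt) != (ab, bb):
        raise ValueError("top and bottom half-ellipsoids must share equatorial semi-axes")
    mem = HalfEllipsoidPair(
        center=(0, 0, 0),
        refractive_index=n1,
        priority=1,
        a=at,
        b=bt,
        c_top=ct,
        c_bottom=cb,
    )
    nuc = Ellipsoid(
        center=nucleus_center,
        refractive_index=n2,
        priority=2,
        semi_axes=nucleus_semiaxes,
    )
    _check_nucleus_inside([nuc], mem)
    return RefractiveIndexScene([mem, nuc], medium_index=nm, name="monocyte_edward")


def build_two_ellipsoid_cell(
    membrane_semiaxes=(6.0, 6.0, 5.0),
    nucleus_semiaxes=(3.0, 3.0, 2.5),
    nucleus_center=(0.0, 0.0, 0.0),
    n1: float = N_CYTOPLASM,
    n2: float = N_NUCLEUS,
    nm: float = N_MEDIUM,
) -> RefractiveIndexScene:
    """Generic nuclear-type model: an ellipsoidal cell with ellipsoidal nucleus."""
    mem = Ellipsoid(
        center=(0, 0, 0), refractive_index=n1, priority=1, semi_axes=membrane_semiaxes
    )
    nuc = Ellipsoid(
        center=nucleus_center, refractive_index=n2, priority=2, semi_axes=nucleus_semiaxes
    )
    _check_nucleus_inside([nuc], mem)
    return RefractiveIndexScene([mem, nuc], medium_index=nm, name="two_ellipsoid")


BUILDERS = {
    "rbc": build_rbc,
    "lymphocyte": build_lymphocyte,
    "eosinophil": build_eosinophil,
    "neutrophil": build_neutrophil,
    "monocyte": build_monocyte_fig1,
    "basophil": build_basophil,
    "monocyte_edward": build_monocyte_edward,
    "two_ellipsoid": build_two_ellipsoid_cell,
}


# ---------------------------------------------------------------------------
# configuration I/O (flat YAML, one section per part) and voxel export
# ---------------------------------------------------------------------------

_PART_KINDS = {
    "ellipsoid": Ellipsoid,
    "sphere": Ellipsoid,
    "half_ellipsoid_pair": HalfEllipsoidPair,
    "biconcave_disc": BiconcaveDisc,
    "swept_tube": SweptTube,
}


def scene_to_config(scene: RefractiveIndexScene) -> dict:
    return {
        "name": scene.name,
        "medium_index": float(scene.medium_index),
        "bounds": [[float(v) for v in row] for row in scene.bounds],
        "parts": [
            {
                "kind": p.kind(),
                "center": [float(c) for c in p.center],
                "refractive_index": float(p.refractive_index),
                "priority": int(p.priority),
                **p.params(),
            }
            for p in scene.parts
        ],
    }


def scene_from_config(cfg: dict) -> RefractiveIndexScene:
    parts: list[GeometricPart] = []
    for pc in cfg["parts"]:
        pc = dict(pc)
        kind = pc.pop("kind")
        cls = _PART_KINDS[kind]
        common = {
            "center": pc.pop("center"),
            "refractive_index": pc.pop("refractive_index"),
            "priority": pc.pop("priority"),
        }
        if cls is Ellipsoid:
            parts.append(
                Ellipsoid(
                    **common,
                    semi_axes=pc["semi_axes"],
                    rotation_deg=tuple(pc.get("rotation_deg", (0, 0, 0))),
                )
            )
        elif cls is SweptTube:
            arcs = tuple(
                Arc(
                    center=tuple(a["center"]),
                    radius=a["radius"],
                    theta_start_deg=a["theta_start_deg"],
                    theta_end_deg=a["theta_end_deg"],
                )
                for a in pc["arcs"]
            )
            parts.append(SweptTube(**common, arcs=arcs, tube_radius=pc["tube_radius"]))
        else:
            parts.append(cls(**common, **pc))
    return RefractiveIndexScene(
        parts,
        medium_index=cfg["medium_index"],
        bounds=np.asarray(cfg["bounds"], dtype=float) if "bounds" in cfg else None,
        name=cfg.get("name", ""),
    )


def save_scene(scene: RefractiveIndexScene, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scene_to_config(scene), fh, sort_keys=False)


def load_scene(path) -> RefractiveIndexScene:
    with open(path) as fh:
        return scene_from_config(yaml.safe_load(fh))


def voxelize(
    scene: RefractiveIndexScene, voxel_size: float = 0.1, bounds: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the index field on a regular grid.

    Returns ``(grid, origin)`` where ``grid[i, j, k]`` is the index at
    ``origin + voxel_size·(i, j, k)`` (x, y, z order).
    """
    _check_positive(voxel_size=voxel_size)
    b = scene.bounds if bounds is None else np.asarray(bounds, dtype=float)
    axes = [np.arange(b[i, 0], b[i, 1] + voxel_size / 2, voxel_size) for i in range(3)]
    shape = tuple(len(a) for a in axes)
    grid = np.empty(shape, dtype=float)
    # chunk over x-slabs to bound memory
    Y, Z = np.meshgrid(axes[1], axes[2], indexing="ij")
    for i, x in enumerate(axes[0]):
        pts = np.stack([np.full(Y.shape, x), Y, Z], axis=-1)
        grid[i] = index_at(scene, pts.reshape(-1, 3)).reshape(Y.shape)
    origin = np.array([a[0] for a in axes])
    return grid, origin
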