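"""Spherical scalp + synthetically folded cortical patches.

Geometry convention (right-handed, head-centered, lengths in mm):
+z points through the center of the M1-like patch, +x is anterior.  The
scalp is a sphere; each cortical region is an open patch of the cortex
sphere corrugated radially inward by

    s(u) = sulcal_depth * (1 - cos(2*pi*u / wavelength)) / 2

where ``u`` is the coordinate along the region's corrugation axis in the
patch tangent plane.  Gyral ridges therefore run perpendicular to the
corrugation axis, which by default is rotated 45 degrees from the anterior
reference tangent so that the optimal coil angle of the folded geometry
lands near the 45-degree convention.

Vertices are classified into gyral crown / rim / wall / sulcal fundus by
thresholds on the normalized corrugation depth (0 = crown apex,
1 = fundus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .synthdata import HeadParams, RegionSpec, default_head_params

__all__ = [
    "CorticalSurface",
    "HeadModel",
    "CoilPlacement",
    "build_head",
    "place_coil",
    "apply_5cm_rule",
    "scalp_to_cortex_distance",
    "nearest_vertex",
    "export_surface_ply",
    "DEPTH_CLASSES",
    "DEPTH_CLASS_EDGES",
]

ANTERIOR = np.array([1.0, 0.0, 0.0])

#: depth-fraction partition: crown < 0.15 <= rim < 0.35 <= wall < 0.8 <= fundus
DEPTH_CLASS_EDGES = (0.15, 0.35, 0.8)
DEPTH_CLASSES = ("crown", "rim", "wall", "fundus")

#: angle (deg) between the anterior reference tangent and the corrugation axis
CORRUGATION_AXIS_ANGLE_DEG = 45.0


@dataclass
class CorticalSurface:
    """Open triangulated patch of folded cortex for one region."""

    region: str
    vertices: np.ndarray        # (n, 3) mm
    triangles: np.ndarray       # (t, 3) int
    outward_normals: np.ndarray  # (n, 3) unit
    depth_fraction: np.ndarray  # (n,) in [0, 1]
    depth_class: np.ndarray     # (n,) str from DEPTH_CLASSES
    spec: RegionSpec

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles, process=False)


@dataclass
class HeadModel:
    params: HeadParams
    surfaces: dict[str, CorticalSurface]

    @property
    def scalp_radius_mm(self) -> float:
        return self.params.scalp_radius_mm

    @property
    def cortex_radius_mm(self) -> float:
        return self.params.cortex_radius_mm


@dataclass(frozen=True)
class CoilPlacement:
    """Figure-of-eight coil pose against the scalp.

    ``normal`` points into the head (anti-parallel to the scalp radial
    direction); ``handle_direction`` is tangent to the scalp.
    """

    center: np.ndarray
    normal: np.ndarray
    handle_direction: np.ndarray
    rotation_angle_deg: float
    standoff_mm: float


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def _reference_tangent(direction: np.ndarray) -> np.ndarray:
    """Anterior axis projected onto the tangent plane at ``direction``."""
    t = ANTERIOR - np.dot(ANTERIOR, direction) * direction
    n = np.linalg.norm(t)
    if n < 1e-9:
        raise ValueError("reference tangent undefined: direction is anterior")
    return t / n


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _patch_frame(spec: RegionSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e3 = _unit(np.asarray(spec.patch_center_direction, float))
    t0 = _reference_tangent(e3)
    e1 = _rotate_about(t0, e3, np.deg2rad(CORRUGATION_AXIS_ANGLE_DEG))
    e2 = np.cross(e3, e1)
    return e1, e2, e3


def _patch_map(uv: np.ndarray, spec: RegionSpec, cortex_radius: float) -> np.ndarray:
    """Map tangent-plane coordinates (mm) to folded-cortex positions (mm)."""
    e1, e2, e3 = _patch_frame(spec)
    u, v = uv[:, 0], uv[:, 1]
    r = np.hypot(u, v)
    alpha = r / cortex_radius
    with np.errstate(invalid="ignore", divide="ignore"):
        cu = np.where(r > 0, u / r, 1.0)
        cv = np.where(r > 0, v / r, 0.0)
    d = (
        np.cos(alpha)[:, None] * e3
        + (np.sin(alpha) * cu)[:, None] * e1
        + (np.sin(alpha) * cv)[:, None] * e2
    )
    c = (1.0 - np.cos(2.0 * np.pi * u / spec.gyral_wavelength_mm)) / 2.0
    s = spec.sulcal_depth_mm * c**spec.crown_exponent
    return (cortex_radius - s)[:, None] * d


def _build_surface(region: str, spec: RegionSpec, cortex_radius: float,
                   edge_length_mm: float) -> CorticalSurface:
    if spec.gyral_wavelength_mm <= 0:
        raise ValueError("gyral wavelength must be > 0")
    arc = cortex_radius * np.deg2rad(spec.patch_angular_radius_deg)
    n = int(np.ceil(2 * arc / edge_length_mm)) + 1
    g = np.linspace(-arc, arc, n)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    keep = np.hypot(uu, vv) <= arc + 1e-9
    idx = -np.ones((n, n), dtype=int)
    idx[keep] = np.arange(keep.sum())
    uv = np.column_stack([uu[keep], vv[keep]])

    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            if a >= 0 and b >= 0 and c >= 0:
                tris.append((a, b, c))
            if a >= 0 and c >= 0 and d >= 0:
                tris.append((a, c, d))
    triangles = np.asarray(tris, dtype=int)

    verts = _patch_map(uv, spec, cortex_radius)

    # analytic-parametrization normals via tiny central differences of the
    # smooth patch map (h well below mesh scale; effectively exact)
    h = 1e-4
    du = (_patch_map(uv + [h, 0], spec, cortex_radius)
          - _patch_map(uv + [-h, 0], spec, cortex_radius)) / (2 * h)
    dv = (_patch_map(uv + [0, h], spec, cortex_radius)
          - _patch_map(uv + [0, -h], spec, cortex_radius)) / (2 * h)
    nrm = np.cross(du, dv)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    # orient outward (away from head center)
    flip = np.einsum("ij,ij->i", nrm, verts) < 0
    nrm[flip] *= -1

    if spec.sulcal_depth_mm > 0:
        c = (1.0 - np.cos(2.0 * np.pi * uv[:, 0] / spec.gyral_wavelength_mm)) / 2.0
        f = c**spec.crown_exponent
    else:
        f = np.zeros(len(uv))
    edges = DEPTH_CLASS_EDGES
    cls = np.where(
        f < edges[0], DEPTH_CLASSES[0],
        np.where(f < edges[1], DEPTH_CLASSES[1],
                 np.where(f < edges[2], DEPTH_CLASSES[2], DEPTH_CLASSES[3])),
    )
    return CorticalSurface(
        region=region,
        vertices=verts,
        triangles=triangles,
        outward_normals=nrm,
        depth_fraction=f,
        depth_class=cls,
        spec=spec,
    )


def build_head(params: HeadParams | None = None, edge_length_mm: float = 1.0) -> HeadModel:
    """Build the spherical scalp plus one folded patch per region."""
    params = params if params is not None else default_head_params()
    surfaces = {
        name: _build_surface(name, spec, params.cortex_radius_mm, edge_length_mm)
        for name, spec in params.regions.items()
    }
    return HeadModel(params=params, surfaces=surfaces)


def place_coil(head: HeadModel, target: np.ndarray, rotation_angle_deg: float,
               standoff_mm: float = 4.0) -> CoilPlacement:
    """Place the coil at the scalp point nearest the target, offset outward.

    The nearest scalp point to an interior target on a sphere is its radial
    projection; the coil center sits ``standoff_mm`` further out along the
    scalp normal.  The handle direction is the anterior reference tangent
    rotated by ``rotation_angle_deg`` about the (inward) coil normal.
    """
    d = _unit(np.asarray(target, float))
    center = (head.scalp_radius_mm + standoff_mm) * d
    normal = -d
    t0 = _reference_tangent(d)
    handle = _rotate_about(t0, normal, np.deg2rad(rotation_angle_deg))
    return CoilPlacement(
        center=center,
        normal=normal,
        handle_direction=handle,
        rotation_angle_deg=float(rotation_angle_deg),
        standoff_mm=float(standoff_mm),
    )


def apply_5cm_rule(head: HeadModel, m1_placement: CoilPlacement,
                   distance_mm: float = 50.0) -> np.ndarray:
    """Move the scalp point ``distance_mm`` along the anterior scalp geodesic
    (tape-measure convention) and return the nearest cortical vertex.

    Raises ``ValueError`` naming the patch extent if the geodesic endpoint
    is not above any modeled patch.
    """
    d = _unit(m1_placement.center)
    t0 = _reference_tangent(d)
    beta = distance_mm / head.scalp_radius_mm
    new_dir = _unit(np.cos(beta) * d + np.sin(beta) * t0)
    scalp_point = head.scalp_radius_mm * new_dir

    best = None
    for surf in head.surfaces.values():
        dist = np.linalg.norm(surf.vertices - scalp_point, axis=1)
        k = int(np.argmin(dist))
        if best is None or dist[k] < best[0]:
            best = (dist[k], surf, k)
    _, surf, k = best
    center_dir = _unit(np.asarray(surf.spec.patch_center_direction, float))
    ang = np.degrees(np.arccos(np.clip(np.dot(new_dir, center_dir), -1, 1)))
    if ang > surf.spec.patch_angular_radius_deg:
        raise ValueError(
            f"geodesic endpoint leaves the modeled patches: {ang:.1f} deg from "
            f"nearest patch center ({surf.region}), patch extent "
            f"{surf.spec.patch_angular_radius_deg:.1f} deg"
        )
    return surf.vertices[k].copy()


def scalp_to_cortex_distance(head: HeadModel, placement: CoilPlacement,
                             roi_center: np.ndarray) -> float:
    """Euclidean coil-center-to-ROI-center distance in mm."""
    return float(np.linalg.norm(placement.center - np.asarray(roi_center, float)))


def nearest_vertex(surface: CorticalSurface, point: np.ndarray) -> int:
    """Index of the surface vertex nearest to ``point``."""
    return int(np.argmin(np.linalg.norm(surface.vertices - np.asarray(point, float), axis=1)))


def export_surface_ply(surface: CorticalSurface, path) -> None:
    """Write the patch as binary little-endian PLY with per-vertex
    depth_fraction and an integer region label."""
    mesh = surface.as_trimesh()
    mesh.vertex_attributes["depth_fraction"] = surface.depth_fraction.astype(np.float32)
    codes = {c: i for i, c in enumerate(DEPTH_CLASSES)}
    mesh.vertex_attributes["depth_class"] = np.array(
        [codes[c] for c in surface.depth_class], dtype=np.uint8
    )
    with open(path, "wb") as fh:
        fh.write(mesh.export(file_type="ply", encoding="binary"))
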