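"""Assembly of the motion structure as renderer-independent geometry.

A scene is an ordered list of colored primitives — spheres, cylinders, and
triangle meshes with per-vertex color/opacity — plus a camera and lights.  The
builders here turn pathline splines into:

* extruded tubes along each pathline, colored by the temporal gradient;
* the imposed single-pose backbone (spheres at each alpha carbon, linking
  cylinders between sequential neighbors, sequential coloring);
* trailing semi-transparent ribbons between every other pair of pathlines,
  fading behind the backbone to cue the direction of time;
* "ladder rail" rungs between adjacent pathlines for printable output, which
  replace the (unprintable) transparent ribbons and physically tie the
  pathlines together.

Tube ring frames use parallel transport along the sampled polyline rather than
Frenet frames, which avoids frame flips at inflection points.  All lengths are
in Angstrom.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .pathlines import PathlineSpline, fit_natural_cubic
from .styling import (
    SEQUENTIAL_DEFAULT,
    TEMPORAL_DEFAULT,
    ColorGradient,
    fade_alpha,
)
from .pdb_io import Trajectory

__all__ = [
    "Sphere",
    "Cylinder",
    "Mesh",
    "Scene",
    "RenderConfig",
    "build_pathline_tube",
    "build_backbone",
    "build_trailing_membranes",
    "build_ladder_rails",
    "assemble_scene",
    "scene_census",
    "connected_components",
    "scene_to_json",
    "tessellate_sphere",
    "tessellate_cylinder",
]

logger = logging.getLogger(__name__)

_TOUCH_TOLERANCE = 0.05  # A; slack for the primitive-adjacency test


# --------------------------------------------------------------------------
# Primitives
# --------------------------------------------------------------------------

@dataclass
class Sphere:
    center: np.ndarray
    radius: float
    rgb: tuple[float, float, float]
    kind: str = "sphere"
    radius_name: Optional[str] = None  # emitted as an editable scene variable

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def anchors(self) -> np.ndarray:
        return self.center[None, :]

    @property
    def reach(self) -> float:
        return self.radius


@dataclass
class Cylinder:
    end1: np.ndarray
    end2: np.ndarray
    radius: float
    rgb_end1: tuple[float, float, float]
    rgb_end2: tuple[float, float, float]
    kind: str = "cylinder"
    radius_name: Optional[str] = None

    def __post_init__(self) -> None:
        self.end1 = np.asarray(self.end1, dtype=float)
        self.end2 = np.asarray(self.end2, dtype=float)
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if np.allclose(self.end1, self.end2):
            raise ValueError("cylinder endpoints must be distinct")

    @property
    def anchors(self) -> np.ndarray:
        return np.stack([self.end1, 0.5 * (self.end1 + self.end2), self.end2])

    @property
    def reach(self) -> float:
        return self.radius


@dataclass
class Mesh:
    """Triangle mesh with per-vertex color and opacity."""

    vertices: np.ndarray           # (N, 3)
    faces: np.ndarray              # (F, 3) int
    colors: np.ndarray             # (N, 3) in [0, 1]
    opacity: np.ndarray            # (N,) in [0, 1]
    kind: str = "mesh"
    centerline: Optional[np.ndarray] = None  # tube axis samples, for adjacency
    reach_radius: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.colors = np.asarray(self.colors, dtype=float)
        self.opacity = np.asarray(self.opacity, dtype=float)
        n = len(self.vertices)
        if len(self.colors) != n or len(self.opacity) != n:
            raise ValueError("per-vertex color/opacity must match vertex count")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face references out-of-range vertex index")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")

    @property
    def anchors(self) -> np.ndarray:
        if self.centerline is not None:
            return self.centerline
        return self.vertices

    @property
    def reach(self) -> float:
        return self.reach_radius


@dataclass
class Scene:
    primitives: list
    camera_position: np.ndarray
    camera_look_at: np.ndarray
    camera_up: np.ndarray
    lights: list  # (position, rgb) pairs
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)
    declares: dict = field(default_factory=dict)  # editable scalars for export

    def __post_init__(self) -> None:
        self.camera_position = np.asarray(self.camera_position, dtype=float)
        self.camera_look_at = np.asarray(self.camera_look_at, dtype=float)
        self.camera_up = np.asarray(self.camera_up, dtype=float)
        if np.linalg.norm(self.camera_up) == 0:
            raise ValueError("camera up-vector must be nonzero")
        if not self.lights:
            raise ValueError("scene needs at least one light")


class RenderConfig(BaseModel):
    """All user-facing rendering knobs.

    Pose/atom selection uses inclusive start:end:stride ranges.  backbone_time
    is a real-valued parameter along the (possibly subsetted) pose axis; None
    places the backbone at the final pose.  ribbon_fade_fraction expresses the
    ribbon trail length as a fraction of the pose span.
    """

    model_config = ConfigDict(validate_assignment=True)

    pose_start: Optional[int] = Field(default=None, ge=0)
    pose_end: Optional[int] = Field(default=None, ge=0)
    pose_stride: int = Field(default=1, ge=1)
    atom_start: Optional[int] = Field(default=None, ge=0)
    atom_end: Optional[int] = Field(default=None, ge=0)
    atom_stride: int = Field(default=1, ge=1)
    atom_names: tuple[str, ...] = ("CA",)
    backbone_time: Optional[float] = Field(default=None, ge=0)
    backbone_snap: bool = False
    segments_per_interval: int = Field(default=8, ge=1)
    ring_vertices: int = Field(default=8, ge=3)
    tube_radius: float = Field(default=0.3, gt=0)
    sphere_radius: float = Field(default=1.0, gt=0)
    backbone_cylinder_radius: float = Field(default=0.5, gt=0)
    rung_radius: float = Field(default=0.4, gt=0)
    ribbon_fade_fraction: float = Field(default=0.2, gt=0, le=1.0)
    alpha_max: float = Field(default=0.6, gt=0, le=1.0)
    ribbons: bool = True
    ladder_rails: bool = False
    rung_interval: int = Field(default=1, ge=1)
    split_chains: bool = False  # omit backbone links across chain boundaries

    def resolve_backbone_time(self, n_poses: int, *, strict: bool = True) -> float:
        t_max = float(n_poses - 1)
        t_b = t_max if self.backbone_time is None else float(self.backbone_time)
        if not 0.0 <= t_b <= t_max:
            raise ValueError(
                f"backbone_time {t_b:g} outside pose range [0, {t_max:g}]"
            )
        if self.backbone_snap:
            t_b = float(round(t_b))
        return t_b

    def resolve_fade_length(self, n_poses: int) -> float:
        return max(self.ribbon_fade_fraction * max(n_poses - 1, 1), 1e-6)


# --------------------------------------------------------------------------
# Tube extrusion
# --------------------------------------------------------------------------

def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    diffs = np.diff(points, axis=0)
    norms = np.linalg.norm(diffs, axis=1)
    # carry the previous direction across coincident samples
    dirs = np.zeros_like(diffs)
    last = np.array([0.0, 0.0, 1.0])
    for i, (d, n) in enumerate(zip(diffs, norms)):
        if n > 1e-12:
            last = d / n
        dirs[i] = last
    tangents = np.empty_like(points)
    tangents[0] = dirs[0]
    tangents[-1] = dirs[-1]
    tangents[1:-1] = dirs[:-1] + dirs[1:]
    tn = np.linalg.norm(tangents, axis=1, keepdims=True)
    tn[tn < 1e-12] = 1.0
    return tangents / tn


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal/binormal frame at each sample, transported without axial twist."""
    T = _polyline_tangents(points)
    # seed normal: project the least-aligned coordinate axis
    axis = np.eye(3)[np.argmin(np.abs(T[0]))]
    N0 = axis - T[0] * (axis @ T[0])
    N0 /= np.linalg.norm(N0)
    normals = np.empty_like(points)
    normals[0] = N0
    for i in range(1, len(points)):
        v = np.cross(T[i - 1], T[i])
        s = np.linalg.norm(v)
        c = float(np.clip(T[i - 1] @ T[i], -1.0, 1.0))
        if s < 1e-12:
            normals[i] = normals[i - 1]
        else:
            k = v / s
            n = normals[i - 1]
            angle = math.atan2(s, c)
            normals[i] = (
                n * math.cos(angle)
                + np.cross(k, n) * math.sin(angle)
                + k * (k @ n) * (1.0 - math.cos(angle))
            )
        normals[i] -= T[i] * (normals[i] @ T[i])
        normals[i] /= np.linalg.norm(normals[i])
    binormals = np.cross(T, normals)
    return normals, binormals


def build_pathline_tube(
    spline: PathlineSpline,
    cfg: RenderConfig,
    gradient: ColorGradient = TEMPORAL_DEFAULT,
) -> Mesh:
    """Extrude an open-ended tube along a pathline spline.

    The tube has ((M-1)*s + 1) rings of ``ring_vertices`` vertices each and
    2*(M-1)*s*ring_vertices side triangles; every vertex carries the temporal
    color of its sample parameter.
    """
    s, r = cfg.segments_per_interval, cfg.ring_vertices
    params, centers = spline.sample(s)
    normals, binormals = _parallel_transport_frames(centers)
    theta = 2.0 * np.pi * np.arange(r) / r
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    n_rings = len(centers)
    vertices = (
        centers[:, None, :]
        + cfg.tube_radius
        * (cos_t[None, :, None] * normals[:, None, :] + sin_t[None, :, None] * binormals[:, None, :])
    ).reshape(n_rings * r, 3)
    u = params / spline.t_max
    ring_colors = np.array([gradient(float(ui)) for ui in u])
    colors = np.repeat(ring_colors, r, axis=0)
    faces = []
    for i in range(n_rings - 1):
        base = i * r
        for j in range(r):
            a, b = base + j, base + (j + 1) % r
            c, d = a + r, b + r
            faces.append((a, c, b))
            faces.append((b, c, d))
    return Mesh(
        vertices=vertices,
        faces=np.array(faces, dtype=int).reshape(-1, 3),
        colors=colors,
        opacity=np.ones(len(vertices)),
        kind="tube",
        centerline=centers,
        reach_radius=cfg.tube_radius,
    )


# --------------------------------------------------------------------------
# Backbone, ribbons, rails
# --------------------------------------------------------------------------

def build_backbone(
    trajectory: Trajectory,
    splines: Sequence[PathlineSpline],
    cfg: RenderConfig,
    gradient: ColorGradient = SEQUENTIAL_DEFAULT,
) -> list:
    """Spheres at each atom's pathline position at the backbone time, plus
    linking cylinders between sequential neighbors.

    Sphere k gets the sequential color at k/(K-1); linking cylinders
    interpolate their two endpoint colors.  With ``backbone_snap`` the time is
    rounded to the nearest input pose.
    """
    K = trajectory.n_atoms
    t_b = cfg.resolve_backbone_time(trajectory.n_poses)
    if splines:
        centers = np.array([sp.evaluate(t_b) for sp in splines])
    else:  # single-pose, structure-only
        centers = trajectory.positions[:, 0, :]
    prims: list = []
    for k in range(K):
        u = k / (K - 1) if K > 1 else 0.0
        prims.append(
            Sphere(
                center=centers[k],
                radius=cfg.sphere_radius,
                rgb=gradient(u),
                kind="backbone_sphere",
                radius_name="BackboneSphereRadius",
            )
        )
    chains = [a.chain for a in trajectory.atom_meta]
    for k in range(K - 1):
        if cfg.split_chains and chains[k] != chains[k + 1]:
            continue  # no covalent link across a chain boundary
        if np.allclose(centers[k], centers[k + 1]):
            logger.warning("coincident backbone atoms %d/%d; link skipped", k, k + 1)
            continue
        prims.append(
            Cylinder(
                end1=centers[k],
                end2=centers[k + 1],
                radius=cfg.backbone_cylinder_radius,
                rgb_end1=gradient(k / (K - 1)),
                rgb_end2=gradient((k + 1) / (K - 1)),
                kind="backbone_cylinder",
                radius_name="BackboneLinkRadius",
            )
        )
    return prims


def build_trailing_membranes(
    splines: Sequence[PathlineSpline],
    cfg: RenderConfig,
    gradient: ColorGradient = TEMPORAL_DEFAULT,
) -> list[Mesh]:
    """Fading ribbons between every other sequential pair of pathlines.

    Pathlines are paired disjointly — (1,2), (3,4), ... in 1-based order — so
    K pathlines yield floor(K/2) ribbons.  Each ribbon is a quad strip between
    the paired pathlines over [t_b - fade, t_b]; opacity falls linearly from
    alpha_max at the backbone edge to zero at the trailing edge.
    """
    K = len(splines)
    if K < 2:
        return []
    M = splines[0].n_knots
    t_b = cfg.resolve_backbone_time(M)
    fade = cfg.resolve_fade_length(M)
    t_lo = max(0.0, t_b - fade)
    if t_b <= t_lo:
        return []
    n_samples = max(2, int(round((t_b - t_lo) * cfg.segments_per_interval)) + 1)
    ts = np.linspace(t_lo, t_b, n_samples)
    meshes = []
    for pair in range(K // 2):
        a, b = splines[2 * pair], splines[2 * pair + 1]
        pa, pb = a.evaluate(ts), b.evaluate(ts)
        vertices = np.empty((2 * n_samples, 3))
        vertices[0::2] = pa
        vertices[1::2] = pb
        cols = np.array([gradient(float(t / (M - 1))) for t in ts])
        colors = np.repeat(cols, 2, axis=0)
        alpha = np.array([fade_alpha(t_b - t, fade, cfg.alpha_max) for t in ts])
        opacity = np.repeat(alpha, 2)
        faces = []
        for i in range(n_samples - 1):
            v0, v1, v2, v3 = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
            faces.append((v0, v1, v2))
            faces.append((v1, v3, v2))
        meshes.append(
            Mesh(
                vertices=vertices,
                faces=np.array(faces, dtype=int),
                colors=colors,
                opacity=opacity,
                kind="membrane",
            )
        )
    return meshes


def build_ladder_rails(
    splines: Sequence[PathlineSpline],
    cfg: RenderConfig,
    gradient: ColorGradient = TEMPORAL_DEFAULT,
) -> list[Cylinder]:
    """Rigid rungs between sequentially adjacent pathlines, every
    ``rung_interval`` poses, for the printable model.

    Rungs order the pathlines visually and hold the printed tubes in relation
    to each other; with rungs at every pose, K pathlines over M poses produce
    (K-1)*M rung cylinders and the tube+rung graph is connected.
    """
    K = len(splines)
    if K < 2:
        return []
    M = splines[0].n_knots
    times = list(range(0, M, cfg.rung_interval))
    if times[-1] != M - 1:
        times.append(M - 1)  # keep the final pose pinned
    rungs = []
    for k in range(K - 1):
        for t in times:
            p1 = splines[k].evaluate(float(t))
            p2 = splines[k + 1].evaluate(float(t))
            if np.allclose(p1, p2):
                continue
            rgb = gradient(t / (M - 1) if M > 1 else 0.0)
            rungs.append(
                Cylinder(
                    end1=p1,
                    end2=p2,
                    radius=cfg.rung_radius,
                    rgb_end1=rgb,
                    rgb_end2=rgb,
                    kind="rail",
                    radius_name="RungRadius",
                )
            )
    return rungs


# --------------------------------------------------------------------------
# Scene assembly
# --------------------------------------------------------------------------

def assemble_scene(
    trajectory: Trajectory,
    cfg: RenderConfig,
    temporal: ColorGradient = TEMPORAL_DEFAULT,
    sequential: ColorGradient = SEQUENTIAL_DEFAULT,
) -> Scene:
    """Build the full motion structure for a trajectory.

    Pathline tubes for every selected atom, the imposed backbone, trailing
    ribbons and/or ladder rails per the config, and a default camera on +z at
    2.5x the bounding-sphere radius of the control points.  Deterministic for
    fixed inputs.
    """
    K, M = trajectory.n_atoms, trajectory.n_poses
    primitives: list = []
    splines: list[PathlineSpline] = []
    if M >= 2:
        splines = [fit_natural_cubic(trajectory.positions[k]) for k in range(K)]
        for sp in splines:
            primitives.append(build_pathline_tube(sp, cfg, temporal))
    primitives.extend(build_backbone(trajectory, splines, cfg, sequential))
    if M >= 2 and cfg.ribbons:
        primitives.extend(build_trailing_membranes(splines, cfg, temporal))
    if M >= 2 and cfg.ladder_rails:
        primitives.extend(build_ladder_rails(splines, cfg, temporal))

    pts = trajectory.positions.reshape(-1, 3)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = 0.5 * (lo + hi)
    radius = max(0.5 * float(np.linalg.norm(hi - lo)), 1.0)
    cam = center + np.array([0.0, 0.0, 2.5 * radius])
    light = center + np.array([radius, 2.0 * radius, 2.5 * radius])
    return Scene(
        primitives=primitives,
        camera_position=cam,
        camera_look_at=center,
        camera_up=np.array([0.0, 1.0, 0.0]),
        lights=[(light, (1.0, 1.0, 1.0))],
        declares={
            "TubeRadius": cfg.tube_radius,
            "BackboneSphereRadius": cfg.sphere_radius,
            "BackboneLinkRadius": cfg.backbone_cylinder_radius,
            "RungRadius": cfg.rung_radius,
        },
    )


# --------------------------------------------------------------------------
# Introspection helpers
# --------------------------------------------------------------------------

def scene_census(scene: Scene) -> dict:
    """Primitive/vertex/face counts, total and per kind."""
    census: dict = {"spheres": 0, "cylinders": 0, "meshes": 0, "vertices": 0,
                    "faces": 0, "by_kind": {}}
    for p in scene.primitives:
        census["by_kind"][p.kind] = census["by_kind"].get(p.kind, 0) + 1
        if isinstance(p, Sphere):
            census["spheres"] += 1
        elif isinstance(p, Cylinder):
            census["cylinders"] += 1
        elif isinstance(p, Mesh):
            census["meshes"] += 1
            census["vertices"] += len(p.vertices)
            census["faces"] += len(p.faces)
    return census


def connected_components(primitives: Sequence) -> list[set[int]]:
    """Union-find over touching primitives.

    Two primitives touch when some pair of their anchor points lies within the
    sum of their reach radii (plus a small tolerance).  Rung endpoints and
    backbone-sphere centers lie on pathline centerlines, so tubes joined by
    rails or a backbone form one component.
    """
    n = len(primitives)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for i in range(n):
        ai, ri = primitives[i].anchors, primitives[i].reach
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            aj, rj = primitives[j].anchors, primitives[j].reach
            d2 = np.sum((ai[:, None, :] - aj[None, :, :]) ** 2, axis=2)
            if d2.min() <= (ri + rj + _TOUCH_TOLERANCE) ** 2:
                union(i, j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def scene_to_json(scene: Scene) -> str:
    """Deterministic plain-text dump of the scene, for debugging and tests."""
    def prim(p):
        if isinstance(p, Sphere):
            return {"type": "sphere", "kind": p.kind, "center": p.center.tolist(),
                    "radius": p.radius, "rgb": list(p.rgb)}
        if isinstance(p, Cylinder):
            return {"type": "cylinder", "kind": p.kind, "end1": p.end1.tolist(),
                    "end2": p.end2.tolist(), "radius": p.radius,
                    "rgb_end1": list(p.rgb_end1), "rgb_end2": list(p.rgb_end2)}
        return {"type": "mesh", "kind": p.kind, "vertices": p.vertices.tolist(),
                "faces": p.faces.tolist(), "colors": p.colors.tolist(),
                "opacity": p.opacity.tolist()}

    return json.dumps(
        {
            "camera": {
                "position": scene.camera_position.tolist(),
                "look_at": scene.camera_look_at.tolist(),
                "up": scene.camera_up.tolist(),
            },
            "lights": [[np.asarray(p).tolist(), list(c)] for p, c in scene.lights],
            "background": list(scene.background),
            "primitives": [prim(p) for p in scene.primitives],
        },
        sort_keys=True,
    )


# --------------------------------------------------------------------------
# Quadric tessellation (for printable/mesh export)
# --------------------------------------------------------------------------

def tessellate_sphere(sphere: Sphere, n_lat: int = 8, n_lon: int = 12) -> Mesh:
    """UV-sphere triangulation with a flat per-vertex color."""
    verts = [sphere.center + np.array([0.0, 0.0, sphere.radius])]
    for i in range(1, n_lat):
        phi = np.pi * i / n_lat
        for j in range(n_lon):
            th = 2.0 * np.pi * j / n_lon
            verts.append(sphere.center + sphere.radius * np.array(
                [math.sin(phi) * math.cos(th), math.sin(phi) * math.sin(th), math.cos(phi)]
            ))
    verts.append(sphere.center + np.array([0.0, 0.0, -sphere.radius]))
    vertices = np.array(verts)
    faces = []
    for j in range(n_lon):  # top cap
        faces.append((0, 1 + j, 1 + (j + 1) % n_lon))
    for i in range(n_lat - 2):  # bands
        base = 1 + i * n_lon
        for j in range(n_lon):
            a, b = base + j, base + (j + 1) % n_lon
            faces.append((a, a + n_lon, b))
            faces.append((b, a + n_lon, b + n_lon))
    last = len(vertices) - 1
    base = last - n_lon
    for j in range(n_lon):  # bottom cap
        faces.append((last, base + (j + 1) % n_lon, base + j))
    n = len(vertices)
    return Mesh(
        vertices=vertices,
        faces=np.array(faces, dtype=int),
        colors=np.tile(np.asarray(sphere.rgb, dtype=float), (n, 1)),
        opacity=np.ones(n),
        kind=sphere.kind,
        centerline=sphere.center[None, :],
        reach_radius=sphere.radius,
    )


def tessellate_cylinder(cyl: Cylinder, n_side: int = 12) -> Mesh:
    """Capped prism triangulation; end rings carry the two end colors."""
    axis = cyl.end2 - cyl.end1
    length = np.linalg.norm(axis)
    axis = axis / length
    ref = np.eye(3)[np.argmin(np.abs(axis))]
    u = ref - axis * (ref @ axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    theta = 2.0 * np.pi * np.arange(n_side) / n_side
    ring = cyl.radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    ring1 = cyl.end1 + ring
    ring2 = cyl.end2 + ring
    vertices = np.concatenate([ring1, ring2, cyl.end1[None, :], cyl.end2[None, :]])
    c1, c2 = len(vertices) - 2, len(vertices) - 1
    faces = []
    for j in range(n_side):
        a, b = j, (j + 1) % n_side
        faces.append((a, a + n_side, b))
        faces.append((b, a + n_side, b + n_side))
        faces.append((c1, b, a))                      # bottom cap
        faces.append((c2, a + n_side, b + n_side))    # top cap
    colors = np.concatenate([
        np.tile(np.asarray(cyl.rgb_end1, dtype=float), (n_side, 1)),
        np.tile(np.asarray(cyl.rgb_end2, dtype=float), (n_side, 1)),
        [cyl.rgb_end1], [cyl.rgb_end2],
    ])
    n = len(vertices)
    return Mesh(
        vertices=vertices,
        faces=np.array(faces, dtype=int),
        colors=colors,
        opacity=np.ones(n),
        kind=cyl.kind,
        centerline=np.stack([cyl.end1, cyl.end2]),
        reach_radius=cyl.radius,
    )
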