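"""Scene serialization to POV-Ray SDL, VRML 2.0, and ascii PLY.

All three writers are deterministic: identical scenes yield byte-identical
files.  Floating-point output uses a fixed '.'-radix format with no locale
dependence; VRML additionally avoids scientific notation (some printer
toolchains reject it).

Format roles mirror how the motion structures are consumed:

* POV-Ray — publication-quality ray-traced renders.  Spheres and cylinders are
  emitted as native primitives, meshes as ``mesh2`` blocks with one texture
  per vertex; transparency uses POV's ``transmit`` = 1 - opacity.  Editable
  parameters (radii, camera) are hoisted into ``#declare`` variables.
* VRML 2.0 — full-color 3D printing.  Everything is pre-tessellated into
  IndexedFaceSets with ``colorPerVertex TRUE``; transparent membranes are
  dropped (printers cannot realize transparency) and printable primitives are
  merged into one shell per connected component for printer-software
  friendliness.
* PLY — a generic per-vertex-colored triangle mesh loadable by any viewer.
  Like the on-screen form of the visualization it omits the membranes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .scene_build import (
    Cylinder,
    Mesh,
    Scene,
    Sphere,
    connected_components,
    tessellate_cylinder,
    tessellate_sphere,
)

__all__ = ["write_povray", "write_vrml", "write_mesh"]

logger = logging.getLogger(__name__)


def _g(x: float) -> str:
    """6-significant-digit number for POV output."""
    return f"{float(x):.6g}"


def _f(x: float) -> str:
    """Fixed-decimal number (no scientific notation) for VRML/PLY output."""
    s = f"{float(x):.6f}"
    return "0.000000" if s == "-0.000000" else s


def _vec(p) -> str:
    return f"<{_g(p[0])}, {_g(p[1])}, {_g(p[2])}>"


# --------------------------------------------------------------------------
# POV-Ray
# --------------------------------------------------------------------------

def write_povray(scene: Scene, path) -> None:
    """Write the scene as a renderable POV-Ray SDL file.

    Membranes are included (their fading transparency is the point of the
    POV-Ray output).  Radii registered in ``scene.declares`` are emitted as
    ``#declare`` variables so users can retune them by editing the file.
    """
    lines: list[str] = []
    lines.append("// pathflow motion structure — POV-Ray scene")
    lines.append("#version 3.7;")
    lines.append("global_settings { assumed_gamma 1.0 }")
    for name in sorted(scene.declares):
        lines.append(f"#declare {name} = {_g(scene.declares[name])};")
    lines.append(f"#declare Camera_Location = {_vec(scene.camera_position)};")
    lines.append(f"#declare Camera_LookAt = {_vec(scene.camera_look_at)};")
    lines.append(
        f"background {{ color rgb <{_g(scene.background[0])}, "
        f"{_g(scene.background[1])}, {_g(scene.background[2])}> }}"
    )
    lines.append("camera {")
    lines.append("  location Camera_Location")
    lines.append(f"  sky {_vec(scene.camera_up)}")
    lines.append("  look_at Camera_LookAt")
    lines.append("}")
    for pos, rgb in scene.lights:
        lines.append(
            f"light_source {{ {_vec(pos)} color rgb "
            f"<{_g(rgb[0])}, {_g(rgb[1])}, {_g(rgb[2])}> }}"
        )
    for p in scene.primitives:
        if isinstance(p, Sphere):
            radius = p.radius_name or _g(p.radius)
            lines.append(
                f"sphere {{ {_vec(p.center)}, {radius} "
                f"pigment {{ rgb <{_g(p.rgb[0])}, {_g(p.rgb[1])}, {_g(p.rgb[2])}> }} }}"
            )
        elif isinstance(p, Cylinder):
            radius = p.radius_name or _g(p.radius)
            rgb = tuple(0.5 * (a + b) for a, b in zip(p.rgb_end1, p.rgb_end2))
            lines.append(
                f"cylinder {{ {_vec(p.end1)}, {_vec(p.end2)}, {radius} "
                f"pigment {{ rgb <{_g(rgb[0])}, {_g(rgb[1])}, {_g(rgb[2])}> }} }}"
            )
        elif isinstance(p, Mesh):
            lines.extend(_povray_mesh2(p))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _povray_mesh2(mesh: Mesh) -> list[str]:
    n, f = len(mesh.vertices), len(mesh.faces)
    lines = ["mesh2 {"]
    lines.append(f"  vertex_vectors {{ {n},")
    lines.append("    " + ",\n    ".join(_vec(v) for v in mesh.vertices))
    lines.append("  }")
    lines.append(f"  texture_list {{ {n},")
    tex = []
    for rgb, op in zip(mesh.colors, mesh.opacity):
        transmit = 1.0 - float(op)  # POV transmit is the inverse of opacity
        tex.append(
            f"texture {{ pigment {{ rgb <{_g(rgb[0])}, {_g(rgb[1])}, {_g(rgb[2])}> "
            f"transmit {_g(transmit)} }} }}"
        )
    lines.append("    " + ",\n    ".join(tex))
    lines.append("  }")
    lines.append(f"  face_indices {{ {f},")
    lines.append(
        "    "
        + ",\n    ".join(
            f"<{a}, {b}, {c}>, {a}, {b}, {c}" for a, b, c in mesh.faces
        )
    )
    lines.append("  }")
    lines.append("}")
    return lines


# --------------------------------------------------------------------------
# Tessellation shared by VRML and PLY
# --------------------------------------------------------------------------

def _printable_meshes(scene: Scene, drop_membranes: bool) -> list[Mesh]:
    meshes = []
    dropped = 0
    for p in scene.primitives:
        if isinstance(p, Mesh):
            if drop_membranes and p.kind == "membrane":
                dropped += 1
                continue
            meshes.append(p)
        elif isinstance(p, Sphere):
            meshes.append(tessellate_sphere(p))
        elif isinstance(p, Cylinder):
            meshes.append(tessellate_cylinder(p))
    if dropped:
        logger.warning(
            "%d transparent membrane(s) dropped from opaque export", dropped
        )
    return meshes


def _merge_meshes(meshes: Sequence[Mesh]) -> Mesh:
    verts, faces, colors, opac, offset = [], [], [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        colors.append(m.colors)
        opac.append(m.opacity)
        offset += len(m.vertices)
    return Mesh(
        vertices=np.concatenate(verts),
        faces=np.concatenate(faces),
        colors=np.concatenate(colors),
        opacity=np.concatenate(opac),
        kind="merged",
    )


# --------------------------------------------------------------------------
# VRML 2.0
# --------------------------------------------------------------------------

def write_vrml(scene: Scene, path) -> None:
    """Write the scene as a color-per-vertex VRML 2.0 file for 3D printing.

    Every primitive is tessellated; printable geometry is merged into one
    Shape per connected component (union-find over touching primitives).
    Transparency is not representable in print, so membranes are excluded
    with a logged warning.
    """
    meshes = _printable_meshes(scene, drop_membranes=True)
    lines = ["#VRML V2.0 utf8", "# pathflow motion structure — printable model"]
    if meshes:
        comps = connected_components(meshes)
        # deterministic component order: by smallest member index
        for comp in sorted(comps, key=min):
            merged = _merge_meshes([meshes[i] for i in sorted(comp)])
            lines.extend(_vrml_shape(merged))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _vrml_shape(mesh: Mesh) -> list[str]:
    lines = ["Shape {"]
    lines.append("  appearance Appearance { material Material { } }")
    lines.append("  geometry IndexedFaceSet {")
    lines.append("    colorPerVertex TRUE")
    lines.append("    coord Coordinate {")
    lines.append("      point [")
    lines.append(
        "        "
        + ",\n        ".join(f"{_f(v[0])} {_f(v[1])} {_f(v[2])}" for v in mesh.vertices)
    )
    lines.append("      ]")
    lines.append("    }")
    lines.append("    color Color {")
    lines.append("      color [")
    lines.append(
        "        "
        + ",\n        ".join(f"{_f(c[0])} {_f(c[1])} {_f(c[2])}" for c in mesh.colors)
    )
    lines.append("      ]")
    lines.append("    }")
    lines.append("    coordIndex [")
    lines.append(
        "      " + ",\n      ".join(f"{a}, {b}, {c}, -1" for a, b, c in mesh.faces)
    )
    lines.append("    ]")
    lines.append("  }")
    lines.append("}")
    return lines


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

def write_mesh(scene: Scene, path, format: str = "PLY") -> None:
    """Write the scene as a single per-vertex-colored ascii PLY mesh.

    Mirrors the on-screen form of the visualization: membranes are omitted;
    spheres and cylinders are tessellated.  Colors are quantized to 8 bits
    per channel with an alpha channel.
    """
    if format.upper() != "PLY":
        raise ValueError(f"unsupported mesh format: {format!r} (only PLY)")
    meshes = _printable_meshes(scene, drop_membranes=True)
    merged = (
        _merge_meshes(meshes)
        if meshes
        else Mesh(
            vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int),
            colors=np.zeros((0, 3)), opacity=np.zeros(0),
        )
    )
    q = np.clip(np.rint(merged.colors * 255.0), 0, 255).astype(int)
    a = np.clip(np.rint(merged.opacity * 255.0), 0, 255).astype(int)
    lines = [
        "ply",
        "format ascii 1.0",
        "comment pathflow motion structure",
        f"element vertex {len(merged.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "property uchar alpha",
        f"element face {len(merged.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, c, al in zip(merged.vertices, q, a):
        lines.append(
            f"{_f(v[0])} {_f(v[1])} {_f(v[2])} {c[0]} {c[1]} {c[2]} {al}"
        )
    for f3 in merged.faces:
        lines.append(f"3 {f3[0]} {f3[1]} {f3[2]}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
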