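"""Simple analytic test shapes (outward-oriented triangle meshes)."""

from __future__ import annotations

import numpy as np

from .mesh_core import SurfaceMesh

__all__ = ["box", "icosphere", "open_hemisphere", "open_cylinder", "uv_sphere"]


def box(extent=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Axis-aligned box of 12 outward-oriented triangles."""
    e = np.asarray(extent, dtype=float)
    o = np.asarray(origin, dtype=float)
    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                       dtype=float)
    verts = o + corners * e
    # index = 4*x + 2*y + z
    faces = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0, normal -x
        [4, 7, 5], [4, 6, 7],          # x = 1, normal +x
        [0, 4, 5], [0, 5, 1],          # y = 0, normal -y
        [2, 3, 7], [2, 7, 6],          # y = 1, normal +y
        [0, 2, 6], [0, 6, 4],          # z = 0, normal -z
        [1, 5, 7], [1, 7, 3],          # z = 1, normal +z
    ], dtype=np.int64)
    return SurfaceMesh(verts, faces)


def icosphere(radius: float = 1.0, subdivisions: int = 3,
              center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Subdivided icosahedron projected to a sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts[0])
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            idx = cache.get(key)
            if idx is None:
                m = vlist[a] + vlist[b]
                m = m / np.linalg.norm(m)
                idx = len(vlist)
                vlist.append(m)
                cache[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)
    return SurfaceMesh(np.asarray(center, dtype=float) + radius * verts, faces)


def uv_sphere(radius: float = 1.0, n_theta: int = 24, n_phi: int = 48,
              center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Latitude-longitude sphere (useful when targets must differ in layout
    from an icosphere source)."""
    mesh = open_hemisphere(radius, n_theta, n_phi, full=True)
    return SurfaceMesh(np.asarray(center, dtype=float) + mesh.vertices, mesh.faces)


def open_hemisphere(radius: float = 1.0, n_theta: int = 12, n_phi: int = 36,
                    full: bool = False) -> SurfaceMesh:
    """Upper hemisphere (z >= 0) open at the equator; ``full=True`` builds the
    whole sphere instead."""
    lat_lo = -np.pi / 2 if full else 0.0
    thetas = np.linspace(lat_lo, np.pi / 2, n_theta + 1)
    verts = []
    rows = []
    for ti, t in enumerate(thetas):
        if ti == len(thetas) - 1:
            rows.append([len(verts)])
            verts.append([0.0, 0.0, radius])
            continue
        if full and ti == 0:
            rows.append([len(verts)])
            verts.append([0.0, 0.0, -radius])
            continue
        ring = []
        for p in np.linspace(0, 2 * np.pi, n_phi, endpoint=False):
            ring.append(len(verts))
            verts.append([radius * np.cos(t) * np.cos(p),
                          radius * np.cos(t) * np.sin(p),
                          radius * np.sin(t)])
        rows.append(ring)
    faces = []
    for r0, r1 in zip(rows[:-1], rows[1:]):
        faces += _stitch_rows(r0, r1)
    return SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def _stitch_rows(lower: list[int], upper: list[int]) -> list[list[int]]:
    """Triangles between two latitude rings (either may be a single pole).
    Lower ring is CCW seen from +z outside; output faces outward."""
    faces = []
    if len(upper) == 1:
        c = upper[0]
        n = len(lower)
        for i in range(n):
            faces.append([lower[i], lower[(i + 1) % n], c])
    elif len(lower) == 1:
        c = lower[0]
        n = len(upper)
        for i in range(n):
            faces.append([upper[(i + 1) % n], upper[i], c])
    else:
        n = len(lower)
        assert len(upper) == n
        for i in range(n):
            j = (i + 1) % n
            faces.append([lower[i], lower[j], upper[i]])
            faces.append([lower[j], upper[j], upper[i]])
    return faces


def open_cylinder(radius: float = 1.0, height: float = 2.0, n_phi: int = 48,
                  n_z: int = 8) -> SurfaceMesh:
    """Cylinder side wall open at both ends, outward-oriented, axis +z,
    base at z = 0."""
    verts = []
    rows = []
    for z in np.linspace(0, height, n_z + 1):
        ring = []
        for p in np.linspace(0, 2 * np.pi, n_phi, endpoint=False):
            ring.append(len(verts))
            verts.append([radius * np.cos(p), radius * np.sin(p), z])
        rows.append(ring)
    faces = []
    for r0, r1 in zip(rows[:-1], rows[1:]):
        faces += _stitch_rows(r0, r1)
    return SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))
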