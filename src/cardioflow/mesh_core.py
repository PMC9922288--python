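"""Triangle-mesh data model and geometric measures.

Vertices are in millimetres throughout; enclosed volumes are reported in
millilitres (mm^3 / 1000) to match the clinical flow conventions used
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Region",
    "SurfaceMesh",
    "RegionLabels",
    "OrificePlane",
    "build_incidence_matrix",
    "enclosed_volume",
    "surface_area",
    "boundary_loops",
    "cap_boundary_loops",
    "clip_by_plane",
    "extract_region",
    "extract_by_labels",
]

MM3_PER_ML = 1000.0


class Region(IntEnum):
    """Per-vertex anatomical labels of the left-heart blood-pool surface."""

    LV = 1
    LA = 2
    LAA = 3
    BOUNDARY_RING = 4
    LAA_OSTIUM = 5


@dataclass
class SurfaceMesh:
    """Oriented triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex indices per triangle, consistently oriented
        (counter-clockwise seen from outside for closed regions).
    """

    vertices: np.ndarray
    faces: np.ndarray
    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate faces (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, each stored once as (min, max), sorted
        lexicographically."""
        if self._edges is None:
            if self.faces.size == 0:
                self._edges = np.empty((0, 2), dtype=np.int64)
            else:
                e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                               self.faces[:, [2, 0]]])
                e.sort(axis=1)
                self._edges = np.unique(e, axis=0)
        return self._edges

    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same topology, new vertex positions."""
        return SurfaceMesh(vertices, self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class RegionLabels:
    """One :class:`Region` label per vertex."""

    vertex_region: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_region = np.asarray(self.vertex_region, dtype=np.int64)
        valid = np.isin(self.vertex_region, [int(r) for r in Region])
        if not valid.all():
            bad = np.unique(self.vertex_region[~valid])
            raise ValueError(f"unknown region labels: {bad.tolist()}")

    def indices_of(self, *regions: Region) -> np.ndarray:
        return np.flatnonzero(np.isin(self.vertex_region, [int(r) for r in regions]))

    def __len__(self) -> int:
        return len(self.vertex_region)


@dataclass
class OrificePlane:
    """Static plane separating the LAA from the LA.

    ``unit_normal`` points from the LAA side toward the LA side.
    """

    point: np.ndarray
    unit_normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.unit_normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        self.unit_normal = n / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.unit_normal


# ---------------------------------------------------------------------------
# connectivity


def build_incidence_matrix(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Node-arc incidence matrix: one row per unique undirected edge, one
    column per vertex, with -1 at the lower vertex index and +1 at the
    higher.  Rows are ordered lexicographically by (min, max) index."""
    edges = mesh.edges
    ne = len(edges)
    if ne == 0:
        raise ValueError("no edges")
    rows = np.repeat(np.arange(ne), 2)
    cols = edges.ravel()
    data = np.tile([-1.0, 1.0], ne)
    return sp.csr_matrix((data, (rows, cols)), shape=(ne, mesh.n_vertices))


def _directed_edge_counts(mesh: SurfaceMesh):
    f = mesh.faces
    de = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    return de


def _boundary_directed_edges(mesh: SurfaceMesh) -> np.ndarray:
    """Directed edges that occur in exactly one face and whose reverse occurs
    in none — i.e. the oriented boundary of the surface."""
    de = _directed_edge_counts(mesh)
    und = np.sort(de, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    if counts.max(initial=0) > 2:
        bad = uniq[np.argmax(counts)]
        raise ValueError(f"non-manifold edge {tuple(bad.tolist())}: shared by >2 faces")
    return de[counts[inv] == 1]


def is_closed(mesh: SurfaceMesh) -> bool:
    """A mesh bounds a volume iff its directed-edge multiset is balanced
    (every directed edge is matched by its reverse)."""
    if mesh.n_faces == 0:
        return False
    de = _directed_edge_counts(mesh).astype(np.int64)
    n = mesh.n_vertices
    code = de[:, 0] * n + de[:, 1]
    rcode = de[:, 1] * n + de[:, 0]
    return bool(np.array_equal(np.sort(code), np.sort(rcode)))


def boundary_loops(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary, following face orientation.

    Raises if the boundary is non-manifold (a vertex with more than one
    outgoing boundary edge).
    """
    bde = _boundary_directed_edges(mesh)
    if len(bde) == 0:
        return []
    nxt: dict[int, int] = {}
    for a, b in bde:
        a, b = int(a), int(b)
        if a in nxt:
            raise ValueError(f"non-manifold boundary at edge ({a}, {b})")
        nxt[a] = b
    loops = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            if cur in seen or cur not in nxt:
                raise ValueError(f"non-manifold boundary at edge ({loop[-1]}, {cur})")
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


# ---------------------------------------------------------------------------
# measures


def _signed_volume_mm3(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume of a closed oriented mesh via the divergence theorem,
    in ml.  Validates closedness; warns and takes |V| if the orientation is
    inward."""
    if not is_closed(mesh):
        raise ValueError("mesh not closed; cap boundaries first")
    v = _signed_volume_mm3(mesh.vertices, mesh.faces)
    if v < 0:
        warnings.warn("mesh oriented inward (signed volume < 0); using |V|",
                      stacklevel=2)
    return abs(v) / MM3_PER_ML


def vertex_normals(faces: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Area-weighted per-vertex normals (unit length where defined)."""
    v0 = positions[faces[:, 0]]
    fn = np.cross(positions[faces[:, 1]] - v0, positions[faces[:, 2]] - v0)
    out = np.zeros_like(positions)
    for k in range(3):
        np.add.at(out, faces[:, k], fn)
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    return out / norms[:, None]


def surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area in mm^2."""
    if mesh.n_faces == 0:
        return 0.0
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum())


# ---------------------------------------------------------------------------
# capping / clipping


def cap_topology(mesh: SurfaceMesh):
    """Fan-cap topology for every boundary loop.

    Returns ``(cap_faces, loops)`` where ``cap_faces`` references one new
    centroid vertex per loop, appended after the existing vertices in loop
    order.  Splitting topology from coordinates lets callers re-cap a
    deforming mesh without re-tracing loops.
    """
    loops = boundary_loops(mesh)
    n = mesh.n_vertices
    cap_faces = []
    for li, loop in enumerate(loops):
        c = n + li
        # boundary directed edges run a->b with the surface on their left;
        # the cap triangle (b, a, c) restores outward orientation.
        for a, b in zip(loop, np.roll(loop, -1)):
            cap_faces.append((b, a, c))
    cap_faces = (np.asarray(cap_faces, dtype=np.int64)
                 if cap_faces else np.empty((0, 3), dtype=np.int64))
    return cap_faces, loops


def loop_centroids(vertices: np.ndarray, loops: list[np.ndarray]) -> np.ndarray:
    if not loops:
        return np.empty((0, 3))
    return np.array([vertices[loop].mean(axis=0) for loop in loops])


def cap_boundary_loops(mesh: SurfaceMesh) -> SurfaceMesh:
    """Close every boundary loop with a centroid fan; already-closed meshes
    are returned unchanged."""
    cap_faces, loops = cap_topology(mesh)
    if not loops:
        return mesh
    vertices = np.vstack([mesh.vertices, loop_centroids(mesh.vertices, loops)])
    faces = np.vstack([mesh.faces, cap_faces])
    return SurfaceMesh(vertices, faces)


def clip_by_plane(mesh: SurfaceMesh, plane: OrificePlane,
                  keep: str = "negative") -> SurfaceMesh:
    """Cut a closed mesh by a plane and return the capped part on one side.

    ``keep="negative"`` returns the sub-surface where the signed distance to
    the plane is negative (the LAA side for an ostium plane whose normal
    points toward the LA).  Triangles are split exactly at the plane so that
    volume is conserved between the two sides.
    """
    if keep not in ("negative", "positive"):
        raise ValueError("keep must be 'negative' or 'positive'")
    sign = -1.0 if keep == "negative" else 1.0
    d = sign * plane.signed_distance(mesh.vertices)  # keep side: d > 0

    if np.all(d >= 0):
        return mesh
    if np.all(d <= 0):
        return SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))

    verts = [mesh.vertices]
    n_base = mesh.n_vertices
    new_index: dict[tuple[int, int], int] = {}
    extra: list[np.ndarray] = []

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = new_index.get(key)
        if idx is None:
            a, b = key
            t = d[a] / (d[a] - d[b])  # d[a], d[b] have opposite signs
            p = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
            idx = n_base + len(extra)
            extra.append(p)
            new_index[key] = idx
        return idx

    kept_faces: list[tuple[int, int, int]] = []
    for tri in mesh.faces:
        dd = d[tri]
        if np.all(dd >= 0):
            kept_faces.append(tuple(int(x) for x in tri))
            continue
        if np.all(dd <= 0):
            continue
        # polygon clip (Sutherland–Hodgman) of the triangle against d >= 0
        poly: list[int] = []
        for k in range(3):
            i, j = int(tri[k]), int(tri[(k + 1) % 3])
            di, dj = d[i], d[j]
            if di >= 0:
                poly.append(i)
            if (di > 0 and dj < 0) or (di < 0 and dj > 0):
                poly.append(cut_point(i, j))
        for k in range(1, len(poly) - 1):
            a, b, c = poly[0], poly[k], poly[k + 1]
            if a != b and b != c and a != c:
                kept_faces.append((a, b, c))

    if not kept_faces:
        return SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))

    all_verts = np.vstack(verts + [np.asarray(extra)]) if extra else mesh.vertices
    faces = np.asarray(kept_faces, dtype=np.int64)
    used = np.unique(faces)
    remap = np.full(len(all_verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    clipped = SurfaceMesh(all_verts[used], remap[faces])

    # cap the planar cut: fan every boundary edge to the common cut centroid.
    # Unlike per-loop capping this tolerates pinched cut polylines that occur
    # on wrinkled tracked surfaces, and kept/discarded caps cancel exactly.
    bde = _boundary_directed_edges(clipped)
    if len(bde) == 0:
        return clipped
    bverts = np.unique(bde)
    centroid = clipped.vertices[bverts].mean(axis=0)
    ci = clipped.n_vertices
    cap = np.column_stack([bde[:, 1], bde[:, 0], np.full(len(bde), ci)])
    return SurfaceMesh(np.vstack([clipped.vertices, centroid[None, :]]),
                       np.vstack([clipped.faces, cap]))


# ---------------------------------------------------------------------------
# region extraction


def extract_by_labels(mesh: SurfaceMesh, labels: RegionLabels,
                      allowed: set[Region] | set[int]):
    """Submesh of faces whose three vertices all carry a label in ``allowed``.

    Returns ``(submesh, vertex_map)`` where ``vertex_map[i]`` is the parent
    index of submesh vertex ``i`` (use it to write deformed positions back).
    """
    if len(labels) != mesh.n_vertices:
        raise ValueError("labels length does not match vertex count")
    allowed_arr = np.asarray([int(a) for a in allowed])
    vert_ok = np.isin(labels.vertex_region, allowed_arr)
    face_ok = vert_ok[mesh.faces].all(axis=1)
    faces = mesh.faces[face_ok]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = SurfaceMesh(mesh.vertices[used], remap[faces])
    return sub, used


def extract_region(mesh: SurfaceMesh, labels: RegionLabels, region: Region):
    """Submesh of one anatomical region.  The LAA ostium ring is shared: it
    is included both with ``region=Region.LAA`` and with ``region=Region.LA``."""
    region = Region(region)
    if not np.any(labels.vertex_region == int(region)):
        raise ValueError(f"region {region.name} not present in labels")
    allowed: set[Region] = {region}
    if region in (Region.LAA, Region.LA):
        allowed.add(Region.LAA_OSTIUM)
    if region is Region.LA:
        allowed.add(Region.BOUNDARY_RING)  # pulmonary-vein cut rim
    return extract_by_labels(mesh, labels, allowed)
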