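"""Image thresholding to surfaces and file I/O.

Conventions: 0-based voxel indices; the world coordinate of voxel (i, j, k)
is ``origin + spacing * (i, j, k)`` (voxel centers).  Contrast-enhanced
blood is bright, so the blood-pool mask is ``voxels >= threshold``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .mesh_core import RegionLabels, SurfaceMesh, _signed_volume_mm3

__all__ = [
    "ImageVolume",
    "threshold_blood_pool",
    "mask_to_surface",
    "read_mesh",
    "write_mesh",
    "read_image",
    "write_image",
    "write_curve",
    "read_curve",
    "write_metrics",
]

MESH_FORMATS = (".stl", ".ply", ".vtk")
IMAGE_FORMATS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class ImageVolume:
    """3-D scalar grid in Hounsfield units with mm spacing and origin."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")


# ---------------------------------------------------------------------------
# segmentation


def threshold_blood_pool(img: ImageVolume, threshold: float = 250.0,
                         largest_component: bool = True) -> np.ndarray:
    """Binary blood-pool mask: voxels >= threshold (250 HU default),
    optionally reduced to the largest 26-connected component."""
    if img.voxels.size == 0:
        raise ValueError("empty image")
    mask = img.voxels >= threshold
    if not mask.any():
        raise ValueError("no blood pool above threshold")
    if largest_component:
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        lab, n = ndimage.label(mask, structure=structure)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def mask_to_surface(mask: np.ndarray, spacing, origin) -> SurfaceMesh:
    """Marching-cubes isosurface of a binary mask at level 0.5, in world
    coordinates, closed and oriented outward."""
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("mask has no foreground voxels")
    padded = np.pad(mask.astype(np.float32), 1)  # guarantee a closed surface
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * np.asarray(spacing, float) + np.asarray(origin, float)
    mesh = SurfaceMesh(verts, faces.astype(np.int64))
    if _signed_volume_mm3(mesh.vertices, mesh.faces) < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


# ---------------------------------------------------------------------------
# mesh I/O


def _format_error(path: Path, formats) -> ValueError:
    return ValueError(
        f"unknown format {path.suffix!r} for {path.name}; supported: "
        + ", ".join(formats))


def write_mesh(path, mesh: SurfaceMesh, labels: RegionLabels | None = None) -> None:
    """Write STL (geometry only), PLY or legacy VTK polydata; labels are
    stored as a per-vertex integer attribute (PLY/VTK only)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".stl":
        if labels is not None:
            raise ValueError("STL cannot carry per-vertex labels; use PLY or VTK")
        _write_stl(path, mesh)
    elif ext == ".ply":
        _write_ply(path, mesh, labels)
    elif ext == ".vtk":
        _write_vtk(path, mesh, labels)
    else:
        raise _format_error(path, MESH_FORMATS)


def read_mesh(path) -> tuple[SurfaceMesh, RegionLabels | None]:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".stl":
        return _read_stl(path), None
    if ext == ".ply":
        return _read_ply(path)
    if ext == ".vtk":
        return _read_vtk(path)
    raise _format_error(path, MESH_FORMATS)


def _write_stl(path: Path, mesh: SurfaceMesh) -> None:
    v = mesh.vertices
    with open(path, "w") as fh:
        fh.write("solid surface\n")
        for f in mesh.faces:
            n = np.cross(v[f[1]] - v[f[0]], v[f[2]] - v[f[0]])
            nl = np.linalg.norm(n)
            n = n / nl if nl > 0 else n
            fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
            fh.write("    outer loop\n")
            for idx in f:
                p = v[idx]
                fh.write("      vertex "
                         f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid surface\n")


def _read_stl(path: Path) -> SurfaceMesh:
    head = open(path, "rb").read(5)
    if head != b"solid":
        return _read_stl_binary(path)
    verts: list[tuple[float, float, float]] = []
    faces = []
    index: dict[tuple[float, float, float], int] = {}
    tri: list[int] = []
    for line in open(path):
        parts = line.split()
        if parts[:1] == ["vertex"]:
            key = (float(parts[1]), float(parts[2]), float(parts[3]))
            i = index.get(key)
            if i is None:
                i = len(verts)
                verts.append(key)
                index[key] = i
            tri.append(i)
            if len(tri) == 3:
                faces.append(tri)
                tri = []
    return SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def _read_stl_binary(path: Path) -> SurfaceMesh:
    raw = open(path, "rb").read()
    n_tri = int(np.frombuffer(raw[80:84], dtype="<u4")[0])
    rec = np.frombuffer(raw[84:84 + n_tri * 50], dtype=np.uint8).reshape(n_tri, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(n_tri, 3, 3).astype(float)
    flat = tri.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    return SurfaceMesh(uniq, inv.reshape(n_tri, 3).astype(np.int64))


def _write_ply(path: Path, mesh: SurfaceMesh, labels: RegionLabels | None) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if labels is not None:
            fh.write("property int region\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i, p in enumerate(mesh.vertices):
            row = f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}"
            if labels is not None:
                row += f" {int(labels.vertex_region[i])}"
            fh.write(row + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_ply(path: Path):
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"{path.name}: not a PLY file")
        fmt = fh.readline().strip()
        if "ascii" not in fmt:
            raise ValueError(f"{path.name}: only ASCII PLY is supported")
        n_vert = n_face = 0
        vertex_props: list[str] = []
        element = None
        for line in fh:
            line = line.strip()
            if line.startswith("comment"):
                continue
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1]); element = "vertex"
            elif line.startswith("element face"):
                n_face = int(line.split()[-1]); element = "face"
            elif line.startswith("property") and element == "vertex":
                vertex_props.append(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.empty((n_vert, 3))
        regions = np.empty(n_vert, dtype=np.int64) if "region" in vertex_props else None
        ri = vertex_props.index("region") if regions is not None else -1
        for i in range(n_vert):
            parts = fh.readline().split()
            verts[i] = [float(parts[vertex_props.index(c)]) for c in "xyz"]
            if regions is not None:
                regions[i] = int(parts[ri])
        faces = np.empty((n_face, 3), dtype=np.int64)
        for i in range(n_face):
            parts = fh.readline().split()
            if parts[0] != "3":
                raise ValueError(f"{path.name}: non-triangle face")
            faces[i] = [int(x) for x in parts[1:4]]
    labels = RegionLabels(regions) if regions is not None else None
    return SurfaceMesh(verts, faces), labels


def _write_vtk(path: Path, mesh: SurfaceMesh, labels: RegionLabels | None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsurface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if labels is not None:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
            for r in labels.vertex_region:
                fh.write(f"{int(r)}\n")


def _read_vtk(path: Path):
    tokens: list[str] = []
    for li, line in enumerate(open(path)):
        if li == 2 and line.strip().upper() != "ASCII":
            raise ValueError(f"{path.name}: only ASCII legacy VTK is supported")
        if li >= 3:
            tokens.extend(line.split())
    i = 0

    def expect(word):
        nonlocal i
        while tokens[i].upper() != word:
            i += 1

    expect("POINTS")
    n_vert = int(tokens[i + 1]); i += 3
    verts = np.array(tokens[i:i + 3 * n_vert], dtype=float).reshape(n_vert, 3)
    i += 3 * n_vert
    expect("POLYGONS")
    n_face = int(tokens[i + 1]); i += 3
    faces = []
    for _ in range(n_face):
        cnt = int(tokens[i])
        if cnt != 3:
            raise ValueError(f"{path.name}: non-triangle polygon")
        faces.append([int(tokens[i + 1]), int(tokens[i + 2]), int(tokens[i + 3])])
        i += 4
    labels = None
    rest = [t.upper() for t in tokens[i:]]
    if "SCALARS" in rest:
        j = i + rest.index("SCALARS")
        name = tokens[j + 1]
        k = j
        while tokens[k].upper() != "LOOKUP_TABLE":
            k += 1
        vals = np.array(tokens[k + 2:k + 2 + n_vert], dtype=np.int64)
        if name == "region":
            labels = RegionLabels(vals)
    return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64)), labels


# ---------------------------------------------------------------------------
# image I/O


def read_image(path) -> ImageVolume:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        origin = affine[:3, 3]
        return ImageVolume(data, spacing, origin)
    if name.endswith((".mha", ".mhd")):
        return _read_metaimage(path)
    raise _format_error(path, IMAGE_FORMATS)


def write_image(path, img: ImageVolume) -> None:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag(list(img.spacing) + [1.0])
        affine[:3, 3] = img.origin
        nib.save(nib.Nifti1Image(img.voxels.astype(np.float32), affine), str(path))
        return
    if name.endswith(".mha"):
        _write_metaimage(path, img)
        return
    raise _format_error(path, (".nii", ".nii.gz", ".mha"))


_MET_TYPES = {"MET_UCHAR": np.uint8, "MET_CHAR": np.int8,
              "MET_SHORT": np.int16, "MET_USHORT": np.uint16,
              "MET_INT": np.int32, "MET_FLOAT": np.float32,
              "MET_DOUBLE": np.float64}


def _read_metaimage(path: Path) -> ImageVolume:
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline().decode("latin-1")
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
            if key.strip() == "ElementDataFile":
                break
        data_file = header["ElementDataFile"]
        if header.get("CompressedData", "False").lower() == "true":
            raise ValueError("compressed MetaImage is not supported")
        dims = [int(x) for x in header["DimSize"].split()]
        dtype = _MET_TYPES[header["ElementType"]]
        count = int(np.prod(dims))
        if data_file == "LOCAL":
            raw = fh.read(count * np.dtype(dtype).itemsize)
        else:
            raw = open(path.parent / data_file, "rb").read()
    voxels = np.frombuffer(raw, dtype=dtype, count=count)
    # MetaImage stores x fastest; our arrays index (i, j, k) = (x, y, z)
    voxels = voxels.reshape(dims[::-1]).transpose(2, 1, 0).astype(float)
    spacing = [float(x) for x in header.get(
        "ElementSpacing", header.get("ElementSize", "1 1 1")).split()]
    origin = [float(x) for x in header.get(
        "Offset", header.get("Position", "0 0 0")).split()]
    return ImageVolume(voxels, spacing, origin)


def _write_metaimage(path: Path, img: ImageVolume) -> None:
    vox = img.voxels.astype(np.float32)
    with open(path, "wb") as fh:
        head = (
            "ObjectType = Image\nNDims = 3\nBinaryData = True\n"
            "BinaryDataByteOrderMSB = False\nCompressedData = False\n"
            f"DimSize = {vox.shape[0]} {vox.shape[1]} {vox.shape[2]}\n"
            f"ElementSpacing = {img.spacing[0]} {img.spacing[1]} {img.spacing[2]}\n"
            f"Offset = {img.origin[0]} {img.origin[1]} {img.origin[2]}\n"
            "ElementType = MET_FLOAT\nElementDataFile = LOCAL\n")
        fh.write(head.encode())
        fh.write(vox.transpose(2, 1, 0).tobytes())


# ---------------------------------------------------------------------------
# curves and metrics


def write_curve(path, times: np.ndarray, values: np.ndarray,
                value_name: str = "flow_ml_per_s") -> None:
    """CSV with one header line: time_s,<value_name>; full float precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", value_name])
        for t, v in zip(times, values):
            w.writerow([repr(float(t)), repr(float(v))])


def read_curve(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    data = np.array(rows[1:], dtype=float)
    return data[:, 0], data[:, 1]


def write_metrics(path, metrics: dict[str, float]) -> None:
    """Metrics as two-column CSV (metric,value)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "value"])
        for k, v in metrics.items():
            w.writerow([k, repr(float(v))])
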