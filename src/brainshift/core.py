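"""Core volume/mesh/field types, coordinate conventions, interpolation and I/O.

Conventions
-----------
* Voxel indices are 0-based triples ``(i, j, k)`` mapping to world axes
  ``(x, y, z)`` through a diagonal affine: ``world = origin + index * spacing``.
  Oblique orientation matrices are not supported.
* World coordinates are millimetres throughout; displacement fields store
  millimetre vectors (never voxel offsets).
* Image warping is backward (pull): ``out(v) = vol(world(v) + field(v))``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "TetrahedralMesh",
    "DenseDeformationField",
    "PointSet",
    "MeshParseError",
    "voxel_to_world",
    "world_to_voxel",
    "sample_trilinear",
    "sample_field",
    "warp_image",
    "backward_from_forward",
    "invert_displacements",
    "compose_fields",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "read_mesh",
    "write_mesh",
    "read_points",
    "write_points",
]


def _as_triple(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with per-axis spacing and a world origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in arbitrary units.
    spacing : (3,) float
        Voxel size along each axis in mm; all components must be positive.
    origin : (3,) float
        World position (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must have 3 axes, got {self.data.ndim}")
        sp = _as_triple(self.spacing)
        if np.any(sp <= 0):
            raise ValueError(f"spacing components must be > 0, got {sp}")
        self.spacing = tuple(sp)
        self.origin = tuple(_as_triple(self.origin))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_geometry(self, other: "ImageVolume | DenseDeformationField") -> bool:
        return (
            tuple(self.shape[:3]) == tuple(np.shape(other.data)[:3])
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelVolume(ImageVolume):
    """3D grid of non-negative integer tissue labels; label 0 is background."""

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label data must be integer valued")
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")


@dataclass
class DenseDeformationField:
    """A grid of 3-vectors (mm) with the same geometry conventions as a volume."""

    vectors: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValueError("field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("field contains non-finite values")
        sp = _as_triple(self.spacing)
        if np.any(sp <= 0):
            raise ValueError("spacing components must be > 0")
        self.spacing = tuple(sp)
        self.origin = tuple(_as_triple(self.origin))

    # duck-type the geometry checks used for volumes
    @property
    def data(self) -> np.ndarray:
        return self.vectors

    @property
    def shape(self) -> tuple:
        return self.vectors.shape[:3]


@dataclass
class PointSet:
    """An ordered list of world-coordinate (mm) points."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point set contains non-finite coordinates")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class TetrahedralMesh:
    """Tetrahedral mesh: vertices in mm, 4-tuples of vertex indices, tet labels.

    Every tetrahedron must have positive signed volume under the convention
    ``6V = det[v1-v0, v2-v0, v3-v0]``.
    """

    vertices: np.ndarray
    tets: np.ndarray
    tet_labels: np.ndarray = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        if self.tet_labels is None:
            self.tet_labels = np.ones(len(self.tets), dtype=np.int32)
        self.tet_labels = np.asarray(self.tet_labels, dtype=np.int32).reshape(-1)
        if len(self.tet_labels) != len(self.tets):
            raise ValueError("tet_labels length must equal number of tets")
        if len(self.tets) and (
            self.tets.min() < 0 or self.tets.max() >= len(self.vertices)
        ):
            raise ValueError("tet vertex index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_vertices(self) -> np.ndarray:
        """Vertex coordinates per tet, shape (n_tets, 4, 3)."""
        return self.vertices[self.tets]

    def volumes(self) -> np.ndarray:
        """Signed volumes, shape (n_tets,)."""
        v = self.tet_vertices()
        e = v[:, 1:] - v[:, :1]
        return np.linalg.det(e) / 6.0

    def centroids(self) -> np.ndarray:
        return self.tet_vertices().mean(axis=1)


# ---------------------------------------------------------------------------
# coordinate transforms and sampling
# ---------------------------------------------------------------------------

def voxel_to_world(v, vol) -> np.ndarray:
    """Map voxel indices to world mm: ``origin + v * spacing`` (vectorized)."""
    v = np.asarray(v, dtype=float)
    return np.asarray(vol.origin) + v * np.asarray(vol.spacing)


def world_to_voxel(p, vol) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (continuous voxel coordinates)."""
    p = np.asarray(p, dtype=float)
    return (p - np.asarray(vol.origin)) / np.asarray(vol.spacing)


def _grid_coords(vol, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous voxel coordinates plus an inside-grid mask."""
    c = world_to_voxel(np.atleast_2d(pts), vol)
    hi = np.asarray(vol.shape[:3], dtype=float) - 1.0
    inside = np.all((c >= 0.0) & (c <= hi), axis=1)
    return c, inside


def sample_trilinear(vol: ImageVolume, p, background: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of ``vol`` at world point(s) ``p``.

    Points outside the voxel-center hull return ``background``.
    Accepts a single point or an (n, 3) array; returns scalar or (n,) array.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    coords, inside = _grid_coords(vol, p)
    out = map_coordinates(
        np.asarray(vol.data, dtype=float), coords.T, order=1, mode="constant", cval=background
    )
    out = np.where(inside, out, background)
    return float(out[0]) if single else out


def sample_field(fld: DenseDeformationField, p, background: float = 0.0) -> np.ndarray:
    """Trilinearly sample a vector field at world point(s); zero outside."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    coords, inside = _grid_coords(fld, p)
    out = np.empty((len(p), 3))
    for a in range(3):
        out[:, a] = map_coordinates(
            fld.vectors[..., a], coords.T, order=1, mode="constant", cval=background
        )
    out[~inside] = background
    return out


def _grid_world(shape, spacing, origin) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    return np.asarray(origin) + idx * np.asarray(spacing)


def warp_image(
    vol: ImageVolume,
    fld: DenseDeformationField,
    order: int = 1,
    background: float = 0.0,
) -> ImageVolume:
    """Backward-warp ``vol`` onto the grid of ``fld``.

    ``out(v) = vol(world(v) + field(v))`` with interpolation of the given
    ``order`` (1 = trilinear for intensities, 0 = nearest for labels).
    """
    pts = _grid_world(fld.shape, fld.spacing, fld.origin) + fld.vectors
    coords = world_to_voxel(pts.reshape(-1, 3), vol)
    hi = np.asarray(vol.shape[:3], dtype=float) - 1.0
    inside = np.all((coords >= 0.0) & (coords <= hi), axis=1)
    data = map_coordinates(
        np.asarray(vol.data, dtype=float),
        coords.T,
        order=order,
        mode="constant",
        cval=background,
    )
    data = np.where(inside, data, background).reshape(fld.shape)
    cls = LabelVolume if order == 0 else ImageVolume
    if order == 0:
        data = np.round(data).astype(np.int32)
    return cls(data=data, spacing=fld.spacing, origin=fld.origin)


def invert_displacements(
    fld: DenseDeformationField, points: np.ndarray, n_iter: int = 20
) -> np.ndarray:
    """Forward displacement of material points under a backward field.

    A backward field ``t`` satisfies ``warped(v) = vol(v + t(v))``; the material
    point at ``p`` therefore lands at ``v`` with ``v + t(v) = p``.  This solves
    the fixed point ``g(p) = -t(p + g(p))`` by iteration and returns ``g``.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    g = np.zeros_like(p)
    for _ in range(n_iter):
        g = -sample_field(fld, p + g)
    return g


def backward_from_forward(
    forward: DenseDeformationField, n_iter: int = 10
) -> DenseDeformationField:
    """Invert a forward (push) displacement grid into a backward (pull) field.

    Solves ``b(v) = -u(v + b(v))`` by fixed-point iteration on the grid.
    """
    pts = _grid_world(forward.shape, forward.spacing, forward.origin).reshape(-1, 3)
    b = -forward.vectors.reshape(-1, 3).copy()
    for _ in range(n_iter):
        b = -sample_field(forward, pts + b)
    return DenseDeformationField(
        vectors=b.reshape(forward.vectors.shape),
        spacing=forward.spacing,
        origin=forward.origin,
    )


def compose_fields(
    outer: DenseDeformationField, inner: DenseDeformationField
) -> DenseDeformationField:
    """Compose two backward fields: ``c(v) = outer(v) + inner(v + outer(v))``.

    Warping with the result equals warping with ``inner`` then ``outer``.
    """
    pts = _grid_world(outer.shape, outer.spacing, outer.origin).reshape(-1, 3)
    o = outer.vectors.reshape(-1, 3)
    c = o + sample_field(inner, pts + o)
    return DenseDeformationField(
        vectors=c.reshape(outer.vectors.shape),
        spacing=outer.spacing,
        origin=outer.origin,
    )


def zero_field_like(vol) -> DenseDeformationField:
    return DenseDeformationField(
        vectors=np.zeros(tuple(vol.shape[:3]) + (3,)),
        spacing=vol.spacing,
        origin=vol.origin,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class MeshParseError(ValueError):
    """Raised when a mesh file is malformed; message names the offending field."""


def _affine(spacing, origin) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    A[:3, 3] = origin
    return A


def _geometry_from_affine(affine: np.ndarray, path) -> tuple[tuple, tuple]:
    off = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(affine))):
        raise ValueError(f"{path}: oblique orientation matrices are not supported")
    spacing = np.diag(affine[:3, :3])
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine must have positive diagonal spacing")
    return tuple(spacing), tuple(affine[:3, 3])


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine."""
    import nibabel as nib

    data = np.asarray(vol.data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_volume(path, labels: bool = False) -> ImageVolume:
    """Read a NIfTI volume; set ``labels=True`` to get a :class:`LabelVolume`."""
    import nibabel as nib

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume file not found: {p}")
    img = nib.load(str(p))
    spacing, origin = _geometry_from_affine(img.affine, p)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{p}: expected a 3D volume, got {data.ndim} axes")
    if labels:
        return LabelVolume(np.round(data).astype(np.int32), spacing, origin)
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)


def write_field(fld: DenseDeformationField, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(fld.vectors, _affine(fld.spacing, fld.origin))
    nib.save(img, str(path))


def read_field(path) -> DenseDeformationField:
    import nibabel as nib

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"field file not found: {p}")
    img = nib.load(str(p))
    spacing, origin = _geometry_from_affine(img.affine, p)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"{p}: expected a (nx, ny, nz, 3) deformation field")
    return DenseDeformationField(data, spacing, origin)


def write_mesh(mesh: TetrahedralMesh, path) -> None:
    """Write a tet mesh as legacy ASCII VTK with a ``tissue_label`` cell array."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tetrahedral mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        for _ in range(mesh.n_tets):
            fh.write("10\n")
        fh.write(f"CELL_DATA {mesh.n_tets}\n")
        fh.write("SCALARS tissue_label int 1\nLOOKUP_TABLE default\n")
        for lab in mesh.tet_labels:
            fh.write(f"{int(lab)}\n")


def read_mesh(path) -> TetrahedralMesh:
    """Parse a legacy ASCII VTK unstructured grid of tetrahedra."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mesh file not found: {p}")
    tokens: list[str] = []
    with open(p) as fh:
        lines = fh.readlines()
    if len(lines) < 5:
        raise MeshParseError(f"{p}: truncated VTK header")
    if "vtk" not in lines[0].lower():
        raise MeshParseError(f"{p}: missing '# vtk DataFile' header line")
    body = lines[2:]
    if body[0].strip().upper() != "ASCII":
        raise MeshParseError(f"{p}: only ASCII VTK files are supported (format field)")
    for ln in body[1:]:
        tokens.extend(ln.split())
    it = iter(range(len(tokens)))
    pos = 0

    def expect(word: str):
        nonlocal pos
        if pos >= len(tokens) or tokens[pos].upper() != word:
            got = tokens[pos] if pos < len(tokens) else "<eof>"
            raise MeshParseError(f"{p}: expected '{word}', got '{got}'")
        pos += 1

    def take_int(what: str) -> int:
        nonlocal pos
        try:
            val = int(tokens[pos])
        except (IndexError, ValueError) as exc:
            raise MeshParseError(f"{p}: bad integer for {what}") from exc
        pos += 1
        return val

    def take_float(what: str) -> float:
        nonlocal pos
        try:
            val = float(tokens[pos])
        except (IndexError, ValueError) as exc:
            raise MeshParseError(f"{p}: bad number for {what}") from exc
        pos += 1
        return val

    expect("DATASET")
    expect("UNSTRUCTURED_GRID")
    expect("POINTS")
    npts = take_int("POINTS count")
    pos += 1  # dtype token
    verts = np.array(
        [[take_float("point coordinate") for _ in range(3)] for _ in range(npts)]
    )
    expect("CELLS")
    ncell = take_int("CELLS count")
    take_int("CELLS size")
    tets = np.empty((ncell, 4), dtype=np.int64)
    for i in range(ncell):
        k = take_int("cell arity")
        if k != 4:
            raise MeshParseError(f"{p}: cell {i} has {k} vertices; only tetrahedra supported")
        for j in range(4):
            tets[i, j] = take_int("cell vertex index")
    expect("CELL_TYPES")
    nct = take_int("CELL_TYPES count")
    for i in range(nct):
        ct = take_int("cell type")
        if ct != 10:
            raise MeshParseError(f"{p}: cell type {ct} is not VTK_TETRA")
    labels = None
    if pos < len(tokens) and tokens[pos].upper() == "CELL_DATA":
        pos += 1
        take_int("CELL_DATA count")
        expect("SCALARS")
        name = tokens[pos]
        pos += 2  # name, dtype
        if pos < len(tokens) and tokens[pos].upper() == "1":
            pos += 1
        expect("LOOKUP_TABLE")
        pos += 1
        labels = np.array([take_int(f"{name} value") for _ in range(ncell)], dtype=np.int32)
    return TetrahedralMesh(verts, tets, labels)


def write_points(ps: PointSet, path) -> None:
    np.savetxt(path, ps.points, fmt="%.10g")


def read_points(path) -> PointSet:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"point file not found: {p}")
    arr = np.loadtxt(str(p), ndmin=2)
    if arr.size == 0:
        arr = np.zeros((0, 3))
    if arr.shape[1] != 3:
        raise ValueError(f"{p}: expected 3 columns (x y z), got {arr.shape[1]}")
    return PointSet(arr)
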