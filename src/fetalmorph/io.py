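"""Volume and mesh I/O plus the shared geometric conventions.

Conventions
-----------
* Voxel indices are 0-based; the world frame is the NIfTI affine (RAS, mm).
* Closed surface meshes carry outward normals (signed volume > 0); this fixes
  the sign of the principal curvatures globally so that gyri are convex.
* Default label codes: background=0, unmyelinated_wm=1, ventricles=2,
  cerebellum=3, overridable via a JSON sidecar or explicit ``label_map``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .errors import FormatError, GeometryError

DEFAULT_LABEL_MAP = {
    "background": 0,
    "unmyelinated_wm": 1,
    "ventricles": 2,
    "cerebellum": 3,
}

_ISO_TOL = 1e-6  # mm; spacing spread below this counts as isotropic


@dataclass
class LabelVolume:
    """3D integer segmentation grid with world-coordinate geometry.

    Parameters
    ----------
    data : (nx, ny, nz) ndarray of non-negative integers
        Label codes per voxel.
    affine : (4, 4) ndarray
        Voxel-index (0-based) to world-mm map.
    label_map : dict
        Structure name -> integer code. Always contains ``background=0``.
    """

    data: np.ndarray
    affine: np.ndarray
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            flat = np.asarray(self.data, dtype=float)
            if not np.all(flat == np.round(flat)):
                raise FormatError("label volume data must be integer-valued")
            self.data = flat.astype(np.int32)
        if self.data.ndim != 3:
            raise FormatError("label volume must be 3D")
        if np.any(self.data < 0):
            raise FormatError("label codes must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        self.label_map = dict(self.label_map)
        self.label_map.setdefault("background", 0)
        codes = set(self.label_map.values())
        present = set(np.unique(self.data).tolist())
        unknown = present - codes - {0}
        if unknown:
            raise FormatError(f"labels {sorted(unknown)} not in label_map")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def isotropic(self) -> bool:
        s = self.spacing
        return float(s.max() - s.min()) < _ISO_TOL

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def code(self, structure: str) -> int:
        if structure not in self.label_map:
            raise KeyError(f"unknown structure {structure!r}")
        return int(self.label_map[structure])

    def mask(self, structure: str) -> np.ndarray:
        return self.data == self.code(structure)

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class SurfaceMesh:
    """Triangle mesh in world mm with optional per-vertex scalar fields."""

    vertices: np.ndarray
    faces: np.ndarray
    fields: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be (M, 3) triangles")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise FormatError("face indices out of range")
        if self.faces.size:
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise FormatError("degenerate (repeated-index) faces")
        for name, values in self.fields.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != (n,):
                raise FormatError(f"field {name!r} must have one value per vertex")
            self.fields[name] = arr

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, fields: dict | None = None) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, dtype=float),
                   np.asarray(tm.faces, dtype=np.int64),
                   dict(fields or {}))

    def with_fields(self, **fields) -> "SurfaceMesh":
        merged = dict(self.fields)
        merged.update(fields)
        return SurfaceMesh(self.vertices, self.faces, merged)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def signed_volume(self) -> float:
        """Divergence-theorem signed volume; positive for outward winding."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)

    def edge_lengths(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        return np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric lumped vertex areas (1/3 of incident triangle areas)."""
        tri = self.triangle_areas()
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], tri / 3.0)
        return out


# ---------------------------------------------------------------------------
# NIfTI label volumes
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_label_volume(path, label_map: dict | None = None) -> LabelVolume:
    """Read a NIfTI segmentation.

    The label map is taken from, in order of precedence: the ``label_map``
    argument, a JSON sidecar next to the file, the package defaults.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if label_map is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            label_map = {k: int(v) for k, v in json.loads(sidecar.read_text()).items()}
        else:
            label_map = dict(DEFAULT_LABEL_MAP)
    return LabelVolume(data, img.affine, label_map)


def write_label_volume(vol: LabelVolume, path, sidecar: bool = True) -> None:
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.int16), vol.affine)
    nib.save(img, str(path))
    if sidecar:
        _sidecar_path(path).write_text(json.dumps(vol.label_map, indent=1))


# ---------------------------------------------------------------------------
# PLY via trimesh
# ---------------------------------------------------------------------------

def _read_ply(path: Path, triangulate: bool) -> SurfaceMesh:
    tm = trimesh.load(str(path), file_type="ply", process=False)
    raw = tm.metadata.get("_ply_raw", {})

    def _columns(block):
        """PLY element data as {property: array}; handles both the dict and
        structured-array layouts trimesh produces."""
        data = block["data"]
        if isinstance(data, dict):
            return data
        names = data.dtype.names or ()
        return {n: data[n] for n in names}

    if not triangulate and "face" in raw:
        fdata = _columns(raw["face"])
        idx = fdata.get("vertex_indices", fdata.get("vertex_index"))
        if idx is not None:
            arr = np.asarray(idx)
            if arr.dtype.names:  # binary list property: (count, indices)
                lengths = set(np.unique(arr[arr.dtype.names[0]]).tolist())
            elif arr.dtype == object:
                lengths = {len(np.atleast_1d(row)) for row in arr}
            elif arr.ndim >= 2:
                lengths = {arr.shape[-1]}
            else:
                lengths = {len(np.atleast_1d(row)) for row in arr}
            if lengths - {3}:
                raise FormatError("non-triangular faces (pass triangulate=True to allow)")
    fields = {}
    if "vertex" in raw:
        for name, arr in _columns(raw["vertex"]).items():
            if name in ("x", "y", "z", "nx", "ny", "nz", "red", "green", "blue", "alpha"):
                continue
            fields[name] = np.asarray(arr, dtype=float).ravel()
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64), fields)


def _write_ply(mesh: SurfaceMesh, path: Path, binary: bool) -> None:
    tm = mesh.to_trimesh()
    for name, values in mesh.fields.items():
        tm.vertex_attributes[name] = np.asarray(values, dtype=np.float64)
    encoding = "binary" if binary else "ascii"
    data = trimesh.exchange.ply.export_ply(tm, encoding=encoding, include_attributes=True)
    path.write_bytes(data)


# ---------------------------------------------------------------------------
# Legacy VTK ASCII polydata (hand-rolled: tiny, self-contained format)
# ---------------------------------------------------------------------------

def _read_vtk(path: Path, triangulate: bool) -> SurfaceMesh:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise FormatError("not a legacy VTK file")
    tokens: list[str] = []
    for ln in lines[2:]:  # skip header comment line
        tokens.extend(ln.split())
    it = iter(range(len(tokens)))

    def find(word, start=0):
        for i in range(start, len(tokens)):
            if tokens[i].upper() == word:
                return i
        return -1

    if find("ASCII") < 0:
        raise FormatError("only ASCII legacy VTK is supported")
    i = find("POLYDATA")
    if i < 0:
        raise FormatError("only DATASET POLYDATA is supported")
    i = find("POINTS")
    n = int(tokens[i + 1])
    coords = np.array(tokens[i + 3: i + 3 + 3 * n], dtype=float).reshape(n, 3)
    j = find("POLYGONS")
    if j < 0:
        raise FormatError("no POLYGONS block")
    m = int(tokens[j + 1])
    faces = []
    pos = j + 3
    for _ in range(m):
        cnt = int(tokens[pos])
        poly = [int(t) for t in tokens[pos + 1: pos + 1 + cnt]]
        pos += 1 + cnt
        if cnt == 3:
            faces.append(poly)
        elif triangulate:
            faces.extend([[poly[0], poly[k], poly[k + 1]] for k in range(1, cnt - 1)])
        else:
            raise FormatError("non-triangular faces (pass triangulate=True to allow)")
    fields = {}
    k = find("POINT_DATA")
    if k >= 0:
        pos = k + 2
        while pos < len(tokens):
            if tokens[pos].upper() == "SCALARS":
                name = tokens[pos + 1]
                pos += 3  # SCALARS <name> <type>
                ncomp = 1
                if tokens[pos].isdigit():  # optional numComp
                    ncomp = int(tokens[pos])
                    pos += 1
                if tokens[pos].upper() == "LOOKUP_TABLE":
                    pos += 2
                vals = np.array(tokens[pos: pos + n * ncomp], dtype=float)
                pos += n * ncomp
                fields[name] = vals[::ncomp] if ncomp > 1 else vals
            else:
                pos += 1
    return SurfaceMesh(coords, np.asarray(faces, np.int64), fields)


def _write_vtk(mesh: SurfaceMesh, path: Path) -> None:
    out = ["# vtk DataFile Version 3.0", "fetalmorph surface", "ASCII", "DATASET POLYDATA"]
    n = mesh.n_vertices
    out.append(f"POINTS {n} double")
    out.extend(" ".join(f"{x:.9g}" for x in row) for row in mesh.vertices)
    m = len(mesh.faces)
    out.append(f"POLYGONS {m} {4 * m}")
    out.extend(f"3 {a} {b} {c}" for a, b, c in mesh.faces)
    if mesh.fields:
        out.append(f"POINT_DATA {n}")
        for name, values in mesh.fields.items():
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{v:.9g}" for v in values)
    path.write_text("\n".join(out) + "\n")


def read_mesh(path, triangulate: bool = False) -> SurfaceMesh:
    """Read a PLY or legacy-VTK polydata surface with its point scalar fields."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        return _read_ply(path, triangulate)
    if ext == ".vtk":
        return _read_vtk(path, triangulate)
    raise FormatError(f"unsupported mesh format {ext!r} (use .ply or .vtk)")


def write_mesh(mesh: SurfaceMesh, path, binary: bool = True) -> None:
    """Write a mesh (format chosen by extension) preserving scalar fields."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        _write_ply(mesh, path, binary)
    elif ext == ".vtk":
        _write_vtk(mesh, path)
    else:
        raise FormatError(f"unsupported mesh format {ext!r} (use .ply or .vtk)")


# ---------------------------------------------------------------------------
# Mesh validation
# ---------------------------------------------------------------------------

@dataclass
class MeshReport:
    edge_manifold: bool
    closed: bool
    oriented: bool
    outward: bool
    signed_volume: float
    fixed: bool = False


def validate_closed_oriented(mesh: SurfaceMesh, fix: bool = False):
    """Report closedness/orientation; optionally flip winding to outward.

    Returns ``(report, mesh)``; the mesh is the (possibly re-wound) input.
    """
    tm = mesh.to_trimesh()
    closed = bool(tm.is_watertight)
    oriented = bool(tm.is_winding_consistent)
    manifold = bool(tm.is_watertight or len(trimesh.grouping.group_rows(tm.edges_sorted, require_count=2)) * 2 == len(tm.edges_sorted))
    sv = mesh.signed_volume()
    fixed = False
    out = mesh
    if closed and oriented and sv < 0 and fix:
        flipped = mesh.faces[:, [0, 2, 1]]
        out = SurfaceMesh(mesh.vertices, flipped, dict(mesh.fields))
        sv = out.signed_volume()
        fixed = True
    report = MeshReport(edge_manifold=manifold, closed=closed, oriented=oriented,
                        outward=bool(closed and sv > 0), signed_volume=sv, fixed=fixed)
    if closed and sv < 0 and not fix:
        warnings.warn("closed mesh has inward orientation (signed volume < 0)")
    return report, out
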