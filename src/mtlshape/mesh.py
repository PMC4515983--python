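"""Triangulated-surface data structures, I/O, rigid alignment, and the
vertex-indexed log surface Jacobian marker.

The central quantity produced here is the morphometry marker

    J_v = ln( A_v(deformed) / A_v(template) )

where ``A_v`` is the one-third barycentric vertex area: each triangle
contributes one third of its area to each of its three corners.  This is a
standard discrete surrogate for the determinant of the tangential Jacobian of
the template-to-subject deformation; negative values mean local surface
contraction (atrophy).

Meshes are read and written as OFF and legacy-VTK ASCII (``POINTS`` /
``POLYGONS``), both 0-based on disk.  All coordinates are in millimetres.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class MeshFormatError(ValueError):
    """Malformed mesh file; message carries the offending line number."""


class MeshError(ValueError):
    """Invalid mesh geometry or incompatible mesh pair."""


@dataclasses.dataclass
class TriMesh:
    """Oriented triangle mesh: ``vertices`` (n, 3) float mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array of vertex indices")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same connectivity, new vertex positions."""
        return TriMesh(np.asarray(vertices, dtype=float), self.faces.copy())


@dataclasses.dataclass
class LabelMap:
    """Per-vertex integer labels plus an id -> name table."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        missing = set(np.unique(self.labels)) - set(self.names)
        if missing:
            raise ValueError(f"labels without a name entry: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _tokenize(path: Path) -> list[tuple[int, list[str]]]:
    """Non-empty, non-comment lines as (1-based line number, tokens)."""
    out = []
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append((i, line.split()))
    return out


def read_off(path: str | Path) -> TriMesh:
    path = Path(path)
    lines = _tokenize(path)
    if not lines or lines[0][1][0] != "OFF":
        lineno = lines[0][0] if lines else 1
        raise MeshFormatError(f"{path}:{lineno}: missing OFF header")
    # counts may share the header line ("OFF 8 12 0") or follow it
    if len(lines[0][1]) >= 3:
        counts_line, rest = lines[0], lines[1:]
        counts = counts_line[1][1:4]
    else:
        if len(lines) < 2:
            raise MeshFormatError(f"{path}:1: missing vertex/face counts")
        counts_line, rest = lines[1], lines[2:]
        counts = counts_line[1][:3]
    try:
        nv, nf = int(counts[0]), int(counts[1])
    except (ValueError, IndexError):
        raise MeshFormatError(f"{path}:{counts_line[0]}: bad count line") from None
    if len(rest) < nv + nf:
        raise MeshFormatError(f"{path}: expected {nv} vertices + {nf} faces, file truncated")
    verts = np.empty((nv, 3))
    for k in range(nv):
        lineno, tok = rest[k]
        try:
            verts[k] = [float(t) for t in tok[:3]]
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}:{lineno}: bad vertex line") from None
    faces = np.empty((nf, 3), dtype=np.int64)
    for k in range(nf):
        lineno, tok = rest[nv + k]
        try:
            cnt = int(tok[0])
            idx = [int(t) for t in tok[1 : 1 + cnt]]
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}:{lineno}: bad face line") from None
        if cnt != 3:
            raise MeshFormatError(f"{path}:{lineno}: only triangles supported, got {cnt}-gon")
        if min(idx) < 0 or max(idx) >= nv:
            raise MeshFormatError(f"{path}:{lineno}: face index out of range")
        faces[k] = idx
    return TriMesh(verts, faces)


def write_off(mesh: TriMesh, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_vtk(path: str | Path) -> TriMesh:
    """Legacy-VTK ASCII POLYDATA with POINTS and POLYGONS sections."""
    path = Path(path)
    lines = _tokenize(path)
    verts = None
    faces = None
    i = 0
    while i < len(lines):
        lineno, tok = lines[i]
        key = tok[0].upper()
        if key == "POINTS":
            try:
                nv = int(tok[1])
            except (ValueError, IndexError):
                raise MeshFormatError(f"{path}:{lineno}: bad POINTS line") from None
            flat: list[float] = []
            i += 1
            while i < len(lines) and len(flat) < 3 * nv:
                lno, t = lines[i]
                try:
                    flat.extend(float(x) for x in t)
                except ValueError:
                    raise MeshFormatError(f"{path}:{lno}: bad coordinate") from None
                i += 1
            if len(flat) != 3 * nv:
                raise MeshFormatError(f"{path}:{lineno}: expected {3 * nv} coordinates")
            verts = np.asarray(flat).reshape(nv, 3)
        elif key == "POLYGONS":
            try:
                nf = int(tok[1])
            except (ValueError, IndexError):
                raise MeshFormatError(f"{path}:{lineno}: bad POLYGONS line") from None
            faces = np.empty((nf, 3), dtype=np.int64)
            for k in range(nf):
                i += 1
                if i >= len(lines):
                    raise MeshFormatError(f"{path}:{lineno}: POLYGONS section truncated")
                lno, t = lines[i]
                try:
                    cnt = int(t[0])
                    idx = [int(x) for x in t[1 : 1 + cnt]]
                except (ValueError, IndexError):
                    raise MeshFormatError(f"{path}:{lno}: bad polygon line") from None
                if cnt != 3:
                    raise MeshFormatError(f"{path}:{lno}: only triangles supported")
                faces[k] = idx
            i += 1
        else:
            i += 1
    if verts is None or faces is None:
        raise MeshFormatError(f"{path}: missing POINTS or POLYGONS section")
    if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
        raise MeshFormatError(f"{path}: face index out of range in POLYGONS")
    return TriMesh(verts, faces)


def write_vtk(mesh: TriMesh, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmtlshape surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


_READERS = {"off": read_off, "vtk": read_vtk}
_WRITERS = {"off": write_off, "vtk": write_vtk}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in _READERS:
            raise ValueError(f"unknown mesh format {fmt!r}; use 'off' or 'vtk'")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _READERS:
        return suffix
    raise ValueError(f"cannot infer mesh format from {path.name!r}")


def read_mesh(path: str | Path, fmt: str | None = None) -> TriMesh:
    path = Path(path)
    return _READERS[_infer_format(path, fmt)](path)


def write_mesh(mesh: TriMesh, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    _WRITERS[_infer_format(path, fmt)](mesh, path)


def read_label_map(labels_csv: str | Path, names_csv: str | Path | None = None) -> LabelMap:
    df = pd.read_csv(labels_csv)
    labels = df.sort_values("vertex_id")["label_id"].to_numpy()
    if names_csv is not None:
        nm = pd.read_csv(names_csv)
        names = dict(zip(nm["label_id"].astype(int), nm["name"].astype(str)))
    else:
        names = {int(k): str(k) for k in np.unique(labels)}
    return LabelMap(labels, names)


def write_label_map(lm: LabelMap, labels_csv: str | Path, names_csv: str | Path | None = None) -> None:
    pd.DataFrame({"vertex_id": np.arange(len(lm)), "label_id": lm.labels}).to_csv(
        labels_csv, index=False
    )
    if names_csv is not None:
        pd.DataFrame(
            {"label_id": sorted(lm.names), "name": [lm.names[k] for k in sorted(lm.names)]}
        ).to_csv(names_csv, index=False)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def face_cross(mesh: TriMesh) -> np.ndarray:
    """Unnormalized face normals (v1-v0) x (v2-v0); magnitude = 2 * face area."""
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    return np.cross(v1 - v0, v2 - v0)


def face_areas(mesh: TriMesh) -> np.ndarray:
    return 0.5 * np.linalg.norm(face_cross(mesh), axis=1)


def surface_area(mesh: TriMesh) -> float:
    return float(face_areas(mesh).sum())


def enclosed_volume(mesh: TriMesh) -> float:
    """Volume enclosed by a closed, consistently oriented surface (divergence
    theorem over signed tetrahedra to the origin); absolute value returned."""
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0))


def vertex_area(mesh: TriMesh) -> np.ndarray:
    """One-third barycentric vertex areas (mm^2); sums to the total surface area."""
    fa = face_areas(mesh)
    bad = np.flatnonzero(fa <= 0.0)
    if bad.size:
        raise MeshError(f"degenerate faces (zero area): {bad.tolist()[:20]}")
    va = np.zeros(mesh.n_vertices)
    np.add.at(va, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return va


def log_surface_jacobian(template: TriMesh, deformed: TriMesh) -> np.ndarray:
    """Per-vertex marker J_v = ln(vertex area of deformed / vertex area of template).

    Requires identical connectivity (vertex correspondence established by
    registration). Negative values indicate local contraction (atrophy).
    """
    if template.n_vertices != deformed.n_vertices or not np.array_equal(
        template.faces, deformed.faces
    ):
        raise MeshError("template/deformed connectivity mismatch")
    return np.log(vertex_area(deformed) / vertex_area(template))


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RigidTransform:
    """x -> rotation @ (F x) + translation, with F an optional x-mirror."""

    rotation: np.ndarray
    translation: np.ndarray
    flipped: bool
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if self.flipped:
            pts = pts * np.array([-1.0, 1.0, 1.0])
        return pts @ self.rotation.T + self.translation


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation + translation mapping src onto dst."""
    cs, cd = src.mean(0), dst.mean(0)
    if len(src) > 1 and (np.linalg.norm(src - cs) == 0 or np.linalg.norm(dst - cd) == 0):
        raise MeshError("degenerate point set: rigid alignment underdetermined")
    H = (src - cs).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    rmsd = float(np.sqrt(np.mean(np.sum((src @ R.T + t - dst) ** 2, axis=1))))
    return R, t, rmsd


def rigid_align(
    source: TriMesh,
    target: TriMesh,
    allow_flip: bool = False,
    correspondence: bool | None = None,
    max_icp_iters: int = 50,
    tol: float = 1e-10,
) -> tuple[RigidTransform, TriMesh]:
    """Rigidly align source to target (rotation + translation, optional x-mirror).

    With vertex correspondence (same vertex count, default when counts match)
    this is a closed-form Procrustes fit; otherwise a centroid +
    principal-axes initialization followed by iterative closest point.
    ``allow_flip`` additionally tries a mirror of the x (left/right) axis and
    keeps whichever side has the lower residual — the convention used for
    pooling right-sided structures with left-sided ones.
    """
    if correspondence is None:
        correspondence = source.n_vertices == target.n_vertices

    def _fit(src_pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        if correspondence:
            return _kabsch(src_pts, target.vertices)
        return _icp(src_pts, target.vertices, max_icp_iters, tol)

    candidates = [False, True] if allow_flip else [False]
    best = None
    for flip in candidates:
        pts = source.vertices * np.array([-1.0, 1.0, 1.0]) if flip else source.vertices
        R, t, rmsd = _fit(pts)
        if best is None or rmsd < best[3]:
            best = (R, t, flip, rmsd)
    R, t, flip, rmsd = best
    tr = RigidTransform(R, t, flip, rmsd)
    return tr, source.with_vertices(tr.apply(source.vertices))


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = points.mean(0)
    cov = np.cov((points - c).T)
    w, V = np.linalg.eigh(cov)
    if w[1] <= 1e-12 * max(w[-1], 1.0):
        raise MeshError("degenerate point set: principal axes undefined")
    return c, V[:, ::-1]  # columns ordered by decreasing variance


def _icp(
    src: np.ndarray, dst: np.ndarray, max_iters: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    cs, As = _principal_axes(src)
    cd, Ad = _principal_axes(dst)
    tree = cKDTree(dst)
    best = None
    # principal-axis sign ambiguity: try the four proper-rotation sign choices
    for sx, sy in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
        S = np.diag([sx, sy, sx * sy])
        R0 = Ad @ S @ As.T
        if np.linalg.det(R0) < 0:  # keep proper rotations only
            continue
        R, t = R0, cd - R0 @ cs
        prev = np.inf
        for _ in range(max_iters):
            moved = src @ R.T + t
            d, idx = tree.query(moved)
            rmsd = float(np.sqrt(np.mean(d**2)))
            if prev - rmsd < tol:
                break
            prev = rmsd
            R, t, _ = _kabsch(src, dst[idx])
        moved = src @ R.T + t
        rmsd = float(np.sqrt(np.mean(tree.query(moved)[0] ** 2)))
        if best is None or rmsd < best[2]:
            best = (R, t, rmsd)
    if best is None:
        raise MeshError("icp failed: no proper-rotation initialization")
    return best
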