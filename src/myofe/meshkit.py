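"""Tetrahedral meshes, geometry queries, rigid ICP and mask smoothing.

The mesh model is deliberately small: nodes, 4-node connectivity and a
per-element part label (muscle name, fat, bone, liner, socket).  Node
ordering follows the right-handed convention ``6 V = det[n1-n0, n2-n0,
n3-n0] > 0``; elements violating it are repaired by swapping the last two
nodes, with a logged warning.

File formats are the two ASCII dialects the rest of the toolkit speaks:
legacy VTK unstructured grids and LS-DYNA keyword decks (``*NODE`` /
``*ELEMENT_SOLID``, 1-based ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DataError

__all__ = [
    "TetMesh",
    "RigidTransform",
    "element_centroids_volumes",
    "bounding_box_diagonal",
    "icp_register",
    "smooth_mask",
    "read_mesh",
    "write_mesh",
]

log = logging.getLogger(__name__)


@dataclass
class TetMesh:
    """Linear tetrahedral mesh: nodes (mm), 0-based connectivity, part labels."""

    nodes: np.ndarray
    elements: np.ndarray
    part_labels: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise DataError(f"nodes must be (n, 3), got {self.nodes.shape}")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise DataError(f"elements must be (m, 4), got {self.elements.shape}")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise DataError("element connectivity indices out of range")
        if self.part_labels is None:
            self.part_labels = np.zeros(len(self.elements), dtype=object)
            self.part_labels[:] = "part0"
        self.part_labels = np.asarray(self.part_labels, dtype=object)
        if len(self.part_labels) != len(self.elements):
            raise DataError("part_labels length must equal element count")
        self._repair_orientation()

    def _repair_orientation(self):
        vols = self.element_volumes(signed=True)
        bad = vols < 0
        if np.any(bad):
            log.warning(
                "repairing %d negative-volume element(s) by node swap",
                int(bad.sum()),
            )
            self.elements[bad] = self.elements[bad][:, [0, 1, 3, 2]]
        if np.any(self.element_volumes(signed=True) <= 0):
            raise DataError("mesh contains degenerate (zero-volume) elements")

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elements)

    def element_volumes(self, signed: bool = False) -> np.ndarray:
        x = self.nodes[self.elements]  # (m, 4, 3)
        v = np.einsum(
            "mi,mi->m",
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
            x[:, 3] - x[:, 0],
        ) / 6.0
        return v if signed else np.abs(v)

    @property
    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def element_subset(self, mask) -> "TetMesh":
        mask = np.asarray(mask)
        return TetMesh(self.nodes, self.elements[mask], self.part_labels[mask])

    def part_mask(self, parts) -> np.ndarray:
        if isinstance(parts, str):
            parts = [parts]
        return np.isin(self.part_labels.astype(str), list(map(str, parts)))

    def transformed(self, transform: "RigidTransform") -> "TetMesh":
        return TetMesh(
            transform.apply(self.nodes), self.elements.copy(), self.part_labels
        )


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise DataError("rotation must be proper orthogonal (det = 1)")

    @classmethod
    def identity(cls):
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points):
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def element_centroids_volumes(mesh: TetMesh):
    """Per-element centroid ``x_i`` and volume ``v_e``."""
    centroids = mesh.nodes[mesh.elements].mean(axis=1)
    return centroids, mesh.element_volumes()


def bounding_box_diagonal(points) -> float:
    """Diagonal length L of the axis-aligned bounding box of a point set."""
    points = np.atleast_2d(np.asarray(points, float))
    return float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------


def _kabsch(src, dst):
    """Closed-form least-squares rigid fit mapping src onto dst."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, dc - R @ sc)


def _check_not_collinear(points, name):
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise DataError(f"{name} cloud needs >= 3 points")
    cov = np.cov((pts - pts.mean(axis=0)).T)
    ev = np.linalg.eigvalsh(cov)
    if ev[-2] <= 1e-12 * max(ev[-1], 1.0):
        raise DataError(f"{name} cloud is (near-)collinear; ICP is ill-posed")


def icp_register(source, target, max_iter: int = 100, tol: float = 1e-10):
    """Point-to-point iterative-closest-point rigid registration.

    Alternates nearest-neighbour pairing (KD-tree) with the closed-form
    least-squares rigid fit until the RMS pairing distance changes by less
    than ``tol`` between iterations.

    Returns
    -------
    transform : RigidTransform
        Motion mapping ``source`` points onto ``target``.
    rms : float
        Final RMS nearest-neighbour distance.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    _check_not_collinear(source, "source")
    _check_not_collinear(target, "target")
    tree = cKDTree(target)
    transform = RigidTransform.identity()
    moved = source.copy()
    prev_rms = np.inf
    for _ in range(max_iter):
        dist, idx = tree.query(moved)
        rms = float(np.sqrt(np.mean(dist**2)))
        step = _kabsch(moved, target[idx])
        transform = step.compose(transform)
        moved = step.apply(moved)
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    dist, _ = tree.query(moved)
    return transform, float(np.sqrt(np.mean(dist**2)))


# ---------------------------------------------------------------------------
# Binary-mask smoothing
# ---------------------------------------------------------------------------


def smooth_mask(
    mask,
    dilation_steps: int = 1,
    gaussian_sigma: float = 1.5,
    threshold: float | None = None,
):
    """Smooth a binary mask by dilation + Gaussian blur + re-thresholding.

    The morphological dilation closes pinholes and staircase notches, the
    Gaussian blur of the indicator function rounds the surface.  With
    ``threshold=None`` (default) the re-threshold level is chosen by
    volume matching: the blurred indicator is cut at the level whose voxel
    count is closest to the input's, so the smoothing is volume-preserving
    up to one threshold quantum.  Pass an explicit float in (0, 1) to fix
    the level instead.

    Returns
    -------
    smoothed : ndarray of bool
    rel_volume_change : float
        ``|V_after - V_before| / V_before`` (0 for an empty input).
    """
    mask = np.asarray(mask).astype(bool)
    v0 = int(mask.sum())
    if v0 == 0:
        return mask.copy(), 0.0
    work = mask
    if dilation_steps > 0:
        work = ndimage.binary_dilation(work, iterations=int(dilation_steps))
    blur = ndimage.gaussian_filter(work.astype(float), sigma=gaussian_sigma)
    if threshold is None:
        # volume-matched cut: keep exactly the v0 highest blurred voxels
        # (ties broken by raveled index, so the result is deterministic)
        order = np.argpartition(blur.ravel(), len(blur.ravel()) - v0)
        out = np.zeros(blur.size, dtype=bool)
        out[order[-v0:]] = True
        out = out.reshape(blur.shape)
    else:
        if not 0.0 < threshold < 1.0:
            raise DataError(f"threshold must lie in (0, 1), got {threshold}")
        out = blur > threshold
    v1 = int(out.sum())
    return out, abs(v1 - v0) / v0


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------


def write_mesh(mesh: TetMesh, path, dialect: str = "vtk") -> None:
    """Write a mesh as a legacy-VTK unstructured grid or LS-DYNA keyword deck."""
    if dialect == "vtk":
        _write_vtk(mesh, path)
    elif dialect == "dyna":
        _write_dyna(mesh, path)
    else:
        raise DataError(f"unknown mesh dialect {dialect!r}")


def read_mesh(path, dialect: str = "vtk") -> TetMesh:
    if dialect == "vtk":
        return _read_vtk(path)
    if dialect == "dyna":
        return _read_dyna(path)
    raise DataError(f"unknown mesh dialect {dialect!r}")


def _part_ids(mesh):
    """Stable integer id per part label (1-based, first-appearance order)."""
    ids, mapping = [], {}
    for lab in mesh.part_labels:
        mapping.setdefault(lab, len(mapping) + 1)
        ids.append(mapping[lab])
    return np.array(ids), mapping


def _write_vtk(mesh, path, cell_data: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntet mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for e in mesh.elements:
            fh.write(f"4 {e[0]} {e[1]} {e[2]} {e[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["10"] * mesh.n_elements) + "\n")
        pid, _ = _part_ids(mesh)
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS part_id int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(i) for i in pid) + "\n")
        for name, values in (cell_data or {}).items():
            values = np.asarray(values, float)
            if values.ndim == 1:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in values) + "\n")
            else:
                fh.write(f"VECTORS {name} double\n")
                for v in values:
                    fh.write(" ".join(f"{c:.9g}" for c in v) + "\n")


def write_vtk_with_fields(mesh, path, cell_data: dict) -> None:
    """Legacy-VTK export with extra per-element scalar/vector fields."""
    _write_vtk(mesh, path, cell_data=cell_data)


def _read_vtk(path) -> TetMesh:
    with open(path) as fh:
        tokens_lines = fh.read().splitlines()
    it = iter(tokens_lines)
    nodes = elements = part_id = None
    try:
        for line in it:
            up = line.strip().upper()
            if up.startswith("POINTS"):
                n = int(line.split()[1])
                vals = []
                while len(vals) < 3 * n:
                    vals.extend(float(t) for t in next(it).split())
                nodes = np.array(vals).reshape(n, 3)
            elif up.startswith("CELLS"):
                m = int(line.split()[1])
                rows = []
                for _ in range(m):
                    parts = next(it).split()
                    if parts[0] != "4":
                        raise DataError("only 4-node tetrahedra are supported")
                    rows.append([int(t) for t in parts[1:5]])
                elements = np.array(rows, dtype=int)
            elif up.startswith("CELL_TYPES"):
                m = int(line.split()[1])
                types = []
                while len(types) < m:
                    types.extend(int(t) for t in next(it).split())
                if any(t != 10 for t in types):
                    raise DataError("mixed element types are not supported")
            elif up.startswith("SCALARS PART_ID"):
                next(it)  # LOOKUP_TABLE
                vals = []
                while len(vals) < len(elements):
                    vals.extend(int(t) for t in next(it).split())
                part_id = np.array(vals)
    except StopIteration as exc:
        raise DataError(f"truncated VTK file {path}") from exc
    if nodes is None or elements is None:
        raise DataError(f"{path} is not a legacy-VTK unstructured grid")
    labels = None
    if part_id is not None:
        labels = np.array([f"part{i}" for i in part_id], dtype=object)
    return TetMesh(nodes, elements, labels)


def _write_dyna(mesh, path) -> None:
    pid, _ = _part_ids(mesh)
    with open(path, "w") as fh:
        fh.write("*KEYWORD\n*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i:8d}{p[0]:16.8f}{p[1]:16.8f}{p[2]:16.8f}\n")
        fh.write("*ELEMENT_SOLID\n")
        for j, (e, part) in enumerate(zip(mesh.elements, pid), start=1):
            n = e + 1  # 0-based internal -> 1-based keyword ids
            fh.write(
                f"{j:8d}{part:8d}"
                f"{n[0]:8d}{n[1]:8d}{n[2]:8d}{n[3]:8d}"
                f"{n[3]:8d}{n[3]:8d}{n[3]:8d}{n[3]:8d}\n"
            )
        fh.write("*END\n")


def _read_dyna(path) -> TetMesh:
    nodes, node_ids, elems, parts = [], [], [], []
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("$") or not line.strip():
                continue
            if line.startswith("*"):
                section = line.strip().upper()
                continue
            if section == "*NODE":
                toks = line.split()
                node_ids.append(int(toks[0]))
                nodes.append([float(t) for t in toks[1:4]])
            elif section is not None and section.startswith("*ELEMENT_SOLID"):
                toks = [int(t) for t in line.split()]
                conn = toks[2:]
                uniq = list(dict.fromkeys(conn))
                if len(uniq) != 4:
                    raise DataError(
                        "only tetrahedra (4 distinct nodes) are supported, "
                        f"element {toks[0]} has {len(uniq)}"
                    )
                elems.append(uniq)
                parts.append(toks[1])
    if not nodes or not elems:
        raise DataError(f"{path} contains no *NODE/*ELEMENT_SOLID data")
    id_map = {nid: i for i, nid in enumerate(node_ids)}
    elements = np.array([[id_map[n] for n in e] for e in elems], dtype=int)
    labels = np.array([f"part{p}" for p in parts], dtype=object)
    return TetMesh(np.array(nodes), elements, labels)
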