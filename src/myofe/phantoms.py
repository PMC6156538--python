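"""Synthetic phantoms: every pipeline stage is testable without downloads.

Generators emit the same objects and file formats the pipeline consumes —
diffusion-weighted stacks with known ground-truth tensors, structured
cylinder tet meshes with analytically known volume, mosaics, fibre strands
and binary masks.  All randomness is seeded and every generator returns
its ground truth alongside the data.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError
from .imaging import DWIStack, MosaicImage, flatten_stack
from .meshkit import TetMesh
from .tensorfield import FibreStrand, TensorField

__all__ = [
    "default_gradient_scheme",
    "make_dwi_phantom",
    "make_cylinder_mesh",
    "make_mosaic",
    "make_strands",
    "make_mask",
]

#: Default diffusion eigenvalues (mm^2/s): lambda_parallel, lambda_perp.
LAMBDA_PAR = 1.8e-3
LAMBDA_PERP = 0.3e-3

#: Default voxel spacing (mm), matching a muscle DTI protocol
#: (3.2 x 3.2 mm in-plane, 3 mm slices) at reduced matrix size.
DEFAULT_VOXEL_SIZE = (3.2, 3.2, 3.0)


def default_gradient_scheme(n_directions: int = 12, bval: float = 700.0):
    """A deterministic well-spread gradient scheme (Fibonacci hemisphere).

    Returns ``(bvals, bvecs)`` for one b0 volume plus ``n_directions``
    weighted directions at ``bval`` s/mm^2.
    """
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n_directions)
    z = (i + 0.5) / n_directions  # upper hemisphere only
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    bvals = np.concatenate([[0.0], np.full(n_directions, bval)])
    bvecs = np.vstack([np.zeros(3), dirs])
    return bvals, bvecs


def _direction_field(shape, voxel_size, pattern, pitch):
    nx, ny, nz = shape
    vs = np.asarray(voxel_size, float)
    centre = (np.array(shape, float) * vs) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    x = (ii + 0.5) * vs[0] - centre[0]
    y = (jj + 0.5) * vs[1] - centre[1]
    d = np.zeros(shape + (3,))
    if pattern == "axial":
        d[..., 2] = 1.0
    elif pattern == "helical":
        c = pitch / (2.0 * np.pi)
        d[..., 0] = -y
        d[..., 1] = x
        d[..., 2] = c
        on_axis = (np.abs(x) < 1e-12) & (np.abs(y) < 1e-12)
        d[on_axis] = (0.0, 0.0, 1.0)
        d /= np.linalg.norm(d, axis=-1, keepdims=True)
    elif pattern == "bundles":
        # two non-crossing parallel bundles: left half axial, right half
        # tilted 30 degrees in the x-z plane
        d[..., 2] = 1.0
        right = ii >= nx // 2
        d[right] = (np.sin(np.pi / 6), 0.0, np.cos(np.pi / 6))
    else:
        raise DataError(f"unknown fibre pattern {pattern!r}")
    return d


def make_dwi_phantom(
    shape=(12, 12, 12),
    fibre_pattern: str = "axial",
    bvals=None,
    bvecs=None,
    rician_sigma: float = 0.0,
    seed: int = 0,
    s0: float = 100.0,
    voxel_size=DEFAULT_VOXEL_SIZE,
    pitch: float = 60.0,
    n_acquisitions: int = 1,
    n_b0: int | None = None,
):
    """Synthetic DWI stack with known per-voxel tensors.

    Signals follow the mono-exponential model ``S = S0 exp(-b g^T D g)``
    with ``D`` built from the pattern's unit direction and eigenvalues
    (1.8, 0.3, 0.3)e-3 mm^2/s.  With ``rician_sigma > 0``, magnitude
    Rician noise is added with the given seed.  ``n_acquisitions`` repeats
    every weighted direction (and ``n_b0`` b0 volumes, default one per
    acquisition) so acquisition averaging can be exercised.

    Returns
    -------
    stack : DWIStack
    truth : TensorField
        Noise-free ground-truth tensors, FA and principal directions.
    """
    if bvals is None or bvecs is None:
        bvals, bvecs = default_gradient_scheme()
    bvals = np.asarray(bvals, float)
    bvecs = np.asarray(bvecs, float)
    e1 = _direction_field(tuple(shape), voxel_size, fibre_pattern, pitch)

    # D = (lpar - lperp) e1 e1^T + lperp I
    D = (LAMBDA_PAR - LAMBDA_PERP) * np.einsum(
        "...i,...j->...ij", e1, e1
    ) + LAMBDA_PERP * np.eye(3)

    gDg = np.einsum("vi,...ij,vj->...v", bvecs, D, bvecs)
    signal = s0 * np.exp(-bvals * gDg)

    weighted = bvals > 1e-9
    vols, bv, gv, acq = [], [], [], []
    if n_b0 is None:
        n_b0 = n_acquisitions
    for a in range(max(n_b0, 1)):
        vols.append(signal[..., ~weighted][..., 0])
        bv.append(0.0)
        gv.append(np.zeros(3))
        acq.append(a)
    for a in range(max(n_acquisitions, 1)):
        for v in np.where(weighted)[0]:
            vols.append(signal[..., v])
            bv.append(bvals[v])
            gv.append(bvecs[v])
            acq.append(a)
    data = np.stack(vols, axis=-1)

    if rician_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, rician_sigma, data.shape)
        n2 = rng.normal(0.0, rician_sigma, data.shape)
        data = np.sqrt((data + n1) ** 2 + n2**2)

    stack = DWIStack(data, np.array(bv), np.array(gv), tuple(voxel_size), acq)
    fa_true = _fa(LAMBDA_PAR, LAMBDA_PERP)
    truth = TensorField(
        D,
        np.full(tuple(shape), fa_true),
        e1,
        np.ones(tuple(shape), dtype=bool),
        tuple(voxel_size),
    )
    return stack, truth


def _fa(lpar, lperp):
    ev = np.array([lpar, lperp, lperp])
    mean = ev.mean()
    return float(
        np.sqrt(1.5 * np.sum((ev - mean) ** 2) / np.sum(ev**2))
    )


# ---------------------------------------------------------------------------
# Structured cylinder mesh
# ---------------------------------------------------------------------------


def _disc_points(radius, target_edge):
    h = float(target_edge)
    n_ring = max(int(np.ceil(2.0 * np.pi * radius / h)), 8)
    theta = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    xs = np.arange(-radius, radius + 0.5 * h, h)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    keep = np.hypot(grid[:, 0], grid[:, 1]) < radius - 0.55 * h
    return np.vstack([ring, grid[keep]])


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
]
_PRISM_FLIP = (3, 5, 4, 0, 2, 1)


def _split_prism(p):
    """Split a triangular prism (bottom b0,b1,b2; top above) into 3 tets.

    The diagonal of each quad face is chosen from the global vertex
    indices (smallest-index rule), so neighbouring prisms agree and the
    resulting tet mesh is conforming.
    """
    p = list(p)
    mi = int(np.argmin(p))
    if mi >= 3:
        p = [p[i] for i in _PRISM_FLIP]
        mi = int(np.argmin(p))
    p = [p[i] for i in _PRISM_ROTATIONS[mi]]
    if min(p[1], p[5]) < min(p[2], p[4]):
        tets = [(p[0], p[1], p[2], p[5]), (p[0], p[1], p[5], p[4]),
                (p[0], p[4], p[5], p[3])]
    else:
        tets = [(p[0], p[1], p[2], p[4]), (p[0], p[4], p[2], p[5]),
                (p[0], p[4], p[5], p[3])]
    return tets


def make_cylinder_mesh(
    radius: float = 6.0,
    length: float = 12.0,
    target_edge: float | None = None,
    part: str = "muscle",
) -> TetMesh:
    """Structured tet mesh of a solid cylinder (axis z, base at z = 0).

    A triangulated disc (boundary ring at the exact radius, spacing about
    ``target_edge``) is extruded in layers and each prism split into three
    conforming tetrahedra.  The mesh volume equals the extruded polygon
    volume exactly, so it approaches ``pi r^2 L`` as the edge shrinks;
    at the default density the deficit is a small fraction of a percent.
    """
    if target_edge is None:
        target_edge = radius / 5.0
    if radius <= 0 or length <= 0 or target_edge <= 0:
        raise DataError("radius, length and target_edge must be positive")
    from scipy.spatial import Delaunay

    pts2 = _disc_points(radius, target_edge)
    tri = Delaunay(pts2)
    simplices = tri.simplices
    # drop degenerate (zero-area) triangles from collinear grid ties
    e1 = pts2[simplices[:, 1]] - pts2[simplices[:, 0]]
    e2 = pts2[simplices[:, 2]] - pts2[simplices[:, 0]]
    a2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    simplices = simplices[a2 > 1e-12 * target_edge**2]

    n_layers = max(int(round(length / target_edge)), 1)
    zs = np.linspace(0.0, length, n_layers + 1)
    npts = len(pts2)
    nodes = np.column_stack(
        [
            np.tile(pts2, (n_layers + 1, 1)),
            np.repeat(zs, npts),
        ]
    )
    elements = []
    for layer in range(n_layers):
        lo, hi = layer * npts, (layer + 1) * npts
        for t in simplices:
            prism = (lo + t[0], lo + t[1], lo + t[2], hi + t[0], hi + t[1], hi + t[2])
            elements.extend(_split_prism(prism))
    elements = np.array(elements, dtype=int)
    labels = np.empty(len(elements), dtype=object)
    labels[:] = part
    return TetMesh(nodes, elements, labels)


#: Kuhn subdivision of the unit cube: 6 tets sharing the main diagonal
#: (0,0,0)-(1,1,1); identical in every cell, hence conforming across cells.
_KUHN_PATHS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def make_box_mesh(nx=2, ny=2, nz=2, size=(1.0, 1.0, 1.0), part="part0") -> TetMesh:
    """Structured tet mesh of a box: each cell split into 6 Kuhn tets."""
    sx, sy, sz = size
    xs = np.linspace(0.0, sx, nx + 1)
    ys = np.linspace(0.0, sy, ny + 1)
    zs = np.linspace(0.0, sz, nz + 1)
    nid = lambda i, j, k: (i * (ny + 1) + j) * (nz + 1) + k
    nodes = np.array(
        [[xs[i], ys[j], zs[k]]
         for i in range(nx + 1) for j in range(ny + 1) for k in range(nz + 1)]
    )
    elements = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                for path in _KUHN_PATHS:
                    corner = np.array([i, j, k])
                    verts = [nid(*corner)]
                    for axis in path:
                        corner = corner + np.eye(3, dtype=int)[axis]
                        verts.append(nid(*corner))
                    elements.append(verts)
    elements = np.array(elements, dtype=int)
    labels = np.empty(len(elements), dtype=object)
    labels[:] = part
    return TetMesh(nodes, elements, labels)


# ---------------------------------------------------------------------------
# Small generators
# ---------------------------------------------------------------------------


def make_mosaic(volume, grid_n: int) -> MosaicImage:
    """Tile a 3D volume into a mosaic (inverse of stack assembly)."""
    return flatten_stack(volume, grid_n)


def make_strands(
    pattern: str = "line",
    n_strands: int = 5,
    n_points: int = 20,
    spacing: float = 2.0,
    step: float = 1.0,
    direction=(0.0, 0.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    pitch: float = 20.0,
    radius: float = 5.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> list:
    """Generate fibre strands with consecutive numbering from 1.

    ``line``: parallel straight strands offset along x by ``spacing``.
    ``helix``: strands on a cylinder of ``radius`` with the given pitch.
    Optional isotropic Gaussian ``jitter`` is seeded.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    origin = np.asarray(origin, float)
    t = np.arange(n_points) * step
    strands = []
    for s in range(n_strands):
        if pattern == "line":
            offset = origin + np.array([s * spacing, 0.0, 0.0])
            pts = offset + t[:, None] * d
        elif pattern == "helix":
            c = pitch / (2.0 * np.pi)
            phase = 2.0 * np.pi * s / max(n_strands, 1)
            theta = t / np.hypot(radius, c) + phase
            pts = origin + np.column_stack(
                [
                    radius * np.cos(theta),
                    radius * np.sin(theta),
                    c * theta,
                ]
            )
        else:
            raise DataError(f"unknown strand pattern {pattern!r}")
        if jitter > 0:
            pts = pts + rng.normal(0.0, jitter, pts.shape)
        strands.append(FibreStrand(pts, id=s + 1))
    return strands


def make_mask(shape, primitive: str = "sphere", radius=None, length=None, centre=None):
    """Binary volume of a geometric primitive (voxel-centre classification).

    ``sphere``: ball of ``radius`` voxels around ``centre``.
    ``cylinder``: axis along z, ``radius`` and ``length`` in voxels.
    ``box``: solid box of half-extent ``radius`` per axis.
    """
    shape = tuple(shape)
    if centre is None:
        centre = (np.array(shape, float) - 1.0) / 2.0
    centre = np.asarray(centre, float)
    if radius is None:
        radius = min(shape) / 4.0
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    dx, dy, dz = ii - centre[0], jj - centre[1], kk - centre[2]
    if primitive == "sphere":
        return dx**2 + dy**2 + dz**2 <= radius**2
    if primitive == "cylinder":
        if length is None:
            length = shape[2] * 0.75
        return (dx**2 + dy**2 <= radius**2) & (np.abs(dz) <= length / 2.0)
    if primitive == "box":
        return (
            (np.abs(dx) <= radius)
            & (np.abs(dy) <= radius)
            & (np.abs(dz) <= radius)
        )
    raise DataError(f"unknown mask primitive {primitive!r}")
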