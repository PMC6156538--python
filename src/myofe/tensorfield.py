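"""Diffusion-tensor estimation and deterministic fibre tractography.

Water diffusion in skeletal muscle is preferentially directed along the
fibres, so the principal eigenvector of a per-voxel diffusion tensor traces
the local fibre orientation.  This module fits tensors by log-linear least
squares, derives fractional anisotropy (FA), integrates streamlines along
the principal eigenvector field, and groups strands into named muscle
bundles via axis-aligned cropping boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .imaging import DWIStack

__all__ = [
    "TensorField",
    "FibreStrand",
    "FibreBundle",
    "fit_tensor",
    "fractional_anisotropy",
    "track_streamlines",
    "crop_bundle",
    "bundle_to_mask",
    "write_strands",
    "read_strands",
    "write_strands_vtk",
]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with derived maps.

    ``tensors`` has shape ``(nx, ny, nz, 3, 3)`` (mm^2/s); ``fa`` lies in
    [0, 1]; ``e1`` is the unit principal eigenvector; ``mask`` flags voxels
    with a valid fit.  ``voxel_size`` (mm) maps voxel indices to physical
    coordinates: the centre of voxel ``(i, j, k)`` sits at
    ``((i+0.5)*dx, (j+0.5)*dy, (k+0.5)*dz)``.
    """

    tensors: np.ndarray
    fa: np.ndarray
    e1: np.ndarray
    mask: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return self.tensors.shape[:3]

    def voxel_to_mm(self, idx):
        return (np.asarray(idx, float) + 0.5) * np.asarray(self.voxel_size)

    def mm_to_voxel(self, pos):
        return np.asarray(pos, float) / np.asarray(self.voxel_size) - 0.5


@dataclass
class FibreStrand:
    """An ordered fibre polyline; points are consecutively numbered from 1."""

    points: np.ndarray
    id: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise DataError(
                f"a strand needs >=2 3D points, got shape {self.points.shape}"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class FibreBundle:
    """Named group of fibre strands (one anatomical muscle by convention)."""

    name: str
    strands: list = field(default_factory=list)

    def __post_init__(self):
        ids = [s.id for s in self.strands]
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate strand ids in bundle {self.name!r}")


# ---------------------------------------------------------------------------
# Tensor fit
# ---------------------------------------------------------------------------


def _design_matrix(bvals, bvecs):
    g = np.asarray(bvecs, float)
    b = np.asarray(bvals, float)
    # unknowns ordered Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    return -b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(stack: DWIStack) -> TensorField:
    """Log-linear least-squares diffusion tensor fit.

    Solves ``ln(S/S0) = -b g^T D g`` per voxel over the gradient scheme.
    Needs at least 6 weighted directions spanning all tensor components
    plus a b=0 reference.  Voxels with non-positive S0 or any non-positive
    weighted signal are masked out.
    """
    b0 = stack.is_b0
    if not np.any(b0):
        raise DataError("no b=0 volume in the stack")
    dwi_idx = np.where(~b0)[0]
    if len(dwi_idx) < 6:
        raise DataError(
            f"tensor fit needs >=6 weighted directions, got {len(dwi_idx)}"
        )
    A = _design_matrix(stack.bvals[dwi_idx], stack.bvecs[dwi_idx])
    if np.linalg.matrix_rank(A) < 6:
        raise DataError("gradient directions do not span the tensor space")

    S0 = stack.volumes[..., b0].mean(axis=-1)
    S = stack.volumes[..., dwi_idx]
    mask = (S0 > 0) & np.all(S > 0, axis=-1)

    nx, ny, nz = stack.shape
    d6 = np.zeros((nx, ny, nz, 6))
    safe_S0 = np.where(mask, S0, 1.0)
    logs = np.log(np.where(S > 0, S, 1.0)) - np.log(safe_S0)[..., None]
    pinv = np.linalg.pinv(A)
    d6 = np.einsum("cd,...d->...c", pinv, logs)
    d6[~mask] = 0.0

    T = np.zeros((nx, ny, nz, 3, 3))
    T[..., 0, 0] = d6[..., 0]
    T[..., 1, 1] = d6[..., 1]
    T[..., 2, 2] = d6[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = d6[..., 3]
    T[..., 0, 2] = T[..., 2, 0] = d6[..., 4]
    T[..., 1, 2] = T[..., 2, 1] = d6[..., 5]

    evals, evecs = np.linalg.eigh(T)
    fa = np.where(mask, _fa_from_evals(evals), 0.0)
    e1 = evecs[..., -1]  # eigh sorts ascending; last column = principal
    e1[~mask] = 0.0
    return TensorField(T, fa, e1, mask, stack.voxel_size)


def _fa_from_evals(evals):
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.clip(np.nan_to_num(fa), 0.0, 1.0)


def fractional_anisotropy(tensor) -> float:
    """FA of a single symmetric 3x3 tensor, clipped to [0, 1]."""
    evals = np.linalg.eigvalsh(np.asarray(tensor, float))
    return float(_fa_from_evals(evals[None, :])[0])


# ---------------------------------------------------------------------------
# Streamline tracking
# ---------------------------------------------------------------------------


def _sample(field: TensorField, pos_mm):
    """Nearest-voxel sample of (e1, fa, inside-mask) at a physical point."""
    idx = np.round(field.mm_to_voxel(pos_mm)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(field.shape)):
        return None, 0.0, False
    i, j, k = idx
    if not field.mask[i, j, k]:
        return None, 0.0, False
    return field.e1[i, j, k], float(field.fa[i, j, k]), True


def _march(field, start, direction, step, fa_stop, max_angle_deg, max_steps):
    cos_min = np.cos(np.deg2rad(max_angle_deg))
    pts = []
    pos = np.asarray(start, float)
    d = np.asarray(direction, float)
    for _ in range(max_steps):
        pos = pos + step * d
        e1, fa, ok = _sample(field, pos)
        if not ok or fa < fa_stop:
            break
        nd = e1 if np.dot(e1, d) >= 0 else -e1  # hemisphere continuity
        if np.dot(nd, d) < cos_min:
            break
        pts.append(pos.copy())
        d = nd
    return pts


def track_streamlines(
    field: TensorField,
    seeds,
    step_mm: float = 1.0,
    min_length_mm: float = 10.0,
    fa_stop: float = 0.0,
    max_angle_deg: float = 45.0,
    max_steps: int = 2000,
) -> list:
    """Bidirectional Euler streamline tracking along the e1 field.

    From each seed the tracker marches along +e1 and -e1 with the
    eigenvector sign re-aligned to the previous step direction, stopping on
    mask exit, ``fa < fa_stop`` or a turning angle above ``max_angle_deg``.
    Strands shorter than ``min_length_mm`` are discarded.  Tracking is
    deterministic given the seed list.
    """
    if step_mm <= 0:
        raise DataError(f"step_mm must be positive, got {step_mm}")
    strands = []
    sid = 1
    for seed in seeds:
        seed = np.asarray(seed, float)
        e1, fa, ok = _sample(field, seed)
        if not ok:
            raise DataError(f"seed {seed} lies outside the tracking mask")
        if fa < fa_stop:
            continue
        fwd = _march(field, seed, e1, step_mm, fa_stop, max_angle_deg, max_steps)
        bwd = _march(field, seed, -e1, step_mm, fa_stop, max_angle_deg, max_steps)
        pts = bwd[::-1] + [seed] + fwd
        if len(pts) < 2:
            continue
        strand = FibreStrand(np.array(pts), id=sid)
        if strand.length < min_length_mm:
            continue
        strand.id = sid
        sid += 1
        strands.append(strand)
    return strands


# ---------------------------------------------------------------------------
# Bundling
# ---------------------------------------------------------------------------


def crop_bundle(strands, box, name: str) -> FibreBundle:
    """Bundle the strands that pass through an axis-aligned cropping box.

    ``box = (lo, hi)`` with 3-vectors; a strand is included iff at least
    one of its points lies inside the closed box.
    """
    lo, hi = (np.asarray(b, float) for b in box)
    picked = []
    for s in strands:
        inside = np.all((s.points >= lo) & (s.points <= hi), axis=1)
        if np.any(inside):
            picked.append(s)
    return FibreBundle(name, picked)


def bundle_to_mask(bundle: FibreBundle, shape, voxel_size=(1.0, 1.0, 1.0)):
    """Binary volume of the voxels traversed by any strand point."""
    mask = np.zeros(shape, dtype=bool)
    vs = np.asarray(voxel_size, float)
    for s in bundle.strands:
        idx = np.round(s.points / vs - 0.5).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        for i, j, k in idx[ok]:
            mask[i, j, k] = True
    return mask


# ---------------------------------------------------------------------------
# Strand I/O: whitespace text (id, point-index, x, y, z) and VTK polylines
# ---------------------------------------------------------------------------


def write_strands(strands, path) -> None:
    with open(path, "w") as fh:
        fh.write("# strand_id point_index x y z\n")
        for s in strands:
            for n, p in enumerate(s.points, start=1):
                fh.write(f"{s.id} {n} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def read_strands(path) -> list:
    rows = np.loadtxt(path, ndmin=2)
    if rows.size == 0:
        return []
    if rows.shape[1] != 5:
        raise DataError(f"strand file needs 5 columns, got {rows.shape[1]}")
    strands = []
    for sid in np.unique(rows[:, 0]).astype(int):
        sub = rows[rows[:, 0] == sid]
        sub = sub[np.argsort(sub[:, 1])]
        strands.append(FibreStrand(sub[:, 2:5], id=int(sid)))
    return strands


def write_strands_vtk(strands, path) -> None:
    """Legacy-VTK POLYDATA export of strands as polylines."""
    npts = sum(s.n_points for s in strands)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibre strands\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {npts} float\n")
        for s in strands:
            for p in s.points:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        total = sum(s.n_points + 1 for s in strands)
        fh.write(f"LINES {len(strands)} {total}\n")
        off = 0
        for s in strands:
            ids = " ".join(str(off + i) for i in range(s.n_points))
            fh.write(f"{s.n_points} {ids}\n")
            off += s.n_points
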