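"""Mapping fibre strands onto tetrahedral elements.

Each element of a muscle mesh receives an *effective fibre direction*: the
tracked strands are cut into maximal runs of consecutively numbered points
inside the element, a total-least-squares trend line is fitted to each run,
and the run directions are combined with weights ``w_s = n_s^2 / sum n_s^2``
(``n_s`` = points in run ``s``), so long coherent passages dominate short
clips.  The resulting per-element field is then smoothed per muscle with a
Gaussian radial-basis kernel

    phi(x_i, x_e) = exp(-(p ||x_i - x_e|| / L)^2)

where ``L`` is the diagonal of the muscle's bounding box and ``p`` (default
20) sets how many neighbouring elements influence each direction.  Fibre
directions are axial quantities (f and -f are the same fibre), so
contributions are hemisphere-aligned before any summation and all outputs
are normalised to unit length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError
from .meshkit import TetMesh, bounding_box_diagonal, element_centroids_volumes

__all__ = [
    "ElementFibreField",
    "FibreRun",
    "strand_segments_in_element",
    "line_of_best_fit",
    "effective_direction",
    "map_fibres",
    "smooth_fibre_field",
    "export_element_solid_ortho",
]

log = logging.getLogger(__name__)

#: Default Gaussian RBF sharpness for fibre-field smoothing.
DEFAULT_P = 20.0

#: Fallback material axis written for elements with no fibre direction.
FALLBACK_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass
class ElementFibreField:
    """Per-element unit fibre directions (NaN rows = missing) + run counts."""

    directions: np.ndarray
    source_counts: np.ndarray

    def __post_init__(self):
        self.directions = np.asarray(self.directions, float)
        self.source_counts = np.asarray(self.source_counts, int)
        if self.directions.shape != (len(self.source_counts), 3):
            raise DataError("directions must be (n_elements, 3)")
        norms = np.linalg.norm(self.directions, axis=1)
        ok = ~np.isnan(norms)
        if np.any(np.abs(norms[ok] - 1.0) > 1e-9):
            raise DataError("stored directions must be unit vectors")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.directions).any(axis=1)

    @property
    def n_elements(self) -> int:
        return len(self.source_counts)


@dataclass
class FibreRun:
    """A maximal run of consecutive strand points inside one element."""

    direction: np.ndarray  # unit trend-line direction g_s
    n_points: int  # n_s
    strand_id: int = 0


# ---------------------------------------------------------------------------
# Point-in-element classification
# ---------------------------------------------------------------------------


def _barycentric(tet_nodes, points, tol=1e-9):
    """Barycentric coordinates of points wrt a tet; inside iff all >= -tol."""
    T = (tet_nodes[1:] - tet_nodes[0]).T  # 3x3
    lam = np.linalg.solve(T, (np.atleast_2d(points) - tet_nodes[0]).T).T
    lam0 = 1.0 - lam.sum(axis=1, keepdims=True)
    return np.hstack([lam0, lam])


def points_in_tet(tet_nodes, points, tol=1e-9):
    lam = _barycentric(tet_nodes, points)
    return np.all(lam >= -tol, axis=1)


def strand_segments_in_element(strand, mesh: TetMesh, element: int) -> list:
    """Maximal runs of consecutively numbered strand points inside an element.

    Boundary points count as inside.  Returns a list of ``FibreRun``; runs
    of a single point carry no direction and are dropped.
    """
    tet = mesh.nodes[mesh.elements[element]]
    inside = points_in_tet(tet, strand.points)
    return _runs_from_flags(strand, inside)


def _runs_from_flags(strand, inside) -> list:
    runs = []
    start = None
    flags = list(inside) + [False]
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            n = i - start
            if n >= 2:
                g = line_of_best_fit(strand.points[start:i])
                runs.append(FibreRun(g, n, strand.id))
            start = None
    return runs


def line_of_best_fit(points) -> np.ndarray:
    """Unit principal axis of a point set (total least squares).

    The sign follows the traversal direction of the points (last - first).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) < 2:
        raise DataError("line of best fit needs >= 2 points")
    centred = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    g = Vt[0]
    travel = pts[-1] - pts[0]
    if np.dot(g, travel) < 0:
        g = -g
    n = np.linalg.norm(g)
    if n == 0:
        raise DataError("degenerate point set (all points coincide)")
    return g / n


def effective_direction(runs) -> np.ndarray:
    """Combine run directions with weights ``w_s = n_s^2 / sum n_s^2``.

    Directions are hemisphere-aligned to the longest run before summation
    (fibre directions are axial; without alignment antiparallel runs would
    cancel) and the weighted sum is normalised to unit length.
    """
    if not runs:
        raise DataError("effective_direction needs at least one run")
    n = np.array([r.n_points for r in runs], float)
    w = n**2 / np.sum(n**2)
    ref = runs[int(np.argmax(n))].direction
    total = np.zeros(3)
    for wi, r in zip(w, runs):
        d = r.direction if np.dot(r.direction, ref) >= 0 else -r.direction
        total += wi * d
    norm = np.linalg.norm(total)
    if norm < 1e-12:
        raise DataError("run directions cancel; cannot form a direction")
    return total / norm


def run_weights(runs) -> np.ndarray:
    """The ``w_s`` weight vector of a run set (sums to 1)."""
    n = np.array([r.n_points for r in runs], float)
    return n**2 / np.sum(n**2)


# ---------------------------------------------------------------------------
# Whole-mesh mapping
# ---------------------------------------------------------------------------


def find_element(mesh: TetMesh, point, centroid_tree=None, centroids=None, k=32):
    """Index of the element containing a point, or -1.

    Nearest-centroid candidates are tested first; falls back to a full scan
    so boundary-sliver cases stay correct.
    """
    if centroids is None:
        centroids, _ = element_centroids_volumes(mesh)
    if centroid_tree is None:
        centroid_tree = cKDTree(centroids)
    k = min(k, mesh.n_elements)
    _, cand = centroid_tree.query(point, k=k)
    for e in np.atleast_1d(cand):
        if points_in_tet(mesh.nodes[mesh.elements[e]], point)[0]:
            return int(e)
    for e in range(mesh.n_elements):
        if points_in_tet(mesh.nodes[mesh.elements[e]], point)[0]:
            return int(e)
    return -1


def map_fibres(mesh: TetMesh, strands) -> ElementFibreField:
    """Effective fibre direction per element from a set of strands.

    Every strand point is located in the mesh; per element, the maximal
    consecutive runs of each strand are trend-line fitted and combined by
    :func:`effective_direction`.  Elements traversed by no run get a NaN
    (missing) direction.
    """
    centroids, _ = element_centroids_volumes(mesh)
    tree = cKDTree(centroids)
    runs_per_element: dict[int, list] = {}
    for strand in strands:
        owner = np.array(
            [
                find_element(mesh, p, centroid_tree=tree, centroids=centroids)
                for p in strand.points
            ]
        )
        for e in np.unique(owner):
            if e < 0:
                continue
            for run in _runs_from_flags(strand, owner == e):
                runs_per_element.setdefault(int(e), []).append(run)
    directions = np.full((mesh.n_elements, 3), np.nan)
    counts = np.zeros(mesh.n_elements, dtype=int)
    for e, runs in runs_per_element.items():
        directions[e] = effective_direction(runs)
        counts[e] = len(runs)
    return ElementFibreField(directions, counts)


# ---------------------------------------------------------------------------
# RBF smoothing
# ---------------------------------------------------------------------------


def smooth_fibre_field(
    mesh: TetMesh,
    fibre_field: ElementFibreField,
    p: float = DEFAULT_P,
    parts=None,
    density_scaled: bool = False,
    length_scale: float | None = None,
) -> ElementFibreField:
    """Gaussian-RBF smoothing of the per-element direction field, per muscle.

    For each element centroid ``x_i`` of a part the smoothed direction is
    the normalised kernel-weighted sum of all seeded directions of that
    part, ``sum_e phi(x_i, x_e, p) f(x_e)`` with
    ``phi = exp(-(p ||x_i - x_e|| / L)^2)`` and ``L`` the part's
    bounding-box diagonal.  Elements without a direction are filled in.
    Contributions are hemisphere-aligned to the element's own direction
    (or, if missing, to the nearest seeded direction) before summation.

    With ``density_scaled=True`` the kernel sharpness is rescaled by the
    part's element count relative to a 1000-element reference, following
    the rule that denser meshes should use a smaller neighbourhood.
    """
    centroids, _ = element_centroids_volumes(mesh)
    out = np.array(fibre_field.directions, copy=True)
    labels = (
        np.unique(mesh.part_labels.astype(str)) if parts is None else list(parts)
    )
    for label in labels:
        sel = np.where(mesh.part_mask(label))[0]
        if len(sel) == 0:
            continue
        seeded = sel[~fibre_field.missing[sel]]
        if len(seeded) == 0:
            continue  # nothing to interpolate from for this part
        # L: the part's axis-aligned bounding-box diagonal.  Note the AABB
        # is orientation dependent; pass length_scale for a fixed kernel
        # width (e.g. when comparing rotated configurations).
        L = (
            bounding_box_diagonal(mesh.nodes[np.unique(mesh.elements[sel])])
            if length_scale is None
            else float(length_scale)
        )
        if L == 0:
            continue
        p_eff = p
        if density_scaled:
            p_eff = p * (len(sel) / 1000.0) ** (1.0 / 3.0)
        xi = centroids[sel]
        xe = centroids[seeded]
        f = fibre_field.directions[seeded]
        r = np.linalg.norm(xi[:, None, :] - xe[None, :, :], axis=2)
        phi = np.exp(-((p_eff * r / L) ** 2))
        seed_tree = cKDTree(xe)
        for row, e in enumerate(sel):
            ref = fibre_field.directions[e]
            if np.isnan(ref).any():
                _, j = seed_tree.query(centroids[e])
                ref = f[j]
            signs = np.where(f @ ref >= 0, 1.0, -1.0)
            total = (phi[row] * signs) @ f
            norm = np.linalg.norm(total)
            if norm < 1e-300:
                # kernel underflow far from every seed: keep nearest seed
                _, j = seed_tree.query(centroids[e])
                out[e] = f[j]
            else:
                out[e] = total / norm
    counts = fibre_field.source_counts.copy()
    return ElementFibreField(out, counts)


# ---------------------------------------------------------------------------
# LS-DYNA *ELEMENT_SOLID_ORTHO export
# ---------------------------------------------------------------------------


def _orthogonal_axis(a):
    """Any unit vector orthogonal to a (deterministic choice)."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(a)))] = 1.0
    d = np.cross(a, helper)
    return d / np.linalg.norm(d)


def export_element_solid_ortho(mesh: TetMesh, fibre_field, path) -> None:
    """Write per-element fibre directions as ``*ELEMENT_SOLID_ORTHO`` cards.

    Each card is three lines: the 1-based element/part/connectivity line
    (tets degenerate the 8-node slots by repeating the 4th node), the fibre
    direction ``a``, and an auto-generated orthogonal axis ``d``.  Missing
    directions fall back to the global x axis with a logged warning.
    """
    from .meshkit import _part_ids

    pid, _ = _part_ids(mesh)
    missing = fibre_field.missing
    if np.any(missing):
        log.warning(
            "%d element(s) lack a fibre direction; writing fallback axis %s",
            int(missing.sum()),
            FALLBACK_AXIS,
        )
    with open(path, "w") as fh:
        fh.write("*KEYWORD\n*ELEMENT_SOLID_ORTHO\n")
        for j in range(mesh.n_elements):
            n = mesh.elements[j] + 1
            fh.write(
                f"{j + 1:8d}{pid[j]:8d}"
                f"{n[0]:8d}{n[1]:8d}{n[2]:8d}{n[3]:8d}"
                f"{n[3]:8d}{n[3]:8d}{n[3]:8d}{n[3]:8d}\n"
            )
            a = FALLBACK_AXIS if missing[j] else fibre_field.directions[j]
            d = _orthogonal_axis(a)
            fh.write(f"{a[0]:16.8f}{a[1]:16.8f}{a[2]:16.8f}\n")
            fh.write(f"{d[0]:16.8f}{d[1]:16.8f}{d[2]:16.8f}\n")
        fh.write("*END\n")
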