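"""Diffusion-weighted MR image handling.

Scanner mosaics (a single 2D image tiling every slice of a 3D acquisition
in an N x N grid) are assembled into 3D volumes, repeated acquisitions are
averaged per gradient direction, Rician noise is removed with a local-PCA
denoiser, and volumes round-trip through NIfTI-1 with FSL-style bval/bvec
gradient tables.

Index conventions
-----------------
The mosaic slice-index mapping is ``m = N*(l-1) + k`` with 1-based tile
coordinates: ``k`` counts tile *columns* (fastest), ``l`` counts tile
*rows*, so slices fill the mosaic row by row and an empty last row leaves
the populated slice indices contiguous.  Internally everything is 0-based;
the 1-based convention appears only at this formula boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = [
    "MosaicImage",
    "DWIStack",
    "assemble_stack",
    "flatten_stack",
    "average_acquisitions",
    "denoise_local_pca",
    "read_nifti",
    "write_nifti",
    "read_bval_bvec",
    "write_bval_bvec",
    "read_dicom_mosaic",
]

#: Hard eigenvalue threshold of the local-PCA denoiser, in units of the
#: noise variance sigma^2.
LPCA_TAU = 2.3

#: Default local-PCA patch radius (patch edge = 2*radius + 1 voxels).
LPCA_PATCH_RADIUS = 1


@dataclass
class MosaicImage:
    """A 2D mosaic tiling the slices of a 3D scan in a ``grid_n x grid_n`` grid.

    Parameters
    ----------
    pixels : ndarray, shape (grid_n*tile_rows, grid_n*tile_cols)
        Raw mosaic intensities.
    grid_n : int
        Tiles per mosaic row and per mosaic column.
    tile_rows, tile_cols : int
        Pixel extent of one tile.
    n_slices : int, optional
        Number of populated tiles.  When omitted, trailing all-zero tiles
        are treated as empty.
    """

    pixels: np.ndarray
    grid_n: int
    tile_rows: int
    tile_cols: int
    n_slices: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.grid_n < 1:
            raise DataError(f"grid_n must be >= 1, got {self.grid_n}")
        expect = (self.grid_n * self.tile_rows, self.grid_n * self.tile_cols)
        if self.pixels.shape != expect:
            raise DataError(
                "mosaic pixel grid has shape "
                f"{self.pixels.shape}, but grid_n={self.grid_n} with "
                f"{self.tile_rows}x{self.tile_cols} tiles requires {expect}"
            )
        if self.n_slices is None:
            self.n_slices = self._infer_n_slices()
        if not 0 <= self.n_slices <= self.grid_n**2:
            raise DataError(
                f"n_slices={self.n_slices} outside [0, grid_n^2={self.grid_n ** 2}]"
            )

    def _infer_n_slices(self) -> int:
        n = self.grid_n**2
        while n > 0 and not np.any(self.tile(n - 1)):
            n -= 1
        return n

    def tile(self, m0: int) -> np.ndarray:
        """Pixel block of slice ``m0`` (0-based slice index)."""
        n = self.grid_n
        l0, k0 = divmod(m0, n)  # 0-based tile row / tile column
        return self.pixels[
            l0 * self.tile_rows : (l0 + 1) * self.tile_rows,
            k0 * self.tile_cols : (k0 + 1) * self.tile_cols,
        ]


@dataclass
class DWIStack:
    """A diffusion-weighted acquisition: 4D data plus its gradient scheme.

    ``volumes`` is stored ``(nx, ny, nz, n_volumes)``; ``bvals`` (s/mm^2),
    ``bvecs`` (unit vectors, zero rows for b=0) and ``acquisition_ids``
    (repeat index per volume) all run along the last axis.  ``voxel_size``
    is the physical spacing in mm.
    """

    volumes: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    acquisition_ids: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        if self.volumes.ndim != 4:
            raise DataError(f"volumes must be 4D, got ndim={self.volumes.ndim}")
        n = self.volumes.shape[-1]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise DataError(
                f"gradient table size mismatch: {n} volumes, "
                f"{len(self.bvals)} bvals, bvecs {self.bvecs.shape}"
            )
        if self.acquisition_ids is None:
            self.acquisition_ids = np.zeros(n, dtype=int)
        self.acquisition_ids = np.asarray(self.acquisition_ids, dtype=int)
        norms = np.linalg.norm(self.bvecs, axis=1)
        bad = ~(np.isclose(norms, 1.0, atol=1e-3) | np.isclose(norms, 0.0))
        if np.any(bad):
            raise DataError(
                f"bvecs must be unit vectors (or zero for b=0); norms {norms[bad]}"
            )

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[-1]

    @property
    def shape(self) -> tuple:
        return self.volumes.shape[:3]

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= 1e-9


def assemble_stack(mosaic: MosaicImage) -> np.ndarray:
    """Stack the populated tiles of a mosaic into a 3D volume.

    Returns an array of shape ``(tile_rows, tile_cols, n_slices)`` where
    voxel ``(u, v, m)`` equals the mosaic pixel at tile ``(k, l)`` with
    ``m = N*(l-1) + k`` (1-based, converted internally).
    """
    vol = np.empty(
        (mosaic.tile_rows, mosaic.tile_cols, mosaic.n_slices),
        dtype=mosaic.pixels.dtype,
    )
    for m0 in range(mosaic.n_slices):
        vol[:, :, m0] = mosaic.tile(m0)
    return vol


def flatten_stack(volume: np.ndarray, grid_n: int) -> MosaicImage:
    """Inverse of :func:`assemble_stack`: tile a 3D volume into a mosaic."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise DataError(f"expected a 3D volume, got ndim={volume.ndim}")
    tr, tc, ns = volume.shape
    if ns > grid_n**2:
        raise DataError(f"{ns} slices do not fit a {grid_n}x{grid_n} mosaic")
    pixels = np.zeros((grid_n * tr, grid_n * tc), dtype=volume.dtype)
    for m0 in range(ns):
        l0, k0 = divmod(m0, grid_n)
        pixels[l0 * tr : (l0 + 1) * tr, k0 * tc : (k0 + 1) * tc] = volume[:, :, m0]
    return MosaicImage(pixels, grid_n, tr, tc, n_slices=ns)


def _direction_key(bval: float, bvec: np.ndarray) -> tuple:
    if bval <= 1e-9:
        return ("b0",)
    return (round(float(bval), 3),) + tuple(np.round(bvec, 6))


def average_acquisitions(stack: DWIStack) -> DWIStack:
    """Average repeated acquisitions per gradient direction.

    All b=0 volumes collapse to a single mean b0 volume and each distinct
    (b-value, direction) pair to one mean volume, so 4 acquisitions of 12
    directions plus 12 b0 repeats reduce to 13 volumes.  Acquisitions must
    share one gradient table (b0 repeats aside); otherwise the stack is
    rejected.
    """
    groups: dict[tuple, list[int]] = {}
    for i in range(stack.n_volumes):
        key = _direction_key(stack.bvals[i], stack.bvecs[i])
        groups.setdefault(key, []).append(i)
    if ("b0",) not in groups:
        raise DataError("no b=0 volume present; cannot form the reference image")

    # every acquisition must carry the same set of weighted directions
    acq_tables: dict[int, set] = {}
    for i in range(stack.n_volumes):
        if stack.bvals[i] > 1e-9:
            acq = int(stack.acquisition_ids[i])
            acq_tables.setdefault(acq, set()).add(
                _direction_key(stack.bvals[i], stack.bvecs[i])
            )
    tables = list(acq_tables.values())
    if any(t != tables[0] for t in tables[1:]):
        raise DataError("inconsistent gradient tables across acquisitions")

    keys = [("b0",)] + [k for k in groups if k != ("b0",)]
    vols = np.stack(
        [stack.volumes[..., groups[k]].mean(axis=-1) for k in keys], axis=-1
    )
    bvals = np.array([0.0 if k == ("b0",) else k[0] for k in keys])
    bvecs = np.array(
        [np.zeros(3) if k == ("b0",) else np.asarray(k[1:]) for k in keys]
    )
    return DWIStack(vols, bvals, bvecs, stack.voxel_size)


def denoise_local_pca(
    stack: DWIStack,
    patch_radius: int = LPCA_PATCH_RADIUS,
    noise_sigma: float = None,
) -> DWIStack:
    """Local-PCA denoising of a DWI stack with Rician bias correction.

    For every sliding (2r+1)^3 patch the Casorati matrix (patch voxels x
    volumes) is decomposed by PCA across the volume dimension and
    eigenvalues below ``LPCA_TAU * sigma^2`` are suppressed; overlapping
    patch estimates are averaged, then the Rician bias of magnitude data
    is removed via ``sqrt(max(m^2 - 2 sigma^2, 0))``.  This is a
    sliding-window variant of overcomplete local-PCA denoising, sized for
    desk-scale volumes.

    Parameters
    ----------
    patch_radius : int
        Half-width of the cubic patch.
    noise_sigma : float
        Rician noise level of the magnitude data (same units as the
        intensities).  Must be positive.
    """
    if noise_sigma is None or noise_sigma <= 0:
        raise DataError(f"noise_sigma must be positive, got {noise_sigma}")
    if stack.n_volumes < 2:
        raise DataError("local PCA needs at least 2 volumes")
    r = int(patch_radius)
    nx, ny, nz = stack.shape
    w = 2 * r + 1
    if min(nx, ny, nz) < w:
        raise DataError(f"volume {stack.shape} smaller than patch width {w}")

    data = stack.volumes
    acc = np.zeros_like(data)
    cnt = np.zeros(stack.shape)
    tau = LPCA_TAU * noise_sigma**2
    for i in range(nx - w + 1):
        for j in range(ny - w + 1):
            for k in range(nz - w + 1):
                patch = data[i : i + w, j : j + w, k : k + w, :]
                X = patch.reshape(-1, stack.n_volumes)
                mean = X.mean(axis=0)
                Xc = X - mean
                cov = Xc.T @ Xc / max(X.shape[0] - 1, 1)
                evals, evecs = np.linalg.eigh(cov)
                keep = evals > tau
                Xd = (Xc @ evecs[:, keep]) @ evecs[:, keep].T + mean
                acc[i : i + w, j : j + w, k : k + w, :] += Xd.reshape(patch.shape)
                cnt[i : i + w, j : j + w, k : k + w] += 1.0
    out = acc / cnt[..., None]
    # Rician bias: E[m^2] = A^2 + 2 sigma^2 for a magnitude image
    out = np.clip(out, 0.0, None)
    out = np.sqrt(np.clip(out**2 - 2.0 * noise_sigma**2, 0.0, None))
    return DWIStack(
        out, stack.bvals, stack.bvecs, stack.voxel_size, stack.acquisition_ids
    )


# ---------------------------------------------------------------------------
# NIfTI / gradient-table / DICOM-mosaic I/O
# ---------------------------------------------------------------------------


def write_nifti(stack: DWIStack, path, write_gradients: bool = True) -> None:
    """Write a stack as a 4D NIfTI-1 file (plus FSL-style .bval/.bvec)."""
    import nibabel as nib

    affine = np.diag(list(stack.voxel_size) + [1.0])
    img = nib.Nifti1Image(stack.volumes, affine)
    nib.save(img, str(path))
    if write_gradients:
        base = str(path)
        for ext in (".nii.gz", ".nii"):
            if base.endswith(ext):
                base = base[: -len(ext)]
                break
        write_bval_bvec(stack.bvals, stack.bvecs, base + ".bval", base + ".bvec")


def read_nifti(path, bval_path=None, bvec_path=None) -> DWIStack:
    """Read a 3D/4D NIfTI volume into a stack.

    Without a gradient table the volumes are flagged b=0.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise DataError(f"expected a 3D or 4D NIfTI, got ndim={data.ndim}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    n = data.shape[-1]
    if bval_path is not None:
        bvals, bvecs = read_bval_bvec(bval_path, bvec_path)
        if len(bvals) != n:
            raise DataError(
                f"gradient table lists {len(bvals)} entries for {n} volumes"
            )
    else:
        bvals, bvecs = np.zeros(n), np.zeros((n, 3))
    return DWIStack(data, bvals, bvecs, voxel_size)


def write_bval_bvec(bvals, bvecs, bval_path, bvec_path) -> None:
    bvals = np.atleast_1d(np.asarray(bvals, float))
    bvecs = np.atleast_2d(np.asarray(bvecs, float))
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):  # FSL layout: one row per component
            fh.write(" ".join(f"{v:.8f}" for v in bvecs[:, axis]) + "\n")


def read_bval_bvec(bval_path, bvec_path):
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL files are component-major
    return bvals, bvecs


def read_dicom_mosaic(path, grid_n: int | None = None) -> MosaicImage:
    """Read a Siemens-style mosaic DICOM into a :class:`MosaicImage`.

    The mosaic grid is inferred from the private NumberOfImagesInMosaic
    tag (0019,100A) when present; otherwise ``grid_n`` must be supplied.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    pixels = ds.pixel_array
    n_slices = None
    elem = ds.get((0x0019, 0x100A))
    if elem is not None:
        raw = elem.value
        n_slices = int(raw.decode() if isinstance(raw, bytes) else raw)
        if grid_n is None:
            grid_n = int(np.ceil(np.sqrt(n_slices)))
    if grid_n is None:
        raise DataError(
            "mosaic grid size not found in DICOM tags; pass grid_n explicitly"
        )
    rows, cols = pixels.shape
    if rows % grid_n or cols % grid_n:
        raise DataError(
            f"pixel grid {pixels.shape} not divisible by grid_n={grid_n}"
        )
    return MosaicImage(
        pixels, grid_n, rows // grid_n, cols // grid_n, n_slices=n_slices
    )
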