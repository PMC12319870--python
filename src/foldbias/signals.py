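"""Noise generation, volume-to-surface projection, geodesic smoothing.

These are the two mechanisms by which uneven vertex spacing turns
spatially independent noise into spatially structured surface signal:

* **upsampling** — projecting voxel data onto a mesh whose vertices are
  packed more densely than the voxel grid makes nearby vertices share
  voxel values (:func:`project_volume_to_surface`);
* **smoothing** — a fixed-width geodesic Gaussian kernel averages over
  more vertices where they are closely spaced (:func:`build_kernel` +
  :func:`smooth`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .mesh import ScalarMap, TriangleMesh, geodesic_distances
from .synth import VoxelGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TimeSeriesMatrix:
    """n_vertices x T functional signal on a mesh."""

    values: np.ndarray
    mesh_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (vertices x timepoints)")
        if np.isnan(self.values).any():
            raise ValueError("time series must not contain NaN")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class SmoothingKernel:
    """Row-stochastic sparse smoothing weights on a mesh.

    ``weights[u, v] = exp(-d(u, v)^2 / (2 sigma^2))`` for geodesic
    ``d <= radius`` (the self-weight at d = 0 included), rows normalised
    to sum to one so constants are preserved.
    """

    weights: sparse.csr_matrix
    fwhm: float
    truncation_fraction: float
    radius: float

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


def kernel_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given FWHM."""
    return fwhm * FWHM_TO_SIGMA


def truncation_radius(fwhm: float, truncation_fraction: float = 0.01) -> float:
    """Radius beyond which the discarded 2D Gaussian integral fraction
    equals ``truncation_fraction``: exp(-r^2 / 2 sigma^2) = fraction."""
    if not 0 < truncation_fraction < 1:
        raise ValueError("truncation_fraction must lie in (0, 1)")
    return kernel_sigma(fwhm) * np.sqrt(2.0 * np.log(1.0 / truncation_fraction))


def surface_noise(mesh: TriangleMesh | int, T: int, seed: int) -> TimeSeriesMatrix:
    """I.i.d. standard-normal time series, one per vertex."""
    if T < 3:
        raise ValueError("T must be >= 3 for any downstream correlation")
    n = mesh if isinstance(mesh, int) else mesh.n_vertices
    rng = np.random.default_rng(seed)
    return TimeSeriesMatrix(rng.standard_normal((n, T)))


def volume_noise(grid: VoxelGrid, T: int, seed: int) -> VoxelGrid:
    """I.i.d. standard-normal time series, one per voxel (4D output)."""
    if T < 3:
        raise ValueError("T must be >= 3 for any downstream correlation")
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal(grid.shape + (T,))
    return VoxelGrid(shape=grid.shape, affine=grid.affine, values=vals)


def project_volume_to_surface(
    volume: VoxelGrid, mesh: TriangleMesh, method: str = "trilinear"
) -> TimeSeriesMatrix:
    """Sample voxel time series at mesh vertex positions.

    ``trilinear`` interpolates among the 8 surrounding voxel centres in
    voxel-index space (via the inverse affine); ``nearest`` takes the
    closest voxel centre.  Spatial weights are identical across
    timepoints.
    """
    if volume.values is None:
        raise ValueError("volume carries no values")
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    ijk = volume.world_to_voxel(mesh.vertices)
    dims = np.array(volume.shape)
    lo_ok = ijk >= (0.0 if method == "trilinear" else -0.5)
    hi_ok = ijk <= (dims - 1 if method == "trilinear" else dims - 0.5)
    bad = ~np.all(lo_ok & hi_ok, axis=1)
    if bad.any():
        v = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"vertex {v} at voxel coordinates {ijk[v]} lies outside the grid"
        )
    vals = volume.values
    if method == "nearest":
        idx = np.clip(np.round(ijk).astype(int), 0, dims - 1)
        out = vals[idx[:, 0], idx[:, 1], idx[:, 2], :]
        return TimeSeriesMatrix(out)
    i0 = np.minimum(np.floor(ijk).astype(int), dims - 2)
    i0 = np.maximum(i0, 0)
    f = ijk - i0
    out = np.zeros((mesh.n_vertices, vals.shape[3]))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                w = wx * wy * wz
                out += w[:, None] * vals[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz, :]
    return TimeSeriesMatrix(out)


def build_kernel(
    mesh: TriangleMesh, fwhm: float, truncation_fraction: float = 0.01
) -> SmoothingKernel:
    """Geodesic Gaussian smoothing kernel, truncated and row-normalised."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = kernel_sigma(fwhm)
    radius = truncation_radius(fwhm, truncation_fraction)
    dist = geodesic_distances(mesh, max_radius=radius)
    w = dist.copy()
    w.data = np.exp(-(dist.data**2) / (2.0 * sigma**2))
    rowsum = np.asarray(w.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / rowsum)
    return SmoothingKernel(
        weights=(inv @ w).tocsr(),
        fwhm=fwhm,
        truncation_fraction=truncation_fraction,
        radius=radius,
    )


def smooth(data, kernel: SmoothingKernel):
    """Apply the kernel: output = weights @ input, per timepoint.

    Accepts a TimeSeriesMatrix, ScalarMap, or plain array; returns the
    same kind.  Constant inputs are preserved exactly (rows sum to 1).
    """
    if isinstance(data, TimeSeriesMatrix):
        if data.n_vertices != kernel.n_vertices:
            raise ValueError("kernel and series vertex counts differ")
        return TimeSeriesMatrix(kernel.weights @ data.values, mesh_id=data.mesh_id)
    if isinstance(data, ScalarMap):
        if len(data) != kernel.n_vertices:
            raise ValueError("kernel and map vertex counts differ")
        return ScalarMap(kernel.weights @ data.values, name=data.name)
    arr = np.asarray(data, dtype=float)
    if arr.shape[0] != kernel.n_vertices:
        raise ValueError("kernel and data vertex counts differ")
    return kernel.weights @ arr
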