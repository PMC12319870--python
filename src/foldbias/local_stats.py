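"""Local correlation and its variants.

The core statistic: a vertex's *local correlation* is the Fisher-z
average of the Pearson correlations between its time series and those of
its mesh-edge neighbours, transformed back to a correlation.  Variants
cover the coarse-scale normalisation (subtracting the mean within a
geodesic radius), the volumetric 6-neighbour control, the
autocorrelation-vs-distance profile, and parcel-level time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .mesh import ScalarMap, TriangleMesh, as_values, edges, geodesic_distances
from .signals import TimeSeriesMatrix
from .synth import Parcellation, VoxelGrid

#: correlations are clipped to +-(1 - CLIP_EPS) before arctanh so the
#: Fisher transform stays finite on degenerate (identical-series) input.
CLIP_EPS = 1e-12


def _fisher(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS))


def _standardise(x: np.ndarray, warn_label: str = "series"):
    """Z-score rows (population SD); zero-variance rows become NaN."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    sd = np.sqrt((xc**2).mean(axis=-1, keepdims=True))
    zero = (sd == 0).ravel()
    if zero.any():
        warnings.warn(
            f"{zero.sum()} zero-variance {warn_label}; correlations set to NaN",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = xc / sd
    return z


def local_correlation(series: TimeSeriesMatrix, mesh: TriangleMesh) -> ScalarMap:
    """Fisher-averaged neighbour correlation, one value per vertex.

    ``value(v) = tanh(mean over u in adj(v) of artanh(r(v, u)))``.
    Vertices with a zero-variance series (or a zero-variance neighbour)
    get NaN.
    """
    x = series.values if isinstance(series, TimeSeriesMatrix) else np.asarray(series)
    if x.shape[0] != mesh.n_vertices:
        raise ValueError("series and mesh vertex counts differ")
    if x.shape[1] < 3:
        raise ValueError("need T >= 3 timepoints")
    z = _standardise(x)
    e = edges(mesh)
    r = (z[e[:, 0]] * z[e[:, 1]]).mean(axis=1)
    fz = _fisher(r)
    n = mesh.n_vertices
    acc = np.zeros(n)
    np.add.at(acc, e[:, 0], fz)
    np.add.at(acc, e[:, 1], fz)
    deg = np.bincount(e.ravel(), minlength=n)
    return ScalarMap(np.tanh(acc / deg), name="local_correlation")


def normalise_local(
    scalar_map, mesh: TriangleMesh, radius: float = 15.0
) -> ScalarMap:
    """Subtract the (unweighted) mean over all vertices within a geodesic
    radius; the neighbourhood includes the centre vertex itself."""
    v = as_values(scalar_map)
    if v.size != mesh.n_vertices:
        raise ValueError("map and mesh vertex counts differ")
    dist = geodesic_distances(mesh, max_radius=radius)
    ones = dist.copy()
    ones.data = np.ones_like(ones.data)
    counts = np.asarray(ones.sum(axis=1)).ravel()
    sums = ones @ v
    name = scalar_map.name if isinstance(scalar_map, ScalarMap) else ""
    return ScalarMap(v - sums / counts, name=f"normalised[{name}]")


def volumetric_local_correlation(
    volume: VoxelGrid, mask: np.ndarray | None = None
) -> np.ndarray:
    """Fisher-averaged correlation of each voxel with its 6 face
    neighbours, restricted to ``mask``; NaN where undefined."""
    if volume.values is None:
        raise ValueError("volume carries no values")
    vals = volume.values
    if mask is None:
        mask = np.ones(vals.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    z = _standardise(vals, warn_label="voxels")
    T = vals.shape[3]
    acc = np.zeros(vals.shape[:3])
    cnt = np.zeros(vals.shape[:3], dtype=int)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        both = mask[sl_a] & mask[sl_b]
        r = (z[sl_a] * z[sl_b]).sum(axis=-1) / T
        fz = _fisher(r)
        acc[sl_a][both] += fz[both]
        cnt[sl_a][both] += 1
        acc[sl_b][both] += fz[both]
        cnt[sl_b][both] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.tanh(acc / cnt)
    out[~mask | (cnt == 0)] = np.nan
    return out


@dataclass
class AutocorrProfile:
    """Mean pairwise correlation as a function of geodesic distance."""

    bin_edges: np.ndarray
    mean_correlation: np.ndarray
    pair_counts: np.ndarray


def autocorr_profile(
    series: TimeSeriesMatrix,
    mesh: TriangleMesh,
    bin_edges,
    max_radius: float,
) -> AutocorrProfile:
    """Pool all vertex pairs with geodesic distance <= max_radius into
    distance bins; report the Fisher-averaged correlation per bin."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if bin_edges[-1] > max_radius:
        raise ValueError("bins must lie within max_radius")
    x = series.values
    z = _standardise(x)
    dist = geodesic_distances(mesh, max_radius=max_radius).tocoo()
    keep = dist.row < dist.col  # each unordered pair once; drops self-pairs
    i, j, d = dist.row[keep], dist.col[keep], dist.data[keep]
    r = (z[i] * z[j]).mean(axis=1)
    fz = _fisher(r)
    which = np.digitize(d, bin_edges) - 1
    nbins = bin_edges.size - 1
    valid = (which >= 0) & (which < nbins)
    counts = np.bincount(which[valid], minlength=nbins)
    sums = np.bincount(which[valid], weights=fz[valid], minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.tanh(sums / counts)
    means[counts == 0] = np.nan
    return AutocorrProfile(
        bin_edges=bin_edges, mean_correlation=means, pair_counts=counts
    )


def parcel_timeseries(
    series: TimeSeriesMatrix,
    parcellation: Parcellation,
    areas=None,
    weighted: bool = True,
) -> np.ndarray:
    """Per-parcel mean time series (K x T).

    ``weighted=True`` weights each vertex by its surface area (the
    bias-reducing convention); otherwise a plain mean.
    """
    x = series.values
    labels = parcellation.labels
    K = parcellation.n_parcels
    if labels.size != x.shape[0]:
        raise ValueError("parcellation and series vertex counts differ")
    sizes = np.bincount(labels, minlength=K)
    if np.any(sizes == 0):
        raise ValueError(f"empty parcel(s): {np.flatnonzero(sizes == 0).tolist()}")
    if weighted:
        if areas is None:
            raise ValueError("weighted parcel means require vertex areas")
        w = as_values(areas)
    else:
        w = np.ones(x.shape[0])
    mat = sparse.csr_matrix(
        (w, (labels, np.arange(labels.size))), shape=(K, labels.size)
    )
    totals = np.asarray(mat.sum(axis=1)).ravel()
    return (mat @ x) / totals[:, None]


def vertex_parcel_coupling(
    series: TimeSeriesMatrix,
    parcel_series: np.ndarray,
    parcellation: Parcellation,
) -> ScalarMap:
    """Pearson correlation of each vertex with its own parcel's mean series."""
    x = series.values
    p = np.asarray(parcel_series, dtype=float)
    if x.shape[1] != p.shape[1]:
        raise ValueError("series and parcel series timepoint counts differ")
    zx = _standardise(x)
    zp = _standardise(p, warn_label="parcel series")
    r = (zx * zp[parcellation.labels]).mean(axis=1)
    return ScalarMap(r, name="vertex_parcel_coupling")
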