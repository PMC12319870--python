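"""Test-retest identification ("fingerprinting") from functional
connectivity of smoothed noise.

Each participant gets two independent smoothed-noise scans.  Retest
scans are matched to the test scan whose vectorised FC correlates most
strongly; accuracy is the fraction of correct self-matches (chance =
1/n participants).  Parcel-level FC of noise identifies nobody; within-
parcel vertex-level FC identifies almost everyone, because vertex
spacing idiosyncrasy leaks into near-neighbour correlations — and the
effect collapses when pairs closer than a distance threshold are
removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, geodesic_distances, vertex_areas
from .signals import SmoothingKernel, TimeSeriesMatrix, build_kernel, smooth, surface_noise
from .local_stats import parcel_timeseries
from .synth import Cohort, Parcellation, Participant


def fc_matrix(series) -> np.ndarray:
    """Pairwise Pearson correlation between node time series.

    Symmetric with unit diagonal; raises on any zero-variance node.
    """
    x = np.asarray(series.values if hasattr(series, "values") else series, float)
    if x.shape[1] < 3:
        raise ValueError("need T >= 3 timepoints")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance node {bad}")
    fc = np.corrcoef(x)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def vectorise(
    fc: np.ndarray,
    distances: np.ndarray | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Upper-triangle (i < j, row-major) entries of an FC matrix.

    With a distance threshold, pairs *strictly closer* than the threshold
    are dropped (pairs at exactly the threshold are retained; unknown
    distances should be +inf and are retained).
    """
    fc = np.asarray(fc)
    iu = np.triu_indices(fc.shape[0], k=1)
    vals = fc[iu]
    if threshold is None or threshold <= 0:
        return vals
    if distances is None:
        raise ValueError("distance threshold requires a node distance table")
    keep = np.asarray(distances)[iu] >= threshold
    if not keep.any():
        raise ValueError("distance threshold removed all pairs")
    return vals[keep]


@dataclass
class IdentificationResult:
    """Argmax match per retest vector and the resulting accuracy."""

    matches: np.ndarray
    accuracy: float
    similarity: np.ndarray  # retest x test correlation table


def identify(test_vectors: np.ndarray, retest_vectors: np.ndarray) -> IdentificationResult:
    """Match each retest FC vector to its most-correlated test vector.

    Ties break to the lowest participant index.  Accuracy is the
    fraction of retest scans matched to their own test scan.
    """
    t = np.asarray(test_vectors, dtype=float)
    r = np.asarray(retest_vectors, dtype=float)
    if t.shape != r.shape or t.ndim != 2:
        raise ValueError("test and retest vector tables must have equal shape")
    if t.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    zt = (t - t.mean(1, keepdims=True)) / t.std(1, keepdims=True)
    zr = (r - r.mean(1, keepdims=True)) / r.std(1, keepdims=True)
    sim = (zr @ zt.T) / t.shape[1]
    matches = np.argmax(sim, axis=1)  # argmax takes the lowest index on ties
    accuracy = float(np.mean(matches == np.arange(t.shape[0])))
    return IdentificationResult(matches=matches, accuracy=accuracy, similarity=sim)


# ---------------------------------------------------------------------------
# cohort-level pipelines


def scan_seed(participant_seed: int, replicate: int, scan: int) -> list[int]:
    """Disjoint seed stream per participant/replicate/scan."""
    return [participant_seed, replicate, scan]


def smoothed_scan(
    participant: Participant, kernel: SmoothingKernel, T: int, seed
) -> np.ndarray:
    """One synthetic 'scan': white surface noise smoothed on the mesh."""
    noise = surface_noise(participant.mesh, T, seed)
    return smooth(noise, kernel).values


def cohort_kernels(cohort: Cohort, fwhm: float) -> list[SmoothingKernel]:
    return [build_kernel(p.mesh, fwhm) for p in cohort]


def replicate_scans(
    cohort: Cohort, kernels: list[SmoothingKernel], T: int, replicate: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(test, retest) smoothed-noise scan pair per participant."""
    out = []
    for p, k in zip(cohort, kernels):
        test = smoothed_scan(p, k, T, scan_seed(p.seed, replicate, 0))
        retest = smoothed_scan(p, k, T, scan_seed(p.seed, replicate, 1))
        out.append((test, retest))
    return out


def parcel_level_accuracy(
    scans: list[tuple[np.ndarray, np.ndarray]],
    cohort: Cohort,
    parcellation: Parcellation,
) -> float:
    """Fingerprinting accuracy of area-weighted parcel-level FC."""
    tvecs, rvecs = [], []
    for (test, retest), p in zip(scans, cohort):
        areas = vertex_areas(p.mesh)
        for scan, dest in ((test, tvecs), (retest, rvecs)):
            pts = parcel_timeseries(
                TimeSeriesMatrix(scan), parcellation, areas=areas, weighted=True
            )
            dest.append(vectorise(fc_matrix(pts)))
    return identify(np.asarray(tvecs), np.asarray(rvecs)).accuracy


def within_parcel_distances(
    mesh: TriangleMesh, parcellation: Parcellation, max_radius: float
) -> list[np.ndarray]:
    """Per parcel, dense geodesic distance table between its vertices.

    Pairs beyond ``max_radius`` get +inf (they are always retained by
    the strictly-less-than threshold convention).
    """
    out = []
    for k in range(parcellation.n_parcels):
        members = parcellation.members(k)
        sub = geodesic_distances(mesh, max_radius=max_radius, sources=members)
        dense = np.full((members.size, mesh.n_vertices), np.inf)
        coo = sub.tocoo()
        dense[coo.row, coo.col] = coo.data
        out.append(dense[:, members])
    return out


def vertex_level_accuracy(
    scans: list[tuple[np.ndarray, np.ndarray]],
    parcellation: Parcellation,
    thresholds=(0.0,),
    distances: list[list[np.ndarray]] | None = None,
) -> np.ndarray:
    """Within-parcel vertex-level fingerprinting accuracy.

    Returns an (n_thresholds, K) array; parcels whose FC vector is empty
    at a threshold are NaN (skipped).  ``distances[i][k]`` is the
    within-parcel distance table for participant i, parcel k (required
    for thresholds > 0).  Because identification compares vectors across
    participants, the retained-pair mask must be shared: a pair is
    dropped if it is closer than the threshold in *any* participant
    (element-wise minimum of the per-participant distance tables).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    K = parcellation.n_parcels
    n = len(scans)
    fcs = []
    for test, retest in scans:
        per_parcel = []
        for k in range(K):
            members = parcellation.members(k)
            per_parcel.append(
                (fc_matrix(test[members]), fc_matrix(retest[members]))
            )
        fcs.append(per_parcel)
    pooled = None
    if np.any(thresholds > 0):
        if distances is None:
            raise ValueError("thresholds > 0 require within-parcel distances")
        pooled = [
            np.minimum.reduce([distances[i][k] for i in range(n)])
            for k in range(K)
        ]
    acc = np.full((thresholds.size, K), np.nan)
    for ti, theta in enumerate(thresholds):
        for k in range(K):
            try:
                dist = pooled[k] if theta > 0 else None
                tvecs = [
                    vectorise(fcs[i][k][0], distances=dist, threshold=theta)
                    for i in range(n)
                ]
                rvecs = [
                    vectorise(fcs[i][k][1], distances=dist, threshold=theta)
                    for i in range(n)
                ]
                acc[ti, k] = identify(np.asarray(tvecs), np.asarray(rvecs)).accuracy
            except ValueError:
                continue  # parcel skipped at this threshold (vector empty/degenerate)
    return acc


def threshold_sweep(
    cohort: Cohort,
    parcellation: Parcellation,
    thresholds,
    fwhm: float = 2.0,
    T: int = 500,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Accuracy-vs-distance-threshold curves for within-parcel vertex FC.

    Returns a tidy frame (replicate, threshold, parcel, accuracy); NaN
    accuracy marks parcels skipped because the threshold emptied their
    FC vector.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    kernels = cohort_kernels(cohort, fwhm)
    distances = None
    if np.any(thresholds > 0):
        radius = float(thresholds.max())
        distances = [
            within_parcel_distances(p.mesh, parcellation, radius) for p in cohort
        ]
    rows = []
    for rep in range(n_replicates):
        scans = replicate_scans(cohort, kernels, T, rep)
        acc = vertex_level_accuracy(scans, parcellation, thresholds, distances)
        for ti, theta in enumerate(thresholds):
            for k in range(parcellation.n_parcels):
                rows.append(
                    {
                        "replicate": rep,
                        "threshold": theta,
                        "parcel": k,
                        "accuracy": acc[ti, k],
                    }
                )
    return pd.DataFrame(rows)
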