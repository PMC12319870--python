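"""Parcellation experiments: constrained Ward clustering, border bias,
matched/mismatched individuality, and parcel-mean bias.

Clustering biased noise recovers anatomy: because smoothing inflates
correlations in sulci, Ward parcels of pure-noise data grow around
sulcal cores and place their borders on gyral crests.  The operations
here quantify that border bias and its participant specificity.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .inference import TestResult, paired_t, shift_permutation_test, two_sample_t
from .local_stats import parcel_timeseries, vertex_parcel_coupling
from .mesh import ScalarMap, TriangleMesh, as_values, edges
from .signals import TimeSeriesMatrix
from .synth import Cohort, Parcellation


def ward_parcellate(
    series: TimeSeriesMatrix, mesh: TriangleMesh, K: int
) -> Parcellation:
    """Connectivity-constrained Ward agglomerative clustering.

    Clusters vertex time-series vectors under the Ward minimum-variance
    criterion, with candidate merges restricted to cluster pairs joined
    by at least one mesh edge, so parcels are connected by construction.
    The merge cost for clusters A, B is the exact increase in
    within-cluster sum of squares,

        cost(A, B) = |A| |B| / (|A| + |B|) * ||mean(A) - mean(B)||^2,

    recomputed from cluster sums (cluster statistics are immutable per
    cluster id, so pending heap entries whose two ids are both still
    alive are always valid).  Ties break on the lowest (i, j) id pair.
    """
    x = series.values if isinstance(series, TimeSeriesMatrix) else np.asarray(series)
    n = x.shape[0]
    if x.shape[0] != mesh.n_vertices:
        raise ValueError("series and mesh vertex counts differ")
    if K < 1 or K > n:
        raise ValueError("K must lie in [1, n_vertices]")

    counts = [1] * n
    sums = [x[i].copy() for i in range(n)]
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for a, b in edges(mesh):
        nbrs[a].add(int(b))
        nbrs[b].add(int(a))
    children: dict[int, tuple[int, int]] = {}
    alive = set(range(n))

    def cost(i: int, j: int) -> float:
        diff = sums[i] / counts[i] - sums[j] / counts[j]
        return counts[i] * counts[j] / (counts[i] + counts[j]) * float(diff @ diff)

    heap: list[tuple[float, int, int]] = []
    for i in range(n):
        for j in nbrs[i]:
            if i < j:
                heap.append((cost(i, j), i, j))
    heapq.heapify(heap)

    n_clusters = n
    while n_clusters > K:
        while heap:
            c, i, j = heapq.heappop(heap)
            if i in alive and j in alive:
                break
        else:
            raise ValueError(
                f"mesh has more than K={K} connected components; "
                "cannot merge further"
            )
        m = len(counts)
        counts.append(counts[i] + counts[j])
        sums.append(sums[i] + sums[j])
        merged_nbrs = (nbrs[i] | nbrs[j]) - {i, j}
        nbrs.append(merged_nbrs)
        for c_id in merged_nbrs:
            nbrs[c_id].discard(i)
            nbrs[c_id].discard(j)
            nbrs[c_id].add(m)
            heapq.heappush(heap, (cost(c_id, m), min(c_id, m), max(c_id, m)))
        children[m] = (i, j)
        alive.discard(i)
        alive.discard(j)
        alive.add(m)
        n_clusters -= 1

    labels = np.empty(n, dtype=np.int64)
    roots = sorted(alive)
    for k, root in enumerate(roots):
        stack = [root]
        while stack:
            node = stack.pop()
            if node < n:
                labels[node] = k
            else:
                stack.extend(children[node])
    # canonical label order: by first vertex index in each parcel
    first = np.full(K, n, dtype=np.int64)
    np.minimum.at(first, labels, np.arange(n))
    remap = np.empty(K, dtype=np.int64)
    remap[np.argsort(first)] = np.arange(K)
    return Parcellation(labels=remap[labels], n_parcels=K)


def border_vertices(parcellation: Parcellation, mesh: TriangleMesh) -> np.ndarray:
    """Boolean mask: vertex has at least one neighbour in a different parcel."""
    labels = parcellation.labels
    e = edges(mesh)
    mixed = labels[e[:, 0]] != labels[e[:, 1]]
    out = np.zeros(labels.size, dtype=bool)
    out[e[mixed, 0]] = True
    out[e[mixed, 1]] = True
    return out


@dataclass
class BorderDepthResult:
    """Border vs non-border sulcal-depth contrast."""

    mean_border: float
    mean_nonborder: float
    test: TestResult
    permutation_p: float | None = None


def border_depth_test(
    parcellation: Parcellation,
    depth,
    mesh: TriangleMesh,
    n_perm: int = 0,
    seed: int | None = None,
) -> BorderDepthResult:
    """Two-sample t-test of depth between border and non-border vertices.

    Positive t means borders sit on gyri.  With ``n_perm > 0`` a
    shift-permutation p for the border-indicator/depth correlation is
    attached (valid on periodic sheets only).
    """
    d = as_values(depth)
    border = border_vertices(parcellation, mesh)
    if border.all() or not border.any():
        raise ValueError("both border and non-border groups must be non-empty")
    res = two_sample_t(d[border], d[~border])
    perm_p = None
    if n_perm > 0:
        perm = shift_permutation_test(
            border.astype(float), d, mesh, n_perm=n_perm, seed=seed
        )
        perm_p = perm.p
    return BorderDepthResult(
        mean_border=float(d[border].mean()),
        mean_nonborder=float(d[~border].mean()),
        test=res,
        permutation_p=perm_p,
    )


@dataclass
class MatchedMismatched:
    """Per-participant statistic under own vs next participant's depth map."""

    matched: np.ndarray
    mismatched: np.ndarray
    paired: TestResult


def matched_mismatched(
    cohort: Cohort, stat: Callable[..., float]
) -> MatchedMismatched:
    """Evaluate ``stat(participant, depth_values)`` with each participant's
    own depth (matched) and the next participant's depth, cyclically
    (mismatched); paired t-test on the two sets.

    All cohort meshes must share vertex count/topology so depth maps
    transfer by vertex index.
    """
    n0 = cohort[0].mesh.n_vertices
    for p in cohort:
        if p.mesh.n_vertices != n0:
            raise ValueError("cohort meshes must share vertex count")
    matched = []
    mismatched = []
    for i, p in enumerate(cohort):
        other = cohort[cohort.next_index(i)]
        matched.append(stat(p, p.depth.values))
        mismatched.append(stat(p, other.depth.values))
    matched = np.asarray(matched)
    mismatched = np.asarray(mismatched)
    return MatchedMismatched(
        matched=matched, mismatched=mismatched, paired=paired_t(matched, mismatched)
    )


def parcel_mean_bias(
    series: TimeSeriesMatrix,
    parcellation: Parcellation,
    depth,
    areas,
    mesh: TriangleMesh,
    weighted: bool = True,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Association between vertex-parcel coupling and sulcal depth.

    Computes each vertex's correlation with its parcel-mean time series
    (area-weighted or plain mean), then the area-weighted Pearson
    correlation of that coupling map against depth, with a
    shift-permutation p.  Negative r means gyral vertices are
    under-represented in their parcel means.
    """
    pts = parcel_timeseries(series, parcellation, areas=areas, weighted=weighted)
    coupling = vertex_parcel_coupling(series, pts, parcellation)
    perm = shift_permutation_test(
        coupling.values, as_values(depth), mesh, w=areas, n_perm=n_perm, seed=seed
    )
    return {
        "r": perm.observed,
        "p": perm.p,
        "weighted": weighted,
        "coupling": ScalarMap(coupling.values, name="vertex_parcel_coupling"),
    }
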