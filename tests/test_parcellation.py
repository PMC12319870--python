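import numpy as np
import pytest

from foldbias.mesh import TriangleMesh, edges, neighbours, vertex_areas
from foldbias.parcellation import (
    border_depth_test,
    border_vertices,
    matched_mismatched,
    parcel_mean_bias,
    ward_parcellate,
)
from foldbias.signals import TimeSeriesMatrix, build_kernel, smooth, surface_noise
from foldbias.synth import (
    FoldParameters,
    Parcellation,
    make_cohort,
    make_contiguous_parcellation,
)

from conftest import SMALL_PARAMS, planar_grid_mesh, random_bumpy_mesh


def ward_oracle(x: np.ndarray, mesh: TriangleMesh, K: int) -> np.ndarray:
    """O(n^3) reference: recompute every edge-connected merge cost each
    step; merge the global minimum; ties to the lowest (i, j) pair."""
    n = x.shape[0]
    clusters = {i: [i] for i in range(n)}
    nbrs = {i: set() for i in range(n)}
    for a, b in edges(mesh):
        nbrs[a].add(int(b))
        nbrs[b].add(int(a))
    next_id = n
    while len(clusters) > K:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i or j not in nbrs[i]:
                    continue
                mi = x[clusters[i]].mean(axis=0)
                mj = x[clusters[j]].mean(axis=0)
                ni, nj = len(clusters[i]), len(clusters[j])
                cost = ni * nj / (ni + nj) * float((mi - mj) @ (mi - mj))
                if best is None or (cost, i, j) < best:
                    best = (cost, i, j)
        _, i, j = best
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        nbrs[next_id] = (nbrs.pop(i) | nbrs.pop(j)) - {i, j}
        for c in nbrs[next_id]:
            nbrs[c].discard(i)
            nbrs[c].discard(j)
            nbrs[c].add(next_id)
        next_id += 1
    labels = np.empty(n, dtype=int)
    for k, members in enumerate(clusters.values()):
        labels[members] = k
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same partition up to relabelling."""
    pa = {tuple(sorted(np.flatnonzero(a == k))) for k in np.unique(a)}
    pb = {tuple(sorted(np.flatnonzero(b == k))) for k in np.unique(b)}
    return pa == pb


class TestWard:
    def test_singletons(self):
        mesh = planar_grid_mesh(3, 3)
        x = np.random.default_rng(0).standard_normal((9, 5))
        parc = ward_parcellate(TimeSeriesMatrix(x), mesh, 9)
        assert len(np.unique(parc.labels)) == 9

    def test_two_components_recovered(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0],
             [10, 10, 0], [11, 10, 0], [10, 11, 0]], dtype=float
        )
        mesh = TriangleMesh(verts, np.array([[0, 1, 2], [3, 4, 5]]))
        x = np.random.default_rng(1).standard_normal((6, 8))
        parc = ward_parcellate(TimeSeriesMatrix(x), mesh, 2)
        assert len(set(parc.labels[:3])) == 1
        assert len(set(parc.labels[3:])) == 1
        assert parc.labels[0] != parc.labels[3]

    def test_too_many_components_for_k(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0],
             [10, 10, 0], [11, 10, 0], [10, 11, 0]], dtype=float
        )
        mesh = TriangleMesh(verts, np.array([[0, 1, 2], [3, 4, 5]]))
        x = np.random.default_rng(1).standard_normal((6, 8))
        with pytest.raises(ValueError, match="connected components"):
            ward_parcellate(TimeSeriesMatrix(x), mesh, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        mesh = random_bumpy_mesh(5, 6, seed=seed)  # 30 vertices
        x = np.random.default_rng(seed + 10).standard_normal((30, 10))
        got = ward_parcellate(TimeSeriesMatrix(x), mesh, 4).labels
        want = ward_oracle(x, mesh, 4)
        assert partitions_equal(got, want)

    def test_parcels_connected(self, small_folded):
        mesh = small_folded.mesh
        x = surface_noise(mesh, 30, seed=3)
        parc = ward_parcellate(x, mesh, 12)
        adj = neighbours(mesh)
        for k in range(12):
            members = set(parc.members(k).tolist())
            start = next(iter(members))
            seen = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for u in adj[v]:
                    if u in members and u not in seen:
                        seen.add(int(u))
                        stack.append(int(u))
            assert seen == members

    def test_k_bounds(self, small_folded):
        x = surface_noise(small_folded.mesh, 10, seed=0)
        with pytest.raises(ValueError):
            ward_parcellate(x, small_folded.mesh, 0)
        with pytest.raises(ValueError):
            ward_parcellate(x, small_folded.mesh, small_folded.mesh.n_vertices + 1)


class TestBorderVertices:
    def test_single_parcel_no_borders(self, small_folded):
        parc = Parcellation(
            labels=np.zeros(small_folded.mesh.n_vertices, dtype=int), n_parcels=1
        )
        assert not border_vertices(parc, small_folded.mesh).any()

    def test_strip_split_borders(self):
        mesh = planar_grid_mesh(6, 3)  # vertex index = i*3 + j
        labels = (np.arange(18) // 3 >= 3).astype(int)  # split between i=2 and 3
        parc = Parcellation(labels=labels, n_parcels=2)
        border = border_vertices(parc, mesh)
        expected = np.zeros(18, dtype=bool)
        expected[2 * 3:4 * 3] = True  # rows i=2 and i=3 flank the cut
        np.testing.assert_array_equal(border, expected)

    def test_matches_bruteforce_scan(self):
        mesh = random_bumpy_mesh(7, 7, seed=4)
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 5, mesh.n_vertices)
        parc = Parcellation(labels=labels, n_parcels=5)
        border = border_vertices(parc, mesh)
        adj = neighbours(mesh)
        for v in range(mesh.n_vertices):
            expected = any(labels[u] != labels[v] for u in adj[v])
            assert border[v] == expected


class TestBorderDepthTest:
    def test_constant_depth_errors(self, small_folded):
        parc = make_contiguous_parcellation(small_folded.mesh, 5, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            border_depth_test(parc, np.ones(small_folded.mesh.n_vertices),
                              small_folded.mesh)

    def test_borders_on_maxima_give_positive_t(self):
        mesh = planar_grid_mesh(8, 8)
        labels = (np.arange(64) // 8 >= 4).astype(int)
        parc = Parcellation(labels=labels, n_parcels=2)
        border = border_vertices(parc, mesh)
        depth = np.where(border, 1.0, -1.0) + np.random.default_rng(6).normal(
            0, 0.1, 64
        )
        res = border_depth_test(parc, depth, mesh)
        assert res.test.t > 0
        assert res.mean_border > res.mean_nonborder

    def test_null_calibration(self):
        # random borders on random depth: t centred at 0, rejections ~ alpha
        mesh = planar_grid_mesh(10, 10)
        rng = np.random.default_rng(7)
        ts = []
        rejected = 0
        for rep in range(300):
            parc = make_contiguous_parcellation(mesh, 4, seed=rep)
            depth = rng.standard_normal(100)
            res = border_depth_test(parc, depth, mesh)
            ts.append(res.test.t)
            rejected += res.test.p < 0.05
        assert abs(np.mean(ts)) < 0.2
        assert 0.02 <= rejected / len(ts) <= 0.10


@pytest.fixture(scope="module")
def cohort():
    return make_cohort(4, SMALL_PARAMS, master_seed=5)


class TestMatchedMismatched:

    def test_depth_independent_stat_gives_null(self, cohort):
        rng = np.random.default_rng(8)

        def stat(p, depth_values):
            return float(rng.standard_normal())

        mm = matched_mismatched(cohort, stat)
        assert abs(mm.paired.t) < 5  # finite, no systematic direction

    def test_cohort_of_two_swaps(self):
        cohort = make_cohort(2, SMALL_PARAMS, master_seed=2)
        seen = []

        def stat(p, depth_values):
            seen.append((p.id, depth_values[0]))
            return 0.5 * depth_values[0]

        mm = matched_mismatched(cohort, stat)
        d0 = cohort[0].depth.values[0]
        d1 = cohort[1].depth.values[0]
        assert mm.matched[0] == pytest.approx(0.5 * d0)
        assert mm.mismatched[0] == pytest.approx(0.5 * d1)
        assert mm.mismatched[1] == pytest.approx(0.5 * d0)

    def test_topology_mismatch_errors(self, cohort):
        from foldbias.synth import Cohort, make_folded_sheet

        other = make_folded_sheet(FoldParameters(grid_n=16, seed=99))
        bad = Cohort(
            participants=[cohort[0], other], master_seed=0
        )
        with pytest.raises(ValueError, match="vertex count"):
            matched_mismatched(bad, lambda p, d: 0.0)


class TestParcelMeanBias:
    def test_uniform_mesh_unbiased(self, default_uniform):
        p = default_uniform
        kern = build_kernel(p.mesh, fwhm=4.0)
        series = smooth(surface_noise(p.mesh, 300, seed=9), kern)
        parc = make_contiguous_parcellation(p.mesh, 50, seed=9)
        res = parcel_mean_bias(
            series, parc, p.depth, vertex_areas(p.mesh), p.mesh,
            weighted=False, n_perm=99, seed=0,
        )
        assert abs(res["r"]) < 0.05
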