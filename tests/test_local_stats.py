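import numpy as np
import pytest

from foldbias.local_stats import (
    autocorr_profile,
    local_correlation,
    normalise_local,
    parcel_timeseries,
    vertex_parcel_coupling,
    volumetric_local_correlation,
)
from foldbias.mesh import TriangleMesh, edges, geodesic_distances
from foldbias.signals import TimeSeriesMatrix, build_kernel, smooth, surface_noise
from foldbias.synth import Parcellation, VoxelGrid

from conftest import planar_grid_mesh, random_bumpy_mesh


def star_mesh():
    """Centre vertex 0 ringed by vertices 1..3."""
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, -1, 0]], dtype=float
    )
    return TriangleMesh(verts, np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1]]))


class TestLocalCorrelation:
    def test_identical_series_gives_one(self):
        mesh = star_mesh()
        base = np.random.default_rng(0).standard_normal(30)
        series = TimeSeriesMatrix(np.tile(base, (4, 1)))
        out = local_correlation(series, mesh)
        np.testing.assert_allclose(out.values, 1.0)

    def test_exact_half_correlation(self):
        # neighbours of vertex 0 built to correlate exactly 0.5 with it
        mesh = star_mesh()
        rng = np.random.default_rng(1)
        T = 200
        x0 = rng.standard_normal(T)
        x0 = (x0 - x0.mean()) / x0.std()
        rows = [x0]
        for _ in range(3):
            y = rng.standard_normal(T)
            y = y - (y @ x0) / (x0 @ x0) * x0  # orthogonalise
            y = (y - 0.0) / y.std()
            y = y - y.mean()
            y = y / y.std()
            rows.append(0.5 * x0 + np.sqrt(0.75) * y)
        out = local_correlation(TimeSeriesMatrix(np.array(rows)), mesh)
        assert out.values[0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_bruteforce_edge_loop(self):
        mesh = random_bumpy_mesh(5, 10, seed=2)  # 50 vertices
        x = np.random.default_rng(3).standard_normal((50, 40))
        out = local_correlation(TimeSeriesMatrix(x), mesh)
        # independent oracle: per-edge np.corrcoef + Fisher averaging
        n = mesh.n_vertices
        sums = np.zeros(n)
        deg = np.zeros(n)
        for u, v in edges(mesh):
            r = np.corrcoef(x[u], x[v])[0, 1]
            fz = np.arctanh(r)
            sums[u] += fz
            deg[u] += 1
            sums[v] += fz
            deg[v] += 1
        np.testing.assert_allclose(out.values, np.tanh(sums / deg), rtol=1e-9)

    def test_zero_variance_gives_nan_with_warning(self):
        mesh = star_mesh()
        x = np.random.default_rng(0).standard_normal((4, 20))
        x[2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = local_correlation(TimeSeriesMatrix(x), mesh)
        assert np.isnan(out.values[2])

    def test_needs_three_timepoints(self):
        with pytest.raises(ValueError):
            local_correlation(
                TimeSeriesMatrix(np.zeros((4, 2)) + np.arange(2)), star_mesh()
            )


def test_white_noise_local_correlation_centred_at_zero(small_folded):
    series = surface_noise(small_folded.mesh, 500, seed=12)
    out = local_correlation(series, small_folded.mesh)
    assert abs(out.values.mean()) < 4 / np.sqrt(500 * small_folded.mesh.n_vertices / 4)


def test_volumetric_control_projected_to_surface_is_unbiased():
    # volume-space 6-neighbour correlations carry no fold information
    from foldbias.inference import weighted_pearson
    from foldbias.mesh import vertex_areas
    from foldbias.signals import project_volume_to_surface, volume_noise
    from foldbias.synth import FoldParameters, make_folded_sheet, make_voxel_grid

    p = make_folded_sheet(FoldParameters(grid_n=32, seed=0))
    grid = make_voxel_grid(p.mesh, 2.0, pad=4.0)
    vol = volume_noise(grid, 300, seed=5)
    vmap = volumetric_local_correlation(vol)
    projected = project_volume_to_surface(
        VoxelGrid(grid.shape, grid.affine, vmap[..., None]), p.mesh
    )
    r = weighted_pearson(projected.values[:, 0], p.depth, vertex_areas(p.mesh))
    assert abs(r) < 0.1


class TestNormaliseLocal:
    def test_constant_map_zero(self, small_folded):
        mesh = small_folded.mesh
        out = normalise_local(np.full(mesh.n_vertices, 2.5), mesh, radius=5.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_radius_below_smallest_edge_gives_zero(self):
        mesh = planar_grid_mesh(5, 5, spacing=2.0)
        vals = np.random.default_rng(0).standard_normal(25)
        out = normalise_local(vals, mesh, radius=0.5)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_matches_explicit_neighbourhood_means(self, small_folded):
        mesh = small_folded.mesh
        radius = 6.0
        vals = np.random.default_rng(1).standard_normal(mesh.n_vertices)
        out = normalise_local(vals, mesh, radius=radius)
        dist = geodesic_distances(mesh, max_radius=radius)
        for v in range(0, mesh.n_vertices, 37):
            hood = dist[v].tocoo().col  # stored entries = within radius, incl. self
            assert out.values[v] == pytest.approx(vals[v] - vals[hood].mean())


class TestVolumetricLocalCorrelation:
    def test_identical_series_everywhere(self):
        base = np.random.default_rng(0).standard_normal(20)
        vals = np.tile(base, (3, 3, 3, 1))
        vol = VoxelGrid(shape=(3, 3, 3), affine=np.eye(4), values=vals)
        out = volumetric_local_correlation(vol)
        np.testing.assert_allclose(out, 1.0)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((6, 6, 6, 500))
        vol = VoxelGrid(shape=(6, 6, 6), affine=np.eye(4), values=vals)
        out = volumetric_local_correlation(vol)
        assert abs(np.nanmean(out)) < 4 / np.sqrt(500)
        assert np.nanmean(np.abs(out)) < 4 / np.sqrt(500)

    def test_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((3, 3, 3, 15))
        mask = rng.uniform(size=(3, 3, 3)) > 0.2
        mask[1, 1, 1] = True
        vol = VoxelGrid(shape=(3, 3, 3), affine=np.eye(4), values=vals)
        out = volumetric_local_correlation(vol, mask)
        # oracle: explicit 6-neighbour loop with Fisher averaging
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if not mask[i, j, k]:
                        assert np.isnan(out[i, j, k])
                        continue
                    fzs = []
                    for di, dj, dk in [(1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)]:
                        a, b, c = i + di, j + dj, k + dk
                        if 0 <= a < 3 and 0 <= b < 3 and 0 <= c < 3 and mask[a, b, c]:
                            r = np.corrcoef(vals[i, j, k], vals[a, b, c])[0, 1]
                            fzs.append(np.arctanh(r))
                    if fzs:
                        assert out[i, j, k] == pytest.approx(np.tanh(np.mean(fzs)))
                    else:
                        assert np.isnan(out[i, j, k])

    def test_empty_mask_error(self):
        vol = VoxelGrid(
            shape=(2, 2, 2), affine=np.eye(4), values=np.zeros((2, 2, 2, 5))
        )
        with pytest.raises(ValueError):
            volumetric_local_correlation(vol, np.zeros((2, 2, 2), dtype=bool))


class TestAutocorrProfile:
    def test_white_noise_flat_near_zero(self, small_folded):
        series = surface_noise(small_folded.mesh, 400, seed=4)
        prof = autocorr_profile(
            series, small_folded.mesh, [0.0, 2.0, 4.0, 6.0], max_radius=6.0
        )
        assert np.all(np.abs(prof.mean_correlation) < 4 / np.sqrt(400))

    def test_smoothed_noise_decreases_with_distance(self, small_folded):
        kern = build_kernel(small_folded.mesh, fwhm=4.0)
        series = smooth(surface_noise(small_folded.mesh, 400, seed=5), kern)
        prof = autocorr_profile(
            series, small_folded.mesh, [0.0, 2.0, 4.0, 6.0], max_radius=6.0
        )
        m = prof.mean_correlation
        assert m[0] > m[1] > m[2]

    def test_single_pair_bin(self):
        mesh = planar_grid_mesh(2, 2, spacing=1.0)
        x = np.random.default_rng(6).standard_normal((4, 30))
        # diagonal pair (0, 3) at sqrt(2) is the only pair in [1.2, 1.5)
        prof = autocorr_profile(
            TimeSeriesMatrix(x), mesh, [1.2, 1.5], max_radius=2.0
        )
        assert prof.pair_counts[0] == 1
        expected = np.corrcoef(x[0], x[3])[0, 1]
        assert prof.mean_correlation[0] == pytest.approx(expected)

    def test_bins_must_fit_radius(self, small_folded):
        with pytest.raises(ValueError):
            autocorr_profile(
                surface_noise(small_folded.mesh, 10, seed=0),
                small_folded.mesh,
                [0.0, 10.0],
                max_radius=5.0,
            )


class TestParcelTimeseries:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((12, 25))
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        parc = Parcellation(labels=labels, n_parcels=3)
        areas = rng.uniform(0.5, 3.0, 12)
        return TimeSeriesMatrix(x), parc, areas

    def test_equal_areas_match_unweighted(self, setup):
        series, parc, _ = setup
        w = parcel_timeseries(series, parc, areas=np.ones(12), weighted=True)
        u = parcel_timeseries(series, parc, weighted=False)
        np.testing.assert_allclose(w, u, rtol=1e-12)

    def test_single_vertex_parcel(self):
        x = np.random.default_rng(8).standard_normal((3, 10))
        parc = Parcellation(labels=np.array([0, 1, 2]), n_parcels=3)
        out = parcel_timeseries(TimeSeriesMatrix(x), parc, weighted=False)
        np.testing.assert_allclose(out, x, rtol=1e-12)

    def test_matches_weighted_loop_oracle(self, setup):
        series, parc, areas = setup
        out = parcel_timeseries(series, parc, areas=areas, weighted=True)
        for k in range(3):
            members = parc.members(k)
            expected = (
                areas[members][:, None] * series.values[members]
            ).sum(0) / areas[members].sum()
            np.testing.assert_allclose(out[k], expected, rtol=1e-12)

    def test_empty_parcel_error(self):
        x = np.random.default_rng(9).standard_normal((3, 10))
        parc = Parcellation(labels=np.array([0, 0, 2]), n_parcels=3)
        with pytest.raises(ValueError, match="empty parcel"):
            parcel_timeseries(TimeSeriesMatrix(x), parc, weighted=False)


class TestVertexParcelCoupling:
    def test_single_vertex_parcel_couples_fully(self):
        x = np.random.default_rng(10).standard_normal((2, 30))
        parc = Parcellation(labels=np.array([0, 1]), n_parcels=2)
        series = TimeSeriesMatrix(x)
        pts = parcel_timeseries(series, parc, weighted=False)
        out = vertex_parcel_coupling(series, pts, parc)
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-9)

    def test_anticorrelated_pair_symmetry(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal(100)
        eps = 1e-3 * rng.standard_normal(100)
        x = np.array([a + eps, -a + eps])
        parc = Parcellation(labels=np.array([0, 0]), n_parcels=1)
        series = TimeSeriesMatrix(x)
        pts = parcel_timeseries(series, parc, weighted=False)
        out = vertex_parcel_coupling(series, pts, parc)
        # parcel mean is the tiny residual; couplings roughly +/- symmetric
        assert abs(abs(out.values[0]) - abs(out.values[1])) < 0.2
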