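import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vifc import (
    ClusterSpec,
    SignalModel,
    VifcConfig,
    build_distance_index,
    compute_nvifc_map,
    compute_vifc_map,
    compute_vifc_vertex,
    correlation_row,
    make_chain_mesh,
    normality_diagnostic,
    simulate_bold,
    smooth_map,
    smooth_values,
)
from vifc.core import REASON_OK, REASON_ZERO_VARIANCE
from vifc.simulate import cluster_members
from vifc.surface_io import SurfaceMesh, VertexTimeSeries

from oracles import nvifc_brute, vifc_brute


def series_on(mesh, values):
    return VertexTimeSeries(np.asarray(values, dtype=float), mesh)


class TestCorrelationRow:
    def test_affine_is_one(self, tetra, rng):
        x = rng.standard_normal(8)
        values = np.vstack([x, 2 * x + 3, rng.standard_normal(8), rng.standard_normal(8)])
        r = correlation_row(series_on(tetra, values), 0)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(1.0)

    def test_negation_is_minus_one(self, tetra, rng):
        x = rng.standard_normal(8)
        values = np.vstack([x, -x, rng.standard_normal(8), rng.standard_normal(8)])
        r = correlation_row(series_on(tetra, values), 0)
        assert r[1] == pytest.approx(-1.0)

    def test_hand_value(self, tetra, rng):
        # x=(1,2,3,4), y=(1,3,2,4): cov=1, sd_x*sd_y = 1.25 -> r=0.8
        values = np.vstack(
            [[1, 2, 3, 4], [1, 3, 2, 4], rng.standard_normal(4), rng.standard_normal(4)]
        )
        r = correlation_row(series_on(tetra, values), 0)
        assert r[1] == pytest.approx(0.8)

    def test_zero_variance_flagged_not_raised(self, tetra, rng):
        values = rng.standard_normal((4, 6))
        values[2] = 5.0
        r = correlation_row(series_on(tetra, values), 0)
        assert np.isnan(r[2]) and np.isfinite(r[1])


@pytest.fixture(scope="module")
def hexa_mesh():
    """6-vertex octahedron-like mesh for brute-force comparisons."""
    coords = np.array(
        [[10.0, 0, 0], [-10, 0, 0], [0, 10, 0], [0, -10, 0], [0, 0, 10], [0, 0, -10]]
    )
    faces = np.array(
        [[0, 2, 4], [0, 4, 3], [0, 3, 5], [0, 5, 2],
         [1, 2, 4], [1, 4, 3], [1, 3, 5], [1, 5, 2]]
    )
    return SurfaceMesh(coords, faces)


class TestVifcVertex:
    def test_equal_in_out_means_gives_std(self, hexa_mesh):
        # vertex 0's series replicated everywhere: all r = 1, so the
        # in/out ratio is 1 and vIFC(0) = STD(0)
        base = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.25, 2.0, -0.5])
        values = np.vstack([base + 0.0] * 6)
        values += np.linspace(0, 5, 6)[:, None]  # offsets keep r = 1
        ts = series_on(hexa_mesh, values)
        idx = build_distance_index(hexa_mesh, [15.0])
        v = compute_vifc_vertex(ts, idx, 0, VifcConfig(15.0, 0.25))
        std0 = np.sqrt(np.sum((base - base.mean()) ** 2))
        assert v == pytest.approx(std0, rel=1e-12)

    def test_scale_equivariance(self, hexa_mesh, rng):
        values = rng.standard_normal((6, 12)) + rng.standard_normal(12) * 0.8
        idx = build_distance_index(hexa_mesh, [15.0])
        cfg = VifcConfig(15.0, 0.15)
        base = compute_vifc_map(series_on(hexa_mesh, values), idx, cfg)
        for c in (0.5, 2.0, 10.0):
            scaled = compute_vifc_map(series_on(hexa_mesh, c * values + 7.0), idx, cfg)
            np.testing.assert_allclose(
                scaled.values, c * base.values, rtol=1e-10, equal_nan=True
            )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        c=st.floats(0.01, 100.0, allow_nan=False),
        b=st.floats(-50.0, 50.0, allow_nan=False),
    )
    def test_affine_equivariance_property(self, hexa_mesh, c, b):
        rng = np.random.default_rng(1234)
        values = rng.standard_normal((6, 12)) + rng.standard_normal(12) * 0.8
        idx = build_distance_index(hexa_mesh, [15.0])
        cfg = VifcConfig(15.0, 0.15)
        base = compute_vifc_map(series_on(hexa_mesh, values), idx, cfg)
        scaled = compute_vifc_map(series_on(hexa_mesh, c * values + b), idx, cfg)
        np.testing.assert_allclose(
            scaled.values, c * base.values, rtol=1e-8, equal_nan=True
        )

    def test_brute_force_oracle(self, hexa_mesh, rng):
        values = rng.standard_normal((6, 8)) + 0.7 * rng.standard_normal(8)
        ts = series_on(hexa_mesh, values)
        idx = build_distance_index(hexa_mesh, [15.0])
        cfg = VifcConfig(15.0, 0.2)
        got = np.array([compute_vifc_vertex(ts, idx, i, cfg) for i in range(6)])
        ref = vifc_brute(values, hexa_mesh.vertex_coords, hexa_mesh.faces, 15.0, 0.2)
        np.testing.assert_allclose(got, ref, rtol=1e-10, equal_nan=True)


class TestVifcMap:
    def test_independent_noise_mostly_nan(self, ico2, rng):
        # with no planted structure almost no pair clears r >= 0.5
        values = rng.standard_normal((ico2.n_vertices, 300))
        idx = build_distance_index(ico2, [28.0])
        vmap = compute_vifc_map(series_on(ico2, values), idx, VifcConfig(28.0, 0.5))
        assert vmap.n_defined < 0.05 * ico2.n_vertices

    def test_decomposition_invariant(self, ico2_small, rng):
        model = SignalModel(
            cluster_specs=(ClusterSpec(0, 25.0, 1.0),),
            global_weight=0.4,
            noise_sd=1.0,
            n_timepoints=120,
            seed=7,
        )
        ts = simulate_bold(ico2_small, model)
        idx = build_distance_index(ico2_small, [14.0])
        vmap = compute_vifc_map(ts, idx, VifcConfig(14.0, 0.15))
        fin = np.isfinite(vmap.values)
        assert fin.sum() > 10
        np.testing.assert_allclose(
            vmap.values[fin],
            vmap.std_component[fin] * vmap.pcc_in[fin] / vmap.pcc_out[fin],
            rtol=1e-12,
        )
        assert (vmap.pcc_in[fin] >= 0.15).all() and (vmap.pcc_in[fin] <= 1.0).all()
        assert (vmap.pcc_out[fin] >= 0.15).all() and (vmap.pcc_out[fin] <= 1.0).all()
        assert (vmap.values[fin] >= 0).all()
        assert (vmap.reasons[fin] == REASON_OK).all()

    def test_planted_patch_detected(self, ico3):
        """Coherent patch on weakly coupled background lifts median vIFC."""
        idx = build_distance_index(ico3, [14.0])
        cfg = VifcConfig(14.0, 0.3)
        # rho_in = 0.7 needs a = sqrt(0.7/0.3); rho_bg = 0.15 needs
        # b = sqrt(0.15/0.85) on unit noise
        a = np.sqrt(0.7 / 0.3)
        b = np.sqrt(0.15 / 0.85)
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            model = SignalModel(
                cluster_specs=(ClusterSpec(0, 20.0, a),),
                global_weight=b,
                noise_sd=1.0,
                n_timepoints=150,
                seed=seed,
            )
            ts = simulate_bold(ico3, model)
            vmap = compute_vifc_map(ts, idx, cfg)
            patch = cluster_members(ico3, model.cluster_specs[0])
            inside = np.nanmedian(vmap.values[patch])
            outside = np.nanmedian(np.delete(vmap.values, patch))
            if np.isnan(outside) or inside > outside:
                wins += 1
        assert wins >= n_seeds - 1

    def test_grid_provenance(self, hexa_mesh, rng):
        values = rng.standard_normal((6, 30)) + rng.standard_normal(30)
        ts = series_on(hexa_mesh, values)
        idx = build_distance_index(hexa_mesh, [15.0, 25.0])
        maps = {}
        for d in (15.0, 25.0):
            for p in (0.15, 0.2, 0.25, 0.3):
                cfg = VifcConfig(d, p)
                maps[(d, p)] = compute_vifc_map(ts, idx, cfg)
        assert len(maps) == 8
        for (d, p), m in maps.items():
            assert m.config.distance_threshold_mm == d
            assert m.config.connectivity_threshold == p

    def test_missing_radius_rejected(self, hexa_mesh, rng):
        ts = series_on(hexa_mesh, rng.standard_normal((6, 10)))
        idx = build_distance_index(hexa_mesh, [15.0])
        with pytest.raises(ValueError, match="grid"):
            compute_vifc_map(ts, idx, VifcConfig(30.0, 0.2))

    def test_zero_variance_reason_code(self, hexa_mesh, rng):
        values = rng.standard_normal((6, 20)) + rng.standard_normal(20)
        values[3] = 1.5
        vmap = compute_vifc_map(
            series_on(hexa_mesh, values),
            build_distance_index(hexa_mesh, [15.0]),
            VifcConfig(15.0, 0.15),
        )
        assert np.isnan(vmap.values[3])
        assert vmap.reasons[3] == REASON_ZERO_VARIANCE


class TestNvifc:
    def test_ring_equals_ball(self, rng):
        """When the one-ring coincides with the distance ball, N == D."""
        chain = make_chain_mesh(12, spacing_mm=10.0)
        # ring of an interior vertex = {i-2, i-1, i+1, i+2} = ball(25)
        values = rng.standard_normal((12, 40)) + 1.2 * rng.standard_normal(40)
        ts = series_on(chain, values)
        idx = build_distance_index(chain, [25.0])
        cfg = VifcConfig(25.0, 0.15)
        dmap = compute_vifc_map(ts, idx, cfg)
        nmap = compute_nvifc_map(ts, chain, cfg)
        interior = slice(2, 10)
        np.testing.assert_allclose(
            nmap.values[interior], dmap.values[interior], rtol=1e-12, equal_nan=True
        )

    def test_scale_equivariance(self, rng):
        chain = make_chain_mesh(8, spacing_mm=10.0)
        values = rng.standard_normal((8, 25)) + rng.standard_normal(25)
        cfg = VifcConfig(25.0, 0.15)
        base = compute_nvifc_map(series_on(chain, values), chain, cfg)
        scaled = compute_nvifc_map(series_on(chain, 2 * values - 1), chain, cfg)
        np.testing.assert_allclose(
            scaled.values, 2 * base.values, rtol=1e-10, equal_nan=True
        )

    def test_brute_force_oracle(self, rng):
        chain = make_chain_mesh(6, spacing_mm=10.0)
        values = rng.standard_normal((6, 9)) + 0.8 * rng.standard_normal(9)
        cfg = VifcConfig(25.0, 0.2)
        got = compute_nvifc_map(series_on(chain, values), chain, cfg)
        ref = nvifc_brute(values, chain.faces, 0.2)
        np.testing.assert_allclose(got.values, ref, rtol=1e-10, equal_nan=True)


class TestSmoothing:
    def _map_on(self, mesh, values):
        from vifc.core import VifcMap

        return VifcMap(
            values=values,
            std_component=np.zeros_like(values),
            pcc_in=np.zeros_like(values),
            pcc_out=np.zeros_like(values),
            config=VifcConfig(14.0, 0.2, smoothing_fwhm_mm=0.0),
        )

    def test_zero_fwhm_identity(self, ico2, rng):
        values = rng.standard_normal(ico2.n_vertices)
        out = smooth_values(values, ico2, 0.0)
        np.testing.assert_array_equal(out, values)

    def test_constant_fixed_point(self, ico2):
        out = smooth_values(np.full(ico2.n_vertices, 3.7), ico2, 14.0)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_variance_shrinks_mean_preserved(self, ico2, rng):
        values = rng.standard_normal(ico2.n_vertices)
        out = smooth_values(values, ico2, 10.0)
        assert out.var() < values.var()
        assert out.mean() == pytest.approx(values.mean(), abs=1e-6)

    def test_nan_stays_nan_and_excluded(self, ico2, rng):
        values = rng.standard_normal(ico2.n_vertices)
        values[[3, 77]] = np.nan
        out = smooth_values(values, ico2, 12.0)
        assert np.isnan(out[[3, 77]]).all()
        assert np.isfinite(np.delete(out, [3, 77])).all()

    def test_negative_fwhm_rejected(self, ico2):
        with pytest.raises(ValueError):
            smooth_values(np.zeros(ico2.n_vertices), ico2, -1.0)

    def test_smooth_map_updates_config(self, ico2, rng):
        vmap = self._map_on(ico2, rng.standard_normal(ico2.n_vertices))
        out = smooth_map(vmap, ico2, 14.0)
        assert out.config.smoothing_fwhm_mm == 14.0
        assert vmap.config.smoothing_fwhm_mm == 0.0


class TestNormalityDiagnostic:
    def test_normal_sample_scores_high(self, rng):
        score, pairs = normality_diagnostic(rng.standard_normal(1000))
        assert score > 0.99
        assert pairs.shape == (1000, 2)

    def test_heavy_tail_scores_lower(self, rng):
        normal_score, _ = normality_diagnostic(rng.standard_normal(1000))
        heavy_score, _ = normality_diagnostic(rng.lognormal(0, 1.5, size=1000))
        assert heavy_score < normal_score

    def test_constant_unavailable(self):
        with pytest.raises(ValueError):
            normality_diagnostic(np.full(50, 2.0))

    def test_too_few_values_unavailable(self):
        with pytest.raises(ValueError, match="10"):
            normality_diagnostic(np.array([1.0, 2.0, np.nan] * 3))
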