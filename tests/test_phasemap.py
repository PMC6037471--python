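"""Phase-space interpolation: wrapping, limits, and covariate maps."""

import numpy as np
import pandas as pd
import pytest

from vertexdyn import phase as ph
from vertexdyn import phasemap as pm
from vertexdyn import synthetic as syn

DT = 3.0


class TestInterpolator:
    def test_constant_field(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-180, 180, (500, 1))
        g = pm.interp_to_grid(coords, np.full(500, 3.25))
        assert np.allclose(g.values[np.isfinite(g.values)], 3.25, atol=1e-12)

    def test_cosine_recovered(self):
        rng = np.random.default_rng(1)
        phs = rng.uniform(-180, 180, 4000)
        vals = np.cos(np.radians(phs)) + rng.normal(0, 0.1, 4000)
        g = pm.interp_to_grid(phs[:, None], vals)
        target = np.cos(np.radians(g.axes[0]))
        assert np.sqrt(np.nanmean((g.values - target) ** 2)) < 0.05

    def test_wrap_rule_sample_near_plus180(self):
        """A sample at +179 deg contributes to the node at -180 deg with the
        weight of a 1-deg distance."""
        g = pm.interp_to_grid(np.array([[179.0]]), np.array([1.0]),
                              bandwidth=15.0, min_weight=0.0)
        node = int(np.argmin(np.abs(g.axes[0] - (-180.0))))
        w = g.weights[node]
        assert w == pytest.approx(np.exp(-1.0 / (2 * 15.0 ** 2)), rel=1e-6)

    def test_wrap_equivalence_of_edge_nodes(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-180, 180, (1000, 1))
        vals = rng.normal(0, 1, 1000)
        g = pm.interp_to_grid(coords, vals)
        assert abs(g.values[0] - g.values[-1]) < 1e-9
        assert abs(g.weights[0] - g.weights[-1]) < 1e-9

    def test_bandwidth_limits(self):
        phs = np.arange(-180.0, 180.0, 2.0)
        vals = np.sin(np.radians(3 * phs))
        tiny = pm.interp_to_grid(phs[:, None], vals, spacing=10.0,
                                 bandwidth=0.3, min_weight=0.0)
        node_vals = np.sin(np.radians(3 * tiny.axes[0]))
        assert np.nanmax(np.abs(tiny.values - node_vals)) < 1e-6
        wide = pm.interp_to_grid(phs[:, None], vals, spacing=10.0,
                                 bandwidth=1e5, min_weight=0.0)
        assert np.nanmax(np.abs(wide.values - vals.mean())) < 1e-6

    def test_empty_input_fully_masked(self):
        g = pm.interp_to_grid(np.empty((0, 1)), np.empty(0))
        assert np.isnan(g.values).all()

    def test_sparse_regions_masked(self):
        g = pm.interp_to_grid(np.array([[0.0]]), np.array([1.0]),
                              bandwidth=5.0, min_weight=0.5)
        assert np.isnan(g.values[0])        # node at -180, far from the sample
        mid = int(np.argmin(np.abs(g.axes[0])))
        assert np.isfinite(g.values[mid])


def _clean_trace(period=150.0, duration=600.0, seed=0):
    _, areas, true_ph = syn.make_oscillating_areas(
        1, duration, DT, period_range_s=(period, period), snr=0, seed=seed)
    return ph.phase_from_area(areas[0], DT), areas[0], true_ph[0]


class TestLengthVsPhase:
    def test_isotropic_cycle_closes(self):
        """Length proportional to sqrt(area) returns to its start each cycle:
        the 175-deg bin (full-cycle change) is ~0."""
        tr, area, _ = _clean_trace()
        L = pd.Series(np.sqrt(area))
        grid, bins = pm.length_vs_phase([L], [[tr]])
        assert abs(bins["bin_175"]) < 0.01 * np.sqrt(area).mean()

    def test_constant_length_all_bins_zero(self):
        tr, area, _ = _clean_trace()
        L = pd.Series(np.full(len(area), 2.4))
        grid, bins = pm.length_vs_phase([L], [[tr]])
        assert bins["bin_0"] == pytest.approx(0.0, abs=1e-12)
        assert bins["bin_175"] == pytest.approx(0.0, abs=1e-12)

    def test_ratchet_program_detected(self):
        """Length falls only during contraction (phase < 0) and holds during
        expansion: bin(0) < 0 and bin(175) ~ bin(0)."""
        tr, area, true_ph = _clean_trace()
        falling = (true_ph < 0).astype(float)
        L = pd.Series(2.4 - 0.004 * np.cumsum(falling))
        grid, bins = pm.length_vs_phase([L], [[tr]])
        assert bins["bin_0"] < -0.05
        assert abs(bins["bin_175"] - bins["bin_0"]) < 0.2 * abs(bins["bin_0"])

    def test_fractional_length_scale_invariant(self):
        tr, area, _ = _clean_trace()
        L = pd.Series(np.sqrt(area))
        P = 6.1 * np.sqrt(area)
        _, bins1 = pm.fractional_length_vs_phase([L], [[P]], [[tr]])
        _, bins2 = pm.fractional_length_vs_phase([3 * L], [[3 * P]], [[tr]])
        assert bins1["bin_0"] == pytest.approx(bins2["bin_0"], abs=1e-12)
        # isotropic scaling leaves fractional length constant at all phases
        assert abs(bins1["bin_0"]) < 1e-9 and abs(bins1["bin_175"]) < 1e-9


class TestShapeMetric:
    def test_straight_cells_flat_at_one(self):
        tr, _, _ = _clean_trace()
        metric = pd.Series(np.ones(len(tr.phase_deg)))
        grid, bins = pm.shape_metric_vs_phase([metric], [tr])
        assert np.nanmax(np.abs(grid.values - 1.0)) < 1e-9

    def test_bulge_at_minima_raises_bin0(self):
        """Outward bulging at area minima: metric peaks at phase 0."""
        tr, _, true_ph = _clean_trace()
        metric = pd.Series(1.0 + 0.05 * np.cos(np.radians(true_ph)))
        grid, bins = pm.shape_metric_vs_phase([metric], [tr])
        assert bins[0.0] > bins[-180.0]
        assert bins[0.0] > bins[180.0]

    def test_circle_vs_hexagon_ratio(self):
        """Disk contour over its inscribed regular hexagon: analytic ratio at
        every phase."""
        tr, _, _ = _clean_trace()
        ratio = np.pi / (1.5 * np.sqrt(3))
        metric = pd.Series(np.full(len(tr.phase_deg), ratio))
        grid, bins = pm.shape_metric_vs_phase([metric], [tr])
        assert np.nanmax(np.abs(grid.values - ratio)) < 1e-9
        assert ratio > 1


class TestVertexAngle:
    def test_due_ventral_is_zero(self):
        rel = np.array([[0.0, 5.0]])  # +y = ventral by default
        assert pm.vertex_angle(rel)[0] == pytest.approx(0.0)

    def test_due_dorsal_is_180(self):
        rel = np.array([[0.0, -5.0]])
        assert abs(pm.vertex_angle(rel)[0]) == pytest.approx(180.0)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        rel = rng.normal(0, 2, (50, 2))
        a1 = pm.vertex_angle(rel, ventral_angle=90.0)
        rot = np.column_stack([-rel[:, 1], rel[:, 0]])  # rotate +90 deg
        a2 = pm.vertex_angle(rot, ventral_angle=180.0)
        d = (a1 - a2 + 180.0) % 360.0 - 180.0
        assert np.abs(d).max() < 1e-9

    def test_centroid_vertex_masked(self):
        assert np.isnan(pm.vertex_angle(np.zeros((1, 2)))[0])


class TestIntensityAnglePhaseMap:
    def test_t1_band_peak_at_phase_zero(self):
        rng = np.random.default_rng(4)
        n = 6000
        angles = rng.uniform(-180, 180, n)
        phases = rng.uniform(-180, 180, n)
        t1 = np.abs(np.abs(np.abs(angles) - 90.0)) <= 45.0
        intens = np.where(t1, np.cos(np.radians(phases)), 0.0)
        intens = intens + rng.normal(0, 0.05, n)
        grid, curves = pm.intensity_angle_phase_map(angles, phases, intens)
        idx = np.unravel_index(np.nanargmax(grid.values), grid.values.shape)
        peak_angle = grid.axes[0][idx[0]]
        peak_phase = grid.axes[1][idx[1]]
        assert abs(abs(peak_angle) - 90.0) <= 45.0
        assert abs(peak_phase) <= 30.0
        band = curves["t1_band"]
        target = np.cos(np.radians(band.axes[0]))
        assert np.sqrt(np.nanmean((band.values - target) ** 2)) < 0.1

    def test_uniform_noise_maps_near_zero(self):
        rng = np.random.default_rng(5)
        n = 20000
        grid, _ = pm.intensity_angle_phase_map(
            rng.uniform(-180, 180, n), rng.uniform(-180, 180, n),
            rng.normal(0, 1, n))
        finite = grid.values[np.isfinite(grid.values)]
        assert np.abs(finite).max() < 3.0 / np.sqrt(n / grid.values.size)


class Test3PhaseMap:
    def test_zero_motion_zero_map(self):
        rng = np.random.default_rng(6)
        phs = rng.uniform(-180, 180, (2000, 3))
        grid, _ = pm.tangential_rate_3phase_map(phs, np.zeros(2000))
        assert np.nanmax(np.abs(grid.values)) < 1e-12

    def test_wrap_corner_sample(self):
        g, _ = pm.tangential_rate_3phase_map(
            np.array([[179.0, 179.0, 179.0]]), np.array([1.0]), min_weight=0.0)
        corner = g.values[0, 0, 0]  # node (-180, -180, -180)
        assert np.isfinite(corner) and corner == pytest.approx(1.0)

    def test_cell_c_driver_attributed(self):
        rng = np.random.default_rng(7)
        _, _, phases = syn.make_oscillating_areas(60, 300, DT, snr=0, seed=8)
        ph3, rate = [], []
        for v in range(20):
            a, b, c = phases[3 * v], phases[3 * v + 1], phases[3 * v + 2]
            ph3.append(np.column_stack([a, b, c]))
            rate.append(-0.5 * np.cos(np.radians(c))
                        + rng.normal(0, 0.1, phases.shape[1]))
        grid, slices = pm.tangential_rate_3phase_map(
            np.concatenate(ph3), np.concatenate(rate))
        att = pm.variance_attribution(grid)
        assert np.argmax(att) == 2
        assert att[2] > 0.7
        # the (phiA, phiC) slice varies along phiC far more than the
        # (phiA, phiB) slice varies along phiB
        var_c = np.nanvar(np.nanmean(slices["phiA_phiC"], axis=0))
        var_b = np.nanvar(np.nanmean(slices["phiA_phiB"], axis=0))
        assert var_c > 5 * var_b
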