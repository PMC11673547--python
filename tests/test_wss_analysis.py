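"""Wall selection, truncation correction and WSS against the Couette solution."""

import numpy as np
import pytest

from arterysph.aneurysm_model import AneurysmState
from arterysph.kernels import KernelSet
from arterysph.scenarios_io import make_fixture
from arterysph.sph_core import build_neighbors, compute_density
from arterysph.wss_analysis import (
    correction_coefficient,
    orifice_timeseries,
    select_wall_particles,
    wss_at_particle,
    wss_colors,
    wss_frame,
)

H = 0.025


@pytest.fixture(scope="module")
def couette():
    system, geometry, config = make_fixture(
        "couette_channel", height=4 * H, lateral=12 * H, shear_rate=10.0
    )
    kernels = KernelSet(config.h)
    nb = build_neighbors(system.positions, kernels.h)
    compute_density(system, kernels, nb)
    return system, geometry, config, kernels, nb


class TestSelectWallParticles:
    def test_matches_distance_filter_oracle(self, couette):
        system, geometry, config, kernels, _ = couette
        delta = 0.5 * config.h
        ids, normals, wall_points = select_wall_particles(system, geometry, delta)
        # O(N) oracle: per-particle slab distances
        x = system.positions[:, 0]
        d = np.maximum(-x, x - geometry.height)
        expected = np.where(np.abs(d) <= delta)[0]
        assert np.array_equal(ids, expected)
        # projections actually lie on the wall
        d_proj, _ = geometry.signed_distance(wall_points)
        assert np.allclose(d_proj, 0.0, atol=1e-12)

    def test_deep_interior_excluded(self, couette):
        system, geometry, config, _, _ = couette
        ids, _, _ = select_wall_particles(system, geometry, 0.5 * config.h)
        x = system.positions[ids, 0]
        assert np.all((x <= 0.5 * config.h) | (x >= geometry.height - 0.5 * config.h))


class TestCorrectionCoefficient:
    def test_identity_and_ratio(self):
        assert correction_coefficient(40, 40.0) == pytest.approx(1.0)
        assert correction_coefficient(32, 40.0) == pytest.approx(1.25)

    def test_halving_count_doubles_correction(self):
        assert correction_coefficient(16, 40.0) == 2 * correction_coefficient(32, 40.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            correction_coefficient(0, 40.0)


class TestWSSFrame:
    def test_zero_velocity_gives_zero_wss(self, couette):
        system, geometry, config, kernels, nb = couette
        still = system.copy()
        still.velocities[:] = 0.0
        fld = wss_frame(still, geometry, kernels, config, neighbors=nb)
        assert len(fld.wall_particle_ids) > 0
        assert np.all(fld.wss_values == 0.0)
        assert np.all(fld.c_xi > 0.0)

    def test_wall_normal_flow_gives_zero_wss(self, couette):
        system, geometry, config, kernels, nb = couette
        normal_flow = system.copy()
        normal_flow.velocities[:] = (0.25, 0.0, 0.0)  # purely wall-normal
        fld = wss_frame(normal_flow, geometry, kernels, config, neighbors=nb)
        assert np.all(np.abs(fld.wss_values) < 1e-10)

    def test_couette_matches_analytic_shear(self, couette):
        # WSS = mu * gamma for v_t = gamma * x_n, within 15% after the
        # kernel-truncation correction (central wall particles)
        system, geometry, config, kernels, nb = couette
        fld = wss_frame(system, geometry, kernels, config, neighbors=nb)
        pos = fld.wall_positions
        margin = 0.5 * 12 * H - 1.5 * H
        central = (
            (np.abs(pos[:, 1]) < margin)
            & (np.abs(pos[:, 2]) < margin)
            & (pos[:, 0] < 0.5 * config.h)
        )
        got = fld.wss_values[central].mean()
        assert got == pytest.approx(config.mu * 10.0, rel=0.15)

    def test_wss_linear_in_viscosity(self, couette):
        system, geometry, config, kernels, nb = couette
        f1 = wss_frame(system, geometry, kernels, config, neighbors=nb, mu_phys=4.0)
        f2 = wss_frame(system, geometry, kernels, config, neighbors=nb, mu_phys=8.0)
        assert np.allclose(f2.wss_values, 2.0 * f1.wss_values, rtol=1e-12)

    def test_mean_c_xi_is_arithmetic_mean(self, couette):
        system, geometry, config, kernels, nb = couette
        fld = wss_frame(system, geometry, kernels, config, neighbors=nb)
        assert fld.mean_c_xi == pytest.approx(float(np.mean(fld.n_bar / fld.neighbor_counts)))
        assert fld.n_bar == pytest.approx(float(nb.counts.mean()))

    def test_interior_lattice_yields_empty_field(self):
        system, geometry, config = make_fixture("couette_channel", height=8 * H, lateral=4 * H)
        kernels = KernelSet(config.h)
        # keep only particles far from both walls
        keep = (system.positions[:, 0] > config.h) & (
            system.positions[:, 0] < geometry.height - config.h
        )
        from arterysph.sph_core import ParticleSystem

        inner = ParticleSystem(system.positions[keep], mass=config.particle_mass)
        nb = build_neighbors(inner.positions, kernels.h)
        compute_density(inner, kernels, nb)
        fld = wss_frame(inner, geometry, kernels, config, neighbors=nb)
        assert len(fld.wall_particle_ids) == 0

    def test_single_particle_form_matches_vectorised(self, couette):
        system, geometry, config, kernels, nb = couette
        fld = wss_frame(system, geometry, kernels, config, neighbors=nb)
        ids, normals, wall_points = select_wall_particles(system, geometry, fld.delta)
        for slot in (0, len(fld.wall_particle_ids) // 2):
            i = fld.wall_particle_ids[slot]
            ref = wss_at_particle(
                int(i), system, kernels, normals[slot], wall_points[slot],
                float(fld.c_xi[slot]), nb, mu=config.mu,
            )
            assert fld.wss_values[slot] == pytest.approx(ref, rel=1e-10)


class TestOrificeSeries:
    def _fields(self, velocity_scale):
        system, geometry, config = make_fixture("tube_flow", radius=0.05, length=0.2)
        kernels = KernelSet(config.h)
        nb = build_neighbors(system.positions, kernels.h)
        compute_density(system, kernels, nb)
        system.velocities *= velocity_scale
        fields = [
            wss_frame(system, geometry, kernels, config, frame=f, neighbors=nb)
            for f in range(5)
        ]
        state = AneurysmState(
            site=np.array([0.05, 0.1, 0.0]), outward_normal=np.array([1.0, 0.0, 0.0]),
            R=0.015,
        )
        return fields, state

    def test_zero_flow_series_is_zero(self):
        fields, state = self._fields(0.0)
        series = orifice_timeseries(fields, state, orifice_radius=1.5 * 0.015)
        assert len(series) == 5
        assert series["n_orifice"].min() > 0
        assert np.all(series["mean_wss"] == 0.0)

    def test_window_selects_frames(self):
        fields, state = self._fields(1.0)
        series = orifice_timeseries(fields, state, window=(1, 4))
        assert list(series["frame"]) == [1, 2, 3]

    def test_empty_orifice_flagged_missing(self):
        fields, state = self._fields(1.0)
        state.site = np.array([10.0, 10.0, 10.0])
        series = orifice_timeseries(fields, state, orifice_radius=0.01)
        assert series["mean_wss"].isna().all()
        assert (series["n_orifice"] == 0).all()


def test_color_grading_preserves_rank_order(rng):
    vals = rng.random(50) * 12.0
    colors = wss_colors(vals)
    # darker (lower luminance) = larger WSS, monotone in rank
    lum = colors @ np.array([0.299, 0.587, 0.114])
    order = np.argsort(vals)
    assert np.all(np.diff(lum[order]) <= 1e-12)
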