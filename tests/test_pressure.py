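"""Pressure reconstruction against analytic oracles."""
import warnings

import numpy as np
import pytest

from shpower.errors import DataError, SolverError
from shpower.grids import PhysicalParams, PressureFieldSeries, VelocityFieldSeries
from shpower.kinematics import GapeTrace
from shpower.pressure import (
    material_acceleration,
    pressure_at_mouth,
    pressure_multipath,
    pressure_poisson,
    reference_cells,
    reference_offset,
)
from shpower.synthetic import SinkFlowSpec, make_sink_flow

from conftest import pooled_rms_error


def stagnation_series(n=48, L=0.02, strain=50.0, nt=4):
    x = np.linspace(-L / 2, L / 2, n)
    X, Y = np.meshgrid(x, x)
    u = np.repeat((strain * X)[None], nt, axis=0)
    v = np.repeat((-strain * Y)[None], nt, axis=0)
    ser = VelocityFieldSeries(u=u, v=v, mask=np.zeros((n, n), bool), x=x, y=x, dt=1e-3)
    return ser, X, Y


class TestMaterialAcceleration:
    def test_uniform_steady_flow_has_zero_acceleration(self):
        n = 24
        x = np.linspace(0, 1, n)
        u = np.full((3, n, n), 0.7)
        v = np.full((3, n, n), -0.2)
        ser = VelocityFieldSeries(u=u, v=v, mask=np.zeros((n, n), bool),
                                  x=x, y=x, dt=0.1)
        ax, ay = material_acceleration(ser)
        assert np.nanmax(np.abs(ax)) < 1e-12
        assert np.nanmax(np.abs(ay)) < 1e-12

    def test_stagnation_advection_closed_form(self):
        ser, X, Y = stagnation_series()
        ax, ay = material_acceleration(ser)
        # (u . grad) u = (s^2 x, s^2 y), exact for a linear field
        assert np.allclose(ax[1], 50.0**2 * X, rtol=1e-9)
        assert np.allclose(ay[1], 50.0**2 * Y, rtol=1e-9)

    def test_sink_flow_acceleration_matches_model(self, sink_series):
        """Du/Dt from frame differencing matches the analytic
        dQ/dt/(2 pi r^2) - Q^2/(2 pi^2 r^5) of the ramping sink."""
        vel, _ = sink_series
        ax, ay = material_acceleration(vel)
        t = vel.t
        Q = np.asarray(vel.meta["flow_rate"])
        Qdot = np.gradient(Q, t)
        X, Y = np.meshgrid(vel.x, vel.y)
        R = np.hypot(X, Y)
        k = len(t) // 2
        a_r = -(Qdot[k] / (2 * np.pi * R**2)) - Q[k] ** 2 / (2 * np.pi**2 * R**5)
        exp_x, exp_y = a_r * X / R, a_r * Y / R
        interior = ~vel.mask & (R > 2.5e-3) & (R < 4.5e-3)
        scale = np.nanmax(np.hypot(exp_x[interior], exp_y[interior]))
        err = np.nanmax(
            np.hypot(ax[k][interior] - exp_x[interior], ay[k][interior] - exp_y[interior])
        )
        assert err / scale < 0.03

    def test_too_few_frames_rejected(self):
        n = 16
        x = np.linspace(0, 1, n)
        ser = VelocityFieldSeries(u=np.zeros((1, n, n)), v=np.zeros((1, n, n)),
                                  mask=np.zeros((n, n), bool), x=x, y=x, dt=0.1)
        with pytest.raises(DataError, match="2 frames"):
            material_acceleration(ser)

    def test_fully_masked_grid_rejected(self):
        n = 16
        x = np.linspace(0, 1, n)
        ser = VelocityFieldSeries(u=np.zeros((3, n, n)), v=np.zeros((3, n, n)),
                                  mask=np.ones((n, n), bool), x=x, y=x, dt=0.1)
        with pytest.raises(DataError, match="masked"):
            material_acceleration(ser)


@pytest.mark.parametrize("solver", [pressure_poisson, pressure_multipath])
class TestSolvers:
    def test_zero_velocity_gives_zero_pressure(self, solver):
        n = 24
        x = np.linspace(0, 0.01, n)
        ser = VelocityFieldSeries(u=np.zeros((3, n, n)), v=np.zeros((3, n, n)),
                                  mask=np.zeros((n, n), bool), x=x, y=x, dt=1e-3)
        pfs = solver(ser, PhysicalParams(geometry="planar"))
        assert np.nanmax(np.abs(pfs.p)) < 1e-12

    def test_stagnation_closed_form(self, solver):
        ser, X, Y = stagnation_series()
        rho = 1000.0
        pfs = solver(ser, PhysicalParams(density=rho, geometry="planar"))
        ptrue = np.repeat((-0.5 * rho * 50.0**2 * (X**2 + Y**2))[None], 4, axis=0)
        assert pooled_rms_error(pfs, ptrue, pfs.reference_cells) < 0.01

    def test_sink_flow_within_tolerance(self, solver, sink_series_short):
        vel, pex = sink_series_short
        pfs = solver(vel, PhysicalParams(geometry="axisymmetric"))
        assert pooled_rms_error(pfs, pex.p, pfs.reference_cells) < 0.05


def test_poisson_planar_and_axisymmetric_both_accurate(sink_series):
    """On the symmetry plane the in-plane momentum balance is exact, so the
    planar weighting is also consistent; both geometries must recover the
    axisymmetric sink pressure."""
    vel, pex = sink_series
    for geometry in ("planar", "axisymmetric"):
        pfs = pressure_poisson(vel, PhysicalParams(geometry=geometry))
        assert pooled_rms_error(pfs, pex.p, pfs.reference_cells) < 0.05


def test_solver_cross_validation(sink_series_short):
    """Poisson and multi-path agree within 10% RMS of peak |p|."""
    vel, _ = sink_series_short
    ppo = pressure_poisson(vel, PhysicalParams())
    pmp = pressure_multipath(vel, PhysicalParams(), n_paths=8, seed=0)
    assert pooled_rms_error(ppo, pmp.p, ppo.reference_cells) < 0.10


def test_gauge_invariance_of_referenced_comparison(sink_series_short):
    """Adding a spatially uniform constant to the analytic reference field
    does not change re-gauged pressure differences."""
    vel, pex = sink_series_short
    pfs = pressure_poisson(vel, PhysicalParams())
    ref = pfs.reference_cells
    k = pfs.nt // 2

    def regauged_diff(p_exact):
        return (pfs.p[k] - reference_offset(pfs.p[k], ref)) - (
            p_exact - reference_offset(p_exact, ref)
        )

    d0 = regauged_diff(pex.p[k])
    d1 = regauged_diff(pex.p[k] + 1234.5)
    assert np.nanmax(np.abs(d1 - d0)) < 1e-9 * np.nanmax(np.abs(pex.p))


def test_noise_robustness_regression(clean_preset, sink_series, axi_params):
    """5%-of-peak velocity noise raises the RMS error by less than 3x the
    noise-free error (with the shared temporal smoother engaged)."""
    vel, pex = sink_series
    peak_speed = np.nanmax(vel.speed())
    noisy_spec = SinkFlowSpec(
        flow_rate_waveform=clean_preset.flow_rate_waveform,
        noise_sd=0.05 * peak_speed,
    )
    noisy, _ = make_sink_flow(noisy_spec, seed=7)
    e_clean = pooled_rms_error(
        pressure_poisson(vel, axi_params, smooth_window=9), pex.p,
        reference_cells(vel.mask, vel.x, vel.y, (0.0, 0.0)),
    )
    e_noisy = pooled_rms_error(
        pressure_poisson(noisy, axi_params, smooth_window=9), pex.p,
        reference_cells(noisy.mask, noisy.x, noisy.y, (0.0, 0.0)),
    )
    assert e_noisy < 3 * e_clean


def test_unreachable_pocket_flagged_missing():
    """Cells walled off from the reference boundary come back NaN, not 0."""
    n = 32
    x = np.linspace(0, 0.01, n)
    mask = np.zeros((n, n), bool)
    mask[10:21, 10] = mask[10:21, 20] = True
    mask[10, 10:21] = mask[20, 10:21] = True   # closed box wall
    u = np.zeros((3, n, n))
    ser = VelocityFieldSeries(u=u, v=u.copy(), mask=mask, x=x, y=x, dt=1e-3)
    pfs = pressure_multipath(ser, PhysicalParams(geometry="planar"), n_paths=2, seed=0)
    assert np.isnan(pfs.p[1, 15, 15])
    assert np.isfinite(pfs.p[1, 2, 2])


def test_no_boundary_reference_raises():
    mask = np.ones((8, 8), bool)
    mask[3:5, 3:5] = False
    with pytest.raises(SolverError, match="reference"):
        reference_cells(mask, np.linspace(0, 1, 8), np.linspace(0, 1, 8))


class TestMouthPressure:
    def _gape(self, nt, d, center=(1.5e-3, 0.0)):
        return GapeTrace(
            diameter=np.full(nt, d),
            center=np.tile(center, (nt, 1)),
            axis=np.array([-1.0, 0.0]),
            dt=1e-3,
        )

    def test_zero_pressure_gives_zero(self):
        n = 24
        x = np.linspace(-0.005, 0.005, n)
        pfs = PressureFieldSeries(p=np.zeros((3, n, n)), mask=np.zeros((n, n), bool),
                                  x=x, y=x, dt=1e-3)
        pm = pressure_at_mouth(pfs, self._gape(3, 1e-3))
        assert np.allclose(pm, 0.0)

    def test_steady_sink_mouth_pressure_closed_form(self):
        """Sampled just outside the aperture with a small gape, the mouth
        pressure approaches -rho/2 (Q / 2 pi a^2)^2."""
        Q0 = 5e-6
        spec = SinkFlowSpec(flow_rate_waveform=lambda t: np.full_like(t, Q0), n_frames=4)
        _, pres = make_sink_flow(spec, seed=0)
        a = spec.mouth_radius
        gape = self._gape(4, 0.3e-3, center=(1.1 * a, 0.0))
        pm = pressure_at_mouth(pres, gape)
        expect = -0.5 * spec.density * (Q0 / (2 * np.pi * (1.1 * a) ** 2)) ** 2
        assert pm[2] == pytest.approx(expect, rel=0.05)

    def test_mouth_pressure_peaks_before_peak_gape(self, strike_world):
        """|p_mouth| peaks before the gape does, as in the published event
        sequence."""
        vel, pex, trace, gape = strike_world
        pm = pressure_at_mouth(pex, gape)
        t = gape.t
        assert t[np.nanargmax(np.abs(pm))] < t[np.argmax(gape.diameter)]

    def test_masked_mouth_centre_warns_and_yields_nan(self):
        n = 24
        x = np.linspace(-0.005, 0.005, n)
        mask = np.zeros((n, n), bool)
        mask[:, :] = True
        mask[:2, :2] = False
        pfs = PressureFieldSeries(p=np.zeros((2, n, n)), mask=mask, x=x, y=x, dt=1e-3)
        with pytest.warns(UserWarning, match="masked"):
            pm = pressure_at_mouth(pfs, self._gape(2, 1e-3, center=(0.0, 0.0)))
        assert np.isnan(pm).all()
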