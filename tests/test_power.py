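"""Suction-power integral, mass-specific power and event timing."""
import numpy as np
import pytest

from shpower.errors import DataError
from shpower.grids import VelocityFieldSeries
from shpower.kinematics import GapeTrace
from shpower.power import (
    MUSCLE_POWER_CEILING,
    MusclesMeta,
    event_timings,
    flow_rate,
    inflow_speed,
    mass_specific_power,
    net_suction_power,
)
from shpower.pressure import pressure_at_mouth
from shpower.synthetic import SinkFlowSpec, make_sink_flow, sink_energy_budget


def _gape(nt, d, dt=1e-3, center=(1.5e-3, 0.0), axis=(-1.0, 0.0)):
    return GapeTrace(diameter=np.full(nt, float(d)),
                     center=np.tile(center, (nt, 1)),
                     axis=np.asarray(axis, float), dt=dt)


class TestInflowSpeed:
    def test_zero_velocity_gives_zero(self):
        n = 24
        x = np.linspace(-0.005, 0.005, n)
        ser = VelocityFieldSeries(u=np.zeros((3, n, n)), v=np.zeros((3, n, n)),
                                  mask=np.zeros((n, n), bool), x=x, y=x, dt=1e-3)
        assert np.allclose(inflow_speed(ser, _gape(3, 1e-3)), 0.0)

    def test_steady_sink_closed_form(self):
        """A narrow aperture just outside the sink samples Q/(2 pi r^2)."""
        Q0 = 5e-6
        spec = SinkFlowSpec(flow_rate_waveform=lambda t: np.full_like(t, Q0), n_frames=4)
        vel, _ = make_sink_flow(spec, seed=0)
        r = 1.1 * spec.mouth_radius
        u_m = inflow_speed(vel, _gape(4, 0.3e-3, center=(r, 0.0)))
        assert u_m[2] == pytest.approx(Q0 / (2 * np.pi * r**2), rel=0.05)
        assert u_m[2] > 0  # positive = into the mouth

    def test_axis_flip_negates_projection(self):
        """Flipping the stored mouth axis flips u_m; carrying the flipped
        sign through Q leaves the physical power invariant."""
        Q0 = 5e-6
        spec = SinkFlowSpec(flow_rate_waveform=lambda t: np.full_like(t, Q0), n_frames=4)
        vel, pres = make_sink_flow(spec, seed=0)
        g_in = _gape(4, 0.5e-3, center=(1.65e-3, 0.0), axis=(-1.0, 0.0))
        g_out = _gape(4, 0.5e-3, center=(1.65e-3, 0.0), axis=(1.0, 0.0))
        u_in = inflow_speed(vel, g_in)
        u_out = inflow_speed(vel, g_out)
        assert np.allclose(u_in, -u_out, rtol=1e-12)
        pm = pressure_at_mouth(pres, g_in)
        P_in = net_suction_power(pm, flow_rate(g_in, u_in), dt=1e-3)
        P_out = net_suction_power(pm, -flow_rate(g_out, u_out), dt=1e-3)
        assert np.allclose(P_in.P_net, P_out.P_net)


class TestFlowRate:
    def test_zero_gape_gives_zero_rate(self):
        g = _gape(5, 0.0)
        assert np.allclose(flow_rate(g, np.ones(5)), 0.0)

    def test_unit_area_identity(self):
        g = _gape(3, 2.0 / np.sqrt(np.pi))
        assert flow_rate(g, np.ones(3))[0] == pytest.approx(1.0)

    def test_roundtrip_against_generator_product(self, clean_preset, strike_world):
        _, _, _, gape = strike_world
        t = gape.t
        u = clean_preset.flow_speed_waveform(t)
        Q = flow_rate(gape, u)
        expect = u * np.pi * clean_preset.gape_waveform(t) ** 2 / 4
        assert np.allclose(Q, expect, rtol=1e-9)


class TestNetSuctionPower:
    def test_zero_pressure_gives_zero_power_and_work(self):
        tr = net_suction_power(np.zeros(10), np.full(10, 1e-6), dt=1e-3)
        assert np.allclose(tr.P_net, 0.0)
        assert tr.work_J == 0.0

    def test_constant_product_closed_form(self):
        # -(-100 Pa)(1e-5 m^3/s) = 1 mW over 10 ms -> 10 uJ
        nt = 101
        tr = net_suction_power(np.full(nt, -100.0), np.full(nt, 1e-5), dt=1e-4)
        assert np.allclose(tr.P_net, 1e-3)
        assert tr.work_J == pytest.approx(1e-5, rel=1e-9)

    def test_misaligned_series_rejected(self):
        with pytest.raises(DataError, match="misaligned"):
            net_suction_power(np.zeros(5), np.zeros(6), dt=1e-3)

    def test_work_nondecreasing_during_suction(self, strike_world):
        vel, pex, _, gape = strike_world
        pm = pressure_at_mouth(pex, gape)
        u = inflow_speed(vel, gape)
        tr = net_suction_power(pm, flow_rate(gape, u), dt=vel.dt)
        W = np.cumsum(np.nan_to_num(tr.P_net)) * vel.dt
        sucking = (pm < 0) & (tr.Q > 0)
        assert np.all(np.diff(W)[sucking[1:]] >= 0)

    def test_energy_budget_against_sink_model(self, clean_preset):
        """Integrated p*Q work matches the closed-form energy budget of the
        sink (field kinetic energy plus ingested kinetic-energy flux)."""
        dt = 0.125e-3
        t = np.arange(0.0, clean_preset.duration, dt)
        Q = clean_preset.flow_rate_waveform(t)
        tf = np.linspace(t[0], t[-1], 20000)
        Qdot = np.interp(t, tf, np.gradient(clean_preset.flow_rate_waveform(tf), tf))
        a = clean_preset.mouth_radius
        from shpower.synthetic import SEAWATER_DENSITY, sink_pressure_exact

        p_a = sink_pressure_exact(a, Q, Qdot, SEAWATER_DENSITY)
        tr = net_suction_power(p_a, Q, dt=dt)
        expect = sink_energy_budget(t, Q, a, SEAWATER_DENSITY)
        assert tr.work_J == pytest.approx(expect, rel=0.05)


class TestMassSpecificPower:
    def test_zero_power_gives_zero(self):
        tr = net_suction_power(np.zeros(5), np.zeros(5), dt=1e-3)
        meta = MusclesMeta("sp", "i1", muscle_mass_kg=1e-3)
        assert mass_specific_power(tr, meta).value_W_per_kg == 0.0

    def test_ratio_to_muscle_ceiling(self):
        tr = net_suction_power(np.full(5, -100.0), np.full(5, 1e-5), dt=1e-3)
        msp = mass_specific_power(tr, MusclesMeta("sp", "i1", muscle_mass_kg=1e-6))
        assert msp.value_W_per_kg == pytest.approx(1000.0)
        assert msp.ratio_to_muscle_ceiling == pytest.approx(1000.0 / MUSCLE_POWER_CEILING)

    def test_missing_mass_rejected(self):
        with pytest.raises(DataError, match="mass"):
            MusclesMeta("sp", "i1", muscle_mass_kg=np.nan)


class TestEventTimings:
    def test_monotone_gape_is_censored(self):
        nt = 40
        g = GapeTrace(diameter=np.linspace(0, 3e-3, nt),
                      center=np.zeros((nt, 2)), axis=np.array([-1.0, 0.0]), dt=1e-3)
        tr = net_suction_power(np.zeros(nt), np.zeros(nt), dt=1e-3)
        ev = event_timings(g, np.zeros(nt), tr, np.zeros(nt))
        assert ev.censored["gape"]

    def test_seahorse_timings_recovered_noise_free(self, clean_preset, strike_world):
        """Times-to-peak from strike onset recover the configured preset
        values (peak gape 2.5 ms, head-speed peak after gape) within one
        frame."""
        vel, pex, trace, gape = strike_world
        u_m = inflow_speed(vel, gape)
        pm = pressure_at_mouth(pex, gape)
        tr = net_suction_power(pm, flow_rate(gape, u_m), dt=vel.dt, u_m=u_m)
        head = trace.segment_angle("joint_neurocranium", "head_tip")
        ev = event_timings(gape, u_m, tr, head)
        assert ev.t_peak_gape_s == pytest.approx(2.5e-3, abs=vel.dt)
        assert ev.t_peak_head_speed_s == pytest.approx(
            clean_preset.time_to_peak_head_speed, abs=vel.dt
        )
        assert ev.ordering_ok
        assert ev.t_peak_flow_s < ev.t_peak_power_s < ev.t_peak_gape_s
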