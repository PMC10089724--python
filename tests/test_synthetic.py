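"""Generator self-consistency: closed forms, timings, determinism."""
import numpy as np
import pytest

from shpower.errors import ConfigurationError
from shpower.synthetic import (
    SinkFlowSpec,
    TendonTestSpec,
    generalist_preset,
    make_sink_flow,
    make_strike,
    make_tendon_test,
    seahorse_preset,
    sink_pressure_exact,
)


class TestSinkFlow:
    def test_null_flow_gives_null_fields(self):
        spec = SinkFlowSpec(flow_rate_waveform=lambda t: np.zeros_like(t), n_frames=4)
        vel, pres = make_sink_flow(spec, seed=0)
        assert np.nanmax(np.abs(vel.u)) == 0
        assert np.nanmax(np.abs(vel.v)) == 0
        assert np.nanmax(np.abs(pres.p)) == 0

    def test_steady_flow_matches_bernoulli_closed_form(self):
        Q0 = 5e-6
        spec = SinkFlowSpec(flow_rate_waveform=lambda t: np.full_like(t, Q0), n_frames=4)
        vel, pres = make_sink_flow(spec, seed=0)
        X, Y = np.meshgrid(vel.x, vel.y)
        R = np.hypot(X, Y)
        expect = -spec.density * 0.5 * (Q0 / (2 * np.pi * R**2)) ** 2
        fin = ~vel.mask
        assert np.allclose(pres.p[2][fin], expect[fin], rtol=1e-12)
        # speed magnitude Q/(2 pi r^2), directed at the sink
        speed = np.hypot(vel.u[2], vel.v[2])
        assert np.allclose(speed[fin], Q0 / (2 * np.pi * R[fin] ** 2), rtol=1e-12)

    def test_emitted_mouth_speed_peaks_at_configured_flow_time(self, clean_preset):
        """The aperture inflow-speed series must peak 2.1 ms after onset,
        the published seahorse timing the preset is anchored to."""
        spec = SinkFlowSpec(flow_rate_waveform=clean_preset.flow_rate_waveform)
        vel, _ = make_sink_flow(spec, seed=0)
        speed = np.asarray(vel.meta["mouth_speed"])
        t_peak = vel.t[np.argmax(speed)]
        gape = clean_preset.gape_waveform(vel.t)
        onset = vel.t[np.argmax(gape > 0.2 * gape.max())]
        assert t_peak - onset == pytest.approx(2.1e-3, abs=vel.dt)

    def test_pressure_satisfies_momentum_equation_on_interior(self, sink_series, axi_params):
        """grad p must equal -rho Du/Dt to discretization order on interior
        cells (the in-plane momentum balance of the axisymmetric model)."""
        from shpower.pressure import _masked_gradient, material_acceleration

        vel, pres = sink_series
        ax, ay = material_acceleration(vel)
        k = int(np.argmax([np.nanmax(np.abs(f)) for f in pres.p]))
        px = _masked_gradient(pres.p[k], vel.mask, vel.dx, axis=1)
        py = _masked_gradient(pres.p[k], vel.mask, vel.dy, axis=0)
        rx = px + axi_params.density * ax[k]
        ry = py + axi_params.density * ay[k]
        scale = np.nanmax(np.hypot(px, py))
        # one-sided stencils beside the mask are first-order; compare interior
        X, Y = np.meshgrid(vel.x, vel.y)
        interior = ~vel.mask & (np.hypot(X, Y) > 2.0e-3)
        interior[[0, -1], :] = False
        interior[:, [0, -1]] = False
        err = np.nanmax(np.hypot(rx[interior], ry[interior])) / scale
        assert err < 0.05

    def test_grid_too_small_raises(self):
        spec = SinkFlowSpec(flow_rate_waveform=lambda t: np.zeros_like(t),
                            mouth_radius=3e-3, grid_extent=12e-3)
        with pytest.raises(ConfigurationError, match="3 mouth radii"):
            make_sink_flow(spec, seed=0)


class TestStrike:
    def test_rigid_trace_closes_exactly(self):
        pre = seahorse_preset(link4_compression_fraction=0.0, jitter_frac=0.0)
        trace, _ = make_strike(pre, seed=0)
        geom = pre.fourbar_geometry
        for a, b, L in (("joint_neurocranium", "joint_hyoid", geom.L2),
                        ("joint_hyoid", "hyoid_tip", geom.L3),
                        ("hyoid_tip", "cleithrum", geom.L4)):
            assert np.allclose(trace.segment_length(a, b), L, rtol=1e-12)

    def test_compressed_trace_shortens_only_link4(self):
        pre = seahorse_preset(link4_compression_fraction=0.3, jitter_frac=0.0)
        trace, _ = make_strike(pre, seed=0)
        L4 = trace.segment_length("hyoid_tip", "cleithrum")
        assert L4.min() == pytest.approx(0.7 * pre.fourbar_geometry.L4, rel=1e-9)
        L3 = trace.segment_length("joint_hyoid", "hyoid_tip")
        assert np.allclose(L3, pre.fourbar_geometry.L3, rtol=1e-12)

    def test_event_ordering_of_waveforms(self, clean_preset):
        """Peak flow before peak gape before peak head-rotation speed, the
        published sequence of strike events."""
        t = np.arange(0.0, clean_preset.duration, clean_preset.frame_interval)
        tp = lambda s: t[np.argmax(s)]
        u = clean_preset.flow_speed_waveform(t)
        d = clean_preset.gape_waveform(t)
        h = np.gradient(clean_preset.head_angle_waveform(t), t)
        assert tp(u) < tp(d) < tp(np.abs(h))

    def test_same_seed_reproduces_trace(self):
        pre = seahorse_preset()
        t1, g1 = make_strike(pre, seed=11)
        t2, g2 = make_strike(pre, seed=11)
        for name in t1.points:
            assert np.array_equal(t1.points[name], t2.points[name])
        assert np.array_equal(g1.diameter, g2.diameter)

    def test_generalist_preset_is_slow_and_wide(self):
        pre = generalist_preset()
        assert pre.time_to_peak_flow == pytest.approx(33e-3)
        assert pre.peak_gape_diameter > seahorse_preset().peak_gape_diameter

    def test_invalid_compression_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            make_strike(seahorse_preset(link4_compression_fraction=1.2), seed=0)


class TestTendonTest:
    def test_linear_spring_limit(self):
        spec = TendonTestSpec(toe_exponent=0.0, noise_sd=0.0, stiffness_scale=100.0)
        s = make_tendon_test(spec)
        assert np.allclose(s[:, 1], 100.0 * s[:, 0], atol=1e-12)

    def test_energy_matches_numerical_integral_of_force(self):
        spec = TendonTestSpec(noise_sd=0.0)
        x = np.linspace(0, spec.max_extension, 20001)
        numeric = np.trapezoid(spec.force(x), x)
        assert spec.energy(spec.max_extension) == pytest.approx(numeric, rel=1e-6)

    def test_fixed_seed_bitwise_reproducible(self):
        spec = TendonTestSpec(noise_sd=0.5, seed=42)
        assert np.array_equal(make_tendon_test(spec), make_tendon_test(spec))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            make_tendon_test(TendonTestSpec(n_samples=3))


def test_sink_pressure_exact_reduces_to_steady_form():
    p = sink_pressure_exact(0.002, Q=1e-5, Qdot=0.0, density=1000.0)
    assert p == pytest.approx(-0.5 * 1000.0 * (1e-5 / (2 * np.pi * 0.002**2)) ** 2)
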