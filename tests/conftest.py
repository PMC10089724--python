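"""Shared fixtures: one synthetic strike world reused across test modules."""
import logging

import numpy as np
import pytest

from shpower.grids import PhysicalParams
from shpower.synthetic import (
    SinkFlowSpec,
    TendonTestSpec,
    make_sink_flow,
    make_strike_flow,
    make_tendon_test,
    seahorse_preset,
)

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def clean_preset():
    """Seahorse-like preset without landmark jitter."""
    return seahorse_preset(jitter_frac=0.0)


@pytest.fixture(scope="session")
def sink_series(clean_preset):
    """Noise-free 64x64 sink-flow sequence with its exact pressure."""
    spec = SinkFlowSpec(flow_rate_waveform=clean_preset.flow_rate_waveform)
    return make_sink_flow(spec, seed=0)


@pytest.fixture(scope="session")
def sink_series_short(clean_preset):
    """Coarser-in-time sink sequence for the slower multipath solver."""
    spec = SinkFlowSpec(
        flow_rate_waveform=clean_preset.flow_rate_waveform,
        frame_interval=0.375e-3, n_frames=24,
    )
    return make_sink_flow(spec, seed=0)


@pytest.fixture(scope="session")
def strike_world(clean_preset):
    """Full noise-free synthetic strike: fields, exact pressure, kinematics."""
    vel, pex, trace, gape = make_strike_flow(clean_preset, seed=0)
    return vel, pex, trace, gape


@pytest.fixture(scope="session")
def axi_params():
    return PhysicalParams(geometry="axisymmetric", axis_point=(0.0, 0.0),
                          axis_dir=(1.0, 0.0))


@pytest.fixture(scope="session")
def tendon_clean_samples():
    return make_tendon_test(TendonTestSpec(noise_sd=0.0))


def pooled_rms_error(pfs, p_exact, ref):
    """Sequence-pooled RMS difference (after consistent re-gauging) divided
    by the peak |p| of the exact field."""
    from shpower.pressure import reference_offset

    err2, n = 0.0, 0
    peak = np.nanmax(np.abs(p_exact))
    for k in range(pfs.nt):
        d = (pfs.p[k] - reference_offset(pfs.p[k], ref)) - (
            p_exact[k] - reference_offset(p_exact[k], ref)
        )
        fin = np.isfinite(d)
        err2 += float(np.nansum(d[fin] ** 2))
        n += int(fin.sum())
    return float(np.sqrt(err2 / n) / peak)
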