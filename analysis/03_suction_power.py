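"""Suction-power chain on the noise-free seahorse strike.

Checks the two quantitative anchors of the power stage: the correlation
between reconstructed and analytic mouth pressure across frames (the
measured-vs-calculated pressure benchmark), and the closure of the energy
budget — the time integral of p*Q against the sink model's closed-form
work (field kinetic energy + ingested kinetic-energy flux).
"""
import json
from pathlib import Path

import numpy as np

from shpower.grids import PhysicalParams
from shpower.power import flow_rate, inflow_speed, net_suction_power
from shpower.pressure import pressure_at_mouth, pressure_poisson
from shpower.synthetic import (
    SEAWATER_DENSITY,
    make_strike_flow,
    seahorse_preset,
    sink_energy_budget,
    sink_pressure_exact,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    pre = seahorse_preset(jitter_frac=0.0)
    vel, pex, trace, gape = make_strike_flow(pre, seed=0)
    params = PhysicalParams(geometry="axisymmetric", axis_point=(0, 0),
                            axis_dir=(-1, 0))
    pfs = pressure_poisson(vel, params)
    rec = pressure_at_mouth(pfs, gape)
    true = pressure_at_mouth(pex, gape)
    fin = np.isfinite(rec) & np.isfinite(true)
    r2 = float(np.corrcoef(rec[fin], true[fin])[0, 1] ** 2)

    u_m = inflow_speed(vel, gape)
    ptrace = net_suction_power(rec, flow_rate(gape, u_m), dt=vel.dt, u_m=u_m)

    t = vel.t
    Q = np.asarray(vel.meta["flow_rate"])
    tf = np.linspace(t[0], t[-1], 20000)
    Qdot = np.interp(t, tf, np.gradient(pre.flow_rate_waveform(tf), tf))
    a = pre.mouth_radius
    p_a = sink_pressure_exact(a, Q, Qdot, SEAWATER_DENSITY)
    work_model = net_suction_power(p_a, Q, dt=vel.dt).work_J
    work_exact = sink_energy_budget(t, Q, a, SEAWATER_DENSITY)

    out = {
        "mouth_pressure_r2": r2,
        "peak_mouth_pressure_Pa": float(np.nanmin(rec)),
        "peak_net_power_W": ptrace.peak_power_W,
        "pipeline_work_J": ptrace.work_J,
        "model_work_J": work_model,
        "analytic_energy_budget_J": work_exact,
        "energy_budget_error_pct": 100 * abs(work_model - work_exact) / work_exact,
    }
    (OUT / "suction_power.json").write_text(json.dumps(out, indent=1))
    print(f"mouth-pressure R^2 (reconstructed vs analytic): {r2:.4f}")
    print(f"peak mouth suction pressure: {out['peak_mouth_pressure_Pa']:.0f} Pa")
    print(f"p*Q work vs analytic energy budget: {work_model:.3e} vs {work_exact:.3e} J "
          f"({out['energy_budget_error_pct']:.2f}% apart)")
    print("wrote results/suction_power.json")


if __name__ == "__main__":
    main()
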