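"""End-to-end strike pipeline: fields + landmarks -> StrikeSummary.

One configured run chains every stage: pressure reconstruction from the
velocity sequence, mouth-pressure and inflow sampling, the p*Q power
integral, mass-specific power, event timings, four-bar rigidity and bar
compression, and tendon recoil power.  Results are written as a tidy
one-row-per-strike CSV plus a JSON report carrying full provenance
(configuration hash, package version, input description, seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ShpowerError
from .fourbar import bar_compression, rigidity_test
from .grids import PhysicalParams, VelocityFieldSeries
from .kinematics import GapeTrace, KinematicTrace
from .power import (
    MusclesMeta,
    event_timings,
    flow_rate,
    inflow_speed,
    mass_specific_power,
    net_suction_power,
)
from .pressure import pressure_at_mouth, pressure_multipath, pressure_poisson
from .tendon import fit_force_length, tendon_power

log = logging.getLogger("shpower.pipeline")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run.

    Inputs may be directories/files written in the package's text dialects,
    or (when ``synthetic_preset`` is set) generated on the fly from the
    named preset for self-contained validation runs.
    """

    # inputs
    input_dir: str | None = None            # velocity-sequence directory
    landmarks_csv: str | None = None
    tendon_csv: str | None = None
    synthetic_preset: str | None = "seahorse"   # 'seahorse' | 'generalist'
    preset_overrides: dict[str, Any] = field(default_factory=dict)
    grid_n: int = 64
    velocity_noise_sd: float = 0.0
    # physics / numerics
    density: float = 1025.0
    nu: float = 0.0
    geometry: str = "axisymmetric"
    pressure_method: str = "poisson"        # 'poisson' | 'multipath'
    n_paths: int = 8
    smooth_window: int | None = 9
    smooth_order: int = 2
    onset_frac: float = 0.2
    # individual metadata
    species: str = "synthetic"
    individual: str = "synthetic_0"
    lamsa: bool = True
    muscle_mass_kg: float = 0.5e-3
    slack_length: float | None = None       # None: calibration L4 - test x_max
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pressure_method not in ("poisson", "multipath"):
            raise ConfigurationError(
                f"pressure_method must be 'poisson' or 'multipath', "
                f"got {self.pressure_method!r}"
            )
        if self.geometry not in ("planar", "axisymmetric"):
            raise ConfigurationError(f"unknown geometry {self.geometry!r}")
        if self.synthetic_preset is None and self.input_dir is None:
            raise ConfigurationError("either input_dir or synthetic_preset is required")
        if self.synthetic_preset not in (None, "seahorse", "generalist"):
            raise ConfigurationError(f"unknown preset {self.synthetic_preset!r}")
        if self.muscle_mass_kg <= 0:
            raise ConfigurationError("muscle_mass_kg must be positive")
        if not 0 < self.onset_frac < 1:
            raise ConfigurationError("onset_frac must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


#: columns of the tidy per-strike summary table
SUMMARY_COLUMNS = [
    "species", "individual", "lamsa",
    "peak_gape_m", "peak_flow_speed", "peak_net_power_W",
    "mass_specific_power", "power_ceiling_ratio",
    "peak_tendon_power_W", "mean_tendon_power_W",
    "bar_compression_pct", "fourbar_discrepancy_deg",
    "onset_s", "t_peak_flow_s", "t_peak_power_s", "t_peak_gape_s",
    "t_peak_head_speed_s", "ordering_ok",
    "work_J", "ingested_volume_m3",
    "config_hash", "seed", "version",
]


def _load_inputs(config: PipelineConfig):
    from . import io as shio
    from .synthetic import generalist_preset, make_strike_flow, seahorse_preset

    if config.synthetic_preset is not None:
        preset_fn = seahorse_preset if config.synthetic_preset == "seahorse" else generalist_preset
        preset = preset_fn(**config.preset_overrides)
        vel, _, trace, gape = make_strike_flow(
            preset, seed=config.seed, grid_n=config.grid_n,
            noise_sd=config.velocity_noise_sd,
        )
        tendon_samples = None
        if config.tendon_csv:
            tendon_samples = shio.read_tendon_test(config.tendon_csv)
        else:
            from .synthetic import TendonTestSpec, make_tendon_test

            tendon_samples = make_tendon_test(TendonTestSpec(seed=config.seed))
        return vel, trace, gape, tendon_samples, f"synthetic:{config.synthetic_preset}"

    vel = shio.read_velocity_series(config.input_dir)
    if not config.landmarks_csv:
        raise ConfigurationError("landmarks_csv is required with real input")
    trace = shio.read_landmarks(config.landmarks_csv, dt=vel.dt, t0=vel.t0)
    axis = np.asarray(vel.meta.get("mouth_axis", (-1.0, 0.0)), float)
    gape = GapeTrace.from_landmarks(trace, axis=axis)
    tendon_samples = shio.read_tendon_test(config.tendon_csv) if config.tendon_csv else None
    return vel, trace, gape, tendon_samples, str(config.input_dir)


def run_strike(config: PipelineConfig) -> tuple[dict, dict]:
    """Run every stage for one strike; returns (summary row, full report)."""
    vel, trace, gape, tendon_samples, source = _load_inputs(config)
    report: dict[str, Any] = {
        "source": source,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "version": __version__,
        "stages": {},
    }

    params = PhysicalParams(
        density=config.density, nu=config.nu, geometry=config.geometry,
        axis_point=tuple(np.mean(gape.center, axis=0)),
        axis_dir=tuple(gape.axis),
    )
    log.info("pressure reconstruction (%s, %s)", config.pressure_method, config.geometry)
    if config.pressure_method == "poisson":
        pfs = pressure_poisson(vel, params, config.smooth_window, config.smooth_order)
    else:
        pfs = pressure_multipath(
            vel, params, n_paths=config.n_paths, seed=config.seed,
            smooth_window=config.smooth_window, smooth_order=config.smooth_order,
        )
    p_m = pressure_at_mouth(pfs, gape)
    report["stages"]["pressure"] = {
        "method": config.pressure_method,
        "min_p_mouth_Pa": float(np.nanmin(p_m)),
    }

    log.info("suction power")
    u_m = inflow_speed(vel, gape)
    Q = flow_rate(gape, u_m)
    ptrace = net_suction_power(p_m, Q, dt=vel.dt, t0=vel.t0, u_m=u_m)
    meta = MusclesMeta(
        species=config.species, individual=config.individual,
        muscle_mass_kg=config.muscle_mass_kg, lamsa=config.lamsa,
    )
    msp = mass_specific_power(ptrace, meta)

    head_point = "head_tip" if "head_tip" in trace.points else "joint_hyoid"
    head_angle = trace.segment_angle("joint_neurocranium", head_point)
    events = event_timings(
        gape, u_m, ptrace, head_angle,
        onset_frac=config.onset_frac,
        smooth_window=config.smooth_window, smooth_order=config.smooth_order,
    )
    report["stages"]["power"] = {
        "peak_net_power_W": ptrace.peak_power_W,
        "work_J": ptrace.work_J,
        "mass_specific_power": msp.value_W_per_kg,
    }

    log.info("four-bar rigidity and bar compression")
    rig = rigidity_test(trace)
    comp = bar_compression(trace)
    report["stages"]["fourbar"] = {
        "mean_discrepancy_deg": rig.mean_discrepancy_deg,
        "failed_fraction": rig.failed_fraction,
        "compression_pct": comp.compression_percent,
    }

    peak_tendon = mean_tendon = np.nan
    if tendon_samples is not None:
        log.info("tendon recoil power")
        curve = fit_force_length(tendon_samples)
        slack = config.slack_length
        if slack is None:
            slack = comp.L4_reference - curve.x_max
        tp = tendon_power(
            curve, comp.L4, slack_length=slack, dt=trace.dt,
            smooth_window=config.smooth_window, smooth_order=config.smooth_order,
            allow_extrapolation=True,
        )
        peak_tendon, mean_tendon = tp.peak_power_W, tp.mean_power_W
        report["stages"]["tendon"] = {
            "slack_length_m": slack,
            "released_energy_J": tp.released_energy_J,
        }

    row = {
        "species": config.species,
        "individual": config.individual,
        "lamsa": config.lamsa,
        "peak_gape_m": float(np.nanmax(gape.diameter)),
        "peak_flow_speed": float(np.nanmax(u_m)),
        "peak_net_power_W": ptrace.peak_power_W,
        "mass_specific_power": msp.value_W_per_kg,
        "power_ceiling_ratio": msp.ratio_to_muscle_ceiling,
        "peak_tendon_power_W": peak_tendon,
        "mean_tendon_power_W": mean_tendon,
        "bar_compression_pct": comp.compression_percent,
        "fourbar_discrepancy_deg": rig.mean_discrepancy_deg,
        "onset_s": events.onset_s,
        "t_peak_flow_s": events.t_peak_flow_s,
        "t_peak_power_s": events.t_peak_power_s,
        "t_peak_gape_s": events.t_peak_gape_s,
        "t_peak_head_speed_s": events.t_peak_head_speed_s,
        "ordering_ok": events.ordering_ok,
        "work_J": ptrace.work_J,
        "ingested_volume_m3": ptrace.ingested_volume_m3,
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    report["summary"] = row
    return row, report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run one strike and persist summary CSV + JSON report.

    On stage failure the partial report is persisted with a failure
    manifest before the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        row, report = run_strike(config)
    except ShpowerError as exc:
        manifest = {
            "failed": True, "error": str(exc), "error_type": type(exc).__name__,
            "config": config.to_dict(), "config_hash": config.hash(),
            "version": __version__,
        }
        (out / "failure_manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    df = pd.DataFrame([row], columns=SUMMARY_COLUMNS)
    df.to_csv(out / "strike_summary.csv", index=False)
    (out / "strike_report.json").write_text(
        json.dumps(report, indent=1, default=_json_default)
    )
    return df


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return str(o)
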