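"""Readers and writers for the pipeline's text formats.

Velocity/pressure sequences use a per-frame delimited-text dialect (one
file per frame, lexicographic order, columns ``x y u v [p] mask`` with a
one-line header) plus a sequence-level ``metadata.json`` holding grid
spacing, frame interval, density and the mouth trajectory.  Landmarks are
tidy CSV (``frame,point_name,x,y``); tendon tests are CSV
(``extension_m,force_N``).  All units SI; ingest scaling factors live in
metadata, never inferred.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .grids import PressureFieldSeries, VelocityFieldSeries
from .kinematics import KinematicTrace

_FMT = "%.17g"  # round-trips float64 exactly


def write_velocity_series(
    series: VelocityFieldSeries,
    directory: str | Path,
    pressure: PressureFieldSeries | None = None,
) -> Path:
    """Write per-frame grids and metadata; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X, Y = np.meshgrid(series.x, series.y)
    cols = "x y u v p mask" if pressure is not None else "x y u v mask"
    for k in range(series.nt):
        arrays = [X.ravel(), Y.ravel(), series.u[k].ravel(), series.v[k].ravel()]
        if pressure is not None:
            arrays.append(pressure.p[k].ravel())
        arrays.append(series.mask.ravel().astype(float))
        np.savetxt(
            directory / f"frame_{k:05d}.dat",
            np.column_stack(arrays),
            fmt=_FMT,
            header=cols,
            comments="# ",
        )
    meta = {
        "nx": len(series.x), "ny": len(series.y),
        "x0": series.x[0], "y0": series.y[0],
        "dx": series.dx, "dy": series.dy,
        "dt": series.dt, "t0": series.t0,
        "n_frames": series.nt,
        **{k: v for k, v in series.meta.items()},
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_velocity_series(directory: str | Path) -> VelocityFieldSeries:
    """Read a velocity-sequence directory written by the writer (also the
    ingest dialect for real PIV exports).

    NaN velocities in unmasked cells are masked and counted in
    ``meta['flagged_cells']``; inconsistent grids raise with the offending
    frame named.
    """
    directory = Path(directory)
    frames = sorted(directory.glob("frame_*.dat"))
    if not frames:
        raise DataError(f"no frames found in {directory}")
    mpath = directory / "metadata.json"
    if not mpath.exists():
        raise DataError(f"missing metadata.json in {directory}")
    meta = json.loads(mpath.read_text())
    for key in ("nx", "ny", "dt"):
        if key not in meta:
            raise DataError(f"metadata.json lacks required key {key!r}")
    nx, ny = int(meta["nx"]), int(meta["ny"])

    us, vs = [], []
    mask = None
    bad_union = None
    x = y = None
    flagged = 0
    for f in frames:
        dat = np.loadtxt(f)
        if dat.shape[0] != nx * ny:
            raise DataError(
                f"frame {f.name}: {dat.shape[0]} rows, expected {nx * ny}"
            )
        has_p = dat.shape[1] == 6
        if dat.shape[1] not in (5, 6):
            raise DataError(f"frame {f.name}: expected 5 or 6 columns")
        xg = dat[:, 0].reshape(ny, nx)
        yg = dat[:, 1].reshape(ny, nx)
        u = dat[:, 2].reshape(ny, nx)
        v = dat[:, 3].reshape(ny, nx)
        m = dat[:, 5 if has_p else 4].reshape(ny, nx) > 0.5
        if x is None:
            x, y, mask = xg[0], yg[:, 0], m
        elif not (np.array_equal(xg[0], x) and np.array_equal(yg[:, 0], y)):
            raise DataError(f"frame {f.name}: grid differs from first frame")
        elif not np.array_equal(m, mask):
            raise DataError(f"frame {f.name}: mask differs from first frame")
        bad = (~np.isfinite(u) | ~np.isfinite(v)) & ~mask
        if bad.any():
            flagged += int(bad.sum())
            bad_union = bad if bad_union is None else (bad_union | bad)
        us.append(u)
        vs.append(v)
    extra = {
        k: v for k, v in meta.items()
        if k not in ("nx", "ny", "x0", "y0", "dx", "dy", "dt", "t0", "n_frames")
    }
    extra["flagged_cells"] = flagged
    if bad_union is not None:
        mask = mask | bad_union
    return VelocityFieldSeries(
        u=np.stack(us), v=np.stack(vs), mask=mask, x=x, y=y,
        dt=float(meta["dt"]), t0=float(meta.get("t0", 0.0)), meta=extra,
    )


def write_pressure_series(
    series: VelocityFieldSeries, pressure: PressureFieldSeries, directory: str | Path
) -> Path:
    """Velocity + pressure in the shared grid dialect (``p`` column)."""
    return write_velocity_series(series, directory, pressure=pressure)


def read_pressure_series(directory: str | Path) -> PressureFieldSeries:
    directory = Path(directory)
    frames = sorted(directory.glob("frame_*.dat"))
    if not frames:
        raise DataError(f"no frames found in {directory}")
    meta = json.loads((directory / "metadata.json").read_text())
    nx, ny = int(meta["nx"]), int(meta["ny"])
    ps, mask = [], None
    x = y = None
    for f in frames:
        dat = np.loadtxt(f)
        if dat.shape[1] != 6:
            raise DataError(f"frame {f.name}: no pressure column")
        if x is None:
            x = dat[:, 0].reshape(ny, nx)[0]
            y = dat[:, 1].reshape(ny, nx)[:, 0]
            mask = dat[:, 5].reshape(ny, nx) > 0.5
        ps.append(dat[:, 4].reshape(ny, nx))
    return PressureFieldSeries(
        p=np.stack(ps), mask=mask, x=x, y=y,
        dt=float(meta["dt"]), t0=float(meta.get("t0", 0.0)),
        reference=str(meta.get("pressure_reference", "as written")), meta=meta,
    )


# -- landmarks ---------------------------------------------------------------

def write_landmarks(trace: KinematicTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(path, index=False)
    return path


def read_landmarks(path: str | Path, dt: float, t0: float = 0.0) -> KinematicTrace:
    df = pd.read_csv(path)
    return KinematicTrace.from_frame(df, dt=dt, t0=t0)


# -- tendon tests ------------------------------------------------------------

def write_tendon_test(samples: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(samples, columns=["extension_m", "force_N"]).to_csv(path, index=False)
    return path


def read_tendon_test(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("extension_m", "force_N"):
        if col not in df.columns:
            raise DataError(f"tendon test CSV must have column {col!r}")
    return df[["extension_m", "force_N"]].to_numpy(float)
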