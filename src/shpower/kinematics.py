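"""Digitized-landmark traces (DLTdv-style point tracks)."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .errors import DataError

#: landmark names used by the synthetic generator and expected by the
#: four-bar routines; real digitizations are renamed on ingest.
FOURBAR_POINTS = ("joint_neurocranium", "cleithrum", "joint_hyoid", "hyoid_tip")


@dataclass
class KinematicTrace:
    """Per-frame 2-D coordinates of named landmarks.

    points maps landmark name -> (nt, 2) array in metres; missing frames are
    NaN.  All arrays share the frame base (``dt``, ``t0``).
    """

    points: dict[str, np.ndarray]
    dt: float
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DataError("frame interval dt must be positive")
        nts = set()
        for name, arr in self.points.items():
            arr = np.asarray(arr, float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise DataError(f"landmark {name!r} must be an (nt, 2) array")
            self.points[name] = arr
            nts.add(arr.shape[0])
        if len(nts) > 1:
            raise DataError(f"landmarks disagree on frame count: {sorted(nts)}")

    @property
    def nt(self) -> int:
        return next(iter(self.points.values())).shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.nt)

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise DataError(f"trace is missing landmarks: {missing}")

    def segment_length(self, a: str, b: str) -> np.ndarray:
        """Per-frame distance between two landmarks."""
        self.require((a, b))
        return np.linalg.norm(self.points[a] - self.points[b], axis=1)

    def segment_angle(self, a: str, b: str) -> np.ndarray:
        """Per-frame orientation (rad, CCW from +x) of the a -> b segment."""
        self.require((a, b))
        d = self.points[b] - self.points[a]
        return np.arctan2(d[:, 1], d[:, 0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy ``frame, point_name, x, y`` table."""
        rows = []
        for name, arr in sorted(self.points.items()):
            for k in range(arr.shape[0]):
                rows.append((k, name, arr[k, 0], arr[k, 1]))
        return pd.DataFrame(rows, columns=["frame", "point_name", "x", "y"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float, t0: float = 0.0) -> "KinematicTrace":
        required = {"frame", "point_name", "x", "y"}
        if not required.issubset(df.columns):
            raise DataError(f"landmark table must have columns {sorted(required)}")
        nt = int(df["frame"].max()) + 1
        points: dict[str, np.ndarray] = {}
        for name, sub in df.groupby("point_name"):
            arr = np.full((nt, 2), np.nan)
            idx = sub["frame"].to_numpy(int)
            arr[idx, 0] = sub["x"].to_numpy(float)
            arr[idx, 1] = sub["y"].to_numpy(float)
            points[str(name)] = arr
        return cls(points=points, dt=dt, t0=t0)


@dataclass
class GapeTrace:
    """Mouth-aperture geometry per frame.

    diameter : (nt,) gape diameter d(t) in m, from the two digitized
        mouth-margin landmarks.
    center : (nt, 2) aperture centre coordinates (m).
    axis : (2,) unit vector along the mouth axis pointing *into* the mouth;
        inflow projected on this axis is positive.
    """

    diameter: np.ndarray
    center: np.ndarray
    axis: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, float)
        self.center = np.asarray(self.center, float)
        self.axis = np.asarray(self.axis, float)
        n = np.hypot(*self.axis)
        if n == 0:
            raise DataError("mouth axis must be a non-zero vector")
        self.axis = self.axis / n
        if np.nanmin(self.diameter) < 0:
            raise DataError("gape diameter cannot be negative")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.diameter))

    @classmethod
    def from_landmarks(
        cls,
        trace: KinematicTrace,
        axis: np.ndarray,
        dorsal: str = "mouth_dorsal",
        ventral: str = "mouth_ventral",
    ) -> "GapeTrace":
        trace.require((dorsal, ventral))
        d = trace.segment_length(dorsal, ventral)
        c = 0.5 * (trace.points[dorsal] + trace.points[ventral])
        return cls(diameter=d, center=c, axis=np.asarray(axis, float),
                   dt=trace.dt, t0=trace.t0)


def fill_small_gaps(series: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; longer runs stay NaN."""
    out = np.asarray(series, float).copy()
    bad = ~np.isfinite(out)
    if not bad.any():
        return out
    idx = np.arange(len(out))
    runs = []
    start = None
    for k in range(len(out)):
        if bad[k] and start is None:
            start = k
        elif not bad[k] and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, len(out) - 1))
    good = ~bad
    for s, e in runs:
        if e - s + 1 <= max_gap and s > 0 and e < len(out) - 1:
            out[s : e + 1] = np.interp(idx[s : e + 1], idx[good], out[good])
    return out
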