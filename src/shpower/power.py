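"""Net suction power from mouth pressure and inflow (the p·Q integral).

The power needed to accelerate the water outside the mouth is obtained by
combining the gauge pressure at the mouth aperture with the volumetric
inflow rate, Q(t) = u_m(t) * pi d(t)^2 / 4 (circular-aperture assumption,
with d the digitized gape diameter and u_m the PIV inflow speed averaged
over the aperture).  The instantaneous net suction power is

    P_net(t) = -p_mouth(t) * Q(t),

positive while suction (negative gauge pressure) draws water in; the
cumulative work is its time integral.  This is a lower bound on the total
suction power: the power spent accelerating the skeletal and muscle
tissues of the buccal cavity (a few percent of the total in largemouth
bass, possibly more in seahorses) is not included.

Mass-specific power divides peak P_net by the mass of the epaxial and
hypaxial muscles that drive the system and compares it against the maximum
power ever recorded from vertebrate muscle, 1121 W/kg: sustained exceedance
implies elastic (spring-loaded) actuation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .errors import DataError
from .grids import VelocityFieldSeries
from .kinematics import GapeTrace

#: maximum mass-specific power recorded from vertebrate muscle (W/kg)
MUSCLE_POWER_CEILING = 1121.0


@dataclass
class MusclesMeta:
    """Identity and driving-muscle mass of one individual."""

    species: str
    individual: str
    muscle_mass_kg: float
    lamsa: bool = False

    def __post_init__(self) -> None:
        if not self.species or not self.individual:
            raise DataError("species and individual identifiers must be non-empty")
        if not np.isfinite(self.muscle_mass_kg) or self.muscle_mass_kg <= 0:
            raise DataError("muscle mass must be positive")


@dataclass
class PowerTrace:
    """Aligned time series of the suction-power calculation."""

    u_m: np.ndarray          # inflow speed at the mouth (m/s, + into mouth)
    Q: np.ndarray            # volumetric flow rate (m^3/s)
    p_mouth: np.ndarray      # gauge pressure at the mouth (Pa, suction < 0)
    P_net: np.ndarray        # instantaneous net suction power (W)
    dt: float
    t0: float = 0.0
    peak_power_W: float = field(init=False)
    work_J: float = field(init=False)
    ingested_volume_m3: float = field(init=False)

    def __post_init__(self) -> None:
        fin = np.isfinite(self.P_net)
        self.peak_power_W = float(np.max(self.P_net[fin])) if fin.any() else np.nan
        tt = self.t0 + self.dt * np.arange(len(self.P_net))
        self.work_J = _nantrapz(self.P_net, tt)
        self.ingested_volume_m3 = _nantrapz(self.Q, tt)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.P_net))


def _nantrapz(yv: np.ndarray, tv: np.ndarray) -> float:
    fin = np.isfinite(yv)
    if fin.sum() < 2:
        return 0.0
    return float(np.trapezoid(yv[fin], tv[fin]))


def inflow_speed(
    series: VelocityFieldSeries, gape: GapeTrace, n_samples: int = 9
) -> np.ndarray:
    """Inflow speed at the mouth per frame (m/s, positive into the mouth).

    Velocity is interpolated on the aperture line (length d(t), centred on
    the mouth centre, perpendicular to the mouth axis), projected on the
    mouth axis and averaged.  Frames with zero gape report 0.
    """
    from .pressure import _aperture_points, interp_masked  # shared samplers

    nt = min(series.nt, len(gape.diameter))
    out = np.zeros(nt)
    for k in range(nt):
        if gape.diameter[k] <= 0:
            continue
        pts = _aperture_points(gape, k, n_samples)
        uu = interp_masked(series.u[k], series.x, series.y, pts)
        vv = interp_masked(series.v[k], series.x, series.y, pts)
        proj = uu * gape.axis[0] + vv * gape.axis[1]
        out[k] = float(np.nanmean(proj)) if np.isfinite(proj).any() else np.nan
    return out


def flow_rate(gape: GapeTrace, u_m: np.ndarray) -> np.ndarray:
    """Volumetric inflow Q(t) = u_m * pi d^2 / 4 (circular aperture)."""
    d = gape.diameter[: len(u_m)]
    if np.nanmin(d) < 0:
        raise DataError("negative gape diameter")
    return np.asarray(u_m, float) * np.pi * d**2 / 4.0


def net_suction_power(
    p_mouth: np.ndarray, Q: np.ndarray, dt: float, t0: float = 0.0,
    u_m: Optional[np.ndarray] = None,
) -> PowerTrace:
    """Instantaneous net suction power, peak power and cumulative work."""
    p_mouth = np.asarray(p_mouth, float)
    Q = np.asarray(Q, float)
    if p_mouth.shape != Q.shape:
        raise DataError(
            f"misaligned series: p_mouth {p_mouth.shape} vs Q {Q.shape}"
        )
    P = -p_mouth * Q
    if u_m is None:
        u_m = np.full_like(Q, np.nan)
    return PowerTrace(u_m=np.asarray(u_m, float), Q=Q, p_mouth=p_mouth, P_net=P,
                      dt=dt, t0=t0)


@dataclass
class MassSpecificPower:
    value_W_per_kg: float
    ratio_to_muscle_ceiling: float
    ceiling_W_per_kg: float = MUSCLE_POWER_CEILING


def mass_specific_power(trace: PowerTrace, meta: MusclesMeta) -> MassSpecificPower:
    """Peak net suction power per unit driving-muscle mass (W/kg)."""
    v = trace.peak_power_W / meta.muscle_mass_kg
    return MassSpecificPower(
        value_W_per_kg=float(v),
        ratio_to_muscle_ceiling=float(v / MUSCLE_POWER_CEILING),
    )


# ---------------------------------------------------------------------------
# event timings
# ---------------------------------------------------------------------------

@dataclass
class EventTimings:
    """Times of the kinematic landmarks of a strike, from strike onset.

    Onset is the first frame with gape above ``onset_frac`` of peak gape.
    The published ordering for seahorse strikes is peak flow speed, then
    peak power, then peak gape, then peak head-rotation speed;
    ``ordering_ok`` flags whether this trace respects it.  Peaks falling on
    the first or last frame are censored (the true peak may lie outside the
    recording), not errors.
    """

    onset_s: float
    t_peak_flow_s: float
    t_peak_power_s: float
    t_peak_gape_s: float
    t_peak_head_speed_s: float
    censored: dict[str, bool]
    ordering_ok: bool
    onset_frac: float = 0.2


def _smoothed(yv: np.ndarray, window: int | None, order: int) -> np.ndarray:
    if window is None or len(yv) <= window:
        return yv
    return savgol_filter(yv, window, order)


def _peak_time(yv: np.ndarray, tt: np.ndarray) -> tuple[float, bool]:
    fin = np.isfinite(yv)
    if not fin.any():
        return np.nan, True
    yv = np.where(fin, yv, -np.inf)
    k = int(np.argmax(yv))  # earliest index on ties
    return float(tt[k]), k in (0, len(yv) - 1)


def event_timings(
    gape: GapeTrace,
    u_m: np.ndarray,
    power: PowerTrace,
    head_angle: np.ndarray,
    onset_frac: float = 0.2,
    smooth_window: int | None = None,
    smooth_order: int = 2,
) -> EventTimings:
    """Detect onset and peak times of flow, power, gape and head rotation.

    All series must share the frame base of ``gape``.  Head-rotation speed
    is the absolute finite-difference derivative of the head angle.  The
    same optional Savitzky-Golay smoother as the pressure module is applied
    before peak-finding; ties resolve to the earliest frame.
    """
    tt = gape.t
    d = _smoothed(gape.diameter, smooth_window, smooth_order)
    u = _smoothed(np.asarray(u_m, float), smooth_window, smooth_order)
    P = _smoothed(power.P_net, smooth_window, smooth_order)
    ang = np.unwrap(np.asarray(head_angle, float))
    if smooth_window is not None and len(ang) > smooth_window:
        # differentiate inside the smoother: far less peak wobble than
        # smoothing a finite-difference speed
        head_speed = np.abs(
            savgol_filter(ang, smooth_window, smooth_order, deriv=1, delta=gape.dt)
        )
    else:
        head_speed = np.abs(np.gradient(ang, gape.dt))

    above = d > onset_frac * np.nanmax(d)
    onset = float(tt[np.argmax(above)]) if above.any() else float(tt[0])

    t_flow, c_flow = _peak_time(u, tt)
    t_pow, c_pow = _peak_time(P, tt)
    t_gape, c_gape = _peak_time(d, tt)
    t_head, c_head = _peak_time(head_speed, tt)
    ordering = t_flow < t_pow < t_gape < t_head
    return EventTimings(
        onset_s=onset,
        t_peak_flow_s=t_flow - onset,
        t_peak_power_s=t_pow - onset,
        t_peak_gape_s=t_gape - onset,
        t_peak_head_speed_s=t_head - onset,
        censored={
            "flow": c_flow, "power": c_pow, "gape": c_gape, "head": c_head,
        },
        ordering_ok=bool(ordering),
        onset_frac=onset_frac,
    )
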