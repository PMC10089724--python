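"""Four-bar linkage kinematics and rigidity diagnostics.

Link numbering follows the cranial linkage of pivot-feeding syngnathids:

* link 1 — fixed frame (pectoral girdle / suspensorium), between the
  neurocranium pivot N and the ventral cleithrum protrusion C;
* link 2 — the head (neurocranium unit), grounded at N; its rotation is
  the head elevation observed in video;
* link 3 — the hyoid, the coupler connecting the head-hyoid joint H to the
  distal hyoid tip T;
* link 4 — the urohyal + sternohyoideus complex, grounded at C.  In
  seahorses this link is a muscle-tendon complex and can shorten; a rigid
  linkage assumes its length fixed.

In a rigid four-bar the motion of any one link determines the rest, so the
head elevation expected from the observed hyoid motion can be compared with
the digitized head elevation; a systematic discrepancy indicates that the
ventral link changes length.  Angles are measured counterclockwise from the
fixed link (the C -> N direction).
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .errors import DataError, KinematicsError
from .kinematics import FOURBAR_POINTS, KinematicTrace, fill_small_gaps

#: tolerance on link-length closure residuals (relative)
CLOSURE_RTOL = 1e-9


@dataclass
class FourBarGeometry:
    """Link lengths (m): L1 ground, L2 head, L3 hyoid, L4 ventral complex."""

    L1: float
    L2: float
    L3: float
    L4: float

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "L3", "L4"):
            if getattr(self, name) <= 0:
                raise DataError(f"link length {name} must be positive")

    def lengths(self) -> np.ndarray:
        return np.array([self.L1, self.L2, self.L3, self.L4])


def circle_intersection(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Both intersection points of two circles, or None if they miss.

    The points are returned in a deterministic order: the first lies to the
    left of the c1 -> c2 direction.  Tangency returns two equal points.
    """
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    d = c2 - c1
    dist = float(np.hypot(*d))
    if dist == 0.0 or dist > r1 + r2 or dist < abs(r1 - r2):
        return None
    along = (r1**2 - r2**2 + dist**2) / (2 * dist)
    h2 = r1**2 - along**2
    h = np.sqrt(max(h2, 0.0))
    mid = c1 + along * d / dist
    perp = np.array([-d[1], d[0]]) / dist
    return mid + h * perp, mid - h * perp


def solve_fourbar(
    geometry: FourBarGeometry, input_angle: float, branch: str = "open"
) -> tuple[float, float]:
    """Closed-form position solution driven by the grounded link 4.

    With C at the origin and N at (L1, 0), ``input_angle`` is the angle of
    link 4 (C -> T) and the returned pair is (output angle of link 2, i.e.
    N -> H, and coupler angle of link 3, T -> H), all CCW from the fixed
    link.  ``branch`` picks the elbow: 'open' and 'crossed' select the two
    roots of the loop-closure (Freudenstein) relation.

    Raises KinematicsError if the configuration cannot close.
    """
    if branch not in ("open", "crossed"):
        raise DataError(f"branch must be 'open' or 'crossed', got {branch!r}")
    L1, L2, L3, L4 = geometry.lengths()
    th4 = float(input_angle)
    # loop closure |N + L2 e^{i th2} - L4 e^{i th4}| = L3 expanded in th2:
    A = 2 * L2 * (L1 - L4 * np.cos(th4))
    B = -2 * L2 * L4 * np.sin(th4)
    E = L1**2 + L2**2 + L4**2 - L3**2 - 2 * L1 * L4 * np.cos(th4)
    R = np.hypot(A, B)
    if R == 0:
        raise KinematicsError("degenerate linkage (zero-radius output circle)")
    c = -E / R
    if abs(c) > 1 + 1e-12:
        raise KinematicsError(
            f"four-bar cannot close at input angle {np.degrees(th4):.2f} deg"
        )
    delta = np.arccos(np.clip(c, -1.0, 1.0))
    phi = np.arctan2(B, A)
    th2 = phi + delta if branch == "open" else phi - delta
    H = np.array([L1 + L2 * np.cos(th2), L2 * np.sin(th2)])
    T = np.array([L4 * np.cos(th4), L4 * np.sin(th4)])
    th3 = float(np.arctan2(H[1] - T[1], H[0] - T[0]))
    # closure check
    resid = abs(np.hypot(*(H - T)) - L3) / L3
    if resid > 1e-6:
        raise KinematicsError(f"closure residual {resid:.2e} exceeds tolerance")
    return float(np.mod(th2, 2 * np.pi)), float(np.mod(th3, 2 * np.pi))


def _expected_head_joint(
    N: np.ndarray,
    C: np.ndarray,
    L2: float,
    L3: float,
    L4: float,
    theta3: float,
    near: np.ndarray,
) -> Optional[np.ndarray]:
    """Head-hyoid joint position expected under rigid closure, driven by the
    observed hyoid (coupler) orientation ``theta3`` (world coordinates,
    H -> T direction).  ``near`` resolves the branch by continuity."""
    # T = H + L3 e^{i theta3} and |T - C| = L4  =>  H on two circles
    offset = C - L3 * np.array([np.cos(theta3), np.sin(theta3)])
    sol = circle_intersection(N, L2, offset, L4)
    if sol is None:
        return None
    return min(sol, key=lambda s: float(np.hypot(*(s - near))))


@dataclass
class RigidityResult:
    """Expected-vs-observed head elevation under the rigid-linkage assumption."""

    observed_deg: np.ndarray       # head elevation relative to calibration
    expected_deg: np.ndarray       # rigid-linkage expectation (NaN: no closure)
    discrepancy_deg: np.ndarray    # |observed - expected| per frame
    mean_discrepancy_deg: float    # mean over moving (post-calibration) frames
    max_discrepancy_deg: float
    failed_fraction: float         # fraction of moving frames with no closure
    calibration_frame: int
    l4_datum: str
    geometry: FourBarGeometry = dc_field(repr=False, default=None)


def calibration_frame_index(trace: KinematicTrace, threshold: float = 0.05) -> int:
    """Last quiet frame before hyoid angular speed exceeds ``threshold`` of
    its peak (pre-strike posture)."""
    th3 = trace.segment_angle("joint_hyoid", "hyoid_tip")
    speed = np.abs(np.gradient(np.unwrap(th3), trace.dt))
    peak = np.nanmax(speed)
    if peak == 0:
        return 0
    moving = np.flatnonzero(speed > threshold * peak)
    if len(moving) == 0 or moving[0] == 0:
        return 0
    return int(moving[0] - 1)


def geometry_from_trace(trace: KinematicTrace, frame: int) -> FourBarGeometry:
    """Link lengths measured from the digitized joints of one frame."""
    trace.require(FOURBAR_POINTS)
    N = trace.points["joint_neurocranium"][frame]
    C = trace.points["cleithrum"][frame]
    H = trace.points["joint_hyoid"][frame]
    T = trace.points["hyoid_tip"][frame]
    return FourBarGeometry(
        L1=float(np.hypot(*(C - N))),
        L2=float(np.hypot(*(H - N))),
        L3=float(np.hypot(*(T - H))),
        L4=float(np.hypot(*(T - C))),
    )


def rigidity_test(
    trace: KinematicTrace,
    geometry: FourBarGeometry | None = None,
    l4_datum: str = "calibration",
    speed_threshold: float = 0.05,
) -> RigidityResult:
    """Compare observed head elevation with the rigid four-bar expectation.

    The linkage is calibrated from the pre-strike posture (link lengths from
    the digitized joints of the calibration frame); the expected head motion
    is then driven by the observed hyoid orientation under rigid closure.
    ``l4_datum`` selects the fixed length assumed for the ventral link:
    'calibration' (pre-strike length) or 'mean' (mean digitized length).
    """
    if l4_datum not in ("calibration", "mean"):
        raise DataError("l4_datum must be 'calibration' or 'mean'")
    trace.require(FOURBAR_POINTS)
    cal = calibration_frame_index(trace, speed_threshold)
    if geometry is None:
        geometry = geometry_from_trace(trace, cal)
    N = trace.points["joint_neurocranium"][cal]
    C = trace.points["cleithrum"][cal]
    L4_fixed = geometry.L4
    if l4_datum == "mean":
        L4_fixed = float(np.nanmean(trace.segment_length("hyoid_tip", "cleithrum")))

    th2_obs = np.unwrap(trace.segment_angle("joint_neurocranium", "joint_hyoid"))
    th3_obs = trace.segment_angle("joint_hyoid", "hyoid_tip")
    nt = trace.nt
    expected = np.full(nt, np.nan)
    near = trace.points["joint_hyoid"][cal]
    for k in range(nt):
        if not np.isfinite(th3_obs[k]):
            continue
        H_exp = _expected_head_joint(
            N, C, geometry.L2, geometry.L3, L4_fixed, float(th3_obs[k]), near
        )
        if H_exp is None:
            continue
        near = H_exp
        expected[k] = np.arctan2(H_exp[1] - N[1], H_exp[0] - N[0])
    expected = _unwrap_nan(expected)

    obs_el = np.degrees(th2_obs - th2_obs[cal])
    exp_el = np.degrees(expected - expected[cal])
    disc = np.abs(obs_el - exp_el)

    # summarize over the frames where the hyoid actually moves
    th3_speed = np.abs(np.gradient(np.unwrap(th3_obs), trace.dt))
    moving = th3_speed > speed_threshold * np.nanmax(th3_speed)
    moving[: cal + 1] = False
    if not moving.any():
        moving = np.ones(nt, bool)
    sel = disc[moving]
    failed = float(np.mean(~np.isfinite(sel)))
    return RigidityResult(
        observed_deg=obs_el,
        expected_deg=exp_el,
        discrepancy_deg=disc,
        mean_discrepancy_deg=float(np.nanmean(sel)) if np.isfinite(sel).any() else np.nan,
        max_discrepancy_deg=float(np.nanmax(sel)) if np.isfinite(sel).any() else np.nan,
        failed_fraction=failed,
        calibration_frame=cal,
        l4_datum=l4_datum,
        geometry=geometry,
    )


def _unwrap_nan(angles: np.ndarray) -> np.ndarray:
    out = angles.copy()
    ok = np.isfinite(out)
    if ok.any():
        out[ok] = np.unwrap(out[ok])
    return out


@dataclass
class BarCompression:
    """Length series of the flexible ventral link and its peak compression."""

    L4: np.ndarray                # per-frame hyoid-tip -> cleithrum distance (m)
    L4_reference: float           # calibration-frame length (m)
    compression_percent: float    # 100 * (L4_ref - min L4) / L4_ref
    calibration_frame: int


def bar_compression(trace: KinematicTrace, max_gap: int = 2) -> BarCompression:
    """Shortening of the ventral bar during hyoid retroversion.

    Missing landmark frames are interpolated across gaps of up to
    ``max_gap`` frames; longer gaps are excluded from the minimum.
    """
    trace.require(("hyoid_tip", "cleithrum"))
    L4 = trace.segment_length("hyoid_tip", "cleithrum")
    L4 = fill_small_gaps(L4, max_gap=max_gap)
    cal = calibration_frame_index(trace) if all(
        p in trace.points for p in FOURBAR_POINTS
    ) else 0
    ref = L4[cal]
    if not np.isfinite(ref):
        raise DataError("calibration frame has no ventral-bar length")
    comp = 100.0 * (ref - np.nanmin(L4)) / ref
    return BarCompression(
        L4=L4, L4_reference=float(ref),
        compression_percent=float(comp), calibration_frame=cal,
    )
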