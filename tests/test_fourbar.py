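"""Four-bar solver, rigidity diagnostics and bar compression."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from shpower.errors import KinematicsError
from shpower.fourbar import (
    FourBarGeometry,
    bar_compression,
    calibration_frame_index,
    rigidity_test,
    solve_fourbar,
)
from shpower.kinematics import KinematicTrace
from shpower.synthetic import make_strike, seahorse_preset


# ---------------------------------------------------------------------------
# closed-form solver vs an independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_output_angles(geom: FourBarGeometry, th4: float) -> list[float]:
    """All output angles satisfying the loop closure, found by dense scan +
    root refinement of |H(th2) - T| - L3 (independent of the solver)."""
    T = geom.L4 * np.array([np.cos(th4), np.sin(th4)])
    N = np.array([geom.L1, 0.0])

    def f(th2):
        H = N + geom.L2 * np.array([np.cos(th2), np.sin(th2)])
        return np.hypot(*(H - T)) - geom.L3

    grid = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    vals = np.array([f(g) for g in grid])
    roots = []
    for i in range(len(grid)):
        a, b = grid[i], grid[(i + 1) % len(grid)] + (2 * np.pi if i + 1 == len(grid) else 0)
        fa, fb = vals[i], vals[(i + 1) % len(grid)]
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(brentq(f, a, b, xtol=1e-14))
    return [r % (2 * np.pi) for r in roots]


def test_solver_matches_brute_force_oracle_on_random_linkages():
    rng = np.random.default_rng(12345)
    checked = 0
    while checked < 1000:
        L = rng.uniform(0.5, 2.0, size=4)
        geom = FourBarGeometry(*L)
        th4 = rng.uniform(0, 2 * np.pi)
        try:
            th2_open, _ = solve_fourbar(geom, th4, branch="open")
            th2_crossed, _ = solve_fourbar(geom, th4, branch="crossed")
        except KinematicsError:
            continue
        oracle = brute_force_output_angles(geom, th4)
        assert oracle, "oracle found no closure where solver did"
        for th2 in {th2_open, th2_crossed}:
            nearest = min(oracle, key=lambda r: abs(np.angle(np.exp(1j * (r - th2)))))
            assert abs(np.angle(np.exp(1j * (nearest - th2)))) < 1e-9
        checked += 1


def test_solver_closure_residual():
    geom = FourBarGeometry(1.0, 0.4, 0.9, 0.7)
    for th4 in np.linspace(0.6, 1.6, 50):  # feasible input range of this linkage
        th2, th3 = solve_fourbar(geom, th4, branch="open")
        H = np.array([geom.L1 + geom.L2 * np.cos(th2), geom.L2 * np.sin(th2)])
        T = geom.L4 * np.array([np.cos(th4), np.sin(th4)])
        assert abs(np.hypot(*(H - T)) - geom.L3) / geom.L3 < 1e-9


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    th4=st.floats(0.05, 2 * np.pi - 0.05),
    L1=st.floats(0.5, 2.0),
    L2=st.floats(0.3, 1.5),
)
def test_parallelogram_output_equals_input(th4, L1, L2):
    """L1 = L3, L2 = L4: the two cranks stay parallel on one branch."""
    geom = FourBarGeometry(L1=L1, L2=L2, L3=L1, L4=L2)
    sols = []
    for branch in ("open", "crossed"):
        try:
            sols.append(solve_fourbar(geom, th4, branch)[0])
        except KinematicsError:
            pass
    assert sols
    assert any(abs(np.angle(np.exp(1j * (s - th4)))) < 1e-9 for s in sols)


def test_rhombus_right_angle():
    geom = FourBarGeometry(1.0, 1.0, 1.0, 1.0)
    outs = [solve_fourbar(geom, np.pi / 2, b)[0] for b in ("open", "crossed")]
    assert any(abs(o - np.pi / 2) < 1e-9 for o in outs)


def test_impossible_closure_raises_with_angle():
    geom = FourBarGeometry(L1=10.0, L2=1.0, L3=1.0, L4=1.0)
    with pytest.raises(KinematicsError, match="deg"):
        solve_fourbar(geom, 1.0)


# ---------------------------------------------------------------------------
# rigidity test
# ---------------------------------------------------------------------------

def _trace(compression, seed=0, **kw):
    pre = seahorse_preset(link4_compression_fraction=compression,
                          jitter_frac=0.0, **kw)
    trace, _ = make_strike(pre, seed=seed)
    return trace


def test_rigid_trace_zero_discrepancy_and_compression():
    trace = _trace(0.0)
    rig = rigidity_test(trace)
    assert rig.mean_discrepancy_deg == pytest.approx(0.0, abs=1e-6)
    assert rig.failed_fraction == 0.0
    assert bar_compression(trace).compression_percent == pytest.approx(0.0, abs=1e-9)


def test_discrepancy_monotone_in_compression():
    discs = [rigidity_test(_trace(c)).mean_discrepancy_deg
             for c in (0.0, 0.1, 0.3, 0.5)]
    assert all(d2 > d1 for d1, d2 in zip(discs, discs[1:]))


def test_both_link4_datums_reported():
    trace = _trace(0.3)
    cal = rigidity_test(trace, l4_datum="calibration")
    mean = rigidity_test(trace, l4_datum="mean")
    assert cal.mean_discrepancy_deg > 0
    assert mean.mean_discrepancy_deg > 0
    assert cal.l4_datum != mean.l4_datum


def _transform(trace, scale=1.0, rot=0.0, shift=(0.0, 0.0)):
    c, s = np.cos(rot), np.sin(rot)
    Rm = np.array([[c, -s], [s, c]])
    pts = {k: scale * v @ Rm.T + np.asarray(shift) for k, v in trace.points.items()}
    return KinematicTrace(points=pts, dt=trace.dt)


def test_discrepancy_invariant_to_similarity_transform():
    trace = _trace(0.3)
    base = rigidity_test(trace).mean_discrepancy_deg
    moved = _transform(trace, scale=3.7, rot=0.8, shift=(0.12, -0.05))
    assert rigidity_test(moved).mean_discrepancy_deg == pytest.approx(base, rel=1e-6)


def test_compression_scale_invariant_and_exact():
    trace = _trace(0.3)
    assert bar_compression(trace).compression_percent == pytest.approx(30.0, abs=1e-9)
    scaled = _transform(trace, scale=0.01)
    assert bar_compression(scaled).compression_percent == pytest.approx(30.0, abs=1e-9)


def test_compression_interpolates_small_landmark_gaps():
    trace = _trace(0.3)
    pts = {k: v.copy() for k, v in trace.points.items()}
    pts["hyoid_tip"][30:32] = np.nan   # 2-frame dropout
    gappy = KinematicTrace(points=pts, dt=trace.dt)
    assert bar_compression(gappy).compression_percent == pytest.approx(30.0, abs=0.5)


def test_calibration_frame_precedes_hyoid_motion():
    trace = _trace(0.3)
    cal = calibration_frame_index(trace)
    th3 = np.unwrap(trace.segment_angle("joint_hyoid", "hyoid_tip"))
    assert np.allclose(th3[: cal + 1], th3[0], atol=1e-9)
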