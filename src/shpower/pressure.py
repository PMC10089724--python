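"""Pressure-field reconstruction from PIV velocity sequences.

Two established routes from gridded velocity to gauge pressure are provided,
both driven by the material acceleration Du/Dt = du/dt + (u . grad) u:

``pressure_poisson``
    A finite-volume least-squares solve: the pressure gradient on every
    face between fluid cells is matched to the inviscid momentum source
    -rho Du/Dt, and the normal equations of that weighted least-squares
    problem are exactly a Poisson discretization of
    div(w grad p) = div(w g) with Neumann conditions on mask edges (faces
    into the body simply carry no constraint).  In axisymmetric mode the
    face weight w is the distance from the mouth axis, which turns the
    operator into the cylindrical-coordinate Poisson operator for flows
    whose symmetry plane is the PIV plane.

``pressure_multipath``
    Median of line integrals of -rho Du/Dt along randomized axis-aligned
    staircase paths from the zero-pressure boundary cells, after the
    multi-path integration schemes used for PIV pressure.

Gauge: pressure is anchored to zero on "far-field" reference cells, the
unmasked domain-boundary cells farthest from the mouth.  Comparisons with
analytic fields must reference both fields the same way (see
``reference_offset``).
"""
from __future__ import annotations

import heapq
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.signal import savgol_filter

from .errors import DataError, SolverError
from .grids import PhysicalParams, PressureFieldSeries, VelocityFieldSeries
from .kinematics import GapeTrace


# ---------------------------------------------------------------------------
# material acceleration
# ---------------------------------------------------------------------------

def _masked_gradient(f: np.ndarray, mask: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Spatial derivative with centred stencils, one-sided next to the mask."""
    g = np.full_like(f, np.nan)
    fm = np.where(mask, np.nan, f)
    fp = np.roll(fm, -1, axis=axis)
    fb = np.roll(fm, 1, axis=axis)
    if axis == 0:
        fp[-1, :] = np.nan
        fb[0, :] = np.nan
    else:
        fp[:, -1] = np.nan
        fb[:, 0] = np.nan
    okp, okb = np.isfinite(fp), np.isfinite(fb)
    both = okp & okb
    fwd = okp & ~okb
    bwd = ~okp & okb
    g[both] = (fp[both] - fb[both]) / (2 * h)
    g[fwd] = (fp[fwd] - fm[fwd]) / h
    g[bwd] = (fm[bwd] - fb[bwd]) / h
    g[mask] = np.nan
    return g


def material_acceleration(
    series: VelocityFieldSeries,
    smooth_window: int | None = None,
    smooth_order: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Du/Dt per frame: centred time differences (one-sided at the ends),
    centred space differences with one-sided stencils next to the mask.

    Optional Savitzky-Golay smoothing in time (odd ``smooth_window`` frames,
    polynomial ``smooth_order``) is applied to the velocity before
    differencing; useful for noisy PIV sequences.
    """
    if series.nt < 2:
        raise DataError("need at least 2 frames for a time derivative")
    if series.mask.all():
        raise DataError("all cells are masked")
    u, v = series.u, series.v
    if smooth_window is not None:
        if smooth_window % 2 == 0 or smooth_window < 3:
            raise DataError("smooth_window must be odd and >= 3")
        if series.nt > smooth_window:
            # savgol rejects NaN; masked cells are static, fill and restore
            u = savgol_filter(np.where(series.mask, 0.0, u), smooth_window,
                              smooth_order, axis=0)
            v = savgol_filter(np.where(series.mask, 0.0, v), smooth_window,
                              smooth_order, axis=0)
            u[:, series.mask] = np.nan
            v[:, series.mask] = np.nan

    dt = series.dt
    dudt = np.gradient(u, dt, axis=0)  # centred interior, one-sided ends
    dvdt = np.gradient(v, dt, axis=0)

    ax = np.empty_like(u)
    ay = np.empty_like(v)
    for k in range(series.nt):
        dudx = _masked_gradient(u[k], series.mask, series.dx, axis=1)
        dudy = _masked_gradient(u[k], series.mask, series.dy, axis=0)
        dvdx = _masked_gradient(v[k], series.mask, series.dx, axis=1)
        dvdy = _masked_gradient(v[k], series.mask, series.dy, axis=0)
        ax[k] = dudt[k] + u[k] * dudx + v[k] * dudy
        ay[k] = dvdt[k] + u[k] * dvdx + v[k] * dvdy
    return ax, ay


# ---------------------------------------------------------------------------
# gauge reference
# ---------------------------------------------------------------------------

def reference_cells(
    series_mask: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    mouth_center: tuple[float, float] | None = None,
    frac: float = 0.95,
) -> np.ndarray:
    """Unmasked domain-boundary cells farthest from the mouth (the gauge
    zero).  Returns (k, 2) row/col indices; cells whose distance from the
    mouth is at least ``frac`` of the maximum boundary distance qualify."""
    ny, nx = series_mask.shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    on_edge = (ii == 0) | (ii == ny - 1) | (jj == 0) | (jj == nx - 1)
    cand = on_edge & ~series_mask
    if not cand.any():
        raise SolverError("no unmasked boundary cell available as pressure reference")
    if mouth_center is None:
        mouth_center = (float(np.mean(x)), float(np.mean(y)))
    X, Y = np.meshgrid(x, y)
    d = np.hypot(X - mouth_center[0], Y - mouth_center[1])
    dmax = d[cand].max()
    sel = cand & (d >= frac * dmax)
    return np.argwhere(sel)


def reference_offset(p_frame: np.ndarray, ref: np.ndarray) -> float:
    """Mean pressure over the reference cells (subtract to re-gauge)."""
    vals = p_frame[ref[:, 0], ref[:, 1]]
    return float(np.nanmean(vals))


def _mouth_center_from_meta(series: VelocityFieldSeries) -> tuple[float, float] | None:
    mc = series.meta.get("mouth_center")
    return (float(mc[0]), float(mc[1])) if mc is not None else None


# ---------------------------------------------------------------------------
# Poisson (least-squares gradient matching)
# ---------------------------------------------------------------------------

def pressure_poisson(
    series: VelocityFieldSeries,
    params: PhysicalParams | None = None,
    smooth_window: int | None = None,
    smooth_order: int = 2,
    ref_frac: float = 0.95,
) -> PressureFieldSeries:
    """Reconstruct gauge pressure by the finite-volume Poisson route."""
    params = params or PhysicalParams()
    ax, ay = material_acceleration(series, smooth_window, smooth_order)
    mask = series.mask
    ny, nx = mask.shape
    ref = reference_cells(mask, series.x, series.y, _mouth_center_from_meta(series), ref_frac)

    idx = -np.ones((ny, nx), int)
    fluid = np.argwhere(~mask)
    idx[fluid[:, 0], fluid[:, 1]] = np.arange(len(fluid))

    X, Y = np.meshgrid(series.x, series.y)
    if params.geometry == "axisymmetric":
        W = params.axis_distance(X, Y)
        floor = 0.25 * min(series.dx, series.dy)
        W = np.maximum(W, floor)
    else:
        W = np.ones_like(X)

    gx = -params.density * ax
    gy = -params.density * ay

    # face structure is static (mask-defined); keep faces whose source is
    # finite in every frame so one factorization serves the whole sequence
    fin_x = np.all(np.isfinite(gx[:, :, :-1]) & np.isfinite(gx[:, :, 1:]), axis=0)
    fin_y = np.all(np.isfinite(gy[:, :-1, :]) & np.isfinite(gy[:, 1:, :]), axis=0)
    face_x = (~mask[:, :-1]) & (~mask[:, 1:]) & fin_x
    face_y = (~mask[:-1, :]) & (~mask[1:, :]) & fin_y

    fxi, fxj = np.nonzero(face_x)
    fyi, fyj = np.nonzero(face_y)
    wx = np.sqrt(0.5 * (W[fxi, fxj] + W[fxi, fxj + 1]))
    wy = np.sqrt(0.5 * (W[fyi, fyj] + W[fyi + 1, fyj]))

    n_face = len(fxi) + len(fyi)
    n_ref = len(ref)
    rows = np.repeat(np.arange(n_face), 2)
    cols = np.empty(2 * n_face, int)
    vals = np.empty(2 * n_face)
    cols[0 : 2 * len(fxi) : 2] = idx[fxi, fxj + 1]
    cols[1 : 2 * len(fxi) : 2] = idx[fxi, fxj]
    vals[0 : 2 * len(fxi) : 2] = wx / series.dx
    vals[1 : 2 * len(fxi) : 2] = -wx / series.dx
    off = 2 * len(fxi)
    cols[off::2] = idx[fyi + 1, fyj]
    cols[off + 1 :: 2] = idx[fyi, fyj]
    vals[off::2] = wy / series.dy
    vals[off + 1 :: 2] = -wy / series.dy

    # gauge anchor: one row constraining the *mean* over the reference cells
    # to zero (per-cell anchors would tilt the field wherever the true
    # far-field pressure varies along the reference region)
    wref = float(np.mean(np.concatenate([wx, wy]))) / min(series.dx, series.dy)
    rows = np.concatenate([rows, np.full(n_ref, n_face)])
    cols = np.concatenate([cols, idx[ref[:, 0], ref[:, 1]]])
    vals = np.concatenate([vals, np.full(n_ref, wref / n_ref)])
    if (cols < 0).any():
        raise SolverError("face equations touch masked cells (inconsistent mask)")

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_face + 1, len(fluid)))
    AtA = (A.T @ A).tocsc()
    try:
        lu = splu(AtA)
    except RuntimeError as exc:  # pragma: no cover - singular only if no reference
        raise SolverError(f"pressure system is singular: {exc}") from exc

    p = np.full((series.nt, ny, nx), np.nan)
    for k in range(series.nt):
        b = np.concatenate([
            wx * 0.5 * (gx[k, fxi, fxj] + gx[k, fxi, fxj + 1]),
            wy * 0.5 * (gy[k, fyi, fyj] + gy[k, fyi + 1, fyj]),
            [0.0],
        ])
        sol = lu.solve(A.T @ b)
        if not np.all(np.isfinite(sol)):
            raise SolverError(f"pressure solve produced non-finite values at frame {k}")
        p[k, fluid[:, 0], fluid[:, 1]] = sol
    return PressureFieldSeries(
        p=p, mask=mask, x=series.x, y=series.y, dt=series.dt, t0=series.t0,
        reference=f"zero mean over {n_ref} far-field boundary cells",
        reference_cells=ref,
        meta={**series.meta, "method": "poisson", "geometry": params.geometry},
    )


# ---------------------------------------------------------------------------
# multi-path integration
# ---------------------------------------------------------------------------

def pressure_multipath(
    series: VelocityFieldSeries,
    params: PhysicalParams | None = None,
    n_paths: int = 8,
    seed: int = 0,
    smooth_window: int | None = None,
    smooth_order: int = 2,
    ref_frac: float = 0.95,
) -> PressureFieldSeries:
    """Reconstruct gauge pressure as the per-cell median of staircase line
    integrals of -rho Du/Dt from the far-field reference cells.

    Each of the ``n_paths`` passes grows a random spanning tree of the fluid
    cells (randomized-priority flood fill from the reference cells), which
    realizes one axis-aligned staircase route to every reachable cell.
    Unreachable cells are flagged NaN, never silently zero.
    """
    if n_paths < 1:
        raise DataError("n_paths must be >= 1")
    params = params or PhysicalParams()
    ax, ay = material_acceleration(series, smooth_window, smooth_order)
    mask = series.mask
    ny, nx = mask.shape
    ref = reference_cells(mask, series.x, series.y, _mouth_center_from_meta(series), ref_frac)
    rng = np.random.default_rng(seed)

    p = np.full((series.nt, ny, nx), np.nan)
    for k in range(series.nt):
        gx = -params.density * ax[k] * series.dx
        gy = -params.density * ay[k] * series.dy
        acc = []
        for _ in range(n_paths):
            est = np.full((ny, nx), np.nan)
            heap: list[tuple[float, int, int]] = []
            # one root per pass; the pass is re-gauged afterwards, so the
            # root's own (unknown) absolute pressure cancels
            ri, rj = ref[rng.integers(len(ref))]
            est[ri, rj] = 0.0
            heapq.heappush(heap, (rng.random(), int(ri), int(rj)))
            while heap:
                _, i, j = heapq.heappop(heap)
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    i2, j2 = i + di, j + dj
                    if not (0 <= i2 < ny and 0 <= j2 < nx):
                        continue
                    if mask[i2, j2] or np.isfinite(est[i2, j2]):
                        continue
                    step = (
                        0.5 * (gy[i, j] + gy[i2, j2]) * di
                        if di
                        else 0.5 * (gx[i, j] + gx[i2, j2]) * dj
                    )
                    if not np.isfinite(step):
                        continue
                    est[i2, j2] = est[i, j] + step
                    heapq.heappush(heap, (rng.random(), i2, j2))
            est = est - reference_offset(est, ref)
            acc.append(est)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            p[k] = np.nanmedian(acc, axis=0)
    return PressureFieldSeries(
        p=p, mask=mask, x=series.x, y=series.y, dt=series.dt, t0=series.t0,
        reference=f"zero at {len(ref)} far-field boundary cells",
        reference_cells=ref,
        meta={**series.meta, "method": "multipath", "n_paths": n_paths},
    )


# ---------------------------------------------------------------------------
# interpolation and mouth sampling
# ---------------------------------------------------------------------------

def interp_masked(
    field: np.ndarray, x: np.ndarray, y: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Bilinear interpolation that renormalizes over finite corner values.

    ``pts`` is (k, 2) in grid coordinates; NaN where no finite corner exists
    or the point is outside the grid.
    """
    pts = np.atleast_2d(pts)
    out = np.full(len(pts), np.nan)
    dx = x[1] - x[0]
    dy = y[1] - y[0]
    fx = (pts[:, 0] - x[0]) / dx
    fy = (pts[:, 1] - y[0]) / dy
    j0 = np.floor(fx).astype(int)
    i0 = np.floor(fy).astype(int)
    inside = (j0 >= 0) & (j0 < len(x) - 1) & (i0 >= 0) & (i0 < len(y) - 1)
    for n in np.flatnonzero(inside):
        i, j = i0[n], j0[n]
        tx, ty = fx[n] - j, fy[n] - i
        corners = np.array(
            [field[i, j], field[i, j + 1], field[i + 1, j], field[i + 1, j + 1]]
        )
        w = np.array([(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty])
        ok = np.isfinite(corners)
        if not ok.any() or w[ok].sum() <= 0:
            continue
        out[n] = float(np.sum(w[ok] * corners[ok]) / np.sum(w[ok]))
    return out


def _aperture_points(gape: GapeTrace, k: int, n_samples: int) -> np.ndarray:
    """Sample points across the aperture line (perpendicular to the mouth
    axis, centred on the mouth centre, length = gape diameter)."""
    c = gape.center[k]
    d = gape.diameter[k]
    ax_ = gape.axis
    perp = np.array([-ax_[1], ax_[0]])
    if d <= 0:
        return c[None, :]
    s = np.linspace(-d / 2, d / 2, n_samples)
    return c[None, :] + s[:, None] * perp[None, :]


def pressure_at_mouth(
    pfs: PressureFieldSeries, gape: GapeTrace, n_samples: int = 9
) -> np.ndarray:
    """Gauge pressure at the mouth aperture per frame (Pa; suction < 0).

    Pressure is interpolated on the aperture line and averaged; frames whose
    aperture lies wholly in masked cells yield NaN with a warning.
    """
    nt = min(pfs.nt, len(gape.diameter))
    out = np.full(nt, np.nan)
    n_missing = 0
    for k in range(nt):
        vals = interp_masked(pfs.p[k], pfs.x, pfs.y, _aperture_points(gape, k, n_samples))
        if np.isfinite(vals).any():
            out[k] = float(np.nanmean(vals))
        else:
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"mouth centre in masked/out-of-grid cells for {n_missing} frames",
            stacklevel=2,
        )
    return out
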