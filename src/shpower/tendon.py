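"""Tendon force-length curves, elastic energy and recoil power.

Material tests give force-extension samples for the sternohyoideus tendon
complex.  The fitted curve must be physically monotone (a tendon cannot
produce less force at a larger stretch, and stored energy must be
non-negative), so the fit is isotonic-constrained: duplicate extensions
are averaged, an isotonic regression enforces monotonicity, and a
monotone piecewise-cubic (PCHIP) interpolant through the isotonic values,
anchored at F(0) = 0, gives a smooth evaluable curve.

Elastic energy between two extensions is the area under the curve; recoil
power during observed shortening of the ventral bar is

    P_t(t) = F(x(t)) * (-dx/dt),   x(t) = max(L4(t) - slack_length, 0),

clipped to zero while the tendon lengthens or is slack (a tendon cannot
push).  By construction the integral of P_t over a shortening episode
equals the stored-energy difference between its endpoint extensions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .errors import DataError


@dataclass
class TendonCurve:
    """Monotone force-extension relation F(x) on the calibration range."""

    knots_x: np.ndarray          # m, ascending, knots_x[0] == 0
    knots_f: np.ndarray          # N, non-decreasing, knots_f[0] == 0
    rms_residual_N: float
    _interp: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._interp is None:
            self._interp = PchipInterpolator(self.knots_x, self.knots_f)

    @property
    def x_max(self) -> float:
        return float(self.knots_x[-1])

    def force(self, x: np.ndarray, allow_extrapolation: bool = False) -> np.ndarray:
        x = np.asarray(x, float)
        if not allow_extrapolation and (np.any(x < -1e-12) or np.any(x > self.x_max * (1 + 1e-9))):
            raise DataError(
                f"extension outside calibration range [0, {self.x_max:.4g}] m; "
                "pass allow_extrapolation=True to override"
            )
        return self._interp(np.clip(x, 0.0, None) if allow_extrapolation else x)

    def to_dict(self) -> dict:
        return {
            "knots_x_m": self.knots_x.tolist(),
            "knots_f_N": self.knots_f.tolist(),
            "rms_residual_N": self.rms_residual_N,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TendonCurve":
        return cls(
            knots_x=np.asarray(d["knots_x_m"], float),
            knots_f=np.asarray(d["knots_f_N"], float),
            rms_residual_N=float(d["rms_residual_N"]),
        )


def fit_force_length(samples: np.ndarray, decreasing_tol: float = 0.2) -> TendonCurve:
    """Fit a monotone force-extension curve to material-test samples.

    ``samples`` is (n, 2): extension (m), force (N).  Duplicate extensions
    are averaged (so the fit is invariant to sample order), the curve is
    anchored at F(0) = 0, and a data-quality error is raised when a
    smoothed version of the raw data *decreases* over more than
    ``decreasing_tol`` of the extension range — noise cannot explain a
    sustained falling trend in a tendon test.
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise DataError("samples must be an (n, 2) array of (extension, force)")
    if samples.shape[0] < 4:
        raise DataError("need at least 4 samples to fit a force-length curve")
    if np.any(samples[:, 0] < -1e-12):
        raise DataError("extensions must be non-negative")

    order = np.argsort(samples[:, 0], kind="stable")
    x = samples[order, 0]
    f = samples[order, 1]
    # average duplicate extensions
    ux, inv = np.unique(np.round(x, 12), return_inverse=True)
    uf = np.bincount(inv, weights=f) / np.bincount(inv)

    _check_monotone_trend(ux, uf, decreasing_tol)

    iso = IsotonicRegression(y_min=0.0, increasing=True)
    fit = iso.fit_transform(ux, uf)
    rms = float(np.sqrt(np.mean((fit - uf) ** 2)))

    if ux[0] > 0:
        ux = np.concatenate([[0.0], ux])
        fit = np.concatenate([[0.0], fit])
    else:
        fit[0] = 0.0
    # PCHIP needs strictly increasing knots; collapse exact duplicates
    keep = np.concatenate([[True], np.diff(ux) > 0])
    return TendonCurve(knots_x=ux[keep], knots_f=fit[keep], rms_residual_N=rms)


def _check_monotone_trend(x: np.ndarray, f: np.ndarray, tol: float) -> None:
    if len(x) < 8:
        return
    w = max(3, len(x) // 10)
    kern = np.ones(w) / w
    sm = np.convolve(f, kern, mode="valid")
    xs = np.convolve(x, kern, mode="valid")
    dec = np.diff(sm) < 0
    if len(dec) == 0:
        return
    span = np.sum(np.diff(xs)[dec])
    if span > tol * (x[-1] - x[0]):
        raise DataError(
            "force decreases over "
            f"{100 * span / (x[-1] - x[0]):.0f}% of the extension range — "
            "not a valid tendon loading curve"
        )


def tendon_energy(
    curve: TendonCurve, x0: float, x1: float = 0.0, allow_extrapolation: bool = False
) -> float:
    """Elastic energy (J) released when recoiling from extension x0 to x1."""
    if not 0 <= x1 <= x0:
        raise DataError("require 0 <= x1 <= x0 (recoil from x0 down to x1)")
    if x0 > curve.x_max * (1 + 1e-9) and not allow_extrapolation:
        raise DataError(
            f"x0 = {x0:.4g} m beyond calibration range [0, {curve.x_max:.4g}]"
        )
    anti = curve._interp.antiderivative()
    return float(anti(x0) - anti(x1))


@dataclass
class TendonPowerResult:
    """Recoil power of the ventral-bar tendon during a strike."""

    P_t: np.ndarray              # instantaneous tendon power (W, >= 0)
    extension: np.ndarray        # x(t) = max(L4 - slack, 0) (m)
    peak_power_W: float
    mean_power_W: float          # mean over the shortening episode
    released_energy_J: float     # integral of P_t
    dt: float


def tendon_power(
    curve: TendonCurve,
    L4: np.ndarray,
    slack_length: float,
    dt: float,
    smooth_window: int | None = None,
    smooth_order: int = 2,
    allow_extrapolation: bool = False,
) -> TendonPowerResult:
    """Power released by the recoiling tendon along an observed L4(t).

    ``slack_length`` maps the digitized bar length to test-bench extension:
    x(t) = L4(t) - slack_length, clipped at zero (a slack tendon stores
    nothing).  dx/dt uses the shared smoother when a window is given,
    otherwise centred differences.
    """
    if slack_length <= 0:
        raise DataError("slack_length must be positive")
    L4 = np.asarray(L4, float)
    if len(L4) < 2:
        raise DataError("need at least 2 frames of L4")
    if slack_length >= np.nanmax(L4):
        warnings.warn(
            "slack length exceeds the minimum observed bar length: "
            "the tendon is never taut in this trace", stacklevel=2,
        )
    x = np.clip(L4 - slack_length, 0.0, None)
    if smooth_window is not None and len(x) > smooth_window:
        from scipy.signal import savgol_filter

        x = savgol_filter(x, smooth_window, smooth_order)
        x = np.clip(x, 0.0, None)
    dxdt = np.gradient(x, dt)
    F = curve.force(x, allow_extrapolation=allow_extrapolation)
    P = np.where(dxdt < 0, F * (-dxdt), 0.0)
    shortening = dxdt < 0
    tt = dt * np.arange(len(P))
    fin = np.isfinite(P)
    released = float(np.trapezoid(P[fin], tt[fin])) if fin.sum() > 1 else 0.0
    return TendonPowerResult(
        P_t=P,
        extension=x,
        peak_power_W=float(np.nanmax(P)) if fin.any() else np.nan,
        mean_power_W=float(np.nanmean(P[shortening])) if shortening.any() else 0.0,
        released_energy_J=released,
        dt=dt,
    )
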