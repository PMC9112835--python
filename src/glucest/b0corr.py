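"""WASSR-based B0 inhomogeneity estimation and CEST stack correction.

Per pixel, the water center frequency is the center of a single
Lorentzian fitted to the WASSR sweep (with a spline-interpolated argmin
fallback when the fit fails).  Correction resamples each CEST spectrum
at the nominal offsets shifted by the pixel's delta, so the water
minimum lands back at 0 ppm; offsets shifted out of the observed range
become missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from glucest.zspec import FrequencyAxis, ZStack, lorentzian, resample

#: Shifts beyond this magnitude (ppm) are considered implausible: the
#: WASSR sweep covers +/-1.5 ppm and the fit needs margin.
DEFAULT_DELTA_CAP = 1.0

METHOD_FIT = 1
METHOD_SPLINE = 2
METHOD_NAMES = {0: "missing", METHOD_FIT: "lorentzian_fit", METHOD_SPLINE: "spline_min"}


@dataclass
class B0Map:
    """Per-pixel center-frequency offset (ppm) estimated from WASSR."""

    delta: np.ndarray  # ppm; NaN where not estimable
    method: np.ndarray  # int codes, see METHOD_NAMES
    quality: np.ndarray  # per-pixel residual RMS of the estimate

    def __post_init__(self) -> None:
        if not (self.delta.shape == self.method.shape == self.quality.shape):
            raise ValueError("delta/method/quality shapes must match")

    def summary(self) -> dict:
        ok = np.isfinite(self.delta)
        return {
            "mean_abs_delta_ppm": float(np.mean(np.abs(self.delta[ok]))) if ok.any() else None,
            "max_abs_delta_ppm": float(np.max(np.abs(self.delta[ok]))) if ok.any() else None,
            "fallback_fraction": float(np.mean(self.method[ok] == METHOD_SPLINE)) if ok.any() else None,
            "n_estimated": int(ok.sum()),
        }


def _spline_argmin(offs: np.ndarray, z: np.ndarray, n_dense: int = 2001) -> float:
    spline = CubicSpline(offs, z, bc_type="natural")
    dense = np.linspace(offs[0], offs[-1], n_dense)
    return float(dense[np.argmin(spline(dense))])


def _fit_water_center(offs: np.ndarray, z: np.ndarray) -> tuple[float, float, bool]:
    """Single-Lorentzian fit; returns (center, residual_rms, ok)."""
    c0 = float(offs[np.argmin(z)])
    a0 = max(1.0 - float(np.min(z)), 1e-3)
    theta0 = np.array([1.0, a0, c0, 0.5])  # baseline, amplitude, center, fwhm

    def resid(t):
        return t[0] - t[1] * lorentzian(offs, t[2], t[3]) - z

    lower = [0.5, 0.0, offs[0], 1e-3]
    upper = [1.5, 1.5, offs[-1], 10.0 * (offs[-1] - offs[0])]
    try:
        res = least_squares(resid, np.clip(theta0, lower, upper),
                            bounds=(lower, upper), xtol=1e-12, ftol=1e-12,
                            max_nfev=400)
    except Exception:
        return np.nan, np.inf, False
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    ok = bool(res.status > 0 and np.isfinite(rms))
    return float(res.x[2]), rms, ok


def estimate_b0(wassr: ZStack, fit_residual_tol: float = 0.05) -> B0Map:
    """Estimate the per-pixel water center frequency from a WASSR stack.

    Pixels whose Lorentzian fit fails (or fits poorly, residual RMS above
    ``fit_residual_tol``) fall back to the spline-interpolated argmin and
    are flagged as such; all-missing pixels stay NaN.
    """
    h, w = wassr.shape
    delta = np.full((h, w), np.nan)
    method = np.zeros((h, w), dtype=int)
    quality = np.full((h, w), np.nan)
    offs = wassr.axis.offsets

    for i, j in zip(*np.nonzero(wassr.mask)):
        z = wassr.data[i, j] / wassr.s0[i, j]
        good = np.isfinite(z)
        if good.sum() < 4:
            continue
        o, zz = offs[good], z[good]
        center, rms, ok = _fit_water_center(o, zz)
        if ok and rms <= fit_residual_tol and o[0] <= center <= o[-1]:
            delta[i, j], method[i, j], quality[i, j] = center, METHOD_FIT, rms
        else:
            delta[i, j] = _spline_argmin(o, zz)
            method[i, j] = METHOD_SPLINE
            quality[i, j] = rms if np.isfinite(rms) else np.inf
    return B0Map(delta=delta, method=method, quality=quality)


def correct_zstack(cest: ZStack, b0: B0Map,
                   delta_cap: float = DEFAULT_DELTA_CAP) -> ZStack:
    """Shift each pixel's spectrum back onto the nominal frequency axis.

    The corrected spectrum at nominal offset d is the observed spectrum
    resampled at d + delta (cubic spline); samples falling outside the
    observed range are missing.  Pixels with |delta| > ``delta_cap`` or
    with no delta estimate are flagged unreliable and left uncorrected.
    """
    if b0.delta.shape != cest.shape:
        raise ValueError("B0 map grid does not match the CEST stack")
    out = np.array(cest.data, copy=True)
    offs = cest.axis.offsets

    for i, j in zip(*np.nonzero(cest.mask)):
        d = b0.delta[i, j]
        if not np.isfinite(d) or abs(d) > delta_cap:
            continue  # unreliable: left uncorrected
        if d == 0.0:
            continue
        spec = cest.spectrum_at(i, j)
        shifted = resample(
            spec, FrequencyAxis(offs + d, cest.axis.field_mhz))
        out[i, j] = shifted.z * cest.s0[i, j]
    return ZStack(cest.axis, out, cest.mask, cest.s0)
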