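"""Core spectral types and numerics shared by all pipeline stages.

Frequency-axis handling (ppm <-> Hz at the scanner field), Z-spectrum
normalization, multi-pool Lorentzian least-squares fitting, and
cubic-spline resampling.

Conventions
-----------
* Positive ppm offsets are downfield of water; water sits at 0 ppm.
* The nominal proton resonance frequency is 400 MHz (9.4 T), so a
  3 ppm offset maps to exactly 1200 Hz.
* Missing samples are represented as NaN and propagate as NaN; they are
  never silently zero-filled or extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

#: Nominal proton resonance frequency in MHz at 9.4 T.  The physical
#: gamma*B0 value is ~400.2 MHz; the nominal value keeps 3 ppm == 1200 Hz.
NOMINAL_FIELD_MHZ = 400.0


@dataclass(frozen=True)
class FrequencyAxis:
    """Ordered saturation offsets in ppm plus the field for Hz conversion."""

    offsets: np.ndarray
    field_mhz: float = NOMINAL_FIELD_MHZ

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", offs)
        if offs.ndim != 1 or offs.size < 1:
            raise ValueError("offsets must be a non-empty 1D array")
        if not np.all(np.diff(offs) > 0):
            raise ValueError("offsets must be strictly increasing")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def hz(self) -> np.ndarray:
        return ppm_to_hz(self.offsets, self)

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.offsets, -self.offsets[::-1], atol=tol))

    @classmethod
    def linspace(cls, start: float, stop: float, step: float,
                 field_mhz: float = NOMINAL_FIELD_MHZ) -> "FrequencyAxis":
        n = int(round((stop - start) / step)) + 1
        return cls(np.linspace(start, stop, n), field_mhz)


def cest_axis(field_mhz: float = NOMINAL_FIELD_MHZ) -> FrequencyAxis:
    """Default CEST sweep: -5..+5 ppm in 0.25 ppm steps (41 offsets)."""
    return FrequencyAxis.linspace(-5.0, 5.0, 0.25, field_mhz)


def wassr_axis(field_mhz: float = NOMINAL_FIELD_MHZ) -> FrequencyAxis:
    """Default WASSR sweep: -1.5..+1.5 ppm in 0.125 ppm steps (25 offsets)."""
    return FrequencyAxis.linspace(-1.5, 1.5, 0.125, field_mhz)


def ppm_to_hz(x: float | np.ndarray, axis: FrequencyAxis) -> float | np.ndarray:
    """Convert a ppm offset to Hz at the axis' field: Hz = ppm * field_MHz."""
    if axis.field_mhz <= 0:
        raise ValueError("field_mhz must be positive")
    return x * axis.field_mhz


def hz_to_ppm(x: float | np.ndarray, axis: FrequencyAxis) -> float | np.ndarray:
    """Inverse of :func:`ppm_to_hz`; exact round-trip."""
    if axis.field_mhz <= 0:
        raise ValueError("field_mhz must be positive")
    return x / axis.field_mhz


@dataclass
class ZSpectrum:
    """Saturated signal per offset with its unsaturated reference S0."""

    axis: FrequencyAxis
    signal: np.ndarray
    s0: float = 1.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (len(self.axis),):
            raise ValueError("signal length must match axis length")
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")

    @property
    def z(self) -> np.ndarray:
        """Normalized signal S/S0."""
        return self.signal / self.s0

    def normalized(self) -> "ZSpectrum":
        """Return a copy with S0 folded into the signal (idempotent)."""
        return ZSpectrum(self.axis, self.signal / self.s0, 1.0)


@dataclass
class ZStack:
    """Per-pixel Z-spectra over a 2D grid with a shared frequency axis.

    ``data`` has shape (H, W, n_offsets); pixels outside ``mask`` hold NaN.
    """

    axis: FrequencyAxis
    data: np.ndarray
    mask: np.ndarray
    s0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (H, W, n_offsets)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError("third dimension must match axis length")
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match data grid")
        if self.s0 is None:
            self.s0 = np.ones(self.mask.shape)
        else:
            self.s0 = np.asarray(self.s0, dtype=float)
            if self.s0.shape != self.mask.shape:
                raise ValueError("s0 shape must match data grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def spectrum_at(self, i: int, j: int) -> ZSpectrum:
        return ZSpectrum(self.axis, self.data[i, j], float(self.s0[i, j]))


def lorentzian(x: np.ndarray | float, center: float, fwhm: float) -> np.ndarray | float:
    """Unit-peak Lorentzian: L = (w/2)^2 / ((w/2)^2 + (x - c)^2)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    hw2 = (fwhm / 2.0) ** 2
    return hw2 / (hw2 + np.square(np.asarray(x, dtype=float) - center))


@dataclass
class LorentzianFit:
    """Result of a bounded multi-pool Lorentzian least-squares fit."""

    pools: list  # list[PoolParams]; imported lazily to avoid a cycle
    baseline: float
    residual_rms: float
    converged: bool

    def model(self, x: np.ndarray) -> np.ndarray:
        out = np.full_like(np.asarray(x, dtype=float), self.baseline)
        for p in self.pools:
            out = out - p.amplitude * lorentzian(x, p.center, p.fwhm)
        return out


def _pack(pools, baseline: float) -> np.ndarray:
    theta = [baseline]
    for p in pools:
        theta.extend([p.amplitude, p.center, p.fwhm])
    return np.asarray(theta, dtype=float)


def _unpack(theta: np.ndarray):
    from glucest.phantom import PoolParams

    baseline = float(theta[0])
    pools = []
    for k in range((len(theta) - 1) // 3):
        a, c, w = theta[1 + 3 * k: 4 + 3 * k]
        pools.append(PoolParams(name=f"pool{k}", center=float(c),
                                fwhm=float(w), amplitude=float(a)))
    return pools, baseline


# Default starting points per pool count: (amplitude, center ppm, fwhm ppm).
# Documented constants; centers follow the conventional water / amide /
# glutamate / NOE / MT assignment.
_DEFAULT_INITS: dict[int, list[tuple[float, float, float]]] = {
    1: [(0.5, 0.0, 1.0)],
    2: [(0.8, 0.0, 2.0), (0.05, 3.0, 1.0)],
    3: [(0.8, 0.0, 2.0), (0.03, 3.0, 1.0), (0.03, -3.5, 1.0)],
    4: [(0.8, 0.0, 2.0), (0.02, 3.5, 1.0), (0.03, 3.0, 1.0), (0.02, -3.5, 1.0)],
    5: [(0.8, 0.0, 2.0), (0.02, 3.5, 1.0), (0.03, 3.0, 1.0), (0.02, -3.5, 1.0),
        (0.05, 0.0, 20.0)],
}


def fit_lorentzian(spec: ZSpectrum, n_pools: int = 1,
                   init: Sequence | None = None) -> LorentzianFit:
    """Fit Z(d) = baseline - sum_i A_i * L(d; c_i, w_i) by bounded least squares.

    Deterministic: a fixed default initialization (plus an argmin-centered
    variant for single pools) is tried and the lowest-residual solution
    wins.  Non-convergence is reported via ``converged=False``; no
    exception is raised for it.
    """
    offs = spec.axis.offsets
    z = spec.z
    good = np.isfinite(z)
    offs, z = offs[good], z[good]
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    if offs.size < 3 * n_pools + 1:
        raise ValueError(
            f"need >= {3 * n_pools + 1} finite samples for {n_pools} pools, "
            f"got {offs.size}")
    if np.ptp(offs) <= 0:
        raise ValueError("degenerate frequency axis")

    span = float(offs[-1] - offs[0])
    lo_c, hi_c = float(offs[0]) - 0.5, float(offs[-1]) + 0.5
    # per-pool bounds: amplitude, center, fwhm; baseline first
    lower = [0.0] + [0.0, lo_c, 1e-3] * n_pools
    upper = [2.0] + [1.5, hi_c, 10.0 * span] * n_pools

    starts: list[np.ndarray] = []
    if init is not None:
        if len(init) != n_pools:
            raise ValueError("init must supply one PoolParams per pool")
        starts.append(_pack(init, 1.0))
    else:
        from glucest.phantom import PoolParams

        base = _DEFAULT_INITS.get(n_pools)
        if base is not None:
            starts.append(_pack(
                [PoolParams("init", c, w, a) for a, c, w in base], 1.0))
        # argmin-centered start: put the first pool at the deepest dip
        c_min = float(offs[np.argmin(z)])
        guesses = [(max(1.0 - float(np.min(z)), 1e-3), c_min, span / 8.0)]
        guesses += [(0.05, lo_c + (k + 1) * span / (n_pools + 1), span / 8.0)
                    for k in range(n_pools - 1)]
        starts.append(_pack(
            [PoolParams("init", c, w, a) for a, c, w in guesses], 1.0))

    def resid(theta: np.ndarray) -> np.ndarray:
        pools, baseline = _unpack(theta)
        model = np.full_like(offs, baseline)
        for p in pools:
            model = model - p.amplitude * lorentzian(offs, p.center, p.fwhm)
        return model - z

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lower, upper)
        try:
            res = least_squares(resid, theta0, bounds=(lower, upper),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return LorentzianFit([], 1.0, float("inf"), False)

    pools, baseline = _unpack(best.x)
    rms = float(np.sqrt(np.mean(np.square(resid(best.x)))))
    converged = bool(best.status > 0 and np.isfinite(rms))
    return LorentzianFit(pools, baseline, rms, converged)


def resample(spec: ZSpectrum, new_axis: FrequencyAxis) -> ZSpectrum:
    """Resample onto ``new_axis`` with a natural cubic spline.

    Offsets outside the observed range come back as NaN (missing), never
    extrapolated.  NaN input samples are dropped before fitting the
    spline; at least 4 finite samples are required.
    """
    offs = spec.axis.offsets
    z = spec.z
    good = np.isfinite(z)
    offs, z = offs[good], z[good]
    if offs.size < 4:
        raise ValueError("resample requires >= 4 finite samples")
    spline = CubicSpline(offs, z, bc_type="natural")
    new = np.asarray(new_axis.offsets, dtype=float)
    out = np.full(new.shape, np.nan)
    inside = (new >= offs[0]) & (new <= offs[-1])
    out[inside] = spline(new[inside])
    return ZSpectrum(new_axis, out * spec.s0, spec.s0)
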