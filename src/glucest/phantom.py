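"""Seeded synthetic CEST/WASSR acquisitions over a mouse-brain-like phantom.

The signal model is a sum of unit-peak Lorentzians (water ~0 ppm, amide
+3.5 ppm, glutamate +3.0 ppm, NOE -3.5 ppm, broad MT), not full
Bloch-McConnell: saturation power is absorbed into the pool amplitudes,
and Lorentzian sums admit closed-form asymmetry oracles used throughout
the test suite.  Noise is additive Gaussian on the normalized signal;
the B0 field is a seeded low-order 2D polynomial scaled to a peak
amplitude.  Every output is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from glucest.zspec import (
    FrequencyAxis,
    ZSpectrum,
    ZStack,
    cest_axis,
    lorentzian,
    wassr_axis,
)

#: ROI label identities, top-to-bottom placement order.
ROI_NAMES = ("cortex", "corpus_callosum", "hippocampus", "caudate", "subiculum")

#: Glutamate readout offset, ppm (1200 Hz at the nominal 400 MHz field).
GLU_OFFSET_PPM = 3.0


@dataclass(frozen=True)
class PoolParams:
    """One Lorentzian saturation pool."""

    name: str
    center: float  # ppm
    fwhm: float  # ppm
    amplitude: float  # dimensionless saturation depth in [0, 1]

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


# Fixed non-glutamate pools shared by every cohort.  The slight
# amide/NOE amplitude imbalance leaves a small non-zero asymmetry
# baseline at +3 ppm, which the calibration step must account for.
DEFAULT_POOLS: tuple[PoolParams, ...] = (
    PoolParams("water", 0.0, 2.0, 0.80),
    PoolParams("amide", 3.5, 1.0, 0.012),
    PoolParams("noe", -3.5, 1.0, 0.010),
    PoolParams("mt", 0.0, 20.0, 0.05),
)

GLU_CENTER = GLU_OFFSET_PPM
GLU_FWHM = 1.0

#: Direct water saturation pool used for the low-power WASSR sweep.
#: fwhm wide enough that cubic-spline interpolation on the 0.125 ppm
#: grid localizes the minimum to < 1e-3 ppm.
WASSR_POOL = PoolParams("water_wassr", 0.0, 1.0, 0.90)

#: Default per-ROI glutamate contrast targets (dimensionless MTRasym at
#: 3 ppm) keyed by (genotype, age_group in months).  Order: cortex,
#: corpus callosum, hippocampus, caudate, subiculum.
DEFAULT_ROI_TARGETS: dict[tuple[str, int], tuple[float, ...]] = {
    ("AD", 2): (0.02162, 0.02178, 0.02227, 0.02478, 0.01743),
    ("WT", 2): (0.01768, 0.01368, 0.01704, 0.01326, 0.01042),
    ("AD", 4): (0.02195, 0.02016, 0.02011, 0.02013, 0.01511),
    ("WT", 4): (0.01419, 0.01266, 0.01573, 0.01517, 0.01511),
    ("AD", 7): (0.03170, 0.03130, 0.03461, 0.03805, 0.03186),
    ("WT", 7): (0.02540, 0.02442, 0.02376, 0.03434, 0.02833),
    ("AD", 12): (0.03232, 0.03044, 0.03130, 0.03171, 0.02998),
    ("WT", 12): (0.02730, 0.02767, 0.02860, 0.02545, 0.01972),
}

#: Default number of subjects per (genotype, age_group) cell.
DEFAULT_COHORT_SIZES: dict[tuple[str, int], int] = {
    ("AD", 2): 4, ("WT", 2): 5,
    ("AD", 4): 10, ("WT", 4): 11,
    ("AD", 7): 3, ("WT", 7): 2,
    ("AD", 12): 4, ("WT", 12): 10,
}

AGE_GROUPS = (2, 4, 7, 12)
GENOTYPES = ("AD", "WT")


@dataclass
class LabelMap:
    """Integer ROI label image over an elliptical brain mask.

    ``grid`` holds 0 for background and 1..5 for the ROIs (top to
    bottom: cortex, corpus callosum, hippocampus, caudate, subiculum);
    ``brain`` marks all in-brain pixels including unlabeled parenchyma.
    """

    grid: np.ndarray
    brain: np.ndarray
    fov_mm: float = 16.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.brain = np.asarray(self.brain, dtype=bool)
        if self.grid.shape != self.brain.shape:
            raise ValueError("grid and brain mask shapes differ")
        labels = set(np.unique(self.grid)) - {0}
        if labels != {1, 2, 3, 4, 5}:
            raise ValueError(f"expected ROI labels 1..5, found {sorted(labels)}")
        for lab in range(1, 6):
            if np.count_nonzero(self.grid == lab) < 20:
                raise ValueError(f"ROI {lab} occupies fewer than 20 pixels")
        if not np.any(self.grid == 0):
            raise ValueError("background must exist")
        if np.any((self.grid > 0) & ~self.brain):
            raise ValueError("ROI pixels must lie inside the brain mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def roi_mask(self, label: int) -> np.ndarray:
        return self.grid == label


@dataclass(frozen=True)
class CohortSpec:
    """Specification for one genotype x age-group phantom cohort."""

    genotype: str
    age_group: int
    n_subjects: int
    glu_targets: tuple[float, ...]
    noise_sigma: float = 0.0
    b0_amplitude: float = 0.0
    seed: int = 0
    label_seed: int = 0
    shape: tuple[int, int] = (100, 100)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if len(self.glu_targets) != 5:
            raise ValueError("glu_targets must have exactly 5 entries")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.b0_amplitude < 0:
            raise ValueError("b0_amplitude must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @classmethod
    def from_defaults(cls, genotype: str, age_group: int, **kwargs) -> "CohortSpec":
        """Cohort with the default ROI targets and subject count for a cell."""
        if (genotype, age_group) not in DEFAULT_ROI_TARGETS:
            raise ValueError(f"no default cohort cell ({genotype}, {age_group})")
        kwargs.setdefault("n_subjects", DEFAULT_COHORT_SIZES[(genotype, age_group)])
        return cls(genotype=genotype, age_group=age_group,
                   glu_targets=DEFAULT_ROI_TARGETS[(genotype, age_group)],
                   **kwargs)


@dataclass
class GroundTruth:
    """Known truth behind one simulated subject."""

    glu_amplitude_map: np.ndarray  # per-pixel glutamate pool amplitude
    b0_field: np.ndarray  # per-pixel true center-frequency offset, ppm
    labels: LabelMap
    cohort: CohortSpec

    def __post_init__(self) -> None:
        if self.glu_amplitude_map.shape != self.labels.shape:
            raise ValueError("glu_amplitude_map shape mismatch")
        if self.b0_field.shape != self.labels.shape:
            raise ValueError("b0_field shape mismatch")


class SubjectAcquisition(NamedTuple):
    cest: ZStack
    wassr: ZStack
    truth: GroundTruth
    subject_id: str


def make_label_map(seed: int, shape: tuple[int, int] = (100, 100)) -> LabelMap:
    """Deterministic 5-ROI label map inside an elliptical brain mask.

    ROIs are ellipses stacked top-to-bottom with small seeded jitter.
    Raises if the grid is too small to place all five ROIs.
    """
    h, w = shape
    if h < 32 or w < 32:
        raise ValueError("shape must be at least 32x32 to place 5 ROIs")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.44 * h, 0.36 * w
    brain = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    grid = np.zeros(shape, dtype=int)
    # (vertical position as fraction of brain semi-height, semi-height frac,
    #  semi-width frac) per ROI, top to bottom
    layout = [
        (-0.62, 0.16, 0.60),   # cortex
        (-0.28, 0.09, 0.55),   # corpus callosum
        (0.00, 0.14, 0.45),    # hippocampus
        (0.30, 0.15, 0.40),    # caudate
        (0.62, 0.12, 0.33),    # subiculum
    ]
    for lab, (fy, fh, fw) in enumerate(layout, start=1):
        jy = rng.uniform(-0.02, 0.02) * ay
        jx = rng.uniform(-0.02, 0.02) * ax
        ry = max(fh * ay, 1.6)
        rx = max(fw * ax, 3.0)
        ell = (((yy - (cy + fy * ay + jy)) / ry) ** 2
               + ((xx - (cx + jx)) / rx) ** 2) <= 1.0
        grid[ell & brain & (grid == 0)] = lab

    for lab in range(1, 6):
        if np.count_nonzero(grid == lab) < 20:
            raise ValueError(
                f"shape {shape} too small: ROI {lab} has < 20 pixels")
    return LabelMap(grid=grid, brain=brain)


def _z_model(pools: Sequence[PoolParams], offsets: np.ndarray,
             b0_shift: float | np.ndarray = 0.0) -> np.ndarray:
    z = np.ones_like(offsets, dtype=float)
    for p in pools:
        z = z - p.amplitude * lorentzian(offsets - b0_shift, p.center, p.fwhm)
    return z


def simulate_zspectrum(pools: Sequence[PoolParams], axis: FrequencyAxis | None = None,
                       b0_shift: float = 0.0) -> ZSpectrum:
    """Noiseless Z-spectrum: Z(d) = 1 - sum_i A_i * L(d - b0; c_i, w_i)."""
    if axis is None:
        axis = cest_axis()
    z = _z_model(pools, axis.offsets, b0_shift)
    if np.min(z) < 0:
        raise ValueError("pool amplitudes drive Z below 0")
    return ZSpectrum(axis, z, s0=1.0)


def simulate_wassr(b0_shift: float = 0.0, axis: FrequencyAxis | None = None,
                   pool: PoolParams = WASSR_POOL) -> ZSpectrum:
    """Low-power direct-saturation sweep: single water Lorentzian at b0_shift."""
    if axis is None:
        axis = wassr_axis()
    if not (axis.offsets[0] <= b0_shift <= axis.offsets[-1]):
        raise ValueError(
            f"b0_shift {b0_shift} ppm outside WASSR axis range; "
            "center frequency not observable")
    return simulate_zspectrum([pool], axis, b0_shift)


def analytic_mtrasym(pools: Sequence[PoolParams], offset: float = GLU_OFFSET_PPM,
                     ) -> float:
    """Closed-form noiseless MTRasym at +offset for a Lorentzian-sum model."""
    s_neg = _z_model(pools, np.asarray(-offset))
    s_pos = _z_model(pools, np.asarray(offset))
    return float(s_neg - s_pos)


def calibrate_glu_amplitude(target_mtrasym: float,
                            other_pools: Sequence[PoolParams] = DEFAULT_POOLS,
                            axis: FrequencyAxis | None = None,
                            glu_center: float = GLU_CENTER,
                            glu_fwhm: float = GLU_FWHM) -> float:
    """Glutamate amplitude whose analytic MTRasym at 3 ppm equals the target.

    The asymmetry is linear in the glutamate amplitude, so the solve is
    exact: A = (target - baseline_asym) / (L(+3) - L(-3)).
    """
    if target_mtrasym < 0:
        raise ValueError("target must be >= 0")
    if axis is None:
        axis = cest_axis()
    baseline = analytic_mtrasym(other_pools)
    gain = (lorentzian(GLU_OFFSET_PPM, glu_center, glu_fwhm)
            - lorentzian(-GLU_OFFSET_PPM, glu_center, glu_fwhm))
    if gain <= 0:
        raise ValueError("glutamate pool contributes no positive asymmetry")
    amp = (target_mtrasym - baseline) / gain
    if amp < 0:
        raise ValueError(
            f"target {target_mtrasym} below the fixed-pool asymmetry baseline "
            f"{baseline:.6f}; not reachable with a non-negative amplitude")
    pools = list(other_pools) + [PoolParams("glutamate", glu_center, glu_fwhm, amp)]
    z = _z_model(pools, axis.offsets)
    if np.min(z) < 0 or np.max(z) > 1:
        raise ValueError("calibrated amplitude drives Z outside [0, 1]")
    return float(amp)


def smooth_b0_field(shape: tuple[int, int], amplitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Seeded smooth field: low-order 2D polynomial scaled to peak |amplitude|."""
    h, w = shape
    if amplitude == 0:
        # consume the same random draws so fields with/without B0 share seeds
        rng.standard_normal(6)
        return np.zeros(shape)
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    c = rng.standard_normal(6)
    field = (c[0] + c[1] * x + c[2] * y + c[3] * x * y
             + c[4] * x ** 2 + c[5] * y ** 2)
    peak = np.max(np.abs(field))
    return field * (amplitude / peak)


def build_glu_amplitude_map(labels: LabelMap, glu_targets: Sequence[float],
                            other_pools: Sequence[PoolParams] = DEFAULT_POOLS,
                            ) -> np.ndarray:
    """Per-pixel glutamate amplitude: ROI pixels hit their calibration
    target exactly; unlabeled parenchyma gets the mean-target amplitude."""
    amp_map = np.zeros(labels.shape)
    for lab, target in enumerate(glu_targets, start=1):
        amp_map[labels.roi_mask(lab)] = calibrate_glu_amplitude(
            target, other_pools)
    parenchyma = labels.brain & (labels.grid == 0)
    amp_map[parenchyma] = calibrate_glu_amplitude(
        float(np.mean(glu_targets)), other_pools)
    return amp_map


def _simulate_stack(offsets: np.ndarray, pools: Sequence[PoolParams],
                    amp_map: np.ndarray | None, b0_field: np.ndarray,
                    mask: np.ndarray, sigma: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorized per-pixel Z-stack; NaN outside the mask."""
    shifted = offsets[None, None, :] - b0_field[:, :, None]
    z = np.ones(shifted.shape)
    for p in pools:
        z -= p.amplitude * lorentzian(shifted, p.center, p.fwhm)
    if amp_map is not None:
        z -= amp_map[:, :, None] * lorentzian(shifted, GLU_CENTER, GLU_FWHM)
    if np.nanmin(z[mask]) < 0:
        raise ValueError("pool amplitudes drive Z below 0")
    if sigma > 0:
        z = z + sigma * rng.standard_normal(z.shape)
    z[~mask] = np.nan
    return z


def generate_subject(spec: CohortSpec, labels: LabelMap, subject_idx: int,
                     cest_ax: FrequencyAxis, wassr_ax: FrequencyAxis,
                     ) -> SubjectAcquisition:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_idx]))
    b0 = smooth_b0_field(labels.shape, spec.b0_amplitude, rng)
    amp_map = build_glu_amplitude_map(labels, spec.glu_targets)
    cest = _simulate_stack(cest_ax.offsets, DEFAULT_POOLS, amp_map, b0,
                           labels.brain, spec.noise_sigma, rng)
    wassr = _simulate_stack(wassr_ax.offsets, [WASSR_POOL], None, b0,
                            labels.brain, spec.noise_sigma, rng)
    truth = GroundTruth(glu_amplitude_map=amp_map, b0_field=b0,
                        labels=labels, cohort=spec)
    sid = f"{spec.genotype}_{spec.age_group}m_s{subject_idx:02d}"
    return SubjectAcquisition(
        cest=ZStack(cest_ax, cest, labels.brain),
        wassr=ZStack(wassr_ax, wassr, labels.brain),
        truth=truth, subject_id=sid)


def generate_cohort(spec: CohortSpec) -> list[SubjectAcquisition]:
    """Simulate every subject of a cohort; reproducible from the spec alone."""
    labels = make_label_map(spec.label_seed, spec.shape)
    cest_ax, wassr_ax = cest_axis(), wassr_axis()
    return [generate_subject(spec, labels, i, cest_ax, wassr_ax)
            for i in range(spec.n_subjects)]
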