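"""MTRasym computation, glutamate maps, and ROI group statistics.

MTRasym(d) = (S(-d) - S(d)) / S0 for each positive offset d that has a
sampled counterpart at -d.  The glutamate readout sits at +3 ppm
(1200 Hz at the nominal field).  ROI cell means average per-subject ROI
means (subjects weighted equally, not pixels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from glucest.phantom import AGE_GROUPS, GENOTYPES, GLU_OFFSET_PPM, LabelMap
from glucest.zspec import FrequencyAxis, ZSpectrum, ZStack, hz_to_ppm

_PAIR_TOL = 1e-9


@dataclass
class AsymCurve:
    """MTRasym per positive offset; NaN where a +/- pair is missing."""

    offsets: np.ndarray  # positive ppm
    value: np.ndarray
    axis: FrequencyAxis | None = None

    def at(self, offset_ppm: float) -> float:
        idx = np.argmin(np.abs(self.offsets - offset_ppm))
        if abs(self.offsets[idx] - offset_ppm) > _PAIR_TOL:
            raise KeyError(f"offset {offset_ppm} ppm not sampled")
        return float(self.value[idx])

    def at_hz(self, offset_hz: float) -> float:
        if self.axis is None:
            raise ValueError("curve carries no field information")
        return self.at(float(hz_to_ppm(offset_hz, self.axis)))


@dataclass
class GluMap:
    """Per-pixel MTRasym at the glutamate readout offset."""

    values: np.ndarray  # dimensionless; NaN outside mask
    mask: np.ndarray
    readout_ppm: float = GLU_OFFSET_PPM
    subject_id: str | None = None
    genotype: str | None = None
    age_group: int | None = None
    harmonized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def in_mask_mean(self) -> float:
        vals = self.values[self.mask]
        return float(np.nanmean(vals))

    def roi_mean(self, labels: LabelMap, roi: int) -> float:
        return float(np.nanmean(self.values[labels.roi_mask(roi)]))


def mtrasym_curve(spec: ZSpectrum) -> AsymCurve:
    """Asymmetry curve of one spectrum: value(d) = (S(-d) - S(d)) / S0."""
    offs = spec.axis.offsets
    z = spec.z
    pos = offs[offs > _PAIR_TOL]
    if pos.size == 0:
        raise ValueError("axis has no positive offsets")
    values = np.full(pos.shape, np.nan)
    matched = 0
    for k, d in enumerate(pos):
        i_pos = np.argmin(np.abs(offs - d))
        i_neg = np.argmin(np.abs(offs + d))
        if abs(offs[i_neg] + d) > _PAIR_TOL:
            continue
        matched += 1
        values[k] = z[i_neg] - z[i_pos]
    if matched == 0:
        raise ValueError("no symmetric +/- offset pairs on this axis")
    return AsymCurve(offsets=pos, value=values, axis=spec.axis)


def glucest_map(cest_corrected: ZStack, readout_ppm: float = GLU_OFFSET_PPM,
                **meta) -> GluMap:
    """Per-pixel MTRasym at the readout offset over a (corrected) stack.

    Pixels missing either the +readout or -readout sample are NaN.
    """
    offs = cest_corrected.axis.offsets
    i_pos = int(np.argmin(np.abs(offs - readout_ppm)))
    i_neg = int(np.argmin(np.abs(offs + readout_ppm)))
    if abs(offs[i_pos] - readout_ppm) > _PAIR_TOL or \
            abs(offs[i_neg] + readout_ppm) > _PAIR_TOL:
        raise ValueError(f"axis does not sample +/-{readout_ppm} ppm")
    z_pos = cest_corrected.data[:, :, i_pos] / cest_corrected.s0
    z_neg = cest_corrected.data[:, :, i_neg] / cest_corrected.s0
    values = z_neg - z_pos
    values[~cest_corrected.mask] = np.nan
    return GluMap(values=values, mask=cest_corrected.mask,
                  readout_ppm=readout_ppm, **meta)


def roi_group_table(maps: Sequence[GluMap], labels: LabelMap) -> pd.DataFrame:
    """Per-ROI group means: rows ROI1..5, columns (age_group, genotype).

    Each cell is the mean over subjects of the per-subject ROI-pixel
    mean; empty cells are NaN, never zero.  Mirrors the layout of the
    per-ROI glutamate content table (age-major, AD before WT).
    """
    per_subject: dict[tuple[int, str], list[list[float]]] = {}
    for m in maps:
        if m.genotype is None or m.age_group is None:
            raise ValueError("maps must carry genotype and age_group metadata")
        key = (m.age_group, m.genotype)
        per_subject.setdefault(key, []).append(
            [m.roi_mean(labels, roi) for roi in range(1, 6)])

    cols = pd.MultiIndex.from_tuples(
        [(age, gt) for age in AGE_GROUPS for gt in GENOTYPES],
        names=["age_group", "genotype"])
    table = pd.DataFrame(np.nan, index=[f"ROI{r}" for r in range(1, 6)],
                         columns=cols)
    counts = pd.Series(0, index=cols)
    for key, rows in per_subject.items():
        if key not in table.columns:
            continue
        table[key] = np.mean(np.asarray(rows), axis=0)
        counts[key] = len(rows)
    table.attrs["n_subjects"] = counts.to_dict()
    return table


def age_trend_report(table: pd.DataFrame,
                     young_ages: Sequence[int] = (2, 4),
                     old_ages: Sequence[int] = (7, 12)) -> pd.DataFrame:
    """Signed per-ROI contrasts: old-minus-young within genotype and
    AD-minus-WT within age group."""
    ages = sorted({a for a, _ in table.columns})
    if len(ages) < 2:
        raise ValueError("need at least two age groups")
    rows = []
    for roi in table.index:
        for gt in GENOTYPES:
            old = np.nanmean([table.loc[roi, (a, gt)] for a in old_ages
                              if (a, gt) in table.columns])
            young = np.nanmean([table.loc[roi, (a, gt)] for a in young_ages
                                if (a, gt) in table.columns])
            rows.append({"roi": roi, "comparison": f"old_minus_young_{gt}",
                         "difference": old - young})
        for age in ages:
            if (age, "AD") in table.columns and (age, "WT") in table.columns:
                rows.append({
                    "roi": roi, "comparison": f"AD_minus_WT_{age}m",
                    "difference": table.loc[roi, (age, "AD")]
                    - table.loc[roi, (age, "WT")]})
    return pd.DataFrame(rows)
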