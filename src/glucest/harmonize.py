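"""Age-based data-offset harmonization and image augmentation.

Glutamate maps rise with age regardless of genotype, so young-age maps
(2/4 months) are shifted up by a cohort-derived additive delta before
classification; old-age maps (7/12 months) are never modified.  The
delta is estimated from training subjects only.

The offset is additive by default (group means differ by a level shift);
a multiplicative variant is available via ``mode="multiplicative"``.
Scope defaults to ``pooled`` across genotypes — estimating per genotype
would leak the class label into test data and is allowed only with an
explicit opt-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from glucest.asym import GluMap

YOUNG_AGES = frozenset({2, 4})
OLD_AGES = frozenset({7, 12})


@dataclass(frozen=True)
class OffsetModel:
    """Fitted young-to-old level shift in MTRasym units."""

    delta: float | dict[str, float]
    scope: str  # "pooled" | "per_genotype"
    mode: str  # "additive" | "multiplicative"
    fit_subjects: tuple[str, ...]
    young_ages: frozenset[int] = YOUNG_AGES
    old_ages: frozenset[int] = OLD_AGES

    def delta_for(self, genotype: str | None) -> float:
        if self.scope == "pooled":
            return self.delta  # type: ignore[return-value]
        if genotype is None:
            raise ValueError("per-genotype model needs a genotype")
        return self.delta[genotype]  # type: ignore[index]


@dataclass
class AugmentedSet:
    """Augmented 2D images with full provenance and preserved labels."""

    images: list[np.ndarray]
    provenance: list[dict]
    labels: list[str]

    def __len__(self) -> int:
        return len(self.images)


def _age_class_means(maps: Sequence[GluMap], young_ages, old_ages,
                     genotype: str | None = None):
    young = [m.in_mask_mean() for m in maps
             if m.age_group in young_ages
             and (genotype is None or m.genotype == genotype)]
    old = [m.in_mask_mean() for m in maps
           if m.age_group in old_ages
           and (genotype is None or m.genotype == genotype)]
    if not young or not old:
        raise ValueError(
            "training set must contain both young and old age classes"
            + (f" for genotype {genotype}" if genotype else ""))
    return float(np.mean(young)), float(np.mean(old))


def fit_offset(train_maps: Sequence[GluMap], scope: str = "pooled",
               mode: str = "additive",
               young_ages: Sequence[int] = (2, 4),
               old_ages: Sequence[int] = (7, 12)) -> OffsetModel:
    """Estimate the young-to-old shift from training maps' in-mask means.

    additive: delta = mean(old) - mean(young);
    multiplicative: delta = mean(old) / mean(young).
    """
    if scope not in ("pooled", "per_genotype"):
        raise ValueError("scope must be 'pooled' or 'per_genotype'")
    if mode not in ("additive", "multiplicative"):
        raise ValueError("mode must be 'additive' or 'multiplicative'")
    ya, oa = frozenset(young_ages), frozenset(old_ages)
    fit_ids = tuple(m.subject_id or f"map{k}" for k, m in enumerate(train_maps))

    def one_delta(genotype=None):
        young, old = _age_class_means(train_maps, ya, oa, genotype)
        return old - young if mode == "additive" else old / young

    if scope == "pooled":
        delta: float | dict = one_delta()
    else:
        warnings.warn(
            "per-genotype offsets use the class label during harmonization; "
            "do not apply to held-out data", stacklevel=2)
        genotypes = sorted({m.genotype for m in train_maps if m.genotype})
        delta = {gt: one_delta(gt) for gt in genotypes}
    return OffsetModel(delta=delta, scope=scope, mode=mode,
                       fit_subjects=fit_ids, young_ages=ya, old_ages=oa)


def apply_offset(glu_map: GluMap, model: OffsetModel,
                 age_group: int | None = None) -> GluMap:
    """Shift a young-age map by the fitted delta; old-age maps pass through.

    Refuses to harmonize twice (``harmonized`` provenance flag).
    """
    age = age_group if age_group is not None else glu_map.age_group
    if age is None:
        raise ValueError("age_group required to apply the offset")
    if age in model.old_ages:
        return glu_map
    if age not in model.young_ages:
        raise ValueError(f"age group {age} is neither young nor old in this model")
    if glu_map.harmonized:
        raise ValueError(
            f"map {glu_map.subject_id!r} already harmonized; refusing to "
            "apply the offset twice")
    d = model.delta_for(glu_map.genotype)
    values = np.array(glu_map.values, copy=True)
    if model.mode == "additive":
        values[glu_map.mask] = values[glu_map.mask] + d
    else:
        values[glu_map.mask] = values[glu_map.mask] * d
    return GluMap(values=values, mask=glu_map.mask,
                  readout_ppm=glu_map.readout_ppm,
                  subject_id=glu_map.subject_id, genotype=glu_map.genotype,
                  age_group=glu_map.age_group, harmonized=True)


# augmentation ---------------------------------------------------------------

_MAX_SHIFT_FRAC = 0.08
_MAX_ROT_DEG = 15.0
_MIN_CROP_FRAC = 0.80


def _random_transform(img: np.ndarray, rng: np.random.Generator):
    """One seeded translation / rotation / crop; crops are resized back."""
    kind = rng.choice(["translate", "rotate", "crop"])
    h, w = img.shape
    if kind == "translate":
        dy = int(rng.integers(-round(_MAX_SHIFT_FRAC * h),
                              round(_MAX_SHIFT_FRAC * h) + 1))
        dx = int(rng.integers(-round(_MAX_SHIFT_FRAC * w),
                              round(_MAX_SHIFT_FRAC * w) + 1))
        out = ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
        desc = {"kind": "translate", "dy": dy, "dx": dx}
    elif kind == "rotate":
        angle = float(rng.uniform(-_MAX_ROT_DEG, _MAX_ROT_DEG))
        out = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="constant", cval=0.0)
        desc = {"kind": "rotate", "angle_deg": angle}
    else:
        frac = float(rng.uniform(_MIN_CROP_FRAC, 1.0))
        ch, cw = max(int(frac * h), 4), max(int(frac * w), 4)
        if ch > h or cw > w:  # cannot happen with frac <= 1; guard anyway
            raise ValueError("crop exceeds image")
        y0 = int(rng.integers(0, h - ch + 1))
        x0 = int(rng.integers(0, w - cw + 1))
        out = resize(img[y0:y0 + ch, x0:x0 + cw], (h, w), order=1,
                     mode="constant", anti_aliasing=False)
        desc = {"kind": "crop", "y0": y0, "x0": x0, "height": ch, "width": cw}
    return out, desc


def augment(images: Sequence[np.ndarray], labels: Sequence[str],
            source_ids: Sequence[str], n_per_image: int,
            seed: int) -> AugmentedSet:
    """Seeded augmentation: each input yields itself plus ``n_per_image``
    transformed copies.  Genotype labels are always preserved."""
    if n_per_image < 0:
        raise ValueError("n_per_image must be >= 0")
    if not (len(images) == len(labels) == len(source_ids)):
        raise ValueError("images, labels and source_ids must align")
    rng = np.random.default_rng(seed)
    out_images: list[np.ndarray] = []
    out_prov: list[dict] = []
    out_labels: list[str] = []
    for img, lab, sid in zip(images, labels, source_ids):
        arr = np.nan_to_num(np.asarray(img, dtype=float), nan=0.0)
        out_images.append(arr)
        out_prov.append({"source": sid, "transform": {"kind": "identity"}})
        out_labels.append(lab)
        for _ in range(n_per_image):
            aug, desc = _random_transform(arr, rng)
            out_images.append(aug)
            out_prov.append({"source": sid, "transform": desc})
            out_labels.append(lab)
    return AugmentedSet(images=out_images, provenance=out_prov,
                        labels=out_labels)
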