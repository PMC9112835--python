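"""End-to-end orchestration shared by the CLI, tests and reports.

Stages: simulate -> WASSR B0 estimate -> correct -> per-pixel MTRasym ->
ROI table / harmonize -> augment -> SVM.  Every stage is a pure function
of its inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from glucest.asym import GluMap, glucest_map, roi_group_table
from glucest.b0corr import correct_zstack, estimate_b0
from glucest.classify import (
    ConfusionMatrix,
    MetricsReport,
    split_subjects,
    train_and_eval_svm,
)
from glucest.harmonize import AugmentedSet, OffsetModel, apply_offset, augment, fit_offset
from glucest.phantom import (
    AGE_GROUPS,
    GENOTYPES,
    CohortSpec,
    LabelMap,
    SubjectAcquisition,
    generate_cohort,
    make_label_map,
)


def process_subject(acq: SubjectAcquisition) -> GluMap:
    """WASSR B0 estimate -> CEST correction -> glutamate map for one subject."""
    b0 = estimate_b0(acq.wassr)
    corrected = correct_zstack(acq.cest, b0)
    spec = acq.truth.cohort
    return glucest_map(corrected, subject_id=acq.subject_id,
                       genotype=spec.genotype, age_group=spec.age_group)


def generate_all_cohorts(seed: int = 0, noise_sigma: float = 0.0,
                         b0_amplitude: float = 0.0,
                         shape: tuple[int, int] = (100, 100),
                         n_subjects: int | None = None,
                         label_seed: int = 0,
                         ) -> list[SubjectAcquisition]:
    """All 8 genotype x age cells; per-cell seeds derived from ``seed``."""
    subjects: list[SubjectAcquisition] = []
    for k, (gt, age) in enumerate(
            (g, a) for a in AGE_GROUPS for g in GENOTYPES):
        kwargs = dict(noise_sigma=noise_sigma, b0_amplitude=b0_amplitude,
                      shape=shape, seed=seed * 1000 + k, label_seed=label_seed)
        if n_subjects is not None:
            kwargs["n_subjects"] = n_subjects
        spec = CohortSpec.from_defaults(gt, age, **kwargs)
        subjects.extend(generate_cohort(spec))
    return subjects


def roi_table_from_subjects(subjects: list[SubjectAcquisition],
                            labels: LabelMap) -> pd.DataFrame:
    maps = [process_subject(s) for s in subjects]
    return roi_group_table(maps, labels)


@dataclass
class ExperimentResult:
    confusion: ConfusionMatrix
    report: MetricsReport
    offset_model: OffsetModel | None
    train_ids: list[str]
    test_ids: list[str]


def _augmented_from_maps(maps: list[GluMap], n_aug: int, seed: int) -> AugmentedSet:
    return augment([m.values for m in maps], [m.genotype for m in maps],
                   [m.subject_id for m in maps], n_aug, seed)


def run_classification_experiment(maps: list[GluMap], mask: np.ndarray,
                                  harmonization: bool = True,
                                  n_aug: int = 3,
                                  test_fraction: float = 0.30,
                                  seed: int = 0,
                                  kernel: str = "rbf") -> ExperimentResult:
    """Split by subject, harmonize on training data only, augment the
    training side, fit the SVM and score original test maps."""
    ids = [m.subject_id for m in maps]
    labels = [m.genotype for m in maps]
    train_ids, test_ids = split_subjects(ids, labels, test_fraction, seed)
    train_maps = [m for m in maps if m.subject_id in set(train_ids)]
    test_maps = [m for m in maps if m.subject_id in set(test_ids)]

    model: OffsetModel | None = None
    if harmonization:
        model = fit_offset(train_maps, scope="pooled", mode="additive")
        train_maps = [apply_offset(m, model) for m in train_maps]
        test_maps = [apply_offset(m, model) for m in test_maps]

    train_set = _augmented_from_maps(train_maps, n_aug, seed + 1)
    test_set = _augmented_from_maps(test_maps, 0, seed + 2)
    cm, rep = train_and_eval_svm(train_set, test_set, mask, kernel=kernel,
                                 seed=seed)
    return ExperimentResult(confusion=cm, report=rep, offset_model=model,
                            train_ids=train_ids, test_ids=test_ids)
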