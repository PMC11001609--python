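"""Labelled seizure batches and the Add-One-Forget-One schedule.

A *seizure batch* is the unit of retraining: the interictal plus preictal
data associated with one lead seizure.  The preictal class covers
``[onset - SPH - SOP, onset - SPH)``; the SPH gap, the ictal segment and a
configurable postictal exclusion window are dropped from training data
altogether, since they belong to neither class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .signal_io import SeizureAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "LabelingConfig",
    "SeizureBatch",
    "TrainPlan",
    "Standardiser",
    "filter_lead",
    "label_samples",
    "fit_standardiser",
    "balance_undersample",
    "class_weights",
    "add_one_forget_one",
    "plan_iterations",
]

SOP_GRID_DEFAULT: tuple[int, ...] = (10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class LabelingConfig:
    """Timing parameters of the labelling scheme (all strictly positive).

    ``sop``: seizure occurrence period in minutes (the preictal duration);
    ``sph``: seizure prediction horizon in minutes (the warning gap);
    ``postictal_exclusion``: minutes after seizure offset dropped from the
    interictal class; ``independence_gap``: hours required between lead
    seizures.
    """

    sop: float = 30.0
    sph: float = 10.0
    postictal_exclusion: float = 30.0
    independence_gap: float = 4.5

    def __post_init__(self) -> None:
        if self.sop <= 0 or self.sph <= 0:
            raise ValueError("sop and sph must be positive")
        if self.postictal_exclusion < 0:
            raise ValueError("postictal_exclusion must be >= 0")


@dataclass
class SeizureBatch:
    """Feature rows (interictal + preictal) assigned to one lead seizure."""

    seizure_id: int
    features: np.ndarray
    labels: np.ndarray  # 0 = interictal, 1 = preictal
    epoch_times: np.ndarray
    onset: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0 (interictal) or 1 (preictal)")

    @property
    def n_preictal(self) -> int:
        return int(self.labels.sum())

    @property
    def n_interictal(self) -> int:
        return int((self.labels == 0).sum())


@dataclass(frozen=True)
class TrainPlan:
    """One retraining iteration: training seizures plus the next unseen test
    seizure (3 training seizures under Add-One-Forget-One; all past seizures
    under the optional Chronological variant)."""

    iteration: int
    train_seizure_ids: tuple[int, ...]
    test_seizure_id: int
    validation: str = "leave-one-seizure-out"


def filter_lead(
    annotations: list[SeizureAnnotation], gap_hours: float = 4.5
) -> list[SeizureAnnotation]:
    """Keep only lead seizures: flagged lead and separated from the previous
    kept seizure by at least ``gap_hours``."""
    lead: list[SeizureAnnotation] = []
    for a in sorted(annotations, key=lambda a: a.onset):
        if not a.lead:
            continue
        if lead and a.onset - lead[-1].offset < gap_hours * 3600.0:
            logger.info(
                "seizure at %.0fs dropped: < %.1fh after the previous lead seizure",
                a.onset,
                gap_hours,
            )
            continue
        lead.append(a)
    return lead


@dataclass
class Standardiser:
    """Per-feature z-scoring learned on training rows only.

    Uses the population standard deviation (ddof=0).  Zero-variance features
    are flagged and mapped to 0 (never NaN); their inverse transform returns
    the training mean.
    """

    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale: np.ndarray = field(default=None)  # type: ignore[assignment]
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, rows: np.ndarray) -> "Standardiser":
        rows = np.asarray(rows, dtype=float)
        if rows.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.mean = rows.mean(axis=0)
        sd = rows.std(axis=0)
        self.degenerate = sd <= 0
        self.scale = np.where(self.degenerate, 1.0, sd)
        if self.degenerate.any():
            logger.info(
                "standardiser: %d zero-variance feature(s) flagged",
                int(self.degenerate.sum()),
            )
        return self

    def transform(self, rows: np.ndarray) -> np.ndarray:
        z = (np.asarray(rows, dtype=float) - self.mean) / self.scale
        z[:, self.degenerate] = 0.0
        return z

    def inverse_transform(self, rows: np.ndarray) -> np.ndarray:
        return np.asarray(rows, dtype=float) * self.scale + self.mean


def fit_standardiser(rows: np.ndarray) -> Standardiser:
    return Standardiser().fit(rows)


def label_samples(
    features: FeatureMatrix,
    annotations: list[SeizureAnnotation],
    cfg: LabelingConfig,
) -> list[SeizureBatch]:
    """Assign each valid epoch to at most one seizure batch.

    The interictal span of seizure *k* runs from the end of seizure *k-1*'s
    postictal exclusion (or the recording start) up to *k*'s preictal onset;
    the preictal span is ``[onset - sph - sop, onset - sph)``.  When a
    preictal window would reach into the previous postictal exclusion it is
    truncated with a warning.  SPH, ictal and postictal epochs are dropped.
    """
    lead = [a for a in annotations if a.lead]
    if sorted(a.onset for a in lead) != [a.onset for a in lead]:
        raise ValueError("annotations must be sorted by onset")
    times = features.epoch_start_times
    sph_s = cfg.sph * 60.0
    sop_s = cfg.sop * 60.0
    post_s = cfg.postictal_exclusion * 60.0

    batches: list[SeizureBatch] = []
    n_dropped = 0
    for k, ann in enumerate(lead):
        region_start = 0.0 if k == 0 else lead[k - 1].offset + post_s
        pre_start = ann.onset - sph_s - sop_s
        pre_end = ann.onset - sph_s
        if pre_start < region_start:
            logger.warning(
                "seizure %d: preictal window truncated at %.0fs "
                "(overlaps previous postictal exclusion / recording start)",
                k,
                region_start,
            )
            pre_start = region_start
        in_region = (
            features.valid_mask
            & (times >= region_start)
            & (times < pre_end)
        )
        is_pre = in_region & (times >= pre_start)
        sph_ictal = (
            features.valid_mask & (times >= pre_end) & (times < ann.offset + post_s)
        )
        n_dropped += int(sph_ictal.sum())
        idx = np.nonzero(in_region)[0]
        batches.append(
            SeizureBatch(
                seizure_id=k,
                features=features.values[idx],
                labels=is_pre[idx].astype(int),
                epoch_times=times[idx],
                onset=ann.onset,
            )
        )
    logger.debug(
        "label_samples: %d batches, %d SPH/ictal/postictal epochs dropped",
        len(batches),
        n_dropped,
    )
    return batches


def balance_undersample(
    rows: np.ndarray, labels: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Systematic random undersampling of the majority class.

    Majority-class rows are taken at a fixed stride through their
    chronological order, starting at a seeded random phase, so the kept rows
    cover the timeline approximately uniformly.  The minority class is kept
    whole.  Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels), np.bincount(labels, minlength=2)
    if len(classes) < 2:
        missing = 1 - classes[0] if len(classes) == 1 else "both"
        raise ValueError(f"cannot balance: class {missing} absent from input")
    maj = int(np.argmax(counts))
    maj_idx = np.nonzero(labels == maj)[0]
    min_idx = np.nonzero(labels != maj)[0]
    n_min = len(min_idx)
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0, 1) + np.arange(n_min)
    keep = maj_idx[np.floor(positions * len(maj_idx) / n_min).astype(int) % len(maj_idx)]
    sel = np.sort(np.concatenate([keep, min_idx]))
    return np.asarray(rows)[sel], labels[sel]


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency class weights, normalised so that
    ``sum_c w_c * count_c`` equals the sample count."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("class_weights needs both classes present")
    n = len(labels)
    return {int(c): n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def add_one_forget_one(seizure_ids: list[int], t: int) -> TrainPlan:
    """The *t*-th retraining iteration (t = 0 tests the 4th seizure).

    Training always uses the 3 seizures immediately preceding the test
    seizure; each retraining adds the newest seizure and forgets the oldest.
    """
    if len(seizure_ids) < 4:
        raise ValueError(
            f"patient excluded: {len(seizure_ids)} lead seizures, at least 4 required"
        )
    n_iter = len(seizure_ids) - 3
    if not 0 <= t < n_iter:
        raise ValueError(f"iteration {t} out of range [0, {n_iter})")
    return TrainPlan(
        iteration=t,
        train_seizure_ids=tuple(seizure_ids[t: t + 3]),
        test_seizure_id=seizure_ids[t + 3],
    )


def plan_iterations(seizure_ids: list[int]) -> list[TrainPlan]:
    """All Add-One-Forget-One plans; every seizure after the 3rd is tested
    exactly once, in chronological order."""
    return [add_one_forget_one(seizure_ids, t) for t in range(len(seizure_ids) - 3)]
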