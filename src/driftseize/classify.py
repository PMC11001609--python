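"""SVM training, filter feature selection, sample metrics and grid search.

The hyperparameter grid spans the SVM cost, the number of selected features
and the preictal duration (SOP).  Each combination is scored by
leave-one-seizure-out over the 3 training seizures, using the geometric mean
of sample sensitivity and sample specificity; ties break toward the smaller
SOP (shorter occurrence periods burden the patient less), then the smaller
cost, then fewer features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.svm import SVC

from .dataset import (
    SeizureBatch,
    TrainPlan,
    balance_undersample,
    class_weights,
    fit_standardiser,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SVMConfig",
    "HyperGrid",
    "GridSearchResult",
    "select_features",
    "train_svm",
    "sample_metrics",
    "grid_search",
]

COST_GRID_DEFAULT: tuple[float, ...] = (2**-10, 2**-8, 2**-6, 2**-4, 2**-2, 1.0, 2**2)
N_FEATURES_GRID_DEFAULT: tuple[int, ...] = (10, 20, 30, 40)
SOP_GRID_DEFAULT: tuple[int, ...] = (10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    cost: float = 1.0
    class_weight: dict[int, float] | str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")


@dataclass(frozen=True)
class HyperGrid:
    cost_grid: tuple[float, ...] = COST_GRID_DEFAULT
    n_features_grid: tuple[int, ...] = N_FEATURES_GRID_DEFAULT
    sop_grid: tuple[int, ...] = SOP_GRID_DEFAULT

    def __post_init__(self) -> None:
        if not (self.cost_grid and self.n_features_grid and self.sop_grid):
            raise ValueError("all grids must be non-empty")


@dataclass
class GridSearchResult:
    """Outcome of one iteration's grid search.

    ``table`` holds one row per evaluated (sop, cost, k) with the mean
    validation sensitivity/specificity and the combined score; the selected
    combination maximises the score under the documented tie-break.
    """

    sop: int
    cost: float
    n_features: int
    score: float
    feature_indices: np.ndarray
    table: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def select_features(rows: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Top-k columns by the one-way ANOVA F statistic (univariate filter).

    Deterministic: ties (and all-NaN statistics) break toward the smaller
    column index via a stable sort.
    """
    rows = np.asarray(rows, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > rows.shape[1]:
        raise ValueError(f"k={k} exceeds {rows.shape[1]} columns")
    if len(np.unique(labels)) < 2:
        raise ValueError("select_features needs both classes present")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(rows, labels)
    f_stat = np.where(np.isfinite(f_stat), f_stat, -np.inf)
    order = np.argsort(-f_stat, kind="stable")
    return order[:k]


def train_svm(rows: np.ndarray, labels: np.ndarray, cfg: SVMConfig) -> SVC:
    """Fit an SVM on standardised rows.

    Exposes ``decision_function`` and ``predict``; training is deterministic
    given the data (libsvm's SMO has no random component for fixed inputs;
    ``random_state`` pins the rest).
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("train_svm needs both classes (or rebalanced input)")
    model = SVC(
        kernel=cfg.kernel,
        C=cfg.cost,
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
        cache_size=200,
    )
    model.fit(rows, labels)
    return model


def sample_metrics(
    pred: np.ndarray, true: np.ndarray
) -> tuple[float, float]:
    """Sample sensitivity and specificity.

    S_ss is the fraction of preictal samples predicted preictal
    (TP/(TP+FN)); S_sp the fraction of interictal samples predicted
    interictal (TN/(TN+FP)).  A class absent from the truth makes its
    metric NaN.
    """
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same length")
    n_pre = int((true == 1).sum())
    n_int = int((true == 0).sum())
    sss = float(((pred == 1) & (true == 1)).sum() / n_pre) if n_pre else float("nan")
    ssp = float(((pred == 0) & (true == 0)).sum() / n_int) if n_int else float("nan")
    return sss, ssp


def _fold_data(
    batches: list[SeizureBatch], train_ids: list[int], val_id: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    by_id = {b.seizure_id: b for b in batches}
    Xtr = np.vstack([by_id[i].features for i in train_ids])
    ytr = np.concatenate([by_id[i].labels for i in train_ids])
    return Xtr, ytr, by_id[val_id].features, by_id[val_id].labels


def grid_search(
    plan: TrainPlan,
    batches_by_sop: dict[int, list[SeizureBatch]],
    grid: HyperGrid,
    balance: str = "weights",
    seed: int = 0,
) -> GridSearchResult:
    """Leave-one-seizure-out grid search over (cost, n_features, SOP).

    ``batches_by_sop`` maps each candidate SOP to the plan's training
    seizures labelled under that SOP — labelling depends on the preictal
    duration, so each SOP sees its own batches.  The test seizure is never
    touched.  ``balance`` is ``"weights"`` (inverse-frequency class weights)
    or ``"undersample"`` (systematic random undersampling).

    For each combination the score is the mean over the 3 validation folds
    of sqrt(S_ss * S_sp); folds where either class is missing from the
    validation batch are skipped, and a combination with no scorable fold is
    recorded as NaN and never selected.
    """
    records: list[dict] = []
    train_ids = list(plan.train_seizure_ids)
    for sop in grid.sop_grid:
        if sop not in batches_by_sop:
            raise ValueError(f"no labelled batches supplied for SOP {sop}")
        batches = [
            b for b in batches_by_sop[sop] if b.seizure_id in train_ids
        ]
        if any(b.seizure_id == plan.test_seizure_id for b in batches_by_sop[sop]):
            # leakage guard: test batches must not even be passed in
            raise ValueError("test seizure present in grid-search batches")
        fold_cache: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for val_id in train_ids:
            fold_train = [i for i in train_ids if i != val_id]
            Xtr, ytr, Xva, yva = _fold_data(batches, fold_train, val_id)
            if len(np.unique(ytr)) < 2 or len(np.unique(yva)) < 2:
                logger.info(
                    "grid_search: SOP %d fold val=%d skipped (single class)",
                    sop,
                    val_id,
                )
                continue
            std = fit_standardiser(Xtr)
            Ztr, Zva = std.transform(Xtr), std.transform(Xva)
            ranking = select_features(Ztr, ytr, Ztr.shape[1])
            fold_cache.append((Ztr, ytr, Zva, yva, ranking))
        for cost in grid.cost_grid:
            for k in grid.n_features_grid:
                scores = []
                for Ztr, ytr, Zva, yva, ranking in fold_cache:
                    cols = ranking[: min(k, len(ranking))]
                    if balance == "undersample":
                        Xb, yb = balance_undersample(Ztr[:, cols], ytr, seed)
                        cfg = SVMConfig(cost=cost, seed=seed)
                    elif balance == "weights":
                        Xb, yb = Ztr[:, cols], ytr
                        cfg = SVMConfig(cost=cost, class_weight=class_weights(ytr), seed=seed)
                    else:
                        raise ValueError(f"unknown balance mode {balance!r}")
                    model = train_svm(Xb, yb, cfg)
                    sss, ssp = sample_metrics(model.predict(Zva[:, cols]), yva)
                    scores.append(np.sqrt(sss * ssp))
                mean_score = float(np.mean(scores)) if scores else float("nan")
                records.append(
                    {"sop": sop, "cost": cost, "n_features": k, "score": mean_score}
                )
    table = pd.DataFrame.from_records(records)
    scored = table.dropna(subset=["score"])
    if scored.empty:
        raise ValueError("grid search found no scorable combination")
    # max score; ties -> smaller SOP, then smaller cost, then fewer features
    best = (
        scored.sort_values(
            ["score", "sop", "cost", "n_features"],
            ascending=[False, True, True, True],
            kind="stable",
        )
        .iloc[0]
    )
    sop, cost, k = int(best["sop"]), float(best["cost"]), int(best["n_features"])
    # final feature ranking on the full 3-seizure training set under the
    # selected SOP, after standardisation
    batches = [b for b in batches_by_sop[sop] if b.seizure_id in train_ids]
    Xtr = np.vstack([b.features for b in batches])
    ytr = np.concatenate([b.labels for b in batches])
    std = fit_standardiser(Xtr)
    feature_indices = select_features(std.transform(Xtr), ytr, k)
    return GridSearchResult(
        sop=sop,
        cost=cost,
        n_features=k,
        score=float(best["score"]),
        feature_indices=feature_indices,
        table=table,
    )
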