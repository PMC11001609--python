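"""Concept-drift adaptation strategies for seizure prediction.

Three blind (trigger-free) adapters, each deciding which past data to learn
from at every retraining iteration:

* **Backwards-Landmark Window (BLW)** — grows a training window backwards in
  time from the most recent labelled seizure in 1-hour steps, trains an SVM
  per candidate window and keeps the window minimising a leave-one-out
  error estimate (the xi-alpha bound by default).
* **Seizure-batch Regression (SbR)** — fits a logistic regression per
  chronological combination of training seizures and keeps the combination
  whose weight vector makes the smallest angle with a regression fitted on
  the most recent seizure alone; small angles are read as "same concept".
* **Dynamic Weighted Ensemble (DWE)** — keeps one SVM per 1-hour period of
  interictal data and combines them by weighted voting, each weight
  proportional to the model's accuracy over the last two hours before the
  most recent training seizure (the "current concept").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .classify import SVMConfig, train_svm
from .dataset import SeizureBatch, class_weights

logger = logging.getLogger(__name__)

__all__ = [
    "loo_estimate",
    "BLWSelection",
    "blw_select",
    "sbr_angle",
    "SBRSelection",
    "sbr_select",
    "WeightedEnsemble",
    "dwe_build",
    "dwe_weigh",
    "dwe_predict",
]


def loo_estimate(
    model: SVC,
    rows: np.ndarray,
    labels: np.ndarray,
    mode: str = "xi_alpha",
) -> float:
    """Leave-one-out error estimate for a trained SVM.

    ``rows``/``labels`` must be the model's own training set.  In
    ``xi_alpha`` mode the classical bound ``|{i : a_i R^2 + xi_i >= 1}| / n``
    is returned, with ``a_i`` the dual coefficients, ``xi_i`` the slack of
    point *i* and ``R^2`` the largest kernel self-similarity over the
    training points; it upper-bounds (hence is typically pessimistic about)
    the exact estimate.  In ``exact`` mode the true leave-one-out error is
    computed by *n* retrainings.
    """
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if not hasattr(model, "support_"):
        raise ValueError("model is not a trained SVM")
    if mode == "xi_alpha":
        alpha = np.zeros(n)
        alpha[model.support_] = np.abs(model.dual_coef_[0])
        y_signed = np.where(labels == model.classes_[1], 1.0, -1.0)
        xi = np.maximum(0.0, 1.0 - y_signed * model.decision_function(rows))
        if model.kernel == "linear":
            r2 = float(np.max(np.einsum("ij,ij->i", rows, rows)))
        elif model.kernel == "rbf":
            r2 = 1.0
        else:
            raise ValueError(f"xi_alpha mode unsupported for kernel {model.kernel!r}")
        return float(np.count_nonzero(alpha * r2 + xi >= 1.0 - 1e-9) / n)
    if mode == "exact":
        if n < 2:
            raise ValueError("exact leave-one-out is undefined for n < 2")
        errors = 0
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            yk = labels[keep]
            if len(np.unique(yk)) < 2:
                # held-out point's class vanishes: predict the remaining class
                pred = yk[0]
            else:
                m = clone(model)
                m.fit(rows[keep], yk)
                pred = m.predict(rows[i: i + 1])[0]
            errors += int(pred != labels[i])
        return errors / n
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class BLWSelection:
    """Outcome of the backwards-landmark window search."""

    window_hours: int
    model: SVC
    row_mask: np.ndarray
    loo: float
    table: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def blw_select(
    rows: np.ndarray,
    labels: np.ndarray,
    times: np.ndarray,
    cfg: SVMConfig | None = None,
    step_hours: float = 1.0,
    patience_hours: float = 12.0,
    anchor: float | None = None,
    loo_mode: str = "xi_alpha",
    eval_on: str = "window",
) -> BLWSelection:
    """Select the training window minimising the leave-one-out estimate.

    Candidate windows reach ``w = step, 2*step, ...`` hours backwards from
    ``anchor`` (the most recent training timestamp by default, i.e. the end
    of the last labelled seizure's preictal).  Candidates with a single
    class are recorded but untrainable.  The search stops early once the
    best estimate has not improved over the last ``patience_hours`` of
    window growth.  Ties keep the smallest window.  ``eval_on`` controls
    whether the estimate is computed on the whole candidate window
    (default) or only on the most recent ``step_hours`` of rows.
    """
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    times = np.asarray(times, dtype=float)
    if cfg is None:
        cfg = SVMConfig()
    if anchor is None:
        anchor = float(times.max()) + 1e-9
    span_h = (anchor - float(times.min())) / 3600.0
    if span_h < step_hours:
        raise ValueError("training data must span at least one window step")
    n_candidates = int(np.ceil(span_h / step_hours))

    records: list[dict] = []
    best: tuple[float, int, SVC, np.ndarray] | None = None  # (loo, w, model, mask)
    for j in range(1, n_candidates + 1):
        w = j * step_hours
        if best is not None and w - best[1] >= patience_hours:
            logger.info(
                "blw_select: early stop at %.0fh (no improvement since %.0fh window)",
                w,
                best[1],
            )
            break
        mask = times >= anchor - w * 3600.0
        y_w = labels[mask]
        if len(np.unique(y_w)) < 2:
            records.append({"window_hours": w, "n_rows": int(mask.sum()), "loo": np.nan})
            continue
        weights = class_weights(y_w)
        model = train_svm(
            rows[mask],
            y_w,
            SVMConfig(kernel=cfg.kernel, cost=cfg.cost, class_weight=weights, seed=cfg.seed),
        )
        if eval_on == "window":
            est = loo_estimate(model, rows[mask], y_w, mode=loo_mode)
        elif eval_on == "latest_batch":
            recent = mask & (times >= anchor - step_hours * 3600.0)
            y_r = labels[recent]
            preds = model.predict(rows[recent])
            est = float(np.mean(preds != y_r)) if len(y_r) else float("nan")
        else:
            raise ValueError(f"unknown eval_on {eval_on!r}")
        records.append({"window_hours": w, "n_rows": int(mask.sum()), "loo": est})
        if best is None or est < best[0]:
            best = (est, w, model, mask)
    if best is None:
        raise ValueError(
            "no candidate window contained both classes; widen the window step "
            "or include preictal rows of earlier seizures in the span"
        )
    est, w, model, mask = best
    return BLWSelection(
        window_hours=int(round(w / step_hours)),
        model=model,
        row_mask=mask,
        loo=est,
        table=pd.DataFrame.from_records(records),
    )


def sbr_angle(w1: np.ndarray, w2: np.ndarray) -> float:
    """Angle in degrees between two weight vectors.

    ``arccos`` of the cosine similarity (clamped to [-1, 1]); symmetric,
    scale-invariant for positive scalings, in [0, 180].
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("weight vectors must have equal dimension")
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined for a zero weight vector")
    cos = float(np.clip(np.dot(w1, w2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


@dataclass
class SBRSelection:
    """Outcome of the seizure-batch regression selection."""

    subset: tuple[int, ...]
    angle_degrees: float
    model: SVC
    table: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def _fit_logistic_weights(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    lr = LogisticRegression(
        C=1.0, max_iter=500, class_weight="balanced", random_state=seed
    )
    lr.fit(X, y)
    return lr.coef_[0]  # intercept excluded from the angle


def sbr_select(
    batches: list[SeizureBatch],
    cfg: SVMConfig | None = None,
    angle_tie_tol: float = 45.0,
    seed: int = 0,
) -> SBRSelection:
    """Select the combination of past seizure batches matching the current
    concept.

    Every non-empty chronological subset of the training seizures gets a
    logistic regression; its weight vector is compared (angle) against a
    reference regression fitted on the most recent seizure alone.  Small
    angles are read as "no drift / gradual drift", large angles as
    considerable drift.  Subsets whose angle is within ``angle_tie_tol``
    degrees of the minimum count as tied, and the tie breaks toward the
    larger subset (more data, same concept); 45 degrees — closer to aligned
    than to orthogonal — is the default boundary.  The returned SVM is
    trained on the selected subset with inverse-frequency class weights.
    """
    if len(batches) < 2:
        raise ValueError("sbr_select needs at least 2 training seizure batches")
    if cfg is None:
        cfg = SVMConfig()
    batches = sorted(batches, key=lambda b: b.onset)
    ids = [b.seizure_id for b in batches]
    ref_batch = batches[-1]
    try:
        w_ref = _fit_logistic_weights(ref_batch.features, ref_batch.labels, seed)
    except Exception as exc:
        raise ValueError(f"reference regression failed: {exc}") from exc

    records: list[dict] = []
    results: list[tuple[tuple[int, ...], float]] = []
    for r in range(1, len(batches) + 1):
        for combo in combinations(range(len(batches)), r):
            sel = [batches[i] for i in combo]
            X = np.vstack([b.features for b in sel])
            y = np.concatenate([b.labels for b in sel])
            subset_ids = tuple(ids[i] for i in combo)
            try:
                w = _fit_logistic_weights(X, y, seed)
                angle = sbr_angle(w, w_ref)
            except Exception as exc:
                logger.warning("sbr_select: subset %s skipped (%s)", subset_ids, exc)
                records.append(
                    {"subset": subset_ids, "angle_degrees": np.nan, "n_rows": len(y)}
                )
                continue
            records.append(
                {"subset": subset_ids, "angle_degrees": angle, "n_rows": len(y)}
            )
            results.append((combo, angle))
    if not results:
        raise ValueError("every subset regression failed")
    min_angle = min(a for _, a in results)
    tied = [(c, a) for c, a in results if a <= min_angle + angle_tie_tol]
    # largest subset among ties; equal sizes -> smaller angle
    combo, angle = max(tied, key=lambda ca: (len(ca[0]), -ca[1]))
    sel = [batches[i] for i in combo]
    X = np.vstack([b.features for b in sel])
    y = np.concatenate([b.labels for b in sel])
    model = train_svm(
        X,
        y,
        SVMConfig(kernel=cfg.kernel, cost=cfg.cost, class_weight=class_weights(y), seed=cfg.seed),
    )
    return SBRSelection(
        subset=tuple(ids[i] for i in combo),
        angle_degrees=angle,
        model=model,
        table=pd.DataFrame.from_records(records),
    )


@dataclass
class WeightedEnsemble:
    """Base SVMs over 1-hour periods plus their voting weights."""

    models: list[SVC]
    periods: list[tuple[float, float]]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    concept_hours: float = 2.0


def dwe_build(
    rows: np.ndarray,
    labels: np.ndarray,
    times: np.ndarray,
    cfg: SVMConfig | None = None,
    period_hours: float = 1.0,
    min_rows: int = 12,
    anchor: float | None = None,
    concept_hours: float = 2.0,
) -> WeightedEnsemble:
    """Train one base SVM per 1-hour period of the training span.

    Periods partition the span backwards from ``anchor``.  Each base model
    learns from its own period's rows — so a period overlapping a preictal
    window captures that seizure's concept.  A pure-interictal hour needs a
    preictal class to be trainable; it borrows the preictal rows of the
    current concept (the last ``concept_hours`` before ``anchor``, i.e. the
    most recent training seizure's preictal), falling back to the full
    preictal pool if none exist there.  Periods with fewer than
    ``min_rows`` interictal epochs are skipped with a log message.
    """
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    times = np.asarray(times, dtype=float)
    if cfg is None:
        cfg = SVMConfig()
    if anchor is None:
        anchor = float(times.max()) + 1e-9
    span_h = (anchor - float(times.min())) / 3600.0
    if span_h < 2 * period_hours:
        raise ValueError("training data must span at least two base periods")
    pre_mask = labels == 1
    recent_pre = pre_mask & (times >= anchor - concept_hours * 3600.0)
    borrow = recent_pre if recent_pre.any() else pre_mask
    models: list[SVC] = []
    periods: list[tuple[float, float]] = []
    n_periods = int(np.ceil(span_h / period_hours))
    for j in range(n_periods):
        hi = anchor - j * period_hours * 3600.0
        lo = hi - period_hours * 3600.0
        period = (times >= lo) & (times < hi)
        if (period & ~pre_mask).sum() < min_rows:
            logger.info(
                "dwe_build: period [%.0f, %.0f)s skipped (%d interictal rows)",
                lo,
                hi,
                int((period & ~pre_mask).sum()),
            )
            continue
        if len(np.unique(labels[period])) < 2:
            mask = period | borrow  # pure-interictal hour: borrow current-concept preictal
        else:
            mask = period
        y = labels[mask]
        model = train_svm(
            rows[mask],
            y,
            SVMConfig(kernel=cfg.kernel, cost=cfg.cost, class_weight=class_weights(y), seed=cfg.seed),
        )
        models.append(model)
        periods.append((lo, hi))
    if not models:
        raise ValueError("no viable 1-hour period for ensemble building")
    return WeightedEnsemble(models=models, periods=periods)


def dwe_weigh(
    ensemble: WeightedEnsemble,
    concept_rows: np.ndarray,
    concept_labels: np.ndarray,
) -> np.ndarray:
    """Weight each base model by its accuracy on the current-concept rows
    (the last two hours before the most recent training seizure).

    Weights are normalised to sum to 1; if every accuracy is zero a uniform
    vector is returned with a warning.
    """
    concept_rows = np.asarray(concept_rows, dtype=float)
    concept_labels = np.asarray(concept_labels, dtype=int)
    if len(concept_labels) == 0:
        raise ValueError("empty concept window")
    acc = np.array(
        [float(np.mean(m.predict(concept_rows) == concept_labels)) for m in ensemble.models]
    )
    if acc.sum() == 0:
        logger.warning("dwe_weigh: all base accuracies zero; uniform weights")
        weights = np.full(len(acc), 1.0 / len(acc))
    else:
        weights = acc / acc.sum()
    ensemble.weights = weights
    return weights


def dwe_predict(
    ensemble: WeightedEnsemble,
    rows: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted-vote binary prediction: preictal (1) when the weighted sum
    of base votes reaches 0.5 (ties vote preictal, favouring sensitivity).

    Reduces to a majority vote under uniform weights.
    """
    if weights is None:
        weights = ensemble.weights
    if weights is None:
        raise ValueError("ensemble has no weights; call dwe_weigh first")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(ensemble.models):
        raise ValueError("weight vector length does not match model count")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    rows = np.asarray(rows, dtype=float)
    votes = np.zeros(rows.shape[0])
    for w, m in zip(weights, ensemble.models):
        votes += w * m.predict(rows)
    return (votes >= 0.5 - 1e-12).astype(int)
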