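"""Per-patient iterative train/validate/test loop and cohort reporting.

For every retraining iteration (Add-One-Forget-One by default): label the
training seizures under each candidate preictal duration, grid-search the
SVM cost / feature count / SOP by leave-one-seizure-out, standardise with
train-fitted parameters, train the configured approach (control = plain SVM
with systematic undersampling; blw / sbr / dwe = the drift adapters with
inverse-frequency class weights), classify the unseen stream before the
next seizure, smooth with the Firing Power, raise alarms and accumulate
event-level metrics.  After the last iteration the achieved sensitivity is
surrogate-validated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alarms_eval import (
    AlarmSeries,
    PerformanceReport,
    firing_power,
    raise_alarms,
    score_alarms,
    surrogate_validate,
)
from .classify import GridSearchResult, HyperGrid, SVMConfig, grid_search
from .dataset import (
    LabelingConfig,
    SeizureBatch,
    TrainPlan,
    balance_undersample,
    filter_lead,
    fit_standardiser,
    label_samples,
    plan_iterations,
)
from .drift import blw_select, dwe_build, dwe_predict, dwe_weigh, sbr_select
from .classify import train_svm
from .features import FeatureMatrix
from .signal_io import SeizureAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "APPROACHES",
    "RunConfig",
    "IterationRecord",
    "PatientResult",
    "run_patient",
    "run_cohort",
    "report_hyperparameter_frequencies",
    "assert_chronology",
]

APPROACHES = ("control", "blw", "sbr", "dwe")


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable configuration of one patient run."""

    approach: str = "control"
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    grid: HyperGrid = field(default_factory=HyperGrid)
    fp_threshold: float = 0.5
    surrogate_runs: int = 30
    surrogate_alpha: float = 0.05
    retrain: str = "aofo"  # or "chronological"
    blw_patience_hours: float = 12.0
    dwe_period_hours: float = 1.0
    dwe_concept_hours: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.retrain not in ("aofo", "chronological"):
            raise ValueError("retrain must be 'aofo' or 'chronological'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


@dataclass
class IterationRecord:
    """Everything one retraining iteration produced (audit trail)."""

    plan: TrainPlan
    grid_result: GridSearchResult
    alarms: AlarmSeries
    report: PerformanceReport
    train_time_range: tuple[float, float]
    test_time_range: tuple[float, float]
    test_interval: tuple[float, float]
    adaptation: dict = field(default_factory=dict)


@dataclass
class PatientResult:
    report: PerformanceReport
    iterations: list[IterationRecord]
    config: RunConfig
    seed: int


def _train_adapted_model(
    approach: str,
    Ztr: np.ndarray,
    ytr: np.ndarray,
    ttr: np.ndarray,
    train_batches: list[SeizureBatch],
    std,
    cols: np.ndarray,
    cfg: RunConfig,
    cost: float,
):
    """Dispatch to the configured training strategy.

    Returns ``(predict_fn, adaptation_info)`` where ``predict_fn`` maps
    standardised selected-feature rows to binary labels.
    """
    svm_cfg = SVMConfig(cost=cost, seed=cfg.seed)
    if approach == "control":
        Xb, yb = balance_undersample(Ztr, ytr, cfg.seed)
        model = train_svm(Xb, yb, svm_cfg)
        return model.predict, {"n_train_rows": len(yb)}
    if approach == "blw":
        sel = blw_select(
            Ztr, ytr, ttr, cfg=svm_cfg, patience_hours=cfg.blw_patience_hours
        )
        return sel.model.predict, {
            "window_hours": sel.window_hours,
            "loo": sel.loo,
            "candidate_table": sel.table,
        }
    if approach == "sbr":
        zbatches = [
            SeizureBatch(
                seizure_id=b.seizure_id,
                features=std.transform(b.features)[:, cols],
                labels=b.labels,
                epoch_times=b.epoch_times,
                onset=b.onset,
            )
            for b in train_batches
        ]
        sel = sbr_select(zbatches, cfg=svm_cfg, seed=cfg.seed)
        return sel.model.predict, {
            "subset": sel.subset,
            "angle_degrees": sel.angle_degrees,
            "candidate_table": sel.table,
        }
    if approach == "dwe":
        ens = dwe_build(
            Ztr, ytr, ttr, cfg=svm_cfg,
            period_hours=cfg.dwe_period_hours,
            concept_hours=cfg.dwe_concept_hours,
        )
        last_onset = max(b.onset for b in train_batches)
        concept = ttr >= last_onset - cfg.dwe_concept_hours * 3600.0
        if not concept.any():
            raise ValueError("empty DWE concept window")
        weights = dwe_weigh(ens, Ztr[concept], ytr[concept])
        return (
            lambda rows: dwe_predict(ens, rows),
            {"n_models": len(ens.models), "weights": weights},
        )
    raise ValueError(f"unknown approach {approach!r}")


def run_patient(
    features: FeatureMatrix,
    annotations: list[SeizureAnnotation],
    cfg: RunConfig,
) -> PatientResult:
    """Run the full iterative pipeline for one patient.

    Requires at least 4 lead seizures after independence-gap filtering
    (patients with fewer are excluded, mirroring the cohort inclusion
    rule).  Deterministic: identical (features, annotations, config) give
    bit-identical results.
    """
    lead = filter_lead(annotations, cfg.labeling.independence_gap)
    if len(lead) < 4:
        raise ValueError(
            f"patient excluded: {len(lead)} lead seizures after filtering, 4 required"
        )
    times = features.epoch_start_times
    w = features.window_length

    batches_by_sop: dict[int, list[SeizureBatch]] = {
        sop: label_samples(features, lead, replace(cfg.labeling, sop=sop))
        for sop in cfg.grid.sop_grid
    }

    ids = list(range(len(lead)))
    if cfg.retrain == "aofo":
        plans = plan_iterations(ids)
    else:
        plans = [
            TrainPlan(iteration=t, train_seizure_ids=tuple(ids[: t + 3]), test_seizure_id=ids[t + 3])
            for t in range(len(ids) - 3)
        ]

    iterations: list[IterationRecord] = []
    for plan in plans:
        train_ids = list(plan.train_seizure_ids)
        train_by_sop = {
            sop: [b for b in bs if b.seizure_id in train_ids]
            for sop, bs in batches_by_sop.items()
        }
        balance = "undersample" if cfg.approach == "control" else "weights"
        gs = grid_search(plan, train_by_sop, cfg.grid, balance=balance, seed=cfg.seed)

        train_batches = [
            b for b in batches_by_sop[gs.sop] if b.seizure_id in train_ids
        ]
        Xtr = np.vstack([b.features for b in train_batches])
        ytr = np.concatenate([b.labels for b in train_batches])
        ttr = np.concatenate([b.epoch_times for b in train_batches])
        std = fit_standardiser(Xtr)
        cols = gs.feature_indices
        Ztr = std.transform(Xtr)[:, cols]

        predict, adaptation = _train_adapted_model(
            cfg.approach, Ztr, ytr, ttr, train_batches, std, cols, cfg, gs.cost
        )

        # unseen stream: from the end of the last training seizure's
        # postictal exclusion up to the test seizure's onset
        last_train_ann = lead[train_ids[-1]]
        test_ann = lead[plan.test_seizure_id]
        region_start = last_train_ann.offset + cfg.labeling.postictal_exclusion * 60.0
        test_mask = (
            features.valid_mask & (times >= region_start) & (times < test_ann.onset)
        )
        if not test_mask.any():
            logger.warning(
                "iteration %d: empty test stream; skipped", plan.iteration
            )
            continue
        Zte = std.transform(features.values[test_mask])[:, cols]
        outputs = predict(Zte)

        tau = max(1, int(round(gs.sop * 60.0 / w)))
        trace = firing_power(outputs, tau, epoch_times=times[test_mask])
        alarms = raise_alarms(
            trace, threshold=cfg.fp_threshold, refractory_s=gs.sop * 60.0
        )
        interictal_h = max(
            0.0,
            (test_ann.onset - (cfg.labeling.sph + gs.sop) * 60.0 - region_start)
            / 3600.0,
        )
        report = score_alarms(
            alarms,
            np.array([test_ann.onset]),
            sop_min=gs.sop,
            sph_min=cfg.labeling.sph,
            interictal_hours=interictal_h,
        )
        iterations.append(
            IterationRecord(
                plan=plan,
                grid_result=gs,
                alarms=alarms,
                report=report,
                train_time_range=(float(ttr.min()), float(ttr.max())),
                test_time_range=(
                    float(times[test_mask].min()),
                    float(times[test_mask].max()),
                ),
                test_interval=(region_start, test_ann.onset),
                adaptation=adaptation,
            )
        )

    if not iterations:
        raise ValueError("no iteration produced a testable stream")

    n_tested = len(iterations)
    n_predicted = sum(it.report.n_predicted for it in iterations)
    ss = n_predicted / n_tested
    n_false = sum(it.report.n_false_alarms for it in iterations)
    denom_h = sum(
        it.report.interictal_hours
        - len(it.alarms.alarm_times) * it.alarms.refractory_s / 3600.0
        for it in iterations
    )
    fpr = n_false / denom_h if denom_h > 0 else float("inf")

    surr = surrogate_validate(
        [it.alarms for it in iterations],
        [it.test_interval for it in iterations],
        real_ss=ss,
        sop_min=np.array([it.grid_result.sop for it in iterations], dtype=float),
        sph_min=cfg.labeling.sph,
        n_runs=cfg.surrogate_runs,
        alpha=cfg.surrogate_alpha,
        seed=cfg.seed,
    )
    report = PerformanceReport(
        ss=ss,
        fpr_per_hour=fpr,
        n_seizures=n_tested,
        n_predicted=n_predicted,
        n_false_alarms=n_false,
        interictal_hours=sum(it.report.interictal_hours for it in iterations),
        surrogate_ss=surr.surrogate_ss,
        t_statistic=surr.t_statistic,
        p_value=surr.p_value,
        validated=surr.validated,
        extras={"approach": cfg.approach, **surr.extras},
    )
    result = PatientResult(
        report=report, iterations=iterations, config=cfg, seed=cfg.seed
    )
    assert_chronology([result])
    return result


def assert_chronology(results: list[PatientResult]) -> None:
    """No training epoch may postdate the start of its test stream."""
    for res in results:
        for it in res.iterations:
            if it.train_time_range[1] >= it.test_time_range[0]:
                raise AssertionError(
                    f"chronology violated in iteration {it.plan.iteration}: "
                    f"train up to {it.train_time_range[1]}s, "
                    f"test from {it.test_time_range[0]}s"
                )


def run_cohort(
    results_by_approach: dict[str, list[PatientResult]],
    metadata: list[dict] | None = None,
) -> dict[str, pd.DataFrame]:
    """Aggregate patient reports per approach.

    Returns ``summary`` (mean +/- SD of SS and FPR/h, % validated per
    approach), ``per_patient`` (one row per patient x approach) and, when
    per-patient ``metadata`` tag dicts are given, ``stratified`` aggregates
    per tag value.
    """
    if not results_by_approach or not any(results_by_approach.values()):
        raise ValueError("empty cohort")
    rows = []
    for approach, results in results_by_approach.items():
        for pi, res in enumerate(results):
            row = {
                "approach": approach,
                "patient": pi,
                "ss": res.report.ss,
                "fpr_per_hour": res.report.fpr_per_hour,
                "validated": res.report.validated,
                "n_tested_seizures": res.report.n_seizures,
            }
            if metadata is not None:
                row.update(metadata[pi])
            rows.append(row)
    per_patient = pd.DataFrame(rows)
    summary = (
        per_patient.groupby("approach")
        .agg(
            mean_ss=("ss", "mean"),
            sd_ss=("ss", "std"),
            mean_fpr_per_hour=("fpr_per_hour", "mean"),
            sd_fpr_per_hour=("fpr_per_hour", "std"),
            pct_validated=("validated", lambda v: 100.0 * np.mean(v)),
            n_patients=("ss", "size"),
        )
        .reset_index()
    )
    out = {"summary": summary, "per_patient": per_patient}
    if metadata is not None:
        tag_cols = sorted({k for m in metadata for k in m})
        strata = []
        for col in tag_cols:
            g = (
                per_patient.groupby(["approach", col])
                .agg(
                    mean_ss=("ss", "mean"),
                    mean_fpr_per_hour=("fpr_per_hour", "mean"),
                    pct_validated=("validated", lambda v: 100.0 * np.mean(v)),
                    n_patients=("ss", "size"),
                )
                .reset_index()
                .rename(columns={col: "tag_value"})
            )
            g.insert(1, "tag", col)
            strata.append(g)
        out["stratified"] = pd.concat(strata, ignore_index=True)
    return out


def report_hyperparameter_frequencies(
    results: list[PatientResult],
    n_features_per_channel: int = 59,
    feature_names: list[str] | None = None,
    channel_labels: list[str] | None = None,
) -> dict[str, pd.Series]:
    """Relative frequency of selected SOP, cost, feature-count, channel and
    feature choices across all iterations; each category sums to 1."""
    sops, costs, ks, chans, feats = [], [], [], [], []
    for res in results:
        for it in res.iterations:
            gs = it.grid_result
            sops.append(gs.sop)
            costs.append(gs.cost)
            ks.append(gs.n_features)
            for idx in gs.feature_indices:
                ci, fi = divmod(int(idx), n_features_per_channel)
                chans.append(channel_labels[ci] if channel_labels else ci)
                feats.append(feature_names[fi] if feature_names else fi)
    if not sops:
        raise ValueError("no completed iterations with grid-search artefacts")

    def freq(values: list) -> pd.Series:
        s = pd.Series(values).value_counts(normalize=True).sort_index()
        s.name = "relative_frequency"
        return s

    return {
        "sop": freq(sops),
        "cost": freq(costs),
        "n_features": freq(ks),
        "channel": freq(chans),
        "feature": freq(feats),
    }
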