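"""Firing Power post-processing, alarms and statistical validation.

The raw per-epoch classifier outputs are smoothed by the Firing Power — a
causal moving average over one SOP-worth of epochs — and an alarm fires when
the smoothed value crosses a fixed 0.5 threshold (half of the [0, 1] scale,
deliberately untuned).  Each alarm opens a refractory period equal to the
preictal duration during which no further alarms are allowed; refractory
time is removed from the FPR/h denominator.

An alarm at time *t* is a true prediction when a seizure onset falls inside
``(t + SPH, t + SPH + SOP]``.  Performance above chance is established by a
surrogate analysis: seizure onsets are redrawn uniformly within their own
interictal intervals 30 times, the sensitivity against the unchanged alarms
recomputed each time, and a one-sample t-test asks whether the real
sensitivity exceeds the surrogate distribution (alpha = 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FiringPowerTrace",
    "AlarmSeries",
    "PerformanceReport",
    "firing_power",
    "raise_alarms",
    "score_alarms",
    "surrogate_validate",
]


@dataclass
class FiringPowerTrace:
    """Smoothed classifier output: moving average of binary outputs over the
    last ``tau`` epochs (zero-padded warm-up)."""

    values: np.ndarray
    tau: int
    epoch_times: np.ndarray


@dataclass
class AlarmSeries:
    alarm_times: np.ndarray
    refractory_s: float
    verdicts: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class PerformanceReport:
    """Event-level performance of one patient (or one iteration)."""

    ss: float
    fpr_per_hour: float
    n_seizures: int
    n_predicted: int
    n_false_alarms: int
    interictal_hours: float
    surrogate_ss: np.ndarray | None = None
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    validated: bool = False
    extras: dict = field(default_factory=dict)


def firing_power(outputs: np.ndarray, tau: int, epoch_times: np.ndarray | None = None) -> FiringPowerTrace:
    """Causal moving average of binary classifier outputs.

    ``fp[n]`` is the mean of the last ``tau`` outputs, treating epochs
    before the series start as 0 (damped warm-up, preventing spurious early
    alarms).  ``tau`` is one SOP of epochs (SOP minutes x 12 for 5-s
    epochs).
    """
    outputs = np.asarray(outputs, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if not np.isin(outputs, (0.0, 1.0)).all():
        raise ValueError("outputs must be binary")
    if tau > len(outputs):
        logger.warning(
            "firing_power: tau=%d exceeds series length %d (padded history)",
            tau,
            len(outputs),
        )
    padded = np.concatenate([np.zeros(tau), outputs])
    csum = np.cumsum(padded)
    values = (csum[tau:] - csum[:-tau]) / tau
    if epoch_times is None:
        epoch_times = np.arange(len(outputs), dtype=float)
    return FiringPowerTrace(values=values, tau=tau, epoch_times=np.asarray(epoch_times, dtype=float))


def raise_alarms(
    trace: FiringPowerTrace,
    threshold: float = 0.5,
    refractory_s: float = 1800.0,
) -> AlarmSeries:
    """Threshold crossing with refractory bookkeeping.

    An alarm fires at the first epoch where the trace reaches ``threshold``
    coming from below (upward crossing) outside every earlier alarm's
    refractory interval.  A trace still at/above threshold when a refractory
    interval expires re-alarms immediately — so a persistently saturated
    trace yields exactly one alarm per refractory period.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    values = trace.values
    times = trace.epoch_times
    alarms: list[float] = []
    refractory_until = -np.inf
    prev_blocked = False  # previous epoch inside refractory
    prev_value = 0.0  # virtual epoch before the series (zero warm-up)
    for v, t in zip(values, times):
        if t < refractory_until:
            prev_blocked = True
            prev_value = v
            continue
        if v >= threshold and (prev_value < threshold or prev_blocked):
            alarms.append(float(t))
            refractory_until = t + refractory_s
        prev_blocked = False
        prev_value = v
    return AlarmSeries(
        alarm_times=np.array(alarms),
        refractory_s=refractory_s,
    )


def _classify_alarms(
    alarm_times: np.ndarray, onsets: np.ndarray, sop_min: float, sph_min: float
) -> tuple[np.ndarray, int]:
    """Verdict per alarm plus the number of distinct onsets predicted.

    Alarm t is true iff some onset lies in ``(t + SPH, t + SPH + SOP]``;
    each onset can credit at most one alarm (the earliest).
    """
    sph_s, sop_s = sph_min * 60.0, sop_min * 60.0
    verdicts = np.zeros(len(alarm_times), dtype=bool)
    used = np.zeros(len(onsets), dtype=bool)
    for i, t in enumerate(alarm_times):
        lo, hi = t + sph_s, t + sph_s + sop_s
        for j, onset in enumerate(onsets):
            if not used[j] and lo < onset <= hi:
                verdicts[i] = True
                used[j] = True
                break
    return verdicts, int(used.sum())


def score_alarms(
    alarms: AlarmSeries,
    onsets: np.ndarray,
    sop_min: float,
    sph_min: float,
    interictal_hours: float,
) -> PerformanceReport:
    """Seizure sensitivity and FPR/h for one set of alarms.

    SS = predicted seizures / tested seizures; FPR/h divides false alarms by
    the interictal hours minus the refractory time the alarms opened.  SS is
    NaN (flagged) when no seizure was tested.
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    verdicts, n_predicted = _classify_alarms(
        alarms.alarm_times, onsets, sop_min, sph_min
    )
    alarms.verdicts = verdicts
    n_false = int((~verdicts).sum())
    refractory_h = len(alarms.alarm_times) * alarms.refractory_s / 3600.0
    denom = interictal_hours - refractory_h
    fpr = n_false / denom if denom > 0 else float("inf")
    if len(onsets) == 0:
        logger.warning("score_alarms: zero tested seizures; SS undefined")
        ss = float("nan")
    else:
        ss = n_predicted / len(onsets)
    return PerformanceReport(
        ss=ss,
        fpr_per_hour=fpr,
        n_seizures=len(onsets),
        n_predicted=n_predicted,
        n_false_alarms=n_false,
        interictal_hours=interictal_hours,
    )


def surrogate_validate(
    alarms_by_seizure: list[AlarmSeries],
    intervals: list[tuple[float, float]],
    real_ss: float,
    sop_min: float | np.ndarray,
    sph_min: float,
    n_runs: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> PerformanceReport:
    """Surrogate time-series validation of the achieved sensitivity.

    For each run every tested seizure's onset is redrawn uniformly within
    its own interictal interval (seizure by seizure, so the temporal
    distribution of seizures is respected), keeping the surrogate onset at
    least SPH + SOP from the interval start so the surrogate preictal window
    fits inside the interval.  The unchanged alarms are rescored against the
    surrogate onsets; a one-sample t-test then compares the ``n_runs``
    surrogate sensitivities against the real one.  ``validated`` means the
    real sensitivity exceeds the surrogate mean with p < ``alpha`` under the
    null "the real sensitivity is not superior to the surrogate's".

    ``sop_min`` may be a scalar or one value per tested seizure (the grid
    search may select a different preictal duration per iteration).
    """
    if len(alarms_by_seizure) != len(intervals):
        raise ValueError("need one interictal interval per tested seizure")
    sops = np.broadcast_to(
        np.asarray(sop_min, dtype=float), (len(intervals),)
    )
    rng = np.random.default_rng(seed)
    lows, highs = [], []
    for (lo, hi), sop in zip(intervals, sops):
        draw_lo = lo + (sph_min + sop) * 60.0
        if hi <= lo or hi <= draw_lo:
            raise ValueError(
                f"interictal interval [{lo}, {hi})s too short for a surrogate "
                "onset (must fit SPH + SOP)"
            )
        lows.append(draw_lo)
        highs.append(hi)

    surrogate_ss = np.empty(n_runs)
    for r in range(n_runs):
        predicted = 0
        for series, lo, hi, sop in zip(alarms_by_seizure, lows, highs, sops):
            onset = rng.uniform(lo, hi)
            _, n_pred = _classify_alarms(
                series.alarm_times, np.array([onset]), sop, sph_min
            )
            predicted += n_pred
        surrogate_ss[r] = predicted / len(alarms_by_seizure)

    mean_surr = float(surrogate_ss.mean())
    if np.allclose(surrogate_ss.std(), 0.0):
        # degenerate surrogate distribution: decide by direct comparison
        t_stat = float("inf") if real_ss > mean_surr else float("nan")
        p = 0.0 if real_ss > mean_surr else 1.0
    else:
        t_res = stats.ttest_1samp(surrogate_ss, popmean=real_ss, alternative="less")
        t_stat, p = float(t_res.statistic), float(t_res.pvalue)
    validated = bool(real_ss > mean_surr and p < alpha)
    return PerformanceReport(
        ss=real_ss,
        fpr_per_hour=float("nan"),
        n_seizures=len(alarms_by_seizure),
        n_predicted=int(round(real_ss * len(alarms_by_seizure))),
        n_false_alarms=0,
        interictal_hours=float("nan"),
        surrogate_ss=surrogate_ss,
        t_statistic=t_stat,
        p_value=p,
        validated=validated,
        extras={"surrogate_mean": mean_surr, "alpha": alpha, "n_runs": n_runs},
    )
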