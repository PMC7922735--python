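"""Diel binning, standardized occurrence, POF aging and spawning-cohort assignment.

The inference chain: capture times are pooled into twelve two-hour diel bins;
per-bin stage counts are standardized first by the number of females carrying
POFs in the bin (correcting for uneven catch effort) and then renormalized to
per-bin stage proportions; each stage's diel occurrence then determines

* its spawning-cohort day -- a stage detectable only in a portion of the
  24-h cycle (a contiguous absence block of >= ``min_absent_bins`` sampled
  bins, default 3 bins = 6 h) was left by the night of capture's cycle
  (Day 0), whereas a stage present around the whole cycle must persist more
  than one day and belongs to the previous night (Day 1);
* its mean age -- the occurrence-weighted mean of the interval offsets from
  the daily spawning peak, plus 24 h for Day-1 stages.

Because a Day-1 stage wraps the diel circle, its interval offsets cannot be
averaged on a fixed 0-24 h scale: each bin's offset is first unwrapped to the
representative within +-12 h of the occurrence's weighted circular mean.
Day-0 offsets are anchored on a cut ``pre_peak_window`` hours before the peak,
so samples taken just before the nominal peak (early spawners of the same
night) count as small negative offsets rather than ~+23 h.

Confidence intervals come from a seeded percentile bootstrap resampling
females (clusters), holding each stage's detected cohort day fixed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import (HOURS_PER_DAY, circular_mean_hours, longest_circular_run,
                    unwrap_about)
from .morphometrics import _stage_of, interval_of
from .simulate import OvaryRecord, SimulationConfig
from .staging import STAGES, PofStage

N_BINS = 12
DEFAULT_ASP_HOUR = 22.0
DEFAULT_MIN_ABSENT_BINS = 3   # >= 6 h contiguous absence marks a Day-0 stage
DEFAULT_PRE_PEAK_WINDOW = 3.0  # hours before the peak still counted as "tonight"


@dataclass
class IntervalSummary:
    """Counts and standardized occurrence for one two-hour diel bin."""

    interval_index: int
    midpoint: float                       # clock hour
    n_females: int                        # all sampled females in the bin
    n_females_with_pofs: int
    n_pofs: int
    raw_counts: np.ndarray                # length 6, per stage
    std_occurrence: Optional[np.ndarray] = None  # per-bin stage proportions

    @property
    def sampled(self) -> bool:
        return self.n_females > 0


@dataclass(frozen=True)
class StageAgeEstimate:
    stage: PofStage
    cohort_day: int                       # 0 or 1
    mean_age: float                       # hours since the spawning peak
    ci_low: float
    ci_high: float
    max_persistence: float                # latest offset with nonzero occurrence


@dataclass(frozen=True)
class CohortLabel:
    fish_id: int
    labels: frozenset                     # subset of {"Day0", "Day1"}
    basis: tuple                          # stages observed in the ovary


class DataIntegrityError(ValueError):
    pass


def _capture_hour(rec: OvaryRecord) -> float:
    t = rec.capture_time
    return t.hour + t.minute / 60.0 + t.second / 3600.0


def bin_records(records: Iterable[OvaryRecord]) -> List[IntervalSummary]:
    """Pool records into the twelve half-open diel bins [2k, 2k+2) by clock hour."""
    n_fem = np.zeros(N_BINS, int)
    n_fwp = np.zeros(N_BINS, int)
    counts = np.zeros((N_BINS, 6), int)
    for rec in records:
        b = interval_of(_capture_hour(rec))
        n_fem[b] += 1
        if rec.pofs:
            n_fwp[b] += 1
        for p in rec.pofs:
            counts[b, int(_stage_of(p)) - 1] += 1
    return [IntervalSummary(interval_index=b, midpoint=2.0 * b + 1.0,
                            n_females=int(n_fem[b]),
                            n_females_with_pofs=int(n_fwp[b]),
                            n_pofs=int(counts[b].sum()),
                            raw_counts=counts[b].copy())
            for b in range(N_BINS)]


def standardize_occurrence(summary: IntervalSummary) -> IntervalSummary:
    """Two-step standardization of one bin's stage counts.

    Step 1 divides each stage count by the number of females with POFs in the
    bin (removing catch-effort differences); step 2 renormalizes the result to
    proportions summing to one over stages.  Bins without POFs yield an
    all-missing vector, not zeros.
    """
    if summary.n_pofs > 0 and summary.n_females_with_pofs == 0:
        raise DataIntegrityError(
            f"interval {summary.interval_index}: {summary.n_pofs} POFs recorded "
            "but no females with POFs")
    if summary.n_pofs == 0:
        occ = None
    else:
        v = summary.raw_counts.astype(float) / summary.n_females_with_pofs
        occ = v / v.sum()
    return IntervalSummary(summary.interval_index, summary.midpoint,
                           summary.n_females, summary.n_females_with_pofs,
                           summary.n_pofs, summary.raw_counts.copy(), occ)


def standardize_all(summaries: Iterable[IntervalSummary]) -> List[IntervalSummary]:
    return [standardize_occurrence(s) for s in summaries]


def detect_cohort_day(stage: PofStage, summaries: Sequence[IntervalSummary],
                      min_absent_bins: int = DEFAULT_MIN_ABSENT_BINS) -> int:
    """Day 0 if the stage shows a contiguous circular absence block of at
    least ``min_absent_bins`` sampled bins; Day 1 otherwise (present around
    the whole cycle).  Unsampled bins are ignored, so sparse effort does not
    masquerade as absence."""
    stage = PofStage(stage)
    sampled = [s for s in summaries if s.sampled]
    if not sampled:
        raise ValueError("no sampled intervals")
    present = np.array([s.raw_counts[int(stage) - 1] > 0 for s in sampled])
    if not present.any():
        raise ValueError(f"stage {stage.name} not observed in any interval")
    return 0 if longest_circular_run(~present) >= min_absent_bins else 1


def _signed_offsets(midpoints: np.ndarray, asp_hour: float,
                    pre_peak_window: float) -> np.ndarray:
    raw = (midpoints - asp_hour) % HOURS_PER_DAY
    return np.where(raw >= HOURS_PER_DAY - pre_peak_window,
                    raw - HOURS_PER_DAY, raw)


def _weighted_age(offsets: np.ndarray, weights: np.ndarray, cohort_day: int,
                  pre_peak_window: float) -> float:
    """Occurrence-weighted mean offset, unwrapped on the diel circle."""
    w = weights / weights.sum()
    mu = circular_mean_hours(offsets, w)
    m = float(np.sum(w * unwrap_about(offsets, mu)))
    if cohort_day == 0:
        m = ((m + pre_peak_window) % HOURS_PER_DAY) - pre_peak_window
    else:
        m = m % HOURS_PER_DAY
    return m + HOURS_PER_DAY * cohort_day


def estimate_stage_age(stage: PofStage, summaries: Sequence[IntervalSummary],
                       asp_hour: float = DEFAULT_ASP_HOUR,
                       cohort_day: Optional[int] = None,
                       records: Optional[Sequence[OvaryRecord]] = None,
                       n_boot: int = 1000, seed: int = 0,
                       pre_peak_window: float = DEFAULT_PRE_PEAK_WINDOW,
                       min_absent_bins: int = DEFAULT_MIN_ABSENT_BINS) -> StageAgeEstimate:
    """Mean age of a POF stage relative to the daily spawning peak.

    Weights are the standardized occurrences of the stage over bins (invariant
    to any uniform rescaling); ``cohort_day`` defaults to the detected one and
    adds 24 h for Day-1 stages.  ``max_persistence`` is the latest unwrapped
    offset with nonzero occurrence.  With ``records``, a seeded female-cluster
    bootstrap gives a percentile 95% CI (cohort day held fixed).
    """
    stage = PofStage(stage)
    col = int(stage) - 1
    if cohort_day is None:
        cohort_day = detect_cohort_day(stage, summaries, min_absent_bins)
    if cohort_day not in (0, 1):
        raise ValueError(f"cohort_day must be 0 or 1, got {cohort_day}")
    used = [s for s in summaries
            if s.std_occurrence is not None and s.std_occurrence[col] > 0]
    if not used:
        raise ValueError(f"stage {stage.name} has all-zero occurrence")
    mids = np.array([s.midpoint for s in used])
    w = np.array([s.std_occurrence[col] for s in used])
    offsets = _signed_offsets(mids, asp_hour, pre_peak_window)
    mean_age = _weighted_age(offsets, w, cohort_day, pre_peak_window)

    mu = circular_mean_hours(offsets, w / w.sum())
    unwrapped = unwrap_about(offsets, mu)
    if cohort_day == 0:
        unwrapped = ((unwrapped + pre_peak_window) % HOURS_PER_DAY) - pre_peak_window
    else:
        unwrapped = unwrapped % HOURS_PER_DAY
    max_persistence = float(unwrapped.max() + HOURS_PER_DAY * cohort_day
                            + 1.0)  # to the end of the 2-h bin

    lo = hi = mean_age
    if records is not None and n_boot > 0:
        ages = _bootstrap_ages(records, {stage: cohort_day}, asp_hour,
                               pre_peak_window, n_boot, seed)[stage]
        if ages.size:
            lo, hi = (float(x) for x in np.percentile(ages, [2.5, 97.5]))
            lo, hi = min(lo, mean_age), max(hi, mean_age)
    return StageAgeEstimate(stage, int(cohort_day), float(mean_age),
                            float(lo), float(hi), max_persistence)


def _bootstrap_ages(records: Sequence[OvaryRecord], stage_days: Dict[PofStage, int],
                    asp_hour: float, pre_peak_window: float,
                    n_boot: int, seed: int) -> Dict[PofStage, np.ndarray]:
    """Female-cluster bootstrap of the occurrence-weighted stage ages.

    Smoothed over the diel bins: capture times are only known to a two-hour
    interval, so each replicate represents a bin by a uniform draw within it
    rather than the fixed midpoint; the percentile CI then reflects both the
    female-resampling noise and the interval-censoring of capture times.
    """
    recs = list(records)
    F = len(recs)
    bins = np.array([interval_of(_capture_hour(r)) for r in recs])
    counts = np.zeros((F, N_BINS, 6))
    has_pof = np.zeros((F, N_BINS))
    for i, rec in enumerate(recs):
        if rec.pofs:
            has_pof[i, bins[i]] = 1.0
        for p in rec.pofs:
            counts[i, bins[i], int(_stage_of(p)) - 1] += 1
    mids = 2.0 * np.arange(N_BINS) + 1.0
    offsets = _signed_offsets(mids, asp_hour, pre_peak_window)
    rng = np.random.default_rng(seed)
    p_uniform = np.full(F, 1.0 / F)
    out: Dict[PofStage, list] = {s: [] for s in stage_days}
    flat = counts.reshape(F, -1)
    for _ in range(n_boot):
        wgt = rng.multinomial(F, p_uniform).astype(float)
        # capture times are interval-censored: represent each bin by a point
        # drawn within it, so the CI carries the discretization uncertainty
        offs = offsets + rng.uniform(-1.0, 1.0, N_BINS)
        c = (wgt @ flat).reshape(N_BINS, 6)
        fwp = wgt @ has_pof
        occ = np.zeros((N_BINS, 6))
        nz = c.sum(axis=1) > 0
        ok = nz & (fwp > 0)
        occ[ok] = c[ok] / fwp[ok, None]
        ssum = occ.sum(axis=1, keepdims=True)
        occ = np.divide(occ, ssum, out=np.zeros_like(occ), where=ssum > 0)
        for s, day in stage_days.items():
            w = occ[:, int(s) - 1]
            if w.sum() > 0:
                out[s].append(_weighted_age(offs[w > 0], w[w > 0], day,
                                            pre_peak_window))
    return {s: np.asarray(v) for s, v in out.items()}


def assign_female_cohorts(record: OvaryRecord,
                          stage_days: Dict[PofStage, int]) -> CohortLabel:
    """Label one female with the spawning-cohort days of her observed stages.

    A female carrying both a Day-0 and a Day-1 stage spawned on two
    consecutive nights and receives both labels.
    """
    if not record.pofs:
        raise ValueError(f"fish {record.fish_id} has no staged POFs")
    stages_present = []
    for p in record.pofs:
        s = _stage_of(p)
        if s not in stage_days:
            raise ValueError(
                f"fish {record.fish_id}: POF {p.pof_id} has stage {s.name} "
                "with no cohort-day assignment")
        stages_present.append(s)
    labels = frozenset(f"Day{stage_days[s]}" for s in set(stages_present))
    return CohortLabel(record.fish_id, labels,
                       tuple(sorted(set(stages_present))))


def analyze_records(records: Sequence[OvaryRecord],
                    asp_hour: float = DEFAULT_ASP_HOUR,
                    min_absent_bins: int = DEFAULT_MIN_ABSENT_BINS,
                    pre_peak_window: float = DEFAULT_PRE_PEAK_WINDOW,
                    n_boot: int = 1000, seed: int = 0) -> dict:
    """Run the full aging chain; returns summaries, stage days, ages, labels."""
    summaries = standardize_all(bin_records(records))
    observed = [s for s in STAGES
                if any(sm.raw_counts[int(s) - 1] > 0 for sm in summaries)]
    stage_days = {s: detect_cohort_day(s, summaries, min_absent_bins)
                  for s in observed}
    ages = {}
    if observed:
        day_map = dict(stage_days)
        boot = _bootstrap_ages(records, day_map, asp_hour, pre_peak_window,
                               n_boot, seed)
        for s in observed:
            est = estimate_stage_age(s, summaries, asp_hour, stage_days[s],
                                     records=None, pre_peak_window=pre_peak_window)
            b = boot[s]
            lo, hi = (est.mean_age, est.mean_age)
            if b.size:
                lo, hi = (float(x) for x in np.percentile(b, [2.5, 97.5]))
                lo, hi = min(lo, est.mean_age), max(hi, est.mean_age)
            ages[s] = StageAgeEstimate(s, est.cohort_day, est.mean_age, lo, hi,
                                       est.max_persistence)
    cohorts = [assign_female_cohorts(r, stage_days) for r in records if r.pofs]
    return {"summaries": summaries, "stage_days": stage_days,
            "stage_ages": ages, "cohorts": cohorts}


def recover_parameters(records: Sequence[OvaryRecord], config: SimulationConfig,
                       asp_hour: Optional[float] = None, n_boot: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Validation harness: estimated stage ages / cohort days vs simulator truth.

    Truth per stage is the midpoint of its window in the configured
    (temperature-scaled) schedule and the day containing that midpoint.
    Requires records carrying truth columns; returns an empty frame when no
    POFs were simulated (degenerate configurations must not crash).
    """
    recs = [r for r in records]
    pofs = [p for r in recs for p in r.pofs]
    if pofs and any(p.truth_age is None for p in pofs):
        raise ValueError("records carry no truth columns; "
                         "recover_parameters needs simulated data")
    if not pofs:
        return pd.DataFrame(columns=[
            "stage", "truth_mid_age", "est_mean_age", "bias", "ci_low",
            "ci_high", "ci_covers_truth", "truth_day", "est_day", "day_match"])
    asp = config.asp_hour if asp_hour is None else asp_hour
    res = analyze_records(recs, asp_hour=asp, n_boot=n_boot, seed=seed)
    mids = config.scaled_schedule().mid_stage_ages
    rows = []
    for s, est in res["stage_ages"].items():
        mid = float(mids[int(s) - 1])
        truth_day = 0 if mid < HOURS_PER_DAY else 1
        rows.append({
            "stage": s.name, "truth_mid_age": mid,
            "est_mean_age": est.mean_age, "bias": est.mean_age - mid,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "ci_covers_truth": bool(est.ci_low <= mid <= est.ci_high),
            "truth_day": truth_day, "est_day": est.cohort_day,
            "day_match": est.cohort_day == truth_day})
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[IntervalSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"interval_index": s.interval_index, "midpoint": s.midpoint,
               "n_females": s.n_females,
               "n_females_with_pofs": s.n_females_with_pofs, "n_pofs": s.n_pofs}
        for k, st in enumerate(STAGES):
            row[f"n_{st.name}"] = int(s.raw_counts[k])
            row[f"occ_{st.name}"] = (float(s.std_occurrence[k])
                                     if s.std_occurrence is not None else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def ages_to_frame(ages: Dict[PofStage, StageAgeEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "stage": s.name, "cohort_day": e.cohort_day, "mean_age": e.mean_age,
        "ci_low": e.ci_low, "ci_high": e.ci_high,
        "max_persistence": e.max_persistence,
    } for s, e in sorted(ages.items())])


def cohorts_to_frame(cohorts: Sequence[CohortLabel]) -> pd.DataFrame:
    return pd.DataFrame([{
        "fish_id": c.fish_id,
        "labels": ";".join(sorted(c.labels)),
        "basis": ";".join(s.name for s in c.basis),
    } for c in cohorts])
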