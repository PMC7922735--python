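"""Per-stage POF area statistics and diel area dynamics.

The degeneration of a POF is accompanied by shrinkage of its cross-sectional
area: hardly any between stages I and II, then progressive contraction down to
roughly 28% of the initial area by stage VI.  This module provides

* per-stage area summaries (counts, means, dispersion, ratio to stage I);
* the global Kruskal-Wallis rank test of equal stage areas, with tie
  correction, an exact-enumeration option for tiny samples, and Dunn's
  rank-based pairwise post hoc comparisons with Bonferroni adjustment
  (the upper-triangular matrix layout of the field study's pairwise table);
* the relative area occupied by POFs of each stage on the sectioned gonad
  tissue (mm^2 POF / mm^2 gonad) per two-hour diel interval;
* per-stage resorption rates (relative-area decline per hour along the
  follicle's life) with cluster-bootstrap confidence intervals resampling
  females, not POFs, to respect within-ovary correlation.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import HOURS_PER_DAY
from .simulate import OvaryRecord, PofObservation
from .staging import STAGES, PofStage

UM2_PER_MM2 = 1e6
STAGE_NAMES = [s.name for s in STAGES]


@dataclass(frozen=True)
class StageAreaSummary:
    stage: PofStage
    n: int
    mean_area: float                    # um^2
    dispersion: float                   # sample sd, um^2
    relative_to_stage_I: Optional[float]


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    n_total: int
    p: float
    pairwise: pd.DataFrame  # upper-triangular adjusted p-values, stage x stage


@dataclass(frozen=True)
class ResorptionRateEstimate:
    stage: PofStage
    rate: Optional[float]       # relative-area reduction per hour
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_intervals_used: int
    estimable: bool


def _stage_of(pof: PofObservation) -> PofStage:
    if pof.stage is not None:
        return pof.stage
    if pof.features is not None:
        from .staging import classify_stage
        return classify_stage(pof.features)
    raise ValueError(f"POF {pof.pof_id} has neither stage nor features")


def stage_area_summary(pofs: Iterable[PofObservation]) -> List[StageAreaSummary]:
    """Mean area per stage present, with the ratio to stage I when available."""
    by_stage: dict = {}
    for p in pofs:
        if p.area <= 0:
            raise ValueError(f"POF {p.pof_id} has non-positive area {p.area}")
        by_stage.setdefault(_stage_of(p), []).append(p.area)
    mean_I = float(np.mean(by_stage[PofStage.I])) if PofStage.I in by_stage else None
    out = []
    for s in STAGES:
        if s not in by_stage:
            continue
        a = np.asarray(by_stage[s])
        out.append(StageAreaSummary(
            stage=s, n=a.size, mean_area=float(a.mean()),
            dispersion=float(a.std(ddof=1)) if a.size > 1 else 0.0,
            relative_to_stage_I=(float(a.mean() / mean_I) if mean_I else None)))
    return out


def _dunn_pairwise(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after a Kruskal-Wallis test.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided p, Bonferroni-adjusted
    over the observed pairs.  Upper triangle filled, rest NaN.
    """
    keys = [s for s in STAGES if s in groups]
    values = np.concatenate([np.asarray(groups[k], float) for k in keys])
    ranks = stats.rankdata(values)
    N = values.size
    sizes = {k: len(groups[k]) for k in keys}
    mean_ranks, i0 = {}, 0
    for k in keys:
        mean_ranks[k] = ranks[i0:i0 + sizes[k]].mean()
        i0 += sizes[k]
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var0 = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)) if N > 1 else 0.0
    m = len(keys) * (len(keys) - 1) // 2
    mat = pd.DataFrame(np.nan, index=STAGE_NAMES, columns=STAGE_NAMES)
    for a, b in itertools.combinations(keys, 2):
        se = math.sqrt(var0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        elif adjust != "none":
            raise ValueError(f"unknown adjustment {adjust!r}")
        mat.loc[a.name, b.name] = p
    return mat


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from first principles (used for 'exact')."""
    values = np.concatenate(groups)
    ranks = stats.rankdata(values)
    N = values.size
    h, i0 = 0.0, 0
    for g in groups:
        r = ranks[i0:i0 + len(g)]
        h += len(g) * (r.mean() ** 2)
        i0 += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    denom = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
    return h / denom if denom > 0 else 0.0


def exact_kw_pvalue(groups: Sequence[Sequence[float]]) -> float:
    """Exact permutation p-value of the tie-corrected H by full enumeration.

    Enumerates every assignment of the pooled observations to groups of the
    observed sizes (multivariate hypergeometric support); feasible for pooled
    n up to ~12.  P(H_perm >= H_obs) with a small numerical guard on ties.
    """
    gs = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(gs)
    N = pooled.size
    if N > 12:
        raise ValueError("exact enumeration supported only for pooled n <= 12")
    sizes = [g.size for g in gs]
    h_obs = _kw_statistic(gs)
    idx = list(range(N))
    count = total = 0
    for first in itertools.combinations(idx, sizes[0]):
        rest1 = [i for i in idx if i not in first]
        for second in itertools.combinations(rest1, sizes[1]) if len(sizes) > 2 else [tuple(rest1)]:
            parts = [list(first), list(second)]
            used = set(first) | set(second)
            remaining = [i for i in idx if i not in used]
            if len(sizes) == 2:
                parts = [list(first), remaining]
            elif len(sizes) == 3:
                parts = [list(first), list(second), remaining]
            else:
                raise ValueError("exact enumeration implemented for 2 or 3 groups")
            h = _kw_statistic([pooled[p] for p in parts])
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
    return count / total


def kruskal_wallis_by_stage(pofs: Iterable[PofObservation],
                            method: str = "asymptotic") -> KWResult:
    """Kruskal-Wallis test of equal POF areas across stages, with Dunn post hoc.

    ``method="asymptotic"`` uses the chi-square reference distribution;
    ``method="exact"`` replaces the p-value by full permutation enumeration
    (tiny samples only).  H always carries the standard tie correction.
    """
    groups: dict = {}
    for p in pofs:
        groups.setdefault(_stage_of(p), []).append(p.area)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two non-empty stage groups")
    keys = [s for s in STAGES if s in groups]
    arrays = [np.asarray(groups[k], float) for k in keys]
    if all(np.all(a == arrays[0][0]) for a in arrays):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    if method == "exact":
        p = exact_kw_pvalue(arrays)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    n_total = int(sum(a.size for a in arrays))
    return KWResult(H=float(h), df=len(keys) - 1, n_total=n_total, p=float(p),
                    pairwise=_dunn_pairwise(groups))


def interval_of(clock_hour: float) -> int:
    """Two-hour diel bin index of a clock hour: [2k, 2k+2) -> k."""
    return int((clock_hour % HOURS_PER_DAY) // 2)


def relative_area_by_interval(records: Iterable[OvaryRecord]) -> pd.DataFrame:
    """Mean relative POF-occupied area (mm^2 POF / mm^2 gonad) per interval x stage.

    Each sampled female contributes the summed area of her stage-s POFs
    divided by her sectioned gonad area (females without that stage count as
    zero); intervals with no sampled females are left missing (NaN rows),
    never imputed as zero.
    """
    sums = np.zeros((12, 6))
    n_fem = np.zeros(12, int)
    for rec in records:
        if rec.gonad_section_area <= 0:
            raise ValueError(
                f"fish {rec.fish_id}: gonad_section_area must be positive, "
                f"got {rec.gonad_section_area}")
        hour = rec.capture_time.hour + rec.capture_time.minute / 60.0 \
            + rec.capture_time.second / 3600.0
        b = interval_of(hour)
        n_fem[b] += 1
        for p in rec.pofs:
            s = int(_stage_of(p))
            sums[b, s - 1] += (p.area / UM2_PER_MM2) / rec.gonad_section_area
    mat = np.full((12, 6), np.nan)
    sampled = n_fem > 0
    mat[sampled] = sums[sampled] / n_fem[sampled, None]
    return pd.DataFrame(mat, index=range(12), columns=STAGE_NAMES)


def _elapsed_order(asp_hour: float, pre_peak_window: float = 3.0) -> np.ndarray:
    """Interval indices ordered by elapsed time from the spawning peak."""
    mids = 2.0 * np.arange(12) + 1.0
    raw = (mids - asp_hour) % HOURS_PER_DAY
    raw = np.where(raw >= HOURS_PER_DAY - pre_peak_window, raw - HOURS_PER_DAY, raw)
    return np.argsort(raw)


def _rate_from_series(rel: np.ndarray, order: np.ndarray) -> tuple:
    """Mean per-hour decline over successive present intervals (2 h apart).

    Only the declining limb is used: intervals from the stage's occupancy
    maximum onward (in elapsed order).  Before the maximum the stage is still
    filling with newly arriving follicles, so differences there measure
    cohort influx, not resorption.
    """
    seq = [(pos, rel[i]) for pos, i in enumerate(order)
           if np.isfinite(rel[i]) and rel[i] > 0]
    if not seq:
        return None, 0
    k = int(np.argmax([v for _, v in seq]))
    seq = seq[k:]
    declines = [(a[1] - b[1]) / 2.0
                for a, b in zip(seq, seq[1:]) if b[0] == a[0] + 1]
    if not declines:
        return None, 0
    return float(np.mean(declines)), len(declines) + 1


def _record_contributions(records: Sequence[OvaryRecord]) -> tuple:
    """Per-female diel bin and per-stage relative-area contribution (F x 6)."""
    bins = np.empty(len(records), int)
    contrib = np.zeros((len(records), 6))
    for i, rec in enumerate(records):
        if rec.gonad_section_area <= 0:
            raise ValueError(
                f"fish {rec.fish_id}: gonad_section_area must be positive, "
                f"got {rec.gonad_section_area}")
        hour = rec.capture_time.hour + rec.capture_time.minute / 60.0 \
            + rec.capture_time.second / 3600.0
        bins[i] = interval_of(hour)
        for p in rec.pofs:
            s = int(_stage_of(p))
            contrib[i, s - 1] += (p.area / UM2_PER_MM2) / rec.gonad_section_area
    return bins, contrib


def _matrix_from_contributions(bins: np.ndarray, contrib: np.ndarray,
                               weights: np.ndarray) -> np.ndarray:
    sums = np.zeros((12, 6))
    np.add.at(sums, bins, weights[:, None] * contrib)
    n_fem = np.bincount(bins, weights=weights, minlength=12)
    mat = np.full((12, 6), np.nan)
    mat[n_fem > 0] = sums[n_fem > 0] / n_fem[n_fem > 0, None]
    return mat


def resorption_rate(relative_area_matrix: pd.DataFrame, stage: PofStage,
                    records: Optional[Sequence[OvaryRecord]] = None,
                    asp_hour: float = 22.0, n_boot: int = 1000,
                    seed: int = 0) -> ResorptionRateEstimate:
    """Per-stage resorption rate: relative-area decline per hour along the
    follicle's life (intervals ordered by elapsed time from the spawning peak,
    successive sampled intervals only, gaps never interpolated).

    When ``records`` are given, a seeded bootstrap resampling females yields a
    percentile 95% CI.  A stage present in fewer than two successive intervals
    returns an explicit inestimable result rather than NaN.
    """
    stage = PofStage(stage)
    order = _elapsed_order(asp_hour)
    rel = relative_area_matrix[stage.name].to_numpy(float)
    rate, n_used = _rate_from_series(rel, order)
    if rate is None:
        return ResorptionRateEstimate(stage, None, None, None, 0, False)
    lo = hi = None
    if records is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        recs = list(records)
        bins, contrib = _record_contributions(recs)
        col = int(stage) - 1
        vals = []
        for _ in range(n_boot):
            w = rng.multinomial(len(recs), np.full(len(recs), 1.0 / len(recs)))
            bmat = _matrix_from_contributions(bins, contrib, w.astype(float))
            r, _ = _rate_from_series(bmat[:, col], order)
            if r is not None:
                vals.append(r)
        if vals:
            lo, hi = (float(x) for x in np.percentile(vals, [2.5, 97.5]))
            lo, hi = min(lo, rate), max(hi, rate)
    return ResorptionRateEstimate(stage, rate, lo, hi, n_used, True)


def resorption_rates(records: Sequence[OvaryRecord], asp_hour: float = 22.0,
                     n_boot: int = 1000, seed: int = 0) -> List[ResorptionRateEstimate]:
    """All six stages' resorption rates from one shared bootstrap pass."""
    recs = list(records)
    bins, contrib = _record_contributions(recs)
    order = _elapsed_order(asp_hour)
    point = _matrix_from_contributions(bins, contrib, np.ones(len(recs)))
    rates = [_rate_from_series(point[:, c], order) for c in range(6)]
    boot: list = [[] for _ in range(6)]
    if n_boot > 0 and recs:
        rng = np.random.default_rng(seed)
        p_uniform = np.full(len(recs), 1.0 / len(recs))
        for _ in range(n_boot):
            w = rng.multinomial(len(recs), p_uniform).astype(float)
            bmat = _matrix_from_contributions(bins, contrib, w)
            for c in range(6):
                r, _ = _rate_from_series(bmat[:, c], order)
                if r is not None:
                    boot[c].append(r)
    out = []
    for c, (rate, n_used) in enumerate(rates):
        stage = PofStage(c + 1)
        if rate is None:
            out.append(ResorptionRateEstimate(stage, None, None, None, 0, False))
            continue
        if boot[c]:
            lo, hi = (float(x) for x in np.percentile(boot[c], [2.5, 97.5]))
            lo, hi = min(lo, rate), max(hi, rate)
        else:
            lo = hi = None
        out.append(ResorptionRateEstimate(stage, rate, lo, hi, n_used, True))
    return out


def summaries_to_frame(summaries: List[StageAreaSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "stage": s.stage.name, "n": s.n, "mean_area": s.mean_area,
        "dispersion": s.dispersion, "relative_to_stage_I": s.relative_to_stage_I,
    } for s in summaries])
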