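"""Weighted-mean extrapolation of snippet metrics by history counts.

The stored-snippet sample is small and biased by the device's storage
policy. The daily Neurostimulator History, by contrast, counts (nearly)
every event. The extrapolation combines the two: per-stratum metrics come
from reviewed snippets; per-stratum *weights* come from the snippet trigger
shares multiplied by the aggregate history shares.

Raw weights follow the device-log formulas exactly:

- episode stratum (P, E):
  ``[ECoG episode count of P / total ECoG episode counts] *
  [history count of P / total history pattern counts]``
- long-episode stratum (P, LE):
  ``[ECoG long-episode count of P / total ECoG long-episode counts] *
  [LE_history / (LE_history + E_history)]``

Raw weights do not generally sum to one (the episode block is scaled by the
pattern share rather than the episode share), so a weighted "accuracy" on
raw weights need not lie in [0, 1]. The default mode therefore renormalizes
the raw weights to unit sum over surviving strata; ``mode="literal"``
reproduces the unnormalized sum for auditability.

History days flagged ``histogram_data_missing`` are excluded from weights,
rates and dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

from .performance import EpochConfusion
from .types import (
    ActivityLogRecord,
    EpisodeClass,
    Hemisphere,
    HistogramDay,
    PatternId,
    ProgrammingEpoch,
    StratumKey,
)

#: average calendar-month length in days, used for all per-month rates
DAYS_PER_MONTH = 30.44

#: default dose horizon: 8.5 average months post implantation
DEFAULT_DOSE_HORIZON_DAYS = 8.5 * DAYS_PER_MONTH

WeightMode = Literal["normalized", "literal"]


class NoWeightSupportError(ValueError):
    """Every raw weight is zero: the epoch has no weighting support."""


class UndefinedMetric(Exception):
    """Requested weighted metric is undefined in every surviving stratum."""


@dataclass
class WeightTable:
    """Raw and normalized per-stratum extrapolation weights for one epoch."""

    epoch_id: str
    raw: dict[StratumKey, float]
    normalized: dict[StratumKey, float]
    excluded_strata: set[StratumKey] = field(default_factory=set)


def _history_sums(hist: Iterable[HistogramDay]):
    pattern_totals: dict[PatternId, int] = {p: 0 for p in PatternId}
    e_total = le_total = 0
    n_excluded = 0
    for day in hist:
        if day.histogram_data_missing:
            n_excluded += 1
            continue
        for p, c in day.pattern_counts.items():
            pattern_totals[p] += c
        e_total += day.episode_count
        le_total += day.long_episode_count
    return pattern_totals, e_total, le_total, n_excluded


def compute_weight_table(conf: EpochConfusion,
                         hist: Iterable[HistogramDay]) -> WeightTable:
    """Per-stratum raw weights from ECoG trigger shares x history shares.

    Strata with zero snippet support get zero weight and are listed in
    ``excluded_strata``; normalized weights are raw / sum(raw) over the
    remaining strata. Raises :class:`NoWeightSupportError` when every raw
    weight is zero.
    """
    pattern_totals, e_hist, le_hist, _ = _history_sums(hist)
    h_total = sum(pattern_totals.values())
    ep_total = e_hist + le_hist

    # snippet trigger counts per stratum (tp + fp)
    n_ecog = {s: perf.n_triggered for s, perf in conf.per_stratum.items()}
    ne_total = sum(n for s, n in n_ecog.items()
                   if s.episode_class is EpisodeClass.EPISODE)
    nle_total = sum(n for s, n in n_ecog.items()
                    if s.episode_class is EpisodeClass.LONG_EPISODE)

    raw: dict[StratumKey, float] = {}
    excluded: set[StratumKey] = set()
    for s, n in n_ecog.items():
        if n == 0:
            excluded.add(s)
            raw[s] = 0.0
            continue
        if s.episode_class is EpisodeClass.EPISODE:
            ecog_share = n / ne_total if ne_total else 0.0
            hist_share = (pattern_totals[s.pattern] / h_total) if h_total else 0.0
        else:
            ecog_share = n / nle_total if nle_total else 0.0
            hist_share = (le_hist / ep_total) if ep_total else 0.0
        raw[s] = ecog_share * hist_share
        if raw[s] == 0.0:
            excluded.add(s)

    total = sum(w for s, w in raw.items() if s not in excluded)
    if total <= 0.0:
        raise NoWeightSupportError(
            f"no weighting support in epoch {conf.epoch_id}")
    normalized = {s: (w / total if s not in excluded else 0.0)
                  for s, w in raw.items()}
    return WeightTable(epoch_id=conf.epoch_id, raw=raw, normalized=normalized,
                       excluded_strata=excluded)


def weighted_epoch_metric(conf: EpochConfusion, wt: WeightTable,
                          metric: Literal["accuracy", "sensitivity",
                                          "specificity"],
                          mode: WeightMode = "normalized") -> float | None:
    """Weighted epoch metric: sum over surviving strata of stratum metric x
    weight.

    In ``normalized`` mode the weights are renormalized over the strata where
    the metric is defined, so the result is a convex combination (a genuine
    proportion). ``literal`` mode reproduces the unnormalized raw-weight sum.
    Returns ``None`` when the metric is undefined in every surviving stratum.
    """
    if wt.epoch_id != conf.epoch_id:
        raise ValueError("weight table and confusion belong to different epochs")
    values: dict[StratumKey, float] = {}
    for s, perf in conf.per_stratum.items():
        if s in wt.excluded_strata:
            continue
        v = getattr(perf, metric)
        if v is not None:
            values[s] = v
    if not values:
        return None
    if mode == "literal":
        return sum(wt.raw[s] * v for s, v in values.items())
    total = sum(wt.raw[s] for s in values)
    if total <= 0.0:
        return None
    return sum(wt.raw[s] / total * v for s, v in values.items())


def weighted_latency(conf: EpochConfusion, wt: WeightTable,
                     mode: WeightMode = "normalized") -> float | None:
    """Per-stratum mean TP latency combined with weights renormalized over
    latency-bearing strata. Negative results are legal (stimulation preceded
    the annotated EIP onset). ``None`` when no stratum has an eligible
    latency."""
    means: dict[StratumKey, float] = {}
    for s, perf in conf.per_stratum.items():
        if s in wt.excluded_strata or not perf.latencies_s:
            continue
        means[s] = sum(perf.latencies_s) / len(perf.latencies_s)
    if not means:
        return None
    if mode == "literal":
        return sum(wt.raw[s] * m for s, m in means.items())
    total = sum(wt.raw[s] for s in means)
    if total <= 0.0:
        return None
    return sum(wt.raw[s] / total * m for s, m in means.items())


class RateMetrics(NamedTuple):
    events_per_hour: float | None
    pattern_detections_per_hour: float | None
    stimulations_per_episode: float | None
    pct_days_at_limit: float | None
    days_to_stim_enabled: float | None


def event_rate_metrics(hist: Iterable[HistogramDay],
                       activity: Iterable[ActivityLogRecord],
                       epoch: ProgrammingEpoch,
                       all_epochs: Iterable[ProgrammingEpoch] | None = None,
                       ) -> RateMetrics:
    """Rates computed directly from log data, no weighting.

    Total events are pattern detections + saturations + magnet swipes.
    Days enter the daily-limit percentage only when histogram data are
    present. ``days_to_stim_enabled`` is computed from the patient's epoch
    sequence when ``all_epochs`` is given (days from the first epoch's start
    to the start of the first stimulation-enabled epoch).
    """
    hours = epoch.duration_hours
    if hours <= 0:
        raise ValueError(f"epoch {epoch.epoch_id} has non-positive duration")
    days = [d for d in hist if not d.histogram_data_missing]
    total_events = sum(d.total_events for d in days)
    pattern_events = sum(d.pattern_total for d in days)
    episodes = sum(d.episode_count + d.long_episode_count for d in days)
    therapies = sum(d.therapy_count for d in days)

    stim_per_episode = therapies / episodes if episodes > 0 else None
    at_limit = sum(1 for d in days
                   if d.therapy_count >= epoch.daily_therapy_limit)
    pct_at_limit = 100.0 * at_limit / len(days) if days else None

    days_to_stim: float | None = None
    if all_epochs is not None:
        mine = sorted((e for e in all_epochs
                       if e.patient_id == epoch.patient_id),
                      key=lambda e: e.start)
        if mine:
            first = mine[0].start
            for e in mine:
                if e.stimulation_enabled:
                    days_to_stim = (e.start - first).total_seconds() / 86400.0
                    break
    return RateMetrics(
        events_per_hour=total_events / hours,
        pattern_detections_per_hour=pattern_events / hours,
        stimulations_per_episode=stim_per_episode,
        pct_days_at_limit=pct_at_limit,
        days_to_stim_enabled=days_to_stim,
    )


def eip_rate(conf: EpochConfusion, wt: WeightTable,
             hist: Iterable[HistogramDay],
             epoch: ProgrammingEpoch,
             mode: WeightMode = "normalized") -> float | None:
    """Extrapolated EIPs per (30.44-day) month.

    The weighted EIP fraction — per-stratum TP/(TP+FP) combined with the
    normalized weights — scales the total history episode count; the result
    is divided by the epoch length in months. Returns 0.0 (with nothing to
    scale) when the history holds no episodes.
    """
    days = [d for d in hist if not d.histogram_data_missing]
    episodes = sum(d.episode_count + d.long_episode_count for d in days)
    span_months = epoch.duration_days / DAYS_PER_MONTH
    if span_months <= 0:
        raise ValueError(f"epoch {epoch.epoch_id} spans no time")
    fractions: dict[StratumKey, float] = {}
    for s, perf in conf.per_stratum.items():
        if s in wt.excluded_strata:
            continue
        n = perf.counts.tp + perf.counts.fp
        if n > 0:
            fractions[s] = perf.counts.tp / n
    if not fractions:
        return None
    if mode == "literal":
        frac = sum(wt.raw[s] * f for s, f in fractions.items())
    else:
        total = sum(wt.raw[s] for s in fractions)
        if total <= 0.0:
            return None
        frac = sum(wt.raw[s] / total * f for s, f in fractions.items())
    return frac * episodes / span_months


@dataclass
class DoseResult:
    total_uc_cm2: float
    by_hemisphere: dict[Hemisphere, float]


def charge_dose(hist: Iterable[HistogramDay],
                epochs: Iterable[ProgrammingEpoch],
                horizon_days: float = DEFAULT_DOSE_HORIZON_DAYS) -> DoseResult:
    """Cumulative single-phase charge density (uC/cm^2) at a fixed horizon.

    Per delivered therapy, each configured burst contributes
    ``pulses_per_burst x current_ma x pulse_width_us x 1e-3 /
    electrode_area_cm2``, attributed to the burst's hemisphere. Daily
    delivered-therapy counts come from the histogram (missing-flag days
    excluded); counts are apportioned to therapy slots in configured order —
    slot i fires in every episode that received at least i therapies, so
    slot 1 absorbs up to one delivery per episode, then slot 2, and so on.

    The horizon is measured from the earliest epoch start (implantation).
    """
    import datetime as _dt

    eps = sorted(epochs, key=lambda e: e.start)
    if not eps:
        raise ValueError("no epochs given")
    t0 = eps[0].start
    horizon_date = (t0 + _dt.timedelta(days=horizon_days)).date()
    by_hemi: dict[Hemisphere, float] = {h: 0.0 for h in Hemisphere}

    by_patient_day = {}
    for d in hist:
        if not d.histogram_data_missing:
            by_patient_day[(d.patient_id, d.date)] = d

    for (pid, day), rec in sorted(by_patient_day.items()):
        if day > horizon_date:
            continue
        epoch = next((e for e in eps if e.patient_id == pid
                      and e.start.date() <= day <= e.end.date()), None)
        if epoch is None or not epoch.therapies:
            continue
        n_therapies = rec.therapy_count
        episodes = rec.episode_count + rec.long_episode_count
        slot_counts = _apportion_to_slots(n_therapies, episodes,
                                          len(epoch.therapies))
        for slot_i, count in enumerate(slot_counts):
            if count == 0:
                continue
            for burst in epoch.therapies[slot_i].bursts:
                if burst.electrode_area_cm2 <= 0:  # pragma: no cover
                    raise ValueError("burst has no electrode area")
                dose = (burst.phase_charge_density_uc_cm2
                        * burst.pulses_per_burst * count)
                by_hemi[burst.hemisphere] += dose
    total = sum(by_hemi.values())
    return DoseResult(total_uc_cm2=total, by_hemisphere=by_hemi)


def _apportion_to_slots(n_therapies: int, n_episodes: int,
                        n_slots: int) -> list[int]:
    """Distribute a day's therapy deliveries over configured therapy slots.

    Slot i (0-based) is delivered in every episode receiving > i therapies;
    with only daily totals available, slot 0 takes up to one delivery per
    episode, the remainder spills to slot 1, and so on. Surplus beyond all
    slots x episodes (or with zero episodes) is assigned to slot 0.
    """
    counts = [0] * n_slots
    if n_slots == 0 or n_therapies <= 0:
        return counts
    if n_episodes <= 0:
        counts[0] = n_therapies
        return counts
    remaining = n_therapies
    for i in range(n_slots):
        take = min(remaining, n_episodes)
        counts[i] = take
        remaining -= take
        if remaining <= 0:
            break
    if remaining > 0:
        counts[0] += remaining
    return counts


def convex_bounds(values: Iterable[float]) -> tuple[float, float]:
    vals = list(values)
    return (min(vals), max(vals)) if vals else (math.nan, math.nan)
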