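"""Confusion-matrix classification of reviewed ECoG snippets.

Each annotated recording yields exactly one outcome label. Pattern-triggered
recordings are positives of the detector that fired and land in the
(Pattern, episode-class) stratum; non-triggered recordings (scheduled,
magnet, saturation) sample brain activity independently of the detector and
supply the pooled negative counts (TN without an EIP, FN with one).

Detection latency is recorded only for true positives, as first detection
time minus annotated EIP onset; recordings whose first episode is already in
progress at recording start are excluded from the latency pool (they still
count in the confusion totals). Negative latencies are legal — stimulation
can precede the annotated EIP onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple

from .types import (
    ALL_STRATA,
    EcogRecording,
    ProgrammingEpoch,
    StratumKey,
    TriggerType,
)


class Label(str, Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"


class NegativeAttribution(str, Enum):
    """How pooled negatives enter per-stratum denominators.

    Non-triggered recordings carry no triggering Pattern, so per-stratum
    accuracy/specificity need a policy for placing TN/FN counts:

    - ``LOG_PROPORTIONAL`` (model default): magnet-class negatives are first
      re-leveled with the complete Activity-Log counts — stored snippet
      classes survive storage at different rates, so the stored
      negative-to-trigger ratio is biased; multiplying the magnet-class
      negatives by ``(stored triggers / logged triggers) / (stored magnets /
      logged magnets)`` restores the ratio the log implies — then
      apportioned to strata like ``PROPORTIONAL``. Falls back to
      ``PROPORTIONAL`` when no log totals are supplied.
    - ``PROPORTIONAL``: pooled negatives are apportioned to each stratum in
      proportion to its share of triggered recordings. The convex
      combination of stratum accuracies under true stratum shares then
      reproduces the pooled accuracy exactly.
    - ``REPLICATE_POOLED``: the full pooled counts are copied into every
      stratum (each stratum's accuracy is defined, but negatives are counted
      once per stratum).
    - ``NONE``: strata carry tp/fp only; accuracy degenerates to precision
      and specificity is undefined at stratum level.
    """

    LOG_PROPORTIONAL = "log_proportional"
    PROPORTIONAL = "proportional"
    REPLICATE_POOLED = "replicate"
    NONE = "none"


@dataclass(frozen=True)
class LogTotals:
    """Complete Activity-Log counts for one epoch (storage-unaffected)."""

    pattern_triggers: int
    magnet_swipes: int


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifiedOutcome:
    label: Label
    stratum: StratumKey | None  # None = pooled (non-triggered recording)
    latency_s: float | None = None


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN tallies. Fractional values arise from proportional
    attribution of pooled negatives; raw tallies are integers."""

    tp: float = 0.0
    fp: float = 0.0
    tn: float = 0.0
    fn: float = 0.0

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


class Metrics(NamedTuple):
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


def stratum_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity; ``None`` (never 0) for an empty
    denominator."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total > 0 else None
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    return Metrics(accuracy, sensitivity, specificity)


@dataclass
class StratumPerformance:
    stratum: StratumKey
    counts: ConfusionCounts          # tp/fp raw + policy-attributed negatives
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    latencies_s: list[float] = field(default_factory=list)

    @property
    def n_triggered(self) -> int:
        """Raw number of pattern-triggered reviewed recordings (tp+fp)."""
        return int(round(self.counts.tp + self.counts.fp))


@dataclass
class EpochConfusion:
    """Per-stratum performance plus pooled negatives for one epoch.

    ``pooled_negatives`` are the raw stored tallies (what the standard
    method sees); ``effective_negatives`` are the possibly re-leveled
    negatives that entered the per-stratum denominators.
    """

    epoch_id: str
    per_stratum: dict[StratumKey, StratumPerformance]
    pooled_negatives: ConfusionCounts
    policy: NegativeAttribution
    effective_negatives: ConfusionCounts = field(
        default_factory=ConfusionCounts)

    @property
    def n_classified(self) -> int:
        trig = sum(s.n_triggered for s in self.per_stratum.values())
        return trig + int(self.pooled_negatives.tn + self.pooled_negatives.fn)

    def pooled_counts(self) -> ConfusionCounts:
        """Raw counts pooled across strata plus the pooled negatives."""
        tp = sum(int(round(s.counts.tp)) for s in self.per_stratum.values())
        fp = sum(s.n_triggered - int(round(s.counts.tp))
                 for s in self.per_stratum.values())
        return ConfusionCounts(tp=tp, fp=fp,
                               tn=self.pooled_negatives.tn,
                               fn=self.pooled_negatives.fn)

    def all_latencies(self) -> list[float]:
        out: list[float] = []
        for key in ALL_STRATA:
            if key in self.per_stratum:
                out.extend(self.per_stratum[key].latencies_s)
        return out


def classify_recording(rec: EcogRecording,
                       epoch: ProgrammingEpoch) -> ClassifiedOutcome:
    """Assign one confusion-matrix label to an annotated recording.

    Raises :class:`ClassificationError` on an epoch mismatch or a
    pattern-triggered recording without first-episode detail.
    """
    if rec.epoch_id != epoch.epoch_id:
        raise ClassificationError(
            f"recording {rec.recording_id} belongs to epoch {rec.epoch_id}, "
            f"not {epoch.epoch_id}")
    eip = rec.annotation.eip_present
    if rec.trigger_type is TriggerType.PATTERN:
        fe = rec.first_episode
        if fe is None:
            raise ClassificationError(
                f"recording {rec.recording_id}: PATTERN trigger lacks first_episode")
        stratum = StratumKey(fe.triggering_pattern, fe.episode_class)
        if not eip:
            return ClassifiedOutcome(Label.FP, stratum)
        latency: float | None = None
        if not fe.in_progress_at_start and rec.annotation.eip_onset_s is not None:
            latency = fe.first_detection_s - rec.annotation.eip_onset_s
        return ClassifiedOutcome(Label.TP, stratum, latency)
    # scheduled, magnet and saturation triggers sample independently of the
    # detector: they contribute pooled negatives
    return ClassifiedOutcome(Label.FN if eip else Label.TN, None)


def aggregate_epoch_confusion(
    recs: Iterable[EcogRecording],
    epoch: ProgrammingEpoch,
    policy: NegativeAttribution = NegativeAttribution.PROPORTIONAL,
    log_totals: LogTotals | None = None,
) -> EpochConfusion:
    """Tally classified outcomes into per-stratum performance for one epoch.

    ``log_totals`` supplies the complete Activity-Log counts needed by the
    ``LOG_PROPORTIONAL`` policy; without them that policy degrades to
    ``PROPORTIONAL``. An empty recording list yields all-zero counts (not an
    error); metrics are then undefined.
    """
    tp: dict[StratumKey, int] = {}
    fp: dict[StratumKey, int] = {}
    lat: dict[StratumKey, list[float]] = {}
    # negatives tallied per storage class: magnet-triggered vs other
    # (scheduled/saturation) non-triggered recordings
    magnet_tn = magnet_fn = other_tn = other_fn = 0
    for rec in recs:
        out = classify_recording(rec, epoch)
        if out.stratum is not None:
            if out.label is Label.TP:
                tp[out.stratum] = tp.get(out.stratum, 0) + 1
                if out.latency_s is not None:
                    lat.setdefault(out.stratum, []).append(out.latency_s)
            else:
                fp[out.stratum] = fp.get(out.stratum, 0) + 1
        else:
            is_magnet = rec.trigger_type is TriggerType.MAGNET
            if out.label is Label.TN:
                magnet_tn += is_magnet
                other_tn += not is_magnet
            else:
                magnet_fn += is_magnet
                other_fn += not is_magnet
    pooled_tn = magnet_tn + other_tn
    pooled_fn = magnet_fn + other_fn

    strata = sorted(set(tp) | set(fp), key=lambda s: (s.pattern.value,
                                                      s.episode_class.value))
    n_triggered_total = sum(tp.get(s, 0) + fp.get(s, 0) for s in strata)

    # effective pooled negatives entering stratum denominators
    eff_tn, eff_fn = float(pooled_tn), float(pooled_fn)
    if policy is NegativeAttribution.LOG_PROPORTIONAL:
        factor = _magnet_releveling_factor(n_triggered_total,
                                           magnet_tn + magnet_fn, log_totals)
        eff_tn = other_tn + magnet_tn * factor
        eff_fn = other_fn + magnet_fn * factor

    per_stratum: dict[StratumKey, StratumPerformance] = {}
    for s in strata:
        s_tp, s_fp = tp.get(s, 0), fp.get(s, 0)
        if policy is NegativeAttribution.REPLICATE_POOLED:
            s_tn, s_fn = float(pooled_tn), float(pooled_fn)
        elif policy is NegativeAttribution.NONE:
            s_tn = s_fn = 0.0
        else:  # PROPORTIONAL / LOG_PROPORTIONAL
            share = (s_tp + s_fp) / n_triggered_total if n_triggered_total else 0.0
            s_tn, s_fn = eff_tn * share, eff_fn * share
        counts = ConfusionCounts(tp=s_tp, fp=s_fp, tn=s_tn, fn=s_fn)
        acc, sens, spec = stratum_metrics(counts)
        per_stratum[s] = StratumPerformance(
            stratum=s, counts=counts, accuracy=acc, sensitivity=sens,
            specificity=spec, latencies_s=sorted(lat.get(s, [])))
    return EpochConfusion(
        epoch_id=epoch.epoch_id,
        per_stratum=per_stratum,
        pooled_negatives=ConfusionCounts(tn=pooled_tn, fn=pooled_fn),
        policy=policy,
        effective_negatives=ConfusionCounts(tn=eff_tn, fn=eff_fn),
    )


def _magnet_releveling_factor(n_triggered_stored: int, n_magnet_stored: int,
                              log_totals: LogTotals | None) -> float:
    """Ratio correcting the magnet class for differential storage survival.

    Stored snippet classes are retained at different rates, so the stored
    magnet-to-trigger ratio misstates the true one. The Activity Log counts
    both classes completely; scaling magnet-class tallies by
    ``(stored triggers / logged triggers) / (stored magnets / logged
    magnets)`` restores the logged ratio. Returns 1.0 whenever a term is
    unavailable or zero.
    """
    if (log_totals is None or n_triggered_stored == 0 or n_magnet_stored == 0
            or log_totals.pattern_triggers == 0
            or log_totals.magnet_swipes == 0):
        return 1.0
    trigger_retention = n_triggered_stored / log_totals.pattern_triggers
    magnet_retention = n_magnet_stored / log_totals.magnet_swipes
    return trigger_retention / magnet_retention


class StandardMetrics(NamedTuple):
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    mean_latency_s: float | None


def standard_epoch_metrics(conf: EpochConfusion) -> StandardMetrics:
    """The standard (snippet-only) epoch metrics: counts pooled across all
    strata plus pooled negatives, no history weighting; mean latency is the
    unweighted mean over all eligible TP latencies."""
    pooled = conf.pooled_counts()
    acc, sens, spec = stratum_metrics(pooled)
    lats = conf.all_latencies()
    mean_lat = sum(lats) / len(lats) if lats else None
    return StandardMetrics(acc, sens, spec, mean_lat)
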