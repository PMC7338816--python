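"""Closed-loop device simulator with documented storage degradation.

The generator has two stages. :func:`simulate_ground_truth` draws a complete
labelled event stream — electrographic ictal patterns (EIPs) from an
optionally multidien-modulated Poisson process, per-Pattern detections and
false triggers, scheduled recordings, magnet swipes, and therapy deliveries
under the daily limit. :func:`apply_device_constraints` then degrades that
stream through the device's storage rules: a handful of ECoG slots with
per-trigger-class reservation and oldest-first overwriting, an event list
truncated per interrogation interval, and hourly histogram saturation that
flags whole days as missing.

True detector performance is computed over the *recordable* universe — every
event that would generate a stored recording under unconstrained storage
(triggered episodes, scheduled recordings, magnet swipes). Missed EIPs that
no recording captures are tallied separately (``uncaptured_missed_eips``):
they are invisible to any storage policy and no snippet-based method can
observe them.

All randomness flows from ``SimulationConfig.seed`` through numpy
generators; identical configurations reproduce identical streams.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .io import write_dataset
from .performance import ConfusionCounts, Metrics, stratum_metrics
from .types import (
    ActivityLogRecord,
    Annotation,
    BurstConfig,
    Dataset,
    DeviceConstants,
    EcogRecording,
    EpisodeClass,
    EventListEntry,
    FirstEpisode,
    Hemisphere,
    HistogramDay,
    HistogramHour,
    Laterality,
    PatternId,
    ProgrammingEpoch,
    SeizureReport,
    StratumKey,
    TherapyConfig,
    TriggerType,
    utc,
)

SECONDS_PER_DAY = 86400.0


class EventKind(str, Enum):
    EIP = "EIP"
    INTERICTAL = "INTERICTAL"
    SCHEDULED = "SCHEDULED"
    MAGNET = "MAGNET"


#: storage reservation classes (first-order pattern, scheduled, magnet)
class StorageClass(str, Enum):
    PATTERN_A = "PATTERN_A"
    PATTERN_B = "PATTERN_B"
    SCHEDULED = "SCHEDULED"
    MAGNET = "MAGNET"


@dataclass(frozen=True)
class DetectorSpec:
    """One second-order Pattern detector: EIP hit probability and the rate
    of interictal false triggers."""

    p_detect_eip: float
    false_trigger_rate_per_day: float


def _default_detectors() -> dict[PatternId, DetectorSpec]:
    return {
        PatternId.A1: DetectorSpec(0.70, 6.0),
        PatternId.B1: DetectorSpec(0.35, 1.0),
    }


def _default_therapies() -> tuple[TherapyConfig, ...]:
    # one therapy, two bursts on opposite hemispheres; parameters typical of
    # the device's programming ranges (2 mA, 160 us, 200 Hz, 100 ms bursts,
    # 0.08 cm^2 contact area)
    def burst(h: Hemisphere, cathode: frozenset[int], anode: frozenset[int]):
        return BurstConfig(current_ma=2.0, pulse_width_us=160.0,
                           frequency_hz=200.0, duration_ms=100.0,
                           cathode_electrodes=cathode, anode_electrodes=anode,
                           electrode_area_cm2=0.08, hemisphere=h)
    return (TherapyConfig(bursts=(
        burst(Hemisphere.LEFT, frozenset({1, 2}), frozenset({3, 4})),
        burst(Hemisphere.RIGHT, frozenset({5, 6}), frozenset({7, 8})),
    )),)


def _default_reservation() -> dict[StorageClass, int]:
    return {StorageClass.PATTERN_A: 1, StorageClass.PATTERN_B: 1,
            StorageClass.SCHEDULED: 1, StorageClass.MAGNET: 1}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated patient.

    Rates are per-day; the defaults describe a moderately active patient of
    the kind the device is implanted in: a few EIPs per day, an overly
    sensitive dominant detector producing most false triggers, twice-daily
    scheduled recordings, roughly daily interrogations, and first-generation
    storage limits (4 ECoG slots, ~700-entry event list, 255 events/hour
    histogram saturation).
    """

    seed: int
    duration_days: float = 90.0
    start: dt.datetime = field(default_factory=lambda: utc(2023, 1, 1))
    patient_id: str | None = None

    # ictal / interictal processes
    eip_rate_per_day: float = 3.0
    multidien_period_days: float | None = None
    multidien_amplitude: float = 0.0
    interictal_rate_per_day: float = 0.0

    # detectors
    detectors: dict[PatternId, DetectorSpec] = field(
        default_factory=_default_detectors)
    long_episode_prob: float = 0.15
    long_episode_threshold_s: float = 30.0

    # detection latency: shift + gamma(shape, scale), seconds; small negative
    # mass represents stimulation preceding the annotated EIP onset
    latency_shift_s: float = -0.5
    latency_shape: float = 2.0
    latency_scale: float = 1.5

    # therapy
    therapies_per_episode_mean: float = 1.1
    daily_therapy_limit: int = 2000
    stimulation_enabled: bool = True
    therapies: tuple[TherapyConfig, ...] = field(
        default_factory=_default_therapies)

    # interrogation schedule: lognormal intervals with this mean (heavy right
    # tail; device cohorts average ~30 h with a median near 24 h)
    interrogation_interval_hours: float = 30.3
    interrogation_sigma: float = 0.35

    # observation channels
    scheduled_recordings_per_day: int = 2
    magnet_swipe_prob_on_missed_eip: float = 0.5
    background_magnet_rate_per_day: float = 0.2

    # storage constraints
    ecog_slots: int = 4
    slot_reservation: dict[StorageClass, int] = field(
        default_factory=_default_reservation)
    event_list_capacity: int = 700
    hourly_histogram_cap: int = 255

    # review / reporting
    annotation_noise: float = 0.0
    seizure_report_prob: float = 0.25

    def __post_init__(self) -> None:
        self.validate()
        if self.patient_id is None:
            self.patient_id = f"SIM{self.seed:05d}"

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        if self.eip_rate_per_day < 0 or self.interictal_rate_per_day < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.multidien_amplitude < 1.0:
            raise ValueError("multidien_amplitude must be in [0, 1)")
        if self.multidien_amplitude > 0 and not self.multidien_period_days:
            raise ValueError("multidien modulation needs a period")
        if not self.detectors:
            raise ValueError("at least one detector must be configured")
        for p, spec in self.detectors.items():
            if not 0.0 <= spec.p_detect_eip <= 1.0:
                raise ValueError(f"{p.value}: p_detect_eip must be in [0, 1]")
            if spec.false_trigger_rate_per_day < 0:
                raise ValueError(f"{p.value}: false trigger rate must be >= 0")
        if not 0.0 <= self.long_episode_prob <= 1.0:
            raise ValueError("long_episode_prob must be in [0, 1]")
        if sum(self.slot_reservation.values()) > self.ecog_slots:
            raise ValueError("slot reservations exceed available ECoG slots")
        if self.ecog_slots < 0 or self.event_list_capacity < 0:
            raise ValueError("storage constants must be >= 0")
        if not 0.0 <= self.annotation_noise <= 1.0:
            raise ValueError("annotation_noise must be in [0, 1]")

    @property
    def enabled_patterns(self) -> frozenset[PatternId]:
        return frozenset(self.detectors)

    def epoch(self) -> ProgrammingEpoch:
        end = self.start + dt.timedelta(seconds=self.duration_days
                                        * SECONDS_PER_DAY)
        return ProgrammingEpoch(
            epoch_id=f"{self.patient_id}-E1",
            patient_id=self.patient_id or "",
            start=self.start,
            end=end,
            enabled_patterns=self.enabled_patterns,
            therapies=self.therapies,
            daily_therapy_limit=self.daily_therapy_limit,
            long_episode_threshold_s=self.long_episode_threshold_s,
            stimulation_enabled=self.stimulation_enabled,
        )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "detectors" in raw:
            raw["detectors"] = {
                PatternId(k): DetectorSpec(**v)
                for k, v in raw["detectors"].items()}
        if "slot_reservation" in raw:
            raw["slot_reservation"] = {
                StorageClass(k): int(v)
                for k, v in raw["slot_reservation"].items()}
        if "start" in raw:
            raw["start"] = dt.datetime.fromisoformat(
                str(raw["start"])).replace(tzinfo=dt.timezone.utc)
        return cls(**raw)


@dataclass
class TruthEvent:
    """One event of the complete (pre-degradation) stream.

    ``t_s`` is seconds from epoch start. ``detected_by`` is set for
    triggered episodes (EIP detections and false triggers); ``eip_present``
    is what a reviewer would annotate on the corresponding snippet.
    """

    t_s: float
    kind: EventKind
    detected_by: PatternId | None = None
    episode_class: EpisodeClass | None = None
    latency_s: float | None = None
    therapies_delivered: int = 0
    eip_present: bool = False

    @property
    def is_trigger(self) -> bool:
        return self.detected_by is not None

    @property
    def is_recordable(self) -> bool:
        return self.is_trigger or self.kind in (EventKind.SCHEDULED,
                                                EventKind.MAGNET)

    @property
    def storage_class(self) -> StorageClass | None:
        if self.detected_by is not None:
            return (StorageClass.PATTERN_A
                    if self.detected_by.first_order == "A"
                    else StorageClass.PATTERN_B)
        if self.kind is EventKind.SCHEDULED:
            return StorageClass.SCHEDULED
        if self.kind is EventKind.MAGNET:
            return StorageClass.MAGNET
        return None


@dataclass
class GroundTruthStream:
    """Complete labelled stream plus the unobservable true performance."""

    config: SimulationConfig
    epoch: ProgrammingEpoch
    events: list[TruthEvent]
    per_stratum: dict[StratumKey, ConfusionCounts]
    pooled_negatives: ConfusionCounts
    uncaptured_missed_eips: int
    total_eips: int
    true_latencies_s: list[float]

    def pooled_counts(self) -> ConfusionCounts:
        tp = sum(c.tp for c in self.per_stratum.values())
        fp = sum(c.fp for c in self.per_stratum.values())
        return ConfusionCounts(tp=tp, fp=fp,
                               tn=self.pooled_negatives.tn,
                               fn=self.pooled_negatives.fn)

    def true_metrics(self) -> Metrics:
        """Accuracy/sensitivity/specificity pooled over the recordable
        universe."""
        return stratum_metrics(self.pooled_counts())

    def true_rates(self) -> dict[str, float]:
        hours = self.epoch.duration_hours
        months = self.epoch.duration_days / 30.44
        device_events = sum(1 for e in self.events
                            if e.is_trigger or e.kind is EventKind.MAGNET)
        episodes = sum(1 for e in self.events if e.is_trigger)
        therapies = sum(e.therapies_delivered for e in self.events)
        # mean single-delivery dose over configured slots (the daily-count
        # apportionment in charge_dose reduces to this for one slot)
        per_delivery = sum(
            b.phase_charge_density_uc_cm2 * b.pulses_per_burst
            for t in self.epoch.therapies for b in t.bursts
        ) / max(len(self.epoch.therapies), 1)
        dose = therapies * per_delivery
        return {
            "events_per_hour": device_events / hours,
            "eips_per_month": self.total_eips / months,
            "stimulations_per_episode": (therapies / episodes
                                         if episodes else math.nan),
            "charge_density_uc_cm2": dose,
        }


def _eip_times(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson EIP onsets (seconds) by thinning."""
    t_end = cfg.duration_days * SECONDS_PER_DAY
    base = cfg.eip_rate_per_day / SECONDS_PER_DAY
    if cfg.multidien_amplitude == 0.0 or not cfg.multidien_period_days:
        n = rng.poisson(base * t_end)
        return np.sort(rng.uniform(0.0, t_end, size=n))
    lam_max = base * (1.0 + cfg.multidien_amplitude)
    n = rng.poisson(lam_max * t_end)
    times = np.sort(rng.uniform(0.0, t_end, size=n))
    period_s = cfg.multidien_period_days * SECONDS_PER_DAY
    lam = base * (1.0 + cfg.multidien_amplitude
                  * np.sin(2.0 * np.pi * times / period_s))
    keep = rng.uniform(0.0, lam_max, size=n) < lam
    return times[keep]


def simulate_ground_truth(cfg: SimulationConfig) -> GroundTruthStream:
    """Draw the complete labelled event stream for one patient-epoch."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t_end = cfg.duration_days * SECONDS_PER_DAY
    patterns = sorted(cfg.detectors, key=lambda p: p.value)
    events: list[TruthEvent] = []

    # --- EIPs and their detections -------------------------------------
    missed_eips: list[float] = []
    for t in _eip_times(cfg, rng):
        detected: PatternId | None = None
        for p in patterns:  # first-configured-pattern tie break
            if rng.random() < cfg.detectors[p].p_detect_eip:
                detected = p
                break
        if detected is None:
            missed_eips.append(float(t))
            events.append(TruthEvent(t_s=float(t), kind=EventKind.EIP,
                                     eip_present=True))
            continue
        cls = (EpisodeClass.LONG_EPISODE
               if rng.random() < cfg.long_episode_prob
               else EpisodeClass.EPISODE)
        # latency clipped so onset and detection stay inside a 90-s snippet
        lat = float(np.clip(cfg.latency_shift_s
                            + rng.gamma(cfg.latency_shape, cfg.latency_scale),
                            -20.0, 25.0))
        events.append(TruthEvent(t_s=float(t), kind=EventKind.EIP,
                                 detected_by=detected, episode_class=cls,
                                 latency_s=lat, eip_present=True))

    # --- interictal false triggers per pattern -------------------------
    for p in patterns:
        rate = cfg.detectors[p].false_trigger_rate_per_day / SECONDS_PER_DAY
        n = rng.poisson(rate * t_end)
        for t in np.sort(rng.uniform(0.0, t_end, size=n)):
            cls = (EpisodeClass.LONG_EPISODE
                   if rng.random() < cfg.long_episode_prob
                   else EpisodeClass.EPISODE)
            events.append(TruthEvent(t_s=float(t), kind=EventKind.INTERICTAL,
                                     detected_by=p, episode_class=cls))

    # --- undetected interictal background (detector-invisible) ---------
    if cfg.interictal_rate_per_day > 0:
        n = rng.poisson(cfg.interictal_rate_per_day / SECONDS_PER_DAY * t_end)
        for t in np.sort(rng.uniform(0.0, t_end, size=n)):
            events.append(TruthEvent(t_s=float(t), kind=EventKind.INTERICTAL))

    # --- scheduled recordings at fixed daily times ----------------------
    n_sched = cfg.scheduled_recordings_per_day
    day = 0
    while day < cfg.duration_days:
        for k in range(n_sched):
            t = (day + (k + 0.5) / max(n_sched, 1)) * SECONDS_PER_DAY
            if t < t_end:
                events.append(TruthEvent(t_s=t, kind=EventKind.SCHEDULED))
        day += 1

    # --- magnet swipes ---------------------------------------------------
    n_bg = rng.poisson(cfg.background_magnet_rate_per_day
                       / SECONDS_PER_DAY * t_end)
    for t in np.sort(rng.uniform(0.0, t_end, size=n_bg)):
        events.append(TruthEvent(t_s=float(t), kind=EventKind.MAGNET))
    captured_missed: set[float] = set()
    for t in missed_eips:
        if rng.random() < cfg.magnet_swipe_prob_on_missed_eip:
            swipe_t = t + rng.uniform(20.0, 70.0)
            if swipe_t < t_end:
                events.append(TruthEvent(t_s=swipe_t, kind=EventKind.MAGNET,
                                         eip_present=True))
                captured_missed.add(t)

    # --- scheduled recordings may capture a missed EIP by chance --------
    sched = [e for e in events if e.kind is EventKind.SCHEDULED]
    for e in sched:
        for t in missed_eips:
            if e.t_s - 15.0 <= t <= e.t_s + 75.0:
                e.eip_present = True
                captured_missed.add(t)
                break

    events.sort(key=lambda e: (e.t_s, e.kind.value))

    # --- therapy delivery under the daily limit -------------------------
    if cfg.stimulation_enabled and cfg.therapies:
        per_day_used: dict[int, int] = {}
        for e in events:
            if not e.is_trigger:
                continue
            d = int(e.t_s // SECONDS_PER_DAY)
            used = per_day_used.get(d, 0)
            want = int(min(rng.poisson(cfg.therapies_per_episode_mean), 5))
            give = max(0, min(want, cfg.daily_therapy_limit - used))
            e.therapies_delivered = give
            per_day_used[d] = used + give

    # --- true confusion over the recordable universe --------------------
    per_stratum: dict[StratumKey, ConfusionCounts] = {}
    pooled = ConfusionCounts()
    latencies: list[float] = []
    total_eips = sum(1 for e in events if e.kind is EventKind.EIP)
    for e in events:
        if e.is_trigger:
            key = StratumKey(e.detected_by, e.episode_class)
            counts = per_stratum.setdefault(key, ConfusionCounts())
            if e.eip_present:
                counts.tp += 1
                if e.latency_s is not None:
                    latencies.append(e.latency_s)
            else:
                counts.fp += 1
        elif e.kind in (EventKind.SCHEDULED, EventKind.MAGNET):
            if e.eip_present:
                pooled.fn += 1
            else:
                pooled.tn += 1
    uncaptured = sum(1 for t in missed_eips if t not in captured_missed)
    return GroundTruthStream(
        config=cfg, epoch=cfg.epoch(), events=events,
        per_stratum=per_stratum, pooled_negatives=pooled,
        uncaptured_missed_eips=uncaptured, total_eips=total_eips,
        true_latencies_s=sorted(latencies),
    )


# ---------------------------------------------------------------------------
# storage degradation


def apply_device_constraints(truth: GroundTruthStream,
                             cfg: SimulationConfig | None = None) -> Dataset:
    """Degrade a ground-truth stream through the device's storage rules.

    Between consecutive interrogations, recordable events compete for ECoG
    slots: trigger classes with a reservation keep their newest ``r`` events
    (oldest-first overwriting within the class); classes without one share
    the remaining pool. At interrogation the stored snippets upload and the
    slots clear. The event list keeps the oldest ``capacity`` episodes per
    interval (new events beyond capacity are lost); hourly histogram counts
    saturate at the cap, flagging the day as missing. The activity log is
    always complete.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 0xC0DE])
    epoch = truth.epoch
    t_end = cfg.duration_days * SECONDS_PER_DAY

    # interrogation times (seconds from start), flushed at epoch end
    interrogations: list[float] = []
    t = 0.0
    mean_h = cfg.interrogation_interval_hours
    sigma = cfg.interrogation_sigma
    mu = math.log(mean_h) - sigma * sigma / 2.0
    while True:
        t += rng.lognormal(mu, sigma) * 3600.0
        if t >= t_end:
            break
        interrogations.append(t)
    interrogations.append(t_end)

    shared_slots = cfg.ecog_slots - sum(cfg.slot_reservation.values())
    recordings: list[EcogRecording] = []
    event_list: list[EventListEntry] = []
    activity: list[ActivityLogRecord] = []
    rec_seq = 0

    prev = 0.0
    for t_int in interrogations:
        window = [e for e in truth.events if prev < e.t_s <= t_int]
        # --- ECoG slots -------------------------------------------------
        reserved: dict[StorageClass, list[TruthEvent]] = {
            c: [] for c in StorageClass}
        shared: list[TruthEvent] = []
        for e in window:
            sc = e.storage_class
            if sc is None:
                continue
            r = cfg.slot_reservation.get(sc, 0)
            if r > 0:
                reserved[sc].append(e)
                if len(reserved[sc]) > r:
                    reserved[sc].pop(0)  # overwrite oldest in class
            elif shared_slots > 0:
                shared.append(e)
                if len(shared) > shared_slots:
                    shared.pop(0)
        stored = sorted([e for lst in reserved.values() for e in lst]
                        + shared, key=lambda e: e.t_s)
        for e in stored:
            rec_seq += 1
            recordings.append(_make_recording(e, epoch, cfg, rec_seq, rng))

        # --- event list (oldest kept, newest beyond capacity lost) ------
        episodes = [e for e in window if e.is_trigger]
        for e in episodes[:cfg.event_list_capacity]:
            event_list.append(EventListEntry(
                episode_onset=_at(epoch.start, e.t_s),
                patient_id=epoch.patient_id,
                triggering_pattern=e.detected_by,
                episode_class=e.episode_class,
                therapy_count=e.therapies_delivered,
            ))

        # --- activity log (always complete) ------------------------------
        activity.append(ActivityLogRecord(
            interrogation_time=_at(epoch.start, t_int),
            patient_id=epoch.patient_id,
            pattern_a_events=sum(1 for e in window if e.is_trigger
                                 and e.detected_by.first_order == "A"),
            pattern_b_events=sum(1 for e in window if e.is_trigger
                                 and e.detected_by.first_order == "B"),
            saturations=0,
            magnet_swipes=sum(1 for e in window
                              if e.kind is EventKind.MAGNET),
        ))
        prev = t_int

    hist_daily, hist_hourly = _histograms(truth, cfg, epoch)
    reports = _seizure_reports(truth, epoch, cfg, rng)

    return Dataset(
        epochs=[epoch],
        recordings=recordings,
        event_list=event_list,
        activity_log=activity,
        histogram_daily=hist_daily,
        histogram_hourly=hist_hourly,
        seizure_reports=reports,
        constants=DeviceConstants(
            ecog_slots=cfg.ecog_slots,
            event_list_capacity=cfg.event_list_capacity,
            hourly_histogram_cap=cfg.hourly_histogram_cap,
        ),
    )


def _at(start: dt.datetime, seconds: float) -> dt.datetime:
    return start + dt.timedelta(seconds=int(round(seconds)))


def _make_recording(e: TruthEvent, epoch: ProgrammingEpoch,
                    cfg: SimulationConfig, seq: int,
                    rng: np.random.Generator) -> EcogRecording:
    rid = f"{epoch.patient_id}-R{seq:06d}"
    eip = e.eip_present
    if cfg.annotation_noise > 0 and rng.random() < cfg.annotation_noise:
        eip = not eip
    if e.is_trigger:
        trigger = TriggerType.PATTERN
        # 30 s of pre-trigger buffer precedes the detection marker
        detection_s = 30.0
        onset = detection_s - e.latency_s if (eip and e.latency_s is not None) \
            else (45.0 if eip else None)
        fe = FirstEpisode(
            onset_s=detection_s,
            triggering_pattern=e.detected_by,
            episode_class=e.episode_class,
            in_progress_at_start=False,
            first_detection_s=detection_s,
            therapy_times_s=tuple(detection_s + 2.0 * i
                                  for i in range(e.therapies_delivered)),
        )
        start_s = e.t_s - detection_s
    else:
        trigger = (TriggerType.SCHEDULED if e.kind is EventKind.SCHEDULED
                   else TriggerType.MAGNET)
        fe = None
        onset = 30.0 if eip else None
        start_s = e.t_s - 60.0 if e.kind is EventKind.MAGNET else e.t_s
    lat = Laterality.NA
    if eip:
        u = rng.random()
        lat = (Laterality.LEFT if u < 0.45
               else Laterality.RIGHT if u < 0.9 else Laterality.BILATERAL)
    return EcogRecording(
        recording_id=rid,
        patient_id=epoch.patient_id,
        epoch_id=epoch.epoch_id,
        trigger_type=trigger,
        start_time=_at(epoch.start, max(start_s, 0.0)),
        duration_s=90.0,
        first_episode=fe,
        annotation=Annotation(eip_present=eip, eip_onset_s=onset,
                              laterality=lat),
    )


def _histograms(truth: GroundTruthStream, cfg: SimulationConfig,
                epoch: ProgrammingEpoch):
    """Hourly saturation then daily aggregation of device-counted events."""
    device_events = [e for e in truth.events
                     if e.is_trigger or e.kind is EventKind.MAGNET]
    by_hour: dict[tuple[int, int], list[TruthEvent]] = {}
    for e in device_events:
        d = int(e.t_s // SECONDS_PER_DAY)
        h = int((e.t_s % SECONDS_PER_DAY) // 3600)
        by_hour.setdefault((d, h), []).append(e)

    capped_days: set[int] = set()
    kept: dict[int, list[TruthEvent]] = {}
    hourly: list[HistogramHour] = []
    for (d, h), evs in sorted(by_hour.items()):
        evs = sorted(evs, key=lambda e: e.t_s)
        if len(evs) > cfg.hourly_histogram_cap:
            capped_days.add(d)
            evs = evs[:cfg.hourly_histogram_cap]
        kept.setdefault(d, []).extend(evs)
        hourly.append(HistogramHour(
            date=(epoch.start + dt.timedelta(days=d)).date(), hour=h,
            patient_id=epoch.patient_id, event_count=len(evs)))

    daily: list[HistogramDay] = []
    n_days = int(math.ceil(cfg.duration_days))
    for d in range(n_days):
        evs = kept.get(d, [])
        pattern_counts = {p: 0 for p in PatternId}
        e_count = le_count = therapy = magnet = 0
        for e in evs:
            if e.is_trigger:
                pattern_counts[e.detected_by] += 1
                if e.episode_class is EpisodeClass.LONG_EPISODE:
                    le_count += 1
                else:
                    e_count += 1
                therapy += e.therapies_delivered
            else:
                magnet += 1
        daily.append(HistogramDay(
            date=(epoch.start + dt.timedelta(days=d)).date(),
            patient_id=epoch.patient_id,
            pattern_counts=pattern_counts,
            episode_count=e_count,
            long_episode_count=le_count,
            therapy_count=therapy,
            saturation_count=0,
            magnet_count=magnet,
            histogram_data_missing=d in capped_days,
            diagnostic_data_missing=False,
        ))
    return daily, hourly


def _seizure_reports(truth: GroundTruthStream, epoch: ProgrammingEpoch,
                     cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[SeizureReport]:
    """Monthly patient-reported counts: each EIP is reported with a fixed
    probability (patients notice only a fraction of electrographic events)."""
    eips_by_month: dict[str, int] = {}
    for e in truth.events:
        if e.kind is EventKind.EIP:
            when = epoch.start + dt.timedelta(seconds=e.t_s)
            eips_by_month[when.strftime("%Y-%m")] = \
                eips_by_month.get(when.strftime("%Y-%m"), 0) + 1
    return [SeizureReport(patient_id=epoch.patient_id, month=m,
                          reported_seizures=float(
                              rng.binomial(n, cfg.seizure_report_prob)))
            for m, n in sorted(eips_by_month.items())]


# ---------------------------------------------------------------------------
# rendering and convenience


def render_dataset(obs: Dataset, out_path: Path | str,
                   truth: GroundTruthStream | None = None) -> list[Path]:
    """Write the canonical dataset; ground truth, when given, goes to a
    separate ``truth/`` directory that the evaluation pipeline never reads."""
    out = Path(out_path)
    manifest = write_dataset(obs, out)
    if truth is not None:
        tdir = out / "truth"
        tdir.mkdir(parents=True, exist_ok=True)
        m = truth.true_metrics()
        rates = truth.true_rates()
        rows = [
            ("true_accuracy", m.accuracy),
            ("true_sensitivity", m.sensitivity),
            ("true_specificity", m.specificity),
            ("true_mean_latency_s",
             (sum(truth.true_latencies_s) / len(truth.true_latencies_s))
             if truth.true_latencies_s else None),
            ("total_eips", truth.total_eips),
            ("uncaptured_missed_eips", truth.uncaptured_missed_eips),
        ] + sorted(rates.items())
        path = tdir / "true_metrics.csv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write("metric,value\n")
            for k, v in rows:
                fh.write(f"{k},{'' if v is None else repr(float(v))}\n")
        manifest.append(path)
    return manifest


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[GroundTruthStream, Dataset]:
    truth = simulate_ground_truth(cfg)
    return truth, apply_device_constraints(truth, cfg)


def simulate_cohort(seeds: Iterable[int], duration_days: float = 90.0,
                    config_factory=None,
                    ) -> tuple[Dataset, list[GroundTruthStream]]:
    """Simulate one patient per seed and merge into a single cohort dataset.

    Each seed yields an independent patient with its own (per-seed
    randomized) configuration from ``config_factory`` (default:
    :func:`heterogeneous_storage_config`).
    """
    if config_factory is None:
        config_factory = heterogeneous_storage_config
    merged = Dataset()
    truths: list[GroundTruthStream] = []
    for seed in seeds:
        cfg = config_factory(seed, duration_days)
        truth, ds = simulate_dataset(cfg)
        truths.append(truth)
        merged.epochs += ds.epochs
        merged.recordings += ds.recordings
        merged.event_list += ds.event_list
        merged.activity_log += ds.activity_log
        merged.histogram_daily += ds.histogram_daily
        merged.histogram_hourly += ds.histogram_hourly
        merged.seizure_reports += ds.seizure_reports
        merged.constants = ds.constants
    return merged, truths


# ---------------------------------------------------------------------------
# study scenario factories


def unconstrained_config(seed: int, duration_days: float = 30.0,
                         ) -> SimulationConfig:
    """Exhaustive-storage limit: effectively unlimited slots and caps, a
    single enabled detector and no long episodes.

    In this regime the stored snippets are the complete recordable stream
    and the stratification is trivial (one stratum), so the snippet-only and
    history-weighted estimates must both coincide exactly with the true
    sample metrics — the consistency limit of the pipeline.
    """
    return SimulationConfig(
        seed=seed,
        duration_days=duration_days,
        eip_rate_per_day=3.0,
        detectors={PatternId.A1: DetectorSpec(0.7, 4.0)},
        long_episode_prob=0.0,
        scheduled_recordings_per_day=2,
        magnet_swipe_prob_on_missed_eip=0.5,
        background_magnet_rate_per_day=0.3,
        ecog_slots=10**9,
        slot_reservation={},
        event_list_capacity=10**9,
        hourly_histogram_cap=10**9,
    )


def heterogeneous_storage_config(seed: int, duration_days: float = 90.0,
                                 ) -> SimulationConfig:
    """Bias-study scenario: heterogeneous per-Pattern detectors with strongly
    asymmetric trigger rates, 4 reserved storage slots, and active event-list
    and histogram caps.

    Per-seed detector draws cover both orderings (the dominant detector may
    be the better or the worse one), so the direction of the snippet-only
    bias varies across configurations while per-class slot reservation keeps
    the stored pattern mix flattened relative to the true mix. Per-class
    event rates are moderate — each storage class overflows its reserved
    slot, but by comparable factors — so the stored sample distorts the
    *composition* across strata (which history weighting corrects) more than
    the positive-to-negative balance within the pool (which no snippet-based
    method can correct).
    """
    rng = np.random.default_rng([seed, 0x5CE0])
    # dominant detector fires several-fold more often than the quiet one
    hi_rate = float(rng.uniform(2.5, 8.0))
    lo_rate = float(rng.uniform(0.3, 1.5))
    p_hi = float(rng.uniform(0.3, 0.9))
    p_lo = float(rng.uniform(0.1, 0.8))
    det_hi = DetectorSpec(p_detect_eip=p_hi, false_trigger_rate_per_day=hi_rate)
    det_lo = DetectorSpec(p_detect_eip=p_lo, false_trigger_rate_per_day=lo_rate)
    if rng.random() < 0.5:
        detectors = {PatternId.A1: det_hi, PatternId.B1: det_lo}
    else:
        detectors = {PatternId.A1: det_lo, PatternId.B1: det_hi}
    return SimulationConfig(
        seed=seed,
        duration_days=duration_days,
        eip_rate_per_day=float(rng.uniform(2.0, 5.0)),
        detectors=detectors,
        long_episode_prob=float(rng.uniform(0.05, 0.3)),
        scheduled_recordings_per_day=2,
        magnet_swipe_prob_on_missed_eip=0.9,
        background_magnet_rate_per_day=float(rng.uniform(1.5, 3.0)),
        interrogation_interval_hours=30.3,
        ecog_slots=4,
        slot_reservation=_default_reservation(),
        event_list_capacity=700,
        hourly_histogram_cap=255,
    )
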