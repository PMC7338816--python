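"""Domain types for closed-loop neurostimulator telemetry.

The RNS-type device exposes four tiers of logging: stored ECoG snippets
(richest, scarcest), the per-interrogation Event List, the Activity Log
(complete first-order counts), and the Neurostimulator History histograms
(daily/hourly aggregate counts). The types here mirror those tiers plus the
programming configuration that was active while the data were produced.

All timestamps are timezone-fixed UTC at one-second resolution;
within-recording offsets are floating-point seconds from recording start.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple


class PatternId(str, Enum):
    """Second-order detection Pattern (one detector on one channel).

    A1/A2 compose first-order Pattern A; B1/B2 compose Pattern B.
    """

    A1 = "A1"
    A2 = "A2"
    B1 = "B1"
    B2 = "B2"

    @property
    def first_order(self) -> str:
        return self.value[0]


class EpisodeClass(str, Enum):
    """Detection-initiated episodes split by programmable duration threshold."""

    EPISODE = "EPISODE"
    LONG_EPISODE = "LONG_EPISODE"


class TriggerType(str, Enum):
    PATTERN = "PATTERN"
    MAGNET = "MAGNET"
    SCHEDULED = "SCHEDULED"
    SATURATION = "SATURATION"


class Hemisphere(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    UNKNOWN = "UNKNOWN"


class Laterality(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    BILATERAL = "BILATERAL"
    NA = "NA"


class StratumKey(NamedTuple):
    """Performance stratum: (second-order Pattern, episode class)."""

    pattern: PatternId
    episode_class: EpisodeClass

    def __str__(self) -> str:  # e.g. "A1_E", "B2_LE"
        suffix = "E" if self.episode_class is EpisodeClass.EPISODE else "LE"
        return f"{self.pattern.value}_{suffix}"


#: the eight admissible strata, in canonical order
ALL_STRATA: tuple[StratumKey, ...] = tuple(
    StratumKey(p, c) for p in PatternId for c in EpisodeClass
)


def parse_stratum(text: str) -> StratumKey:
    pattern, _, suffix = text.partition("_")
    cls = EpisodeClass.EPISODE if suffix == "E" else EpisodeClass.LONG_EPISODE
    return StratumKey(PatternId(pattern), cls)


class DomainError(ValueError):
    """An invariant of a domain type is violated."""


@dataclass(frozen=True)
class BurstConfig:
    """One stimulation burst: a charge-balanced biphasic pulse train.

    ``current_ma`` and ``pulse_width_us`` describe a single phase; the
    per-pulse phase charge density is ``current_ma * pulse_width_us * 1e-3
    / electrode_area_cm2`` in uC/cm^2, the convention of the device's
    programming interface.
    """

    current_ma: float
    pulse_width_us: float
    frequency_hz: float
    duration_ms: float
    cathode_electrodes: frozenset[int]
    anode_electrodes: frozenset[int]
    electrode_area_cm2: float
    hemisphere: Hemisphere = Hemisphere.UNKNOWN

    def __post_init__(self) -> None:
        for name in ("current_ma", "pulse_width_us", "frequency_hz", "duration_ms"):
            if getattr(self, name) <= 0:
                raise DomainError(f"BurstConfig.{name} must be > 0")
        if self.electrode_area_cm2 <= 0:
            raise DomainError("BurstConfig.electrode_area_cm2 must be > 0")
        if not self.cathode_electrodes or not self.anode_electrodes:
            raise DomainError("electrode sets must be non-empty")
        if self.cathode_electrodes & self.anode_electrodes:
            raise DomainError("cathode and anode electrode sets must be disjoint")
        bad = {e for e in self.cathode_electrodes | self.anode_electrodes
               if not 1 <= e <= 8}
        if bad:
            raise DomainError(f"electrode indices out of range 1-8: {sorted(bad)}")
        if self.pulses_per_burst < 1:
            raise DomainError("burst too short: pulses_per_burst < 1")

    @property
    def pulses_per_burst(self) -> int:
        return math.floor(self.frequency_hz * self.duration_ms / 1000.0)

    @property
    def phase_charge_density_uc_cm2(self) -> float:
        """Single-phase charge density of one pulse, uC/cm^2."""
        return self.current_ma * self.pulse_width_us * 1e-3 / self.electrode_area_cm2


@dataclass(frozen=True)
class TherapyConfig:
    """One of up to five triggered therapies, holding one or two bursts."""

    bursts: tuple[BurstConfig, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.bursts) <= 2:
            raise DomainError("a therapy holds 1-2 bursts")


@dataclass(frozen=True)
class ProgrammingEpoch:
    """Interval during which detection and stimulation settings are constant."""

    epoch_id: str
    patient_id: str
    start: dt.datetime
    end: dt.datetime
    enabled_patterns: frozenset[PatternId]
    therapies: tuple[TherapyConfig, ...] = ()
    daily_therapy_limit: int = 2000
    long_episode_threshold_s: float = 30.0
    stimulation_enabled: bool = True

    def __post_init__(self) -> None:
        _require_utc(self.start, "ProgrammingEpoch.start")
        _require_utc(self.end, "ProgrammingEpoch.end")
        if not self.start < self.end:
            raise DomainError(f"epoch {self.epoch_id}: start must precede end")
        if len(self.therapies) > 5:
            raise DomainError(f"epoch {self.epoch_id}: at most 5 therapies")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def duration_days(self) -> float:
        return (self.end - self.start).total_seconds() / 86400.0

    def contains(self, when: dt.datetime) -> bool:
        return self.start <= when < self.end


@dataclass(frozen=True)
class FirstEpisode:
    """Detail of the first episode within a stored recording.

    Only the first episode is modelled in detail: all performance
    calculations use the first detection event of the first episode; later
    episodes in a recording contribute only to aggregate counts.
    """

    onset_s: float
    triggering_pattern: PatternId
    episode_class: EpisodeClass
    in_progress_at_start: bool
    first_detection_s: float
    therapy_times_s: tuple[float, ...] = ()


@dataclass(frozen=True)
class Annotation:
    """Expert review outcome for one stored recording.

    Reviewable invariants (an onset given while ``eip_present`` is false, an
    onset outside the recording) are reported by ``validate_dataset`` rather
    than raised here, so that a defective file still loads into a report.
    """

    eip_present: bool
    eip_onset_s: float | None = None
    laterality: Laterality = Laterality.NA


@dataclass(frozen=True)
class EcogRecording:
    """A stored ECoG snippet (nominally 90 s, 4 channels) plus annotation."""

    recording_id: str
    patient_id: str
    epoch_id: str
    trigger_type: TriggerType
    start_time: dt.datetime
    annotation: Annotation
    duration_s: float = 90.0
    first_episode: FirstEpisode | None = None

    def __post_init__(self) -> None:
        _require_utc(self.start_time, "EcogRecording.start_time")


@dataclass(frozen=True)
class ActivityLogRecord:
    """Complete first-order counts accumulated since the previous interrogation."""

    interrogation_time: dt.datetime
    patient_id: str
    pattern_a_events: int
    pattern_b_events: int
    saturations: int
    magnet_swipes: int

    def __post_init__(self) -> None:
        _require_utc(self.interrogation_time, "ActivityLogRecord.interrogation_time")

    @property
    def total_events(self) -> int:
        """Pattern detections + saturations + magnet swipes."""
        return (self.pattern_a_events + self.pattern_b_events
                + self.saturations + self.magnet_swipes)


@dataclass(frozen=True)
class EventListEntry:
    episode_onset: dt.datetime
    patient_id: str
    triggering_pattern: PatternId
    episode_class: EpisodeClass
    therapy_count: int

    def __post_init__(self) -> None:
        _require_utc(self.episode_onset, "EventListEntry.episode_onset")


@dataclass(frozen=True)
class HistogramDay:
    """Daily Neurostimulator History counts — the extrapolation weight source."""

    date: dt.date
    patient_id: str
    pattern_counts: dict[PatternId, int]
    episode_count: int
    long_episode_count: int
    therapy_count: int
    saturation_count: int
    magnet_count: int
    histogram_data_missing: bool = False
    diagnostic_data_missing: bool = False

    @property
    def pattern_total(self) -> int:
        return sum(self.pattern_counts.values())

    @property
    def total_events(self) -> int:
        return self.pattern_total + self.saturation_count + self.magnet_count

    def __eq__(self, other: object) -> bool:  # dict field ⇒ custom eq for hashability opt-out
        if not isinstance(other, HistogramDay):
            return NotImplemented
        return (self.date, self.patient_id, dict(self.pattern_counts),
                self.episode_count, self.long_episode_count, self.therapy_count,
                self.saturation_count, self.magnet_count,
                self.histogram_data_missing, self.diagnostic_data_missing) == (
                other.date, other.patient_id, dict(other.pattern_counts),
                other.episode_count, other.long_episode_count, other.therapy_count,
                other.saturation_count, other.magnet_count,
                other.histogram_data_missing, other.diagnostic_data_missing)

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class HistogramHour:
    """Hourly Neurostimulator History total-event count (saturates at the cap)."""

    date: dt.date
    hour: int
    patient_id: str
    event_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.hour <= 23:
            raise DomainError("HistogramHour.hour must be in 0-23")
        if self.event_count < 0:
            raise DomainError("HistogramHour.event_count must be >= 0")


@dataclass(frozen=True)
class SeizureReport:
    """Patient-reported seizure count for one calendar month ('YYYY-MM')."""

    patient_id: str
    month: str
    reported_seizures: float

    def __post_init__(self) -> None:
        try:
            dt.datetime.strptime(self.month, "%Y-%m")
        except ValueError as exc:
            raise DomainError(f"SeizureReport.month not YYYY-MM: {self.month!r}") from exc
        if self.reported_seizures < 0:
            raise DomainError("SeizureReport.reported_seizures must be >= 0")


@dataclass(frozen=True)
class DeviceConstants:
    """On-device storage limits (defaults from the first-generation device)."""

    ecog_slots: int = 4
    event_list_capacity: int = 700
    hourly_histogram_cap: int = 255


@dataclass
class Dataset:
    """All typed collections for a cohort, plus the device constants."""

    epochs: list[ProgrammingEpoch] = field(default_factory=list)
    recordings: list[EcogRecording] = field(default_factory=list)
    event_list: list[EventListEntry] = field(default_factory=list)
    activity_log: list[ActivityLogRecord] = field(default_factory=list)
    histogram_daily: list[HistogramDay] = field(default_factory=list)
    histogram_hourly: list[HistogramHour] = field(default_factory=list)
    seizure_reports: list[SeizureReport] = field(default_factory=list)
    constants: DeviceConstants = field(default_factory=DeviceConstants)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ep in self.epochs:
            seen.setdefault(ep.patient_id, None)
        return list(seen)

    def epochs_for(self, patient_id: str) -> list[ProgrammingEpoch]:
        return sorted((e for e in self.epochs if e.patient_id == patient_id),
                      key=lambda e: e.start)

    def epoch_by_id(self, epoch_id: str) -> ProgrammingEpoch:
        for ep in self.epochs:
            if ep.epoch_id == epoch_id:
                return ep
        raise KeyError(epoch_id)

    def recordings_for_epoch(self, epoch_id: str) -> list[EcogRecording]:
        return sorted((r for r in self.recordings if r.epoch_id == epoch_id),
                      key=lambda r: r.start_time)

    def histogram_for_epoch(self, epoch: ProgrammingEpoch) -> list[HistogramDay]:
        """Daily histogram rows of the epoch's patient falling inside the epoch."""
        lo, hi = epoch.start.date(), epoch.end.date()
        return [d for d in self.histogram_daily
                if d.patient_id == epoch.patient_id and lo <= d.date <= hi]

    def activity_for_epoch(self, epoch: ProgrammingEpoch) -> list[ActivityLogRecord]:
        return [a for a in self.activity_log
                if a.patient_id == epoch.patient_id
                and epoch.start < a.interrogation_time <= epoch.end]


def _require_utc(when: dt.datetime, what: str) -> None:
    if when.tzinfo is None or when.utcoffset() != dt.timedelta(0):
        raise DomainError(f"{what} must be timezone-fixed UTC")


def utc(year: int, month: int, day: int, hour: int = 0, minute: int = 0,
        second: int = 0) -> dt.datetime:
    """Convenience constructor for UTC timestamps at 1-s resolution."""
    return dt.datetime(year, month, day, hour, minute, second,
                       tzinfo=dt.timezone.utc)
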