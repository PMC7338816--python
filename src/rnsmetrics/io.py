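"""Canonical on-disk schemas: loading, validation, round-tripping.

A dataset directory holds flat UTF-8 CSV files (a JSON mirror with identical
field names is accepted per file) plus an optional ``dataset.yaml`` naming
file locations and device constants:

- ``epochs.csv`` — one row per (epoch, therapy slot, burst); epochs without
  therapies carry a single row with the burst columns empty
- ``recordings.csv``, ``event_list.csv``, ``activity_log.csv``,
  ``histogram_daily.csv``, ``histogram_hourly.csv``, ``seizure_reports.csv``

Timestamps are ISO-8601 UTC (``2023-01-05T13:00:00Z``) at one-second
resolution. Set-valued columns use ``|`` separators. Loading is strict about
headers (a wrong column is a load error naming it) but lenient about
reviewable invariants, which ``validate_dataset`` reports instead.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import yaml

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
    TherapyConfig,
    TriggerType,
)

SCHEMA_VERSION = "1.0"

DEFAULT_FILES = {
    "epochs": "epochs.csv",
    "recordings": "recordings.csv",
    "event_list": "event_list.csv",
    "activity_log": "activity_log.csv",
    "histogram_daily": "histogram_daily.csv",
    "histogram_hourly": "histogram_hourly.csv",
    "seizure_reports": "seizure_reports.csv",
}

_COLUMNS = {
    "epochs": ["epoch_id", "patient_id", "start", "end", "enabled_patterns",
               "daily_therapy_limit", "long_episode_threshold_s",
               "stimulation_enabled", "therapy_index", "burst_index",
               "current_ma", "pulse_width_us", "frequency_hz", "duration_ms",
               "cathode_electrodes", "anode_electrodes", "electrode_area_cm2",
               "hemisphere"],
    "recordings": ["recording_id", "patient_id", "epoch_id", "trigger_type",
                   "start_time", "duration_s", "fe_onset_s",
                   "fe_triggering_pattern", "fe_episode_class",
                   "fe_in_progress_at_start", "fe_first_detection_s",
                   "fe_therapy_times_s", "eip_present", "eip_onset_s",
                   "laterality"],
    "event_list": ["episode_onset", "patient_id", "triggering_pattern",
                   "episode_class", "therapy_count"],
    "activity_log": ["interrogation_time", "patient_id", "pattern_a_events",
                     "pattern_b_events", "saturations", "magnet_swipes"],
    "histogram_daily": ["date", "patient_id", "a1", "a2", "b1", "b2",
                        "episode_count", "long_episode_count", "therapy_count",
                        "saturation_count", "magnet_count",
                        "histogram_data_missing", "diagnostic_data_missing"],
    "histogram_hourly": ["date", "hour", "patient_id", "event_count"],
    "seizure_reports": ["patient_id", "month", "reported_seizures"],
}

_TIME_FMT = "%Y-%m-%dT%H:%M:%SZ"


class DatasetLoadError(Exception):
    pass


# ---------------------------------------------------------------------------
# cell codecs

def _fmt_time(t: dt.datetime) -> str:
    return t.astimezone(dt.timezone.utc).strftime(_TIME_FMT)


def _parse_time(text: str) -> dt.datetime:
    return dt.datetime.strptime(text, _TIME_FMT).replace(tzinfo=dt.timezone.utc)


def _fmt_opt(v: Any) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def _opt_float(text: str) -> float | None:
    return float(text) if text != "" else None


# ---------------------------------------------------------------------------
# generic row I/O (CSV canonical, JSON mirror accepted)

def _read_rows(path: Path, table: str) -> list[dict[str, str]]:
    json_path = path.with_suffix(".json")
    if not path.exists() and json_path.exists():
        path = json_path
    if not path.exists():
        raise DatasetLoadError(f"missing dataset file: {path.name}")
    if path.suffix == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        rows = [{k: _fmt_opt(v) if not isinstance(v, str) else v
                 for k, v in row.items()} for row in raw]
        header = list(rows[0]) if rows else _COLUMNS[table]
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            rows = [dict(r) for r in reader]
    expected = _COLUMNS[table]
    if list(header) != expected:
        missing = [c for c in expected if c not in header]
        extra = [c for c in header if c not in expected]
        raise DatasetLoadError(
            f"{path.name}: schema mismatch "
            f"(missing columns {missing}, unexpected {extra})")
    return rows


def _write_rows(path: Path, table: str, rows: Iterable[Sequence[Any]]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS[table])
        for row in rows:
            writer.writerow([_fmt_opt(v) for v in row])


# ---------------------------------------------------------------------------
# per-table encode/decode

def _epochs_to_rows(epochs: Iterable[ProgrammingEpoch]):
    for ep in epochs:
        base = [ep.epoch_id, ep.patient_id, _fmt_time(ep.start),
                _fmt_time(ep.end),
                "|".join(sorted(p.value for p in ep.enabled_patterns)),
                ep.daily_therapy_limit, repr(ep.long_episode_threshold_s),
                ep.stimulation_enabled]
        if not ep.therapies:
            yield base + [""] * 10
            continue
        for ti, therapy in enumerate(ep.therapies):
            for bi, b in enumerate(therapy.bursts):
                yield base + [
                    ti, bi, repr(b.current_ma), repr(b.pulse_width_us),
                    repr(b.frequency_hz), repr(b.duration_ms),
                    "|".join(str(e) for e in sorted(b.cathode_electrodes)),
                    "|".join(str(e) for e in sorted(b.anode_electrodes)),
                    repr(b.electrode_area_cm2), b.hemisphere.value,
                ]


def _rows_to_epochs(rows: list[dict[str, str]]) -> list[ProgrammingEpoch]:
    grouped: dict[str, list[dict[str, str]]] = {}
    order: list[str] = []
    for row in rows:
        eid = row["epoch_id"]
        if eid not in grouped:
            grouped[eid] = []
            order.append(eid)
        grouped[eid].append(row)
    epochs = []
    for eid in order:
        rws = grouped[eid]
        head = rws[0]
        bursts: dict[int, dict[int, BurstConfig]] = {}
        for row in rws:
            if row["therapy_index"] == "":
                continue
            ti, bi = int(row["therapy_index"]), int(row["burst_index"])
            bursts.setdefault(ti, {})[bi] = BurstConfig(
                current_ma=float(row["current_ma"]),
                pulse_width_us=float(row["pulse_width_us"]),
                frequency_hz=float(row["frequency_hz"]),
                duration_ms=float(row["duration_ms"]),
                cathode_electrodes=frozenset(
                    int(e) for e in row["cathode_electrodes"].split("|") if e),
                anode_electrodes=frozenset(
                    int(e) for e in row["anode_electrodes"].split("|") if e),
                electrode_area_cm2=float(row["electrode_area_cm2"]),
                hemisphere=Hemisphere(row["hemisphere"]),
            )
        therapies = tuple(
            TherapyConfig(bursts=tuple(bursts[ti][bi]
                                       for bi in sorted(bursts[ti])))
            for ti in sorted(bursts))
        epochs.append(ProgrammingEpoch(
            epoch_id=eid,
            patient_id=head["patient_id"],
            start=_parse_time(head["start"]),
            end=_parse_time(head["end"]),
            enabled_patterns=frozenset(
                PatternId(p) for p in head["enabled_patterns"].split("|") if p),
            therapies=therapies,
            daily_therapy_limit=int(head["daily_therapy_limit"]),
            long_episode_threshold_s=float(head["long_episode_threshold_s"]),
            stimulation_enabled=_parse_bool(head["stimulation_enabled"]),
        ))
    return epochs


def _recordings_to_rows(recs: Iterable[EcogRecording]):
    for r in recs:
        fe = r.first_episode
        yield [
            r.recording_id, r.patient_id, r.epoch_id, r.trigger_type.value,
            _fmt_time(r.start_time), repr(r.duration_s),
            None if fe is None else repr(fe.onset_s),
            None if fe is None else fe.triggering_pattern.value,
            None if fe is None else fe.episode_class.value,
            None if fe is None else fe.in_progress_at_start,
            None if fe is None else repr(fe.first_detection_s),
            None if fe is None else "|".join(repr(t)
                                             for t in fe.therapy_times_s),
            r.annotation.eip_present,
            None if r.annotation.eip_onset_s is None
            else repr(r.annotation.eip_onset_s),
            r.annotation.laterality.value,
        ]


def _rows_to_recordings(rows: list[dict[str, str]]) -> list[EcogRecording]:
    out = []
    for row in rows:
        fe = None
        if row["fe_triggering_pattern"] != "":
            fe = FirstEpisode(
                onset_s=float(row["fe_onset_s"]),
                triggering_pattern=PatternId(row["fe_triggering_pattern"]),
                episode_class=EpisodeClass(row["fe_episode_class"]),
                in_progress_at_start=_parse_bool(row["fe_in_progress_at_start"]),
                first_detection_s=float(row["fe_first_detection_s"]),
                therapy_times_s=tuple(
                    float(t) for t in row["fe_therapy_times_s"].split("|") if t),
            )
        out.append(EcogRecording(
            recording_id=row["recording_id"],
            patient_id=row["patient_id"],
            epoch_id=row["epoch_id"],
            trigger_type=TriggerType(row["trigger_type"]),
            start_time=_parse_time(row["start_time"]),
            duration_s=float(row["duration_s"]),
            first_episode=fe,
            annotation=Annotation(
                eip_present=_parse_bool(row["eip_present"]),
                eip_onset_s=_opt_float(row["eip_onset_s"]),
                laterality=Laterality(row["laterality"]),
            ),
        ))
    return out


# ---------------------------------------------------------------------------
# public API

def write_dataset(ds: Dataset, root: Path | str) -> list[Path]:
    """Write all canonical files plus ``dataset.yaml``; returns the paths."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def put(table: str, rows: Iterable[Sequence[Any]]) -> None:
        path = root / DEFAULT_FILES[table]
        _write_rows(path, table, rows)
        written.append(path)

    put("epochs", _epochs_to_rows(ds.epochs))
    put("recordings", _recordings_to_rows(ds.recordings))
    put("event_list", ([_fmt_time(e.episode_onset), e.patient_id,
                        e.triggering_pattern.value, e.episode_class.value,
                        e.therapy_count] for e in ds.event_list))
    put("activity_log", ([_fmt_time(a.interrogation_time), a.patient_id,
                          a.pattern_a_events, a.pattern_b_events,
                          a.saturations, a.magnet_swipes]
                         for a in ds.activity_log))
    put("histogram_daily", ([d.date.isoformat(), d.patient_id,
                             d.pattern_counts.get(PatternId.A1, 0),
                             d.pattern_counts.get(PatternId.A2, 0),
                             d.pattern_counts.get(PatternId.B1, 0),
                             d.pattern_counts.get(PatternId.B2, 0),
                             d.episode_count, d.long_episode_count,
                             d.therapy_count, d.saturation_count,
                             d.magnet_count, d.histogram_data_missing,
                             d.diagnostic_data_missing]
                            for d in ds.histogram_daily))
    put("histogram_hourly", ([h.date.isoformat(), h.hour, h.patient_id,
                              h.event_count] for h in ds.histogram_hourly))
    put("seizure_reports", ([s.patient_id, s.month, repr(s.reported_seizures)]
                            for s in ds.seizure_reports))

    config = {
        "schema_version": SCHEMA_VERSION,
        "files": dict(DEFAULT_FILES),
        "device_constants": {
            "ecog_slots": ds.constants.ecog_slots,
            "event_list_capacity": ds.constants.event_list_capacity,
            "hourly_histogram_cap": ds.constants.hourly_histogram_cap,
        },
    }
    cfg_path = root / "dataset.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=True),
                        encoding="utf-8")
    written.append(cfg_path)
    return written


def load_dataset(root: Path | str) -> Dataset:
    """Load and type a canonical dataset directory.

    Raises :class:`DatasetLoadError` for a missing file, a schema (header)
    mismatch, or a recording referencing an unknown epoch. Reviewable
    invariant breaks survive loading and are reported by
    :func:`validate_dataset`.
    """
    root = Path(root)
    if not root.is_dir():
        raise DatasetLoadError(f"dataset directory not found: {root}")
    files = dict(DEFAULT_FILES)
    constants = DeviceConstants()
    cfg_path = root / "dataset.yaml"
    if cfg_path.exists():
        cfg = yaml.safe_load(cfg_path.read_text(encoding="utf-8")) or {}
        version = str(cfg.get("schema_version", SCHEMA_VERSION))
        if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise DatasetLoadError(
                f"unsupported schema_version {version!r} "
                f"(supported: {SCHEMA_VERSION})")
        files.update(cfg.get("files", {}))
        dc = cfg.get("device_constants", {})
        constants = DeviceConstants(
            ecog_slots=int(dc.get("ecog_slots", constants.ecog_slots)),
            event_list_capacity=int(dc.get("event_list_capacity",
                                           constants.event_list_capacity)),
            hourly_histogram_cap=int(dc.get("hourly_histogram_cap",
                                            constants.hourly_histogram_cap)),
        )

    def rows(table: str) -> list[dict[str, str]]:
        return _read_rows(root / files[table], table)

    try:
        ds = Dataset(
            epochs=_rows_to_epochs(rows("epochs")),
            recordings=_rows_to_recordings(rows("recordings")),
            event_list=[EventListEntry(
                episode_onset=_parse_time(r["episode_onset"]),
                patient_id=r["patient_id"],
                triggering_pattern=PatternId(r["triggering_pattern"]),
                episode_class=EpisodeClass(r["episode_class"]),
                therapy_count=int(r["therapy_count"]),
            ) for r in rows("event_list")],
            activity_log=[ActivityLogRecord(
                interrogation_time=_parse_time(r["interrogation_time"]),
                patient_id=r["patient_id"],
                pattern_a_events=int(r["pattern_a_events"]),
                pattern_b_events=int(r["pattern_b_events"]),
                saturations=int(r["saturations"]),
                magnet_swipes=int(r["magnet_swipes"]),
            ) for r in rows("activity_log")],
            histogram_daily=[HistogramDay(
                date=dt.date.fromisoformat(r["date"]),
                patient_id=r["patient_id"],
                pattern_counts={PatternId.A1: int(r["a1"]),
                                PatternId.A2: int(r["a2"]),
                                PatternId.B1: int(r["b1"]),
                                PatternId.B2: int(r["b2"])},
                episode_count=int(r["episode_count"]),
                long_episode_count=int(r["long_episode_count"]),
                therapy_count=int(r["therapy_count"]),
                saturation_count=int(r["saturation_count"]),
                magnet_count=int(r["magnet_count"]),
                histogram_data_missing=_parse_bool(r["histogram_data_missing"]),
                diagnostic_data_missing=_parse_bool(r["diagnostic_data_missing"]),
            ) for r in rows("histogram_daily")],
            histogram_hourly=[HistogramHour(
                date=dt.date.fromisoformat(r["date"]),
                hour=int(r["hour"]),
                patient_id=r["patient_id"],
                event_count=int(r["event_count"]),
            ) for r in rows("histogram_hourly")],
            seizure_reports=[SeizureReport(
                patient_id=r["patient_id"],
                month=r["month"],
                reported_seizures=float(r["reported_seizures"]),
            ) for r in rows("seizure_reports")],
            constants=constants,
        )
    except (ValueError, KeyError) as exc:
        raise DatasetLoadError(f"malformed cell while loading {root}: {exc}") from exc

    known = {e.epoch_id for e in ds.epochs}
    orphans = sorted({r.epoch_id for r in ds.recordings
                      if r.epoch_id not in known})
    if orphans:
        raise DatasetLoadError(
            "recordings reference unknown epoch ids: " + ", ".join(orphans))
    return ds


# ---------------------------------------------------------------------------
# validation

@dataclass
class Finding:
    code: str
    message: str
    record_ids: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for kind, items in (("ERROR", self.errors), ("WARNING", self.warnings)):
            for f in items:
                ids = f" [{', '.join(f.record_ids)}]" if f.record_ids else ""
                lines.append(f"{kind} {f.code}: {f.message}{ids}")
        return "\n".join(lines)


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Total validation: never raises on loadable input; every finding names
    at least one record id."""
    rep = ValidationReport()

    # epoch ordering / overlap per patient
    for pid in ds.patient_ids:
        eps = ds.epochs_for(pid)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                rep.errors.append(Finding(
                    "EPOCH_OVERLAP",
                    f"patient {pid}: epochs overlap in time",
                    [a.epoch_id, b.epoch_id]))

    known_epochs = {e.epoch_id for e in ds.epochs}
    epoch_by_id = {e.epoch_id: e for e in ds.epochs}
    for r in ds.recordings:
        rid = r.recording_id
        if r.epoch_id not in known_epochs:
            rep.errors.append(Finding(
                "UNKNOWN_EPOCH",
                f"recording {rid} references unknown epoch {r.epoch_id}",
                [rid, r.epoch_id]))
        ann = r.annotation
        if not ann.eip_present and ann.eip_onset_s is not None:
            rep.errors.append(Finding(
                "ONSET_WITHOUT_EIP",
                f"recording {rid}: eip_onset_s given but eip_present is false",
                [rid]))
        if ann.eip_onset_s is not None and not 0 <= ann.eip_onset_s <= r.duration_s:
            rep.errors.append(Finding(
                "ONSET_OUT_OF_RANGE",
                f"recording {rid}: eip_onset_s outside the recording",
                [rid]))
        if r.trigger_type is TriggerType.PATTERN and r.first_episode is None:
            rep.errors.append(Finding(
                "PATTERN_WITHOUT_EPISODE",
                f"recording {rid}: pattern-triggered but no first_episode",
                [rid]))

    for a in ds.activity_log:
        if min(a.pattern_a_events, a.pattern_b_events, a.saturations,
               a.magnet_swipes) < 0:
            rep.errors.append(Finding(
                "NEGATIVE_COUNT",
                f"activity log at {a.interrogation_time.isoformat()} has a "
                f"negative count", [a.patient_id]))
    for d in ds.histogram_daily:
        if (min(d.pattern_counts.values(), default=0) < 0
                or min(d.episode_count, d.long_episode_count, d.therapy_count,
                       d.saturation_count, d.magnet_count) < 0):
            rep.errors.append(Finding(
                "NEGATIVE_COUNT",
                f"daily histogram {d.date.isoformat()} has a negative count",
                [d.patient_id]))
        elif not d.histogram_data_missing and not d.diagnostic_data_missing:
            episodes = d.episode_count + d.long_episode_count
            if episodes > d.pattern_total:
                rep.warnings.append(Finding(
                    "HISTOGRAM_INCONSISTENT",
                    f"daily histogram {d.date.isoformat()}: episode totals "
                    f"exceed pattern trigger totals", [d.patient_id]))

    # per-epoch review coverage
    recs_per_epoch: dict[str, int] = {e: 0 for e in known_epochs}
    for r in ds.recordings:
        if r.epoch_id in recs_per_epoch:
            recs_per_epoch[r.epoch_id] += 1
    for eid, n in sorted(recs_per_epoch.items()):
        if n == 0:
            rep.warnings.append(Finding(
                "NO_REVIEWED_RECORDINGS",
                f"epoch {eid} has no reviewed recordings", [eid]))

    # cross-tier totals (activity log is the source of truth)
    for pid in ds.patient_ids:
        act_total = sum(a.total_events for a in ds.activity_log
                        if a.patient_id == pid)
        hist_total = sum(d.total_events for d in ds.histogram_daily
                         if d.patient_id == pid and not d.histogram_data_missing)
        missing_days = any(d.histogram_data_missing for d in ds.histogram_daily
                           if d.patient_id == pid)
        if act_total and hist_total > act_total:
            rep.warnings.append(Finding(
                "HISTOGRAM_EXCEEDS_ACTIVITY",
                f"patient {pid}: histogram totals exceed activity-log totals",
                [pid]))
        elif act_total and not missing_days and hist_total < act_total:
            rep.warnings.append(Finding(
                "HISTOGRAM_BELOW_ACTIVITY",
                f"patient {pid}: histogram totals below activity-log totals "
                f"with no missing-data flags", [pid]))
    return rep


def write_report_tables(results: Any, out_path: Path | str) -> list[Path]:
    """Write the per-epoch metrics, per-patient summary and agreement tables.

    ``results`` is any object exposing ``epoch_metrics``, ``patient_summary``
    and ``agreement`` DataFrames (a fitted :class:`~rnsmetrics.model.
    DeviceBehaviorResults`). Values round-trip at full precision. Raises on
    empty results.
    """
    frames = {
        "epoch_metrics.csv": results.epoch_metrics,
        "patient_summary.csv": results.patient_summary,
        "agreement.csv": results.agreement,
    }
    if frames["epoch_metrics.csv"] is None or len(frames["epoch_metrics.csv"]) == 0:
        raise ValueError("no results to write")
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for name, frame in frames.items():
        path = out / name
        frame.to_csv(path, index=False, float_format=None)
        manifest.append(path)
    return manifest
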