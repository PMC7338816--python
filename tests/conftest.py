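"""Shared builders for hand-constructed recordings, epochs and histograms."""

from __future__ import annotations

import datetime as dt
import itertools

import pytest

from rnsmetrics.types import (
    Annotation,
    EcogRecording,
    EpisodeClass,
    FirstEpisode,
    HistogramDay,
    Laterality,
    PatternId,
    ProgrammingEpoch,
    TriggerType,
    utc,
)

_REC_COUNTER = itertools.count(1)


def make_epoch(epoch_id: str = "E1", patient_id: str = "P1",
               start: dt.datetime | None = None,
               days: float = 30.0, **kwargs) -> ProgrammingEpoch:
    start = start or utc(2023, 1, 1)
    return ProgrammingEpoch(
        epoch_id=epoch_id,
        patient_id=patient_id,
        start=start,
        end=start + dt.timedelta(days=days),
        enabled_patterns=frozenset(PatternId),
        **kwargs,
    )


def pattern_rec(epoch: ProgrammingEpoch, pattern: PatternId,
                episode_class: EpisodeClass = EpisodeClass.EPISODE,
                eip: bool = True, eip_onset_s: float | None = 10.0,
                first_detection_s: float = 12.5,
                in_progress: bool = False,
                offset_s: float = 0.0) -> EcogRecording:
    """A pattern-triggered reviewed recording."""
    n = next(_REC_COUNTER)
    return EcogRecording(
        recording_id=f"R{n:05d}",
        patient_id=epoch.patient_id,
        epoch_id=epoch.epoch_id,
        trigger_type=TriggerType.PATTERN,
        start_time=epoch.start + dt.timedelta(seconds=offset_s + n),
        first_episode=FirstEpisode(
            onset_s=first_detection_s,
            triggering_pattern=pattern,
            episode_class=episode_class,
            in_progress_at_start=in_progress,
            first_detection_s=first_detection_s,
        ),
        annotation=Annotation(
            eip_present=eip,
            eip_onset_s=eip_onset_s if eip else None,
            laterality=Laterality.LEFT if eip else Laterality.NA,
        ),
    )


def negative_rec(epoch: ProgrammingEpoch,
                 trigger: TriggerType = TriggerType.SCHEDULED,
                 eip: bool = False,
                 offset_s: float = 0.0) -> EcogRecording:
    """A non-triggered (scheduled/magnet) reviewed recording."""
    n = next(_REC_COUNTER)
    return EcogRecording(
        recording_id=f"R{n:05d}",
        patient_id=epoch.patient_id,
        epoch_id=epoch.epoch_id,
        trigger_type=trigger,
        start_time=epoch.start + dt.timedelta(seconds=offset_s + n),
        annotation=Annotation(eip_present=eip,
                              eip_onset_s=30.0 if eip else None),
    )


def hist_day(epoch: ProgrammingEpoch, day: int = 0,
             a1: int = 0, a2: int = 0, b1: int = 0, b2: int = 0,
             episodes: int = 0, long_episodes: int = 0,
             therapies: int = 0, magnets: int = 0,
             missing: bool = False) -> HistogramDay:
    return HistogramDay(
        date=(epoch.start + dt.timedelta(days=day)).date(),
        patient_id=epoch.patient_id,
        pattern_counts={PatternId.A1: a1, PatternId.A2: a2,
                        PatternId.B1: b1, PatternId.B2: b2},
        episode_count=episodes,
        long_episode_count=long_episodes,
        therapy_count=therapies,
        saturation_count=0,
        magnet_count=magnets,
        histogram_data_missing=missing,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated (truth, dataset) pair shared across read-only tests."""
    from rnsmetrics.simulator import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(seed=11, duration_days=15.0)
    return simulate_dataset(cfg)
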