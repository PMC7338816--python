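"""Ground-truth generation and device storage degradation."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from rnsmetrics.agreement import completeness
from rnsmetrics.performance import ConfusionCounts
from rnsmetrics.simulator import (
    DetectorSpec,
    EventKind,
    GroundTruthStream,
    SimulationConfig,
    StorageClass,
    TruthEvent,
    apply_device_constraints,
    simulate_dataset,
    simulate_ground_truth,
)
from rnsmetrics.types import EpisodeClass, PatternId, TriggerType


def base_config(**overrides):
    defaults = dict(seed=1, duration_days=10.0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_reservations_cannot_exceed_slots(self):
        with pytest.raises(ValueError):
            base_config(ecog_slots=2,
                        slot_reservation={StorageClass.PATTERN_A: 2,
                                          StorageClass.SCHEDULED: 1})

    def test_modulation_needs_period_and_bounded_amplitude(self):
        with pytest.raises(ValueError):
            base_config(multidien_amplitude=0.5)
        with pytest.raises(ValueError):
            base_config(multidien_amplitude=1.2, multidien_period_days=7.0)

    def test_detector_probabilities_bounded(self):
        with pytest.raises(ValueError):
            base_config(detectors={PatternId.A1: DetectorSpec(1.4, 1.0)})

    def test_seed_is_mandatory_integer(self):
        with pytest.raises((ValueError, TypeError)):
            SimulationConfig(seed=None)  # type: ignore[arg-type]


class TestYamlConfig:
    def test_round_trip_through_yaml(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "seed: 42\n"
            "duration_days: 12.5\n"
            "eip_rate_per_day: 4.0\n"
            "detectors:\n"
            "  A1: {p_detect_eip: 0.8, false_trigger_rate_per_day: 3.0}\n"
            "  B1: {p_detect_eip: 0.2, false_trigger_rate_per_day: 0.5}\n"
            "slot_reservation: {PATTERN_A: 1, PATTERN_B: 1}\n",
            encoding="utf-8")
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.seed == 42
        assert cfg.detectors[PatternId.B1].p_detect_eip == 0.2
        assert cfg.slot_reservation[StorageClass.PATTERN_A] == 1
        # loaded config drives the simulator exactly like a literal one
        ref = SimulationConfig(
            seed=42, duration_days=12.5, eip_rate_per_day=4.0,
            detectors={PatternId.A1: DetectorSpec(0.8, 3.0),
                       PatternId.B1: DetectorSpec(0.2, 0.5)},
            slot_reservation={StorageClass.PATTERN_A: 1,
                              StorageClass.PATTERN_B: 1})
        assert simulate_ground_truth(cfg).events == \
            simulate_ground_truth(ref).events


class TestGroundTruth:
    def test_same_seed_reproduces_identical_streams(self):
        a = simulate_ground_truth(base_config())
        b = simulate_ground_truth(base_config())
        assert a.events == b.events
        assert a.pooled_counts() == b.pooled_counts()

    def test_different_seeds_differ(self):
        a = simulate_ground_truth(base_config(seed=1))
        b = simulate_ground_truth(base_config(seed=2))
        assert a.events != b.events

    def test_perfect_detector_yields_unit_sensitivity_and_no_fp(self):
        cfg = base_config(detectors={
            PatternId.A1: DetectorSpec(p_detect_eip=1.0,
                                       false_trigger_rate_per_day=0.0)})
        truth = simulate_ground_truth(cfg)
        m = truth.true_metrics()
        assert m.sensitivity == 1.0
        assert truth.pooled_counts().fp == 0
        assert truth.uncaptured_missed_eips == 0

    def test_eip_totals_follow_the_configured_poisson_rate(self):
        # 10/day over 30 days: all 20 seeds inside the central 99.9%
        # interval of Poisson(300)
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], 300)
        for seed in range(20):
            cfg = base_config(seed=seed, duration_days=30.0,
                              eip_rate_per_day=10.0)
            truth = simulate_ground_truth(cfg)
            assert lo <= truth.total_eips <= hi

    def test_multidien_modulation_keeps_mean_rate(self):
        totals = []
        for seed in range(10):
            cfg = base_config(seed=seed, duration_days=28.0,
                              eip_rate_per_day=10.0,
                              multidien_period_days=7.0,
                              multidien_amplitude=0.8)
            totals.append(simulate_ground_truth(cfg).total_eips)
        # over whole periods the modulation integrates out
        assert 280 * 0.8 < np.mean(totals) < 280 * 1.2

    def test_daily_therapy_limit_is_respected(self):
        cfg = base_config(daily_therapy_limit=5, eip_rate_per_day=20.0,
                          therapies_per_episode_mean=3.0)
        truth = simulate_ground_truth(cfg)
        per_day: dict[int, int] = {}
        for e in truth.events:
            d = int(e.t_s // 86400)
            per_day[d] = per_day.get(d, 0) + e.therapies_delivered
        assert max(per_day.values()) <= 5

    def test_detected_eips_carry_latency(self):
        truth = simulate_ground_truth(base_config())
        for e in truth.events:
            if e.kind is EventKind.EIP and e.detected_by is not None:
                assert e.latency_s is not None


def manual_stream(cfg, events):
    """Wrap hand-built events in a GroundTruthStream for constraint tests."""
    return GroundTruthStream(
        config=cfg, epoch=cfg.epoch(), events=sorted(events,
                                                     key=lambda e: e.t_s),
        per_stratum={}, pooled_negatives=ConfusionCounts(),
        uncaptured_missed_eips=0, total_eips=0, true_latencies_s=[])


def trigger_event(t_s, pattern=PatternId.A1, eip=True):
    return TruthEvent(t_s=t_s, kind=EventKind.EIP if eip
                      else EventKind.INTERICTAL,
                      detected_by=pattern,
                      episode_class=EpisodeClass.EPISODE,
                      latency_s=2.0 if eip else None, eip_present=eip)


def single_flush_config(**overrides):
    """One interrogation at epoch end (intervals far longer than the run)."""
    defaults = dict(seed=5, duration_days=1.0,
                    interrogation_interval_hours=10000.0,
                    scheduled_recordings_per_day=0,
                    background_magnet_rate_per_day=0.0,
                    eip_rate_per_day=0.0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestStorageConstraints:
    def test_last_four_survive_without_reservation(self):
        cfg = single_flush_config(ecog_slots=4, slot_reservation={})
        events = [trigger_event(1000.0 * (i + 1)) for i in range(10)]
        obs = apply_device_constraints(manual_stream(cfg, events), cfg)
        stored_times = sorted((r.start_time - cfg.start).total_seconds() + 30.0
                              for r in obs.recordings)
        assert stored_times == [7000.0, 8000.0, 9000.0, 10000.0]

    def test_reservation_protects_a_quiet_trigger_class(self):
        cfg = single_flush_config(
            ecog_slots=4,
            slot_reservation={StorageClass.PATTERN_B: 1},
        )
        events = [trigger_event(100.0 * (i + 1)) for i in range(20)] \
            + [trigger_event(50.0, pattern=PatternId.B1)]
        obs = apply_device_constraints(manual_stream(cfg, events), cfg)
        b_recs = [r for r in obs.recordings
                  if r.first_episode.triggering_pattern is PatternId.B1]
        assert len(b_recs) == 1  # survived despite 20 later A triggers

    def test_event_list_truncates_at_capacity_keeping_oldest(self):
        cfg = single_flush_config(event_list_capacity=700)
        events = [trigger_event(50.0 * (i + 1)) for i in range(1000)]
        obs = apply_device_constraints(manual_stream(cfg, events), cfg)
        assert len(obs.event_list) == 700
        onsets = [(e.episode_onset - cfg.start).total_seconds()
                  for e in obs.event_list]
        assert max(onsets) == 700 * 50.0  # newest beyond capacity are lost
        rep = completeness(obs.activity_log, obs.event_list,
                           [], obs.recordings)
        assert rep.event_list_pct == pytest.approx(70.0)

    def test_hourly_histogram_caps_and_flags_the_day(self):
        cfg = single_flush_config(hourly_histogram_cap=255)
        # 300 triggers within hour 5 of day 0
        events = [trigger_event(5 * 3600.0 + i * 10.0) for i in range(300)]
        obs = apply_device_constraints(manual_stream(cfg, events), cfg)
        hour = [h for h in obs.histogram_hourly if h.hour == 5]
        assert hour[0].event_count == 255
        day0 = obs.histogram_daily[0]
        assert day0.histogram_data_missing
        assert day0.pattern_total == 255

    def test_activity_log_is_always_complete(self):
        cfg = base_config(seed=8)
        truth = simulate_ground_truth(cfg)
        obs = apply_device_constraints(truth, cfg)
        logged = sum(a.total_events for a in obs.activity_log)
        device_events = sum(1 for e in truth.events
                            if e.is_trigger or e.kind is EventKind.MAGNET)
        assert logged == device_events

    def test_stored_recordings_bounded_by_slots_times_interrogations(self):
        cfg = base_config(seed=12)
        truth = simulate_ground_truth(cfg)
        obs = apply_device_constraints(truth, cfg)
        n_interrogations = len(obs.activity_log)
        assert len(obs.recordings) <= cfg.ecog_slots * n_interrogations

    @pytest.mark.parametrize("seed", [3, 14, 25])
    def test_overwriting_biases_stored_sample_toward_interrogations(self, seed):
        """Newest-first retention: stored events sit closer to the next
        interrogation than the average event does."""
        cfg = SimulationConfig(seed=seed, duration_days=20.0)
        truth = simulate_ground_truth(cfg)
        obs = apply_device_constraints(truth, cfg)
        int_times = sorted((a.interrogation_time - cfg.start).total_seconds()
                           for a in obs.activity_log)

        def age(t_s):
            nxt = next((t for t in int_times if t >= t_s), int_times[-1])
            return nxt - t_s

        stored_ages = [age((r.start_time - cfg.start).total_seconds())
                       for r in obs.recordings]
        all_ages = [age(e.t_s) for e in truth.events if e.is_recordable]
        assert np.mean(stored_ages) < np.mean(all_ages)


class TestAnnotationsAndReports:
    def test_stored_recordings_round_classification(self, small_sim):
        truth, ds = small_sim
        for rec in ds.recordings:
            if rec.trigger_type is TriggerType.PATTERN:
                assert rec.first_episode is not None
                if rec.annotation.eip_present:
                    assert rec.annotation.eip_onset_s is not None

    def test_annotation_noise_flips_labels(self):
        cfg_clean = base_config(seed=21)
        cfg_noisy = dataclasses.replace(cfg_clean, annotation_noise=1.0)
        obs_clean = apply_device_constraints(
            simulate_ground_truth(cfg_clean), cfg_clean)
        obs_noisy = apply_device_constraints(
            simulate_ground_truth(cfg_noisy), cfg_noisy)
        flips = [a.annotation.eip_present != b.annotation.eip_present
                 for a, b in zip(obs_clean.recordings, obs_noisy.recordings)]
        assert all(flips)

    def test_seizure_reports_scale_with_eips(self):
        lo = base_config(seed=2, duration_days=30.0, eip_rate_per_day=0.5)
        hi = base_config(seed=2, duration_days=30.0, eip_rate_per_day=20.0)
        _, ds_lo = simulate_dataset(lo)
        _, ds_hi = simulate_dataset(hi)
        assert sum(s.reported_seizures for s in ds_hi.seizure_reports) > \
            sum(s.reported_seizures for s in ds_lo.seizure_reports)
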