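"""History-weighted extrapolation: weights, metrics, rates and dose."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from rnsmetrics.extrapolation import (
    NoWeightSupportError,
    WeightTable,
    charge_dose,
    compute_weight_table,
    eip_rate,
    event_rate_metrics,
    weighted_epoch_metric,
    weighted_latency,
)
from rnsmetrics.performance import (
    NegativeAttribution,
    aggregate_epoch_confusion,
    standard_epoch_metrics,
)
from rnsmetrics.types import (
    ActivityLogRecord,
    BurstConfig,
    EpisodeClass,
    Hemisphere,
    PatternId,
    StratumKey,
    TherapyConfig,
    utc,
)

from conftest import hist_day, make_epoch, negative_rec, pattern_rec

E, LE = EpisodeClass.EPISODE, EpisodeClass.LONG_EPISODE


def conf_from(epoch, spec):
    """Build an EpochConfusion from {(pattern, class): (n_tp, n_fp)}."""
    recs = []
    for (p, c), (tp, fp) in spec.items():
        recs += [pattern_rec(epoch, p, c, eip=True) for _ in range(tp)]
        recs += [pattern_rec(epoch, p, c, eip=False) for _ in range(fp)]
    return aggregate_epoch_confusion(recs, epoch,
                                     NegativeAttribution.NONE)


class TestWeightTable:
    def test_episode_weight_from_printed_shares(self):
        # snippets: A1 triggered 3 of 4 episodes; history: A1=60 of 100
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (2, 1),
                                 (PatternId.A2, E): (1, 0)})
        hist = [hist_day(epoch, 0, a1=60, a2=20, b1=20, b2=0,
                         episodes=90, long_episodes=10)]
        wt = compute_weight_table(conf, hist)
        assert wt.raw[StratumKey(PatternId.A1, E)] == pytest.approx(
            (3 / 4) * (60 / 100))

    def test_long_episode_weight_uses_long_episode_history_share(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.B1, LE): (2, 1)})
        hist = [hist_day(epoch, 0, b1=100, episodes=90, long_episodes=10)]
        wt = compute_weight_table(conf, hist)
        assert wt.raw[StratumKey(PatternId.B1, LE)] == pytest.approx(
            1.0 * (10 / 100))

    def test_single_surviving_stratum_normalizes_to_one(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (1, 1)})
        hist = [hist_day(epoch, 0, a1=7, b1=3, episodes=10)]
        wt = compute_weight_table(conf, hist)
        assert wt.normalized[StratumKey(PatternId.A1, E)] == pytest.approx(1.0)

    def test_zero_support_strata_are_excluded(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (2, 0),
                                 (PatternId.B1, E): (0, 0)})
        hist = [hist_day(epoch, 0, a1=5, b1=5, episodes=10)]
        wt = compute_weight_table(conf, hist)
        assert StratumKey(PatternId.B1, E) not in wt.normalized or \
            wt.normalized.get(StratumKey(PatternId.B1, E), 0.0) == 0.0

    def test_no_support_raises(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (1, 0)})
        hist = [hist_day(epoch, 0)]  # empty history: all raw weights zero
        with pytest.raises(NoWeightSupportError):
            compute_weight_table(conf, hist)

    def test_missing_flagged_days_are_ignored(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (1, 0),
                                 (PatternId.B1, E): (1, 0)})
        clean = [hist_day(epoch, 0, a1=60, b1=40, episodes=100)]
        noisy = clean + [hist_day(epoch, 1, a1=0, b1=999, episodes=999,
                                  missing=True)]
        assert (compute_weight_table(conf, clean).raw
                == compute_weight_table(conf, noisy).raw)

    def test_weights_invariant_to_history_scale(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (3, 1),
                                 (PatternId.B1, E): (1, 1),
                                 (PatternId.B1, LE): (1, 0)})
        h1 = [hist_day(epoch, 0, a1=30, b1=20, episodes=40,
                       long_episodes=10)]
        h7 = [hist_day(epoch, 0, a1=210, b1=140, episodes=280,
                       long_episodes=70)]
        w1 = compute_weight_table(conf, h1)
        w7 = compute_weight_table(conf, h7)
        for s in w1.raw:
            assert w1.raw[s] == pytest.approx(w7.raw[s], abs=1e-15)
            assert w1.normalized[s] == pytest.approx(w7.normalized[s],
                                                     abs=1e-15)


def manual_weight_table(epoch_id, raw):
    total = sum(raw.values())
    return WeightTable(epoch_id=epoch_id, raw=dict(raw),
                       normalized={s: w / total for s, w in raw.items()},
                       excluded_strata=set())


class TestWeightedMetrics:
    def test_two_strata_weighted_accuracy(self):
        epoch = make_epoch()
        # accuracies 1.0 and 0.5 with normalized weights 0.6 / 0.4
        conf = conf_from(epoch, {(PatternId.A1, E): (4, 0),
                                 (PatternId.B1, E): (2, 2)})
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 0.6,
                                  StratumKey(PatternId.B1, E): 0.4})
        got = weighted_epoch_metric(conf, wt, "accuracy")
        assert got == pytest.approx(0.8)

    def test_single_stratum_identity(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (4, 1)})
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 0.37})
        assert weighted_epoch_metric(conf, wt, "accuracy") == \
            pytest.approx(0.8)

    def test_equal_weights_average_the_strata(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {
            (PatternId.A1, E): (1, 4),   # accuracy 0.2
            (PatternId.A2, E): (2, 3),   # 0.4
            (PatternId.B1, E): (3, 2),   # 0.6
            (PatternId.B2, E): (4, 1),   # 0.8
        })
        wt = manual_weight_table(epoch.epoch_id, {
            StratumKey(p, E): 0.25 for p in PatternId})
        assert weighted_epoch_metric(conf, wt, "accuracy") == \
            pytest.approx(0.5)

    def test_literal_mode_reproduces_unnormalized_sum(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (4, 0),
                                 (PatternId.B1, E): (2, 2)})
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 0.3,
                                  StratumKey(PatternId.B1, E): 0.1})
        assert weighted_epoch_metric(conf, wt, "accuracy", "literal") == \
            pytest.approx(0.3 * 1.0 + 0.1 * 0.5)

    def test_metric_undefined_everywhere_returns_none(self):
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (0, 3)})  # no TP/FN
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 1.0})
        assert weighted_epoch_metric(conf, wt, "sensitivity") is None

    def test_degenerate_equality_with_proportional_negatives(self):
        """Equal-size strata + proportional negative attribution: the
        weighted *accuracy* telescopes exactly to the pooled (standard)
        value, because both the numerator and the denominator of each
        stratum's accuracy scale with the stratum's trigger count.
        (Sensitivity and specificity do not telescope: their denominators
        mix tp or fp with the attributed negatives in different
        proportions.)"""
        epoch = make_epoch()
        recs = (
            [pattern_rec(epoch, PatternId.A1, E, eip=True) for _ in range(6)]
            + [pattern_rec(epoch, PatternId.A1, E, eip=False)
               for _ in range(4)]
            + [pattern_rec(epoch, PatternId.B1, E, eip=True)
               for _ in range(2)]
            + [pattern_rec(epoch, PatternId.B1, E, eip=False)
               for _ in range(8)]
            + [negative_rec(epoch, eip=False) for _ in range(5)]
            + [negative_rec(epoch, eip=True) for _ in range(2)]
        )
        conf = aggregate_epoch_confusion(recs, epoch,
                                         NegativeAttribution.PROPORTIONAL)
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 0.5,
                                  StratumKey(PatternId.B1, E): 0.5})
        std = standard_epoch_metrics(conf)
        w = weighted_epoch_metric(conf, wt, "accuracy")
        assert w == pytest.approx(std.accuracy, abs=1e-9)

    def test_printed_weights_are_inconsistent_with_two_unequal_patterns(self):
        """Documented limitation: with exhaustive storage and history counts
        equal to the snippet counts, the printed weight formula multiplies
        the episode share by the *pattern* share, so the normalized weights
        are not the stratum shares and the weighted accuracy deviates from
        the pooled accuracy even without storage bias."""
        epoch = make_epoch()
        conf = conf_from(epoch, {(PatternId.A1, E): (9, 0),    # accuracy 1.0
                                 (PatternId.B1, E): (0, 1)})   # accuracy 0.0
        hist = [hist_day(epoch, 0, a1=9, b1=1, episodes=10)]
        wt = compute_weight_table(conf, hist)
        pooled = standard_epoch_metrics(conf).accuracy           # 0.9
        weighted = weighted_epoch_metric(conf, wt, "accuracy")   # 81/82
        assert pooled == pytest.approx(0.9)
        assert weighted == pytest.approx(81 / 82)
        assert abs(weighted - pooled) > 0.01


class TestWeightedLatency:
    def test_single_stratum_mean(self):
        epoch = make_epoch()
        recs = [pattern_rec(epoch, PatternId.A1, eip=True, eip_onset_s=10.0,
                            first_detection_s=12.0),
                pattern_rec(epoch, PatternId.A1, eip=True, eip_onset_s=10.0,
                            first_detection_s=14.0)]
        conf = aggregate_epoch_confusion(recs, epoch)
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 1.0})
        assert weighted_latency(conf, wt) == pytest.approx(3.0)

    def test_opposite_latencies_cancel_under_equal_weights(self):
        epoch = make_epoch()
        recs = [pattern_rec(epoch, PatternId.A1, eip=True, eip_onset_s=10.0,
                            first_detection_s=11.0),
                pattern_rec(epoch, PatternId.B1, eip=True, eip_onset_s=10.0,
                            first_detection_s=9.0)]
        conf = aggregate_epoch_confusion(recs, epoch)
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 0.5,
                                  StratumKey(PatternId.B1, E): 0.5})
        assert weighted_latency(conf, wt) == pytest.approx(0.0)

    def test_in_progress_recordings_leave_latency_undefined(self):
        epoch = make_epoch()
        recs = [pattern_rec(epoch, PatternId.A1, eip=True, in_progress=True)]
        conf = aggregate_epoch_confusion(recs, epoch)
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 1.0})
        assert weighted_latency(conf, wt) is None


class TestRatesAndDose:
    def test_events_per_hour(self):
        epoch = make_epoch(days=10 / 24)  # 10-hour epoch
        hist = [hist_day(epoch, 0, a1=200, b1=30, magnets=10, episodes=230)]
        rates = event_rate_metrics(hist, [], epoch)
        assert rates.events_per_hour == pytest.approx(24.0)

    def test_stimulations_per_episode(self):
        epoch = make_epoch()
        hist = [hist_day(epoch, 0, a1=100, episodes=90, long_episodes=10,
                         therapies=110)]
        rates = event_rate_metrics(hist, [], epoch)
        assert rates.stimulations_per_episode == pytest.approx(1.1)

    def test_pct_days_at_limit_counts_only_days_with_data(self):
        epoch = make_epoch(daily_therapy_limit=1000)
        hist = [hist_day(epoch, d, a1=10, episodes=10,
                         therapies=1500 if d < 3 else 10)
                for d in range(10)]
        hist.append(hist_day(epoch, 10, therapies=99999, missing=True))
        rates = event_rate_metrics(hist, [], epoch)
        assert rates.pct_days_at_limit == pytest.approx(30.0)

    def test_zero_episodes_leave_stimulation_rate_undefined(self):
        epoch = make_epoch()
        rates = event_rate_metrics([hist_day(epoch, 0)], [], epoch)
        assert rates.stimulations_per_episode is None

    def test_eip_rate_examples(self):
        epoch = make_epoch(days=30.44)
        hist = [hist_day(epoch, 0, a1=200, episodes=200)]
        conf = conf_from(epoch, {(PatternId.A1, E): (1, 1)})  # fraction 0.5
        wt = manual_weight_table(epoch.epoch_id,
                                 {StratumKey(PatternId.A1, E): 1.0})
        assert eip_rate(conf, wt, hist, epoch) == pytest.approx(100.0)

        conf0 = conf_from(epoch, {(PatternId.A1, E): (0, 2)})  # fraction 0
        assert eip_rate(conf0, wt, hist, epoch) == pytest.approx(0.0)

        epoch2 = make_epoch("E2", days=60.88)
        hist2 = [hist_day(epoch2, 0, a1=50, episodes=50)]
        conf1 = conf_from(epoch2, {(PatternId.A1, E): (2, 0)})  # fraction 1
        wt2 = manual_weight_table(epoch2.epoch_id,
                                  {StratumKey(PatternId.A1, E): 1.0})
        assert eip_rate(conf1, wt2, hist2, epoch2) == pytest.approx(25.0)


def _burst(hemi=Hemisphere.LEFT):
    return BurstConfig(current_ma=1.0, pulse_width_us=160.0,
                       frequency_hz=100.0, duration_ms=100.0,
                       cathode_electrodes=frozenset({1}),
                       anode_electrodes=frozenset({2}),
                       electrode_area_cm2=0.08, hemisphere=hemi)


class TestChargeDose:
    def test_per_pulse_oracle(self):
        """Independent per-pulse summation: 1 mA x 160 us over 0.08 cm^2 is
        2 uC/cm^2 per phase; a 100 Hz x 100 ms burst has 10 pulses; 100
        deliveries accumulate 2000 uC/cm^2."""
        burst = _burst()
        per_pulse = burst.current_ma * burst.pulse_width_us * 1e-3 \
            / burst.electrode_area_cm2
        assert per_pulse == pytest.approx(2.0)
        oracle = sum(per_pulse for _delivery in range(100)
                     for _pulse in range(10))

        epoch = make_epoch(therapies=(TherapyConfig(bursts=(burst,)),))
        hist = [hist_day(epoch, 0, a1=100, episodes=100, therapies=100)]
        dose = charge_dose(hist, [epoch], horizon_days=30.0)
        assert dose.total_uc_cm2 == pytest.approx(oracle) == \
            pytest.approx(2000.0)

    def test_zero_deliveries_zero_dose(self):
        epoch = make_epoch(therapies=(TherapyConfig(bursts=(_burst(),)),))
        hist = [hist_day(epoch, 0, a1=5, episodes=5, therapies=0)]
        assert charge_dose(hist, [epoch]).total_uc_cm2 == 0.0

    def test_hemisphere_symmetry(self):
        therapy = TherapyConfig(bursts=(_burst(Hemisphere.LEFT),
                                        _burst(Hemisphere.RIGHT)))
        epoch = make_epoch(therapies=(therapy,))
        hist = [hist_day(epoch, 0, a1=50, episodes=50, therapies=50)]
        dose = charge_dose(hist, [epoch])
        assert dose.by_hemisphere[Hemisphere.LEFT] == \
            pytest.approx(dose.by_hemisphere[Hemisphere.RIGHT])
        assert dose.total_uc_cm2 == pytest.approx(
            2 * dose.by_hemisphere[Hemisphere.LEFT])

    def test_additive_over_disjoint_day_ranges(self):
        epoch = make_epoch(therapies=(TherapyConfig(bursts=(_burst(),)),))
        h1 = [hist_day(epoch, d, a1=10, episodes=10, therapies=7 + d)
              for d in range(5)]
        h2 = [hist_day(epoch, d, a1=10, episodes=10, therapies=3)
              for d in range(5, 9)]
        total = charge_dose(h1 + h2, [epoch]).total_uc_cm2
        assert total == pytest.approx(charge_dose(h1, [epoch]).total_uc_cm2
                                      + charge_dose(h2, [epoch]).total_uc_cm2)

    def test_days_beyond_horizon_are_excluded(self):
        epoch = make_epoch(days=40,
                           therapies=(TherapyConfig(bursts=(_burst(),)),))
        hist = [hist_day(epoch, 0, a1=10, episodes=10, therapies=10),
                hist_day(epoch, 35, a1=10, episodes=10, therapies=10)]
        d_short = charge_dose(hist, [epoch], horizon_days=10.0)
        d_long = charge_dose(hist, [epoch], horizon_days=40.0)
        assert d_long.total_uc_cm2 == pytest.approx(2 * d_short.total_uc_cm2)


class TestConvexity:
    def test_weighted_metrics_stay_within_stratum_bounds(self):
        rng = np.random.default_rng(42)
        epoch = make_epoch()
        for _ in range(200):
            k = rng.integers(1, 5)
            patterns = list(PatternId)[:k]
            spec = {}
            for p in patterns:
                tp = int(rng.integers(0, 8))
                fp = int(rng.integers(0, 8))
                if tp + fp == 0:
                    tp = 1
                spec[(p, E)] = (tp, fp)
            conf = conf_from(epoch, spec)
            raw = {StratumKey(p, E): float(rng.uniform(0.01, 1.0))
                   for p in patterns}
            wt = manual_weight_table(epoch.epoch_id, raw)
            accs = [perf.accuracy for perf in conf.per_stratum.values()
                    if perf.accuracy is not None]
            got = weighted_epoch_metric(conf, wt, "accuracy")
            assert min(accs) - 1e-12 <= got <= max(accs) + 1e-12
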