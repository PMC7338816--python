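"""Model/Results interface over the evaluation pipeline.

:class:`DeviceBehaviorModel` is built from a canonical dataset (in memory or
from a directory) and policy choices; :meth:`DeviceBehaviorModel.fit` runs
classification, weighting, rate/dose computation and agreement statistics,
returning a :class:`DeviceBehaviorResults` carrying tidy DataFrames, a
``summary()`` table, report writing and Bland–Altman plotting.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    CLINICAL_THRESHOLD,
    bland_altman,
    completeness,
    heterogeneity,
    pearson_corr,
    wilcoxon_signed_rank,
)
from .extrapolation import (
    DEFAULT_DOSE_HORIZON_DAYS,
    NoWeightSupportError,
    WeightMode,
    WeightTable,
    charge_dose,
    compute_weight_table,
    eip_rate,
    event_rate_metrics,
    weighted_epoch_metric,
    weighted_latency,
)
from .io import ValidationReport, load_dataset, validate_dataset
from .performance import (
    LogTotals,
    NegativeAttribution,
    aggregate_epoch_confusion,
    standard_epoch_metrics,
)
from .types import Dataset, Hemisphere, ProgrammingEpoch

#: metrics compared between the standard and weighted methods
PAIRED_METRICS = ("accuracy", "sensitivity", "specificity", "latency_s")


class DatasetValidationError(Exception):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(report.summary())


class DeviceBehaviorModel:
    """Quantitative evaluation of closed-loop detector/stimulator behavior.

    Parameters
    ----------
    dataset
        A loaded canonical :class:`~rnsmetrics.types.Dataset`.
    negative_attribution
        Policy for placing pooled TN/FN counts into per-stratum
        denominators; see
        :class:`~rnsmetrics.performance.NegativeAttribution`.
    weight_mode
        ``"normalized"`` (weights renormalized to a convex combination,
        default) or ``"literal"`` (unnormalized raw-formula weights, for
        audit).
    loa_multiplier
        Bland–Altman limits-of-agreement multiplier (1.96 for ~95%).
    dose_horizon_days
        Horizon for cumulative charge density, measured from the first
        epoch start (default 8.5 average months).
    clinical_threshold
        Mean absolute standard-weighted difference deemed clinically
        significant (proportion scale).
    """

    def __init__(self, dataset: Dataset, *,
                 negative_attribution: NegativeAttribution | str =
                 NegativeAttribution.LOG_PROPORTIONAL,
                 weight_mode: WeightMode = "normalized",
                 loa_multiplier: float = 1.96,
                 dose_horizon_days: float = DEFAULT_DOSE_HORIZON_DAYS,
                 clinical_threshold: float = CLINICAL_THRESHOLD,
                 source_path: Path | None = None):
        self.dataset = dataset
        self.negative_attribution = NegativeAttribution(negative_attribution)
        self.weight_mode: WeightMode = weight_mode
        self.loa_multiplier = loa_multiplier
        self.dose_horizon_days = dose_horizon_days
        self.clinical_threshold = clinical_threshold
        self.source_path = source_path

    @classmethod
    def from_directory(cls, path: Path | str, **kwargs: Any
                       ) -> "DeviceBehaviorModel":
        path = Path(path)
        return cls(load_dataset(path), source_path=path, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, validate: bool = True) -> "DeviceBehaviorResults":
        """Run the full evaluation; raises
        :class:`DatasetValidationError` when validation errors are present
        and ``validate`` is true."""
        report = validate_dataset(self.dataset)
        if validate and report.errors:
            raise DatasetValidationError(report)

        rows = []
        weight_tables: dict[str, WeightTable] = {}
        ds = self.dataset
        for epoch in sorted(ds.epochs, key=lambda e: (e.patient_id, e.start)):
            rows.append(self._fit_epoch(epoch, weight_tables))
        epoch_metrics = pd.DataFrame(rows)

        agreement, ba_pairs = self._agreement(epoch_metrics)
        het = self._heterogeneity(epoch_metrics)
        patient_summary = self._patient_summary(epoch_metrics)

        return DeviceBehaviorResults(
            model=self,
            epoch_metrics=epoch_metrics,
            agreement=agreement,
            heterogeneity=het,
            patient_summary=patient_summary,
            weight_tables=weight_tables,
            bland_altman_pairs=ba_pairs,
            validation=report,
        )

    def _fit_epoch(self, epoch: ProgrammingEpoch,
                   weight_tables: dict[str, WeightTable]) -> dict[str, Any]:
        ds = self.dataset
        recs = ds.recordings_for_epoch(epoch.epoch_id)
        hist = ds.histogram_for_epoch(epoch)
        activity = ds.activity_for_epoch(epoch)
        log_totals = LogTotals(
            pattern_triggers=sum(a.pattern_a_events + a.pattern_b_events
                                 for a in activity),
            magnet_swipes=sum(a.magnet_swipes for a in activity),
        ) if activity else None
        conf = aggregate_epoch_confusion(recs, epoch,
                                         self.negative_attribution,
                                         log_totals)
        std = standard_epoch_metrics(conf)

        w_acc = w_sens = w_spec = w_lat = eips = None
        excluded = ""
        try:
            wt = compute_weight_table(conf, hist)
            weight_tables[epoch.epoch_id] = wt
            w_acc = weighted_epoch_metric(conf, wt, "accuracy",
                                          self.weight_mode)
            w_sens = weighted_epoch_metric(conf, wt, "sensitivity",
                                           self.weight_mode)
            w_spec = weighted_epoch_metric(conf, wt, "specificity",
                                           self.weight_mode)
            w_lat = weighted_latency(conf, wt, self.weight_mode)
            eips = eip_rate(conf, wt, hist, epoch, self.weight_mode)
            excluded = "|".join(str(s) for s in sorted(
                wt.excluded_strata, key=str))
        except NoWeightSupportError:
            pass
        rates = event_rate_metrics(hist, activity, epoch, ds.epochs)
        pooled = conf.pooled_counts()
        return {
            "patient_id": epoch.patient_id,
            "epoch_id": epoch.epoch_id,
            "n_reviewed": len(recs),
            "n_triggered_reviewed": int(pooled.tp + pooled.fp),
            "standard_accuracy": _f(std.accuracy),
            "weighted_accuracy": _f(w_acc),
            "standard_sensitivity": _f(std.sensitivity),
            "weighted_sensitivity": _f(w_sens),
            "standard_specificity": _f(std.specificity),
            "weighted_specificity": _f(w_spec),
            "standard_latency_s": _f(std.mean_latency_s),
            "weighted_latency_s": _f(w_lat),
            "eips_per_month": _f(eips),
            "events_per_hour": _f(rates.events_per_hour),
            "pattern_detections_per_hour": _f(rates.pattern_detections_per_hour),
            "stimulations_per_episode": _f(rates.stimulations_per_episode),
            "pct_days_at_limit": _f(rates.pct_days_at_limit),
            "days_to_stim_enabled": _f(rates.days_to_stim_enabled),
            "excluded_strata": excluded,
        }

    def _agreement(self, em: pd.DataFrame):
        rows = []
        pair_rows = []
        for metric in PAIRED_METRICS:
            s_col, w_col = f"standard_{metric}", f"weighted_{metric}"
            if len(em) == 0 or s_col not in em:
                continue
            pairs = [(None if pd.isna(s) else float(s),
                      None if pd.isna(w) else float(w))
                     for s, w in zip(em[s_col], em[w_col])]
            row: dict[str, Any] = {"metric": metric,
                                   "n_pairs": sum(1 for s, w in pairs
                                                  if s is not None
                                                  and w is not None)}
            try:
                ba = bland_altman(pairs, self.loa_multiplier)
                row.update(bias=ba.bias, sd_diff=ba.sd_diff,
                           loa_low=ba.loa_low, loa_high=ba.loa_high,
                           n_dropped=ba.n_dropped)
                for mean, diff in ba.pairs:
                    pair_rows.append({"metric": metric, "mean": mean,
                                      "difference": diff})
            except ValueError:
                row.update(bias=np.nan, sd_diff=np.nan, loa_low=np.nan,
                           loa_high=np.nan, n_dropped=len(pairs))
            try:
                defined = [(s, w) for s, w in pairs
                           if s is not None and w is not None]
                wsr = wilcoxon_signed_rank(defined, self.clinical_threshold)
                # the >5% clinical threshold is a proportion-scale notion;
                # latency (seconds) carries no such flag
                is_proportion = metric != "latency_s"
                row.update(wilcoxon_statistic=wsr.statistic,
                           p_value=wsr.p_value,
                           n_effective=wsr.n_effective,
                           mean_abs_difference=wsr.mean_abs_difference,
                           clinically_significant=(wsr.clinically_significant
                                                   if is_proportion
                                                   else False))
            except ValueError:
                row.update(wilcoxon_statistic=np.nan, p_value=np.nan,
                           n_effective=0, mean_abs_difference=np.nan,
                           clinically_significant=False)
            rows.append(row)
        return pd.DataFrame(rows), pd.DataFrame(pair_rows)

    def _heterogeneity(self, em: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for metric in ("weighted_accuracy", "weighted_sensitivity",
                       "weighted_specificity", "weighted_latency_s",
                       "events_per_hour", "stimulations_per_episode",
                       "eips_per_month"):
            if metric not in em or em[metric].dropna().empty:
                continue
            h = heterogeneity(em[metric].tolist())
            rows.append({"metric": metric, "mean": h.mean, "median": h.median,
                         "q25": h.q25, "q75": h.q75, "min": h.min,
                         "max": h.max, "n": h.n})
        return pd.DataFrame(rows)

    def _patient_summary(self, em: pd.DataFrame) -> pd.DataFrame:
        ds = self.dataset
        rows = []
        for pid in ds.patient_ids:
            sub = em[em.patient_id == pid] if len(em) else em
            hist = [d for d in ds.histogram_daily if d.patient_id == pid]
            comp = completeness(
                [a for a in ds.activity_log if a.patient_id == pid],
                [e for e in ds.event_list if e.patient_id == pid],
                hist,
                [r for r in ds.recordings if r.patient_id == pid])
            epochs = ds.epochs_for(pid)
            try:
                dose = charge_dose(hist, epochs, self.dose_horizon_days)
                dose_total = dose.total_uc_cm2
                dose_left = dose.by_hemisphere[Hemisphere.LEFT]
                dose_right = dose.by_hemisphere[Hemisphere.RIGHT]
            except ValueError:
                dose_total = dose_left = dose_right = np.nan
            r, p = self._seizure_correlation(pid, em)
            rows.append({
                "patient_id": pid,
                "n_epochs": len(epochs),
                "mean_weighted_accuracy": _mean(sub, "weighted_accuracy"),
                "mean_weighted_sensitivity": _mean(sub, "weighted_sensitivity"),
                "mean_weighted_specificity": _mean(sub, "weighted_specificity"),
                "mean_weighted_latency_s": _mean(sub, "weighted_latency_s"),
                "mean_eips_per_month": _mean(sub, "eips_per_month"),
                "ecog_completeness_pct": _f(comp.ecog_pct),
                "event_list_completeness_pct": _f(comp.event_list_pct),
                "histogram_completeness_pct": _f(comp.histogram_pct),
                "dose_total_uc_cm2": dose_total,
                "dose_left_uc_cm2": dose_left,
                "dose_right_uc_cm2": dose_right,
                "seizure_corr_r": r,
                "seizure_corr_p": p,
            })
        return pd.DataFrame(rows)

    def _seizure_correlation(self, pid: str, em: pd.DataFrame):
        """Pearson correlation of monthly extrapolated EIP counts against
        patient-reported seizures, over months with both quantities."""
        ds = self.dataset
        reports = {s.month: s.reported_seizures
                   for s in ds.seizure_reports if s.patient_id == pid}
        if len(reports) < 3:
            return np.nan, np.nan
        frac_by_epoch: dict[str, float] = {}
        for _, row in em[em.patient_id == pid].iterrows():
            months = row["eips_per_month"]
            if pd.isna(months):
                continue
            epoch = ds.epoch_by_id(row["epoch_id"])
            hist = [d for d in ds.histogram_for_epoch(epoch)
                    if not d.histogram_data_missing]
            episodes = sum(d.episode_count + d.long_episode_count
                           for d in hist)
            if episodes:
                # invert the per-month rate back to an EIP fraction
                frac_by_epoch[epoch.epoch_id] = (
                    months * (epoch.duration_days / 30.44) / episodes)
        pairs = []
        for month, reported in sorted(reports.items()):
            est = 0.0
            have = False
            for d in ds.histogram_daily:
                if (d.patient_id != pid or d.histogram_data_missing
                        or d.date.strftime("%Y-%m") != month):
                    continue
                epoch = next((e for e in ds.epochs_for(pid)
                              if e.start.date() <= d.date <= e.end.date()),
                             None)
                if epoch is None or epoch.epoch_id not in frac_by_epoch:
                    continue
                est += frac_by_epoch[epoch.epoch_id] * (
                    d.episode_count + d.long_episode_count)
                have = True
            if have:
                pairs.append((est, reported))
        try:
            return pearson_corr(pairs)
        except ValueError:
            return np.nan, np.nan


def _f(v: float | None) -> float:
    return np.nan if v is None else float(v)


def _mean(frame: pd.DataFrame, col: str) -> float:
    if len(frame) == 0 or col not in frame:
        return np.nan
    vals = frame[col].dropna()
    return float(vals.mean()) if len(vals) else np.nan


@dataclass
class DeviceBehaviorResults:
    """Fitted evaluation results.

    Attributes hold tidy DataFrames: ``epoch_metrics`` (one row per
    programming epoch, standard and weighted values side by side),
    ``agreement`` (one row per compared metric), ``heterogeneity`` (spread
    of the weighted metrics across epochs), ``patient_summary``
    (completeness, dose, seizure correlation), and ``bland_altman_pairs``
    (plot-ready mean/difference pairs).
    """

    model: DeviceBehaviorModel
    epoch_metrics: pd.DataFrame
    agreement: pd.DataFrame
    heterogeneity: pd.DataFrame
    patient_summary: pd.DataFrame
    weight_tables: dict[str, WeightTable]
    bland_altman_pairs: pd.DataFrame
    validation: ValidationReport = field(default_factory=ValidationReport)

    def summary(self) -> str:
        lines = ["Device behavior evaluation",
                 "=" * 60,
                 f"patients: {len(self.patient_summary)}   "
                 f"epochs: {len(self.epoch_metrics)}   "
                 f"policy: {self.model.negative_attribution.value}/"
                 f"{self.model.weight_mode}",
                 ""]
        if len(self.epoch_metrics):
            lines.append("Per-epoch means (standard vs weighted):")
            for metric in PAIRED_METRICS:
                s = _mean(self.epoch_metrics, f"standard_{metric}")
                w = _mean(self.epoch_metrics, f"weighted_{metric}")
                unit = " s" if metric == "latency_s" else ""
                name = metric.replace("_s", "") if metric == "latency_s" \
                    else metric
                if metric == "latency_s":
                    lines.append(f"  {name:<12} S={s:8.3f}{unit}  "
                                 f"W={w:8.3f}{unit}")
                else:
                    lines.append(f"  {name:<12} S={100 * s:7.1f}%  "
                                 f"W={100 * w:7.1f}%")
            lines.append("")
        if len(self.agreement):
            lines.append("Agreement (difference = standard - weighted):")
            for _, row in self.agreement.iterrows():
                if pd.isna(row["bias"]):
                    lines.append(f"  {row['metric']:<12} "
                                 "(needs >= 2 defined epoch pairs)")
                    continue
                if row["metric"] == "latency_s":
                    sig = f"mean |diff| {row['mean_abs_difference']:.3f} s"
                else:
                    sig = ("clinically significant (>5%)"
                           if row.get("clinically_significant")
                           else "within 5%")
                lines.append(
                    f"  {row['metric']:<12} bias={row['bias']:+.4f} "
                    f"LoA=[{row['loa_low']:+.4f}, {row['loa_high']:+.4f}] "
                    f"p={row['p_value']:.3g} ({sig})")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save_tables(self, out_path: Path | str) -> list[Path]:
        """Write all report tables plus a machine-readable run manifest."""
        from .io import write_report_tables

        out = Path(out_path)
        manifest_paths = write_report_tables(self, out)
        extra = {
            "heterogeneity.csv": self.heterogeneity,
            "bland_altman_pairs.csv": self.bland_altman_pairs,
        }
        for name, frame in extra.items():
            p = out / name
            frame.to_csv(p, index=False)
            manifest_paths.append(p)
        wrows = []
        for eid, wt in sorted(self.weight_tables.items()):
            for s in sorted(wt.raw, key=str):
                wrows.append({"epoch_id": eid, "stratum": str(s),
                              "raw_weight": wt.raw[s],
                              "normalized_weight": wt.normalized[s],
                              "excluded": s in wt.excluded_strata})
        wpath = out / "weights.csv"
        pd.DataFrame(wrows).to_csv(wpath, index=False)
        manifest_paths.append(wpath)

        manifest = {
            "software_version": __version__,
            "schema_version": "1.0",
            "generated_fields": sorted(self.epoch_metrics.columns.tolist()),
            "config": {
                "negative_attribution": self.model.negative_attribution.value,
                "weight_mode": self.model.weight_mode,
                "loa_multiplier": self.model.loa_multiplier,
                "dose_horizon_days": self.model.dose_horizon_days,
                "clinical_threshold": self.model.clinical_threshold,
            },
            "input_checksums": self._input_checksums(),
            "n_epochs": int(len(self.epoch_metrics)),
            "n_patients": int(len(self.patient_summary)),
            "validation_warnings": len(self.validation.warnings),
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True),
                         encoding="utf-8")
        manifest_paths.append(mpath)
        return manifest_paths

    def _input_checksums(self) -> dict[str, str]:
        src = self.model.source_path
        if src is None or not Path(src).is_dir():
            return {}
        out = {}
        for p in sorted(Path(src).glob("*.csv")):
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return out

    # -- plotting ---------------------------------------------------------

    def plot_bland_altman(self, metric: str = "accuracy", ax=None):
        """Bland–Altman scatter (mean vs standard-weighted difference) with
        bias and limits of agreement."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        sub = self.bland_altman_pairs
        if len(sub):
            sub = sub[sub.metric == metric]
            ax.scatter(sub["mean"], sub["difference"], s=18, alpha=0.7)
        row = self.agreement[self.agreement.metric == metric] \
            if len(self.agreement) else self.agreement
        if len(row):
            r = row.iloc[0]
            ax.axhline(r["bias"], color="k", lw=1)
            for y in (r["loa_low"], r["loa_high"]):
                ax.axhline(y, color="k", lw=1, ls="--")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel(f"mean of standard and weighted {metric}")
        ax.set_ylabel("standard - weighted")
        ax.set_title(f"Bland-Altman: {metric}")
        return ax
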