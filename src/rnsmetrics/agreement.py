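"""Standard-vs-weighted agreement statistics and cohort summaries.

The direction of the paired difference is fixed everywhere as
``standard - weighted``. Clinical significance of a disagreement is a mean
absolute paired difference above 5% (0.05 on the proportion scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .types import (
    ActivityLogRecord,
    EcogRecording,
    EventListEntry,
    HistogramDay,
)

#: mean absolute difference above which a disagreement is clinically
#: significant (proportion scale)
CLINICAL_THRESHOLD = 0.05


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int
    n_dropped: int
    pairs: list[tuple[float, float]]  # (mean, difference)


def bland_altman(pairs: Iterable[tuple[float | None, float | None]],
                 loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman agreement of paired (standard, weighted) values.

    difference = standard - weighted; mean-axis value = (standard+weighted)/2.
    Limits of agreement are bias +/- multiplier x SD (n-1 denominator).
    Pairs with either value undefined are dropped and counted. Requires at
    least two defined pairs.
    """
    pairs = list(pairs)
    defined = [(s, w) for s, w in pairs if s is not None and w is not None]
    n_dropped = len(pairs) - len(defined)
    if len(defined) < 2:
        raise ValueError(
            f"bland_altman needs >= 2 defined pairs, got {len(defined)}")
    diffs = np.array([s - w for s, w in defined], dtype=float)
    means = np.array([(s + w) / 2.0 for s, w in defined], dtype=float)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        n_pairs=len(defined),
        n_dropped=n_dropped,
        pairs=list(zip(means.tolist(), diffs.tolist())),
    )


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_effective: int
    mean_abs_difference: float
    clinically_significant: bool


#: above this many nonzero differences the normal approximation (with
#: continuity and tie corrections) replaces exact enumeration
EXACT_N_MAX = 25


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]] | Sequence[float],
    clinical_threshold: float = CLINICAL_THRESHOLD,
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Accepts (standard, weighted) pairs or precomputed differences. Zero
    differences are dropped; the exact null distribution is used for up to
    ``EXACT_N_MAX`` nonzero differences without rank ties, the normal
    approximation with continuity and tie corrections otherwise. Raises on
    all-zero differences.
    """
    diffs = np.array([d if np.isscalar(d) else d[0] - d[1] for d in pairs],
                     dtype=float)
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        raise ValueError("degenerate pairs: all differences are zero")
    ranks = stats.rankdata(np.abs(nz))
    has_ties = len(np.unique(ranks)) != len(ranks)
    method = "exact" if (nz.size <= EXACT_N_MAX and not has_ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                         correction=(method == "approx"),
                         zero_method="wilcox")
    mean_abs = float(np.abs(diffs).mean())
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_effective=int(nz.size),
        mean_abs_difference=mean_abs,
        clinically_significant=mean_abs > clinical_threshold,
    )


@dataclass
class CompletenessReport:
    """Per-source completeness against the Activity Log (source of truth)."""

    ecog_pct: float | None
    event_list_pct: float | None
    histogram_pct: float | None
    total_events: int
    capped: bool = False  # any percentage capped at 100


def completeness(activity: Iterable[ActivityLogRecord],
                 event_list: Iterable[EventListEntry],
                 hist: Iterable[HistogramDay],
                 stored_recordings: Iterable[EcogRecording],
                 ) -> CompletenessReport:
    """Share of Activity-Log total events surviving at each logging tier.

    Total events = pattern detections + saturations + magnet swipes from the
    Activity Log. Histogram events count only days without the missing flag.
    Percentages are capped at 100 (``capped`` is then set). With zero total
    events all percentages are ``None``.
    """
    total = sum(a.total_events for a in activity)
    if total == 0:
        return CompletenessReport(None, None, None, 0)
    n_ecog = sum(1 for _ in stored_recordings)
    n_entries = sum(1 for _ in event_list)
    n_hist = sum(d.total_events for d in hist if not d.histogram_data_missing)
    values = [100.0 * n / total for n in (n_ecog, n_entries, n_hist)]
    capped = any(v > 100.0 for v in values)
    values = [min(v, 100.0) for v in values]
    return CompletenessReport(values[0], values[1], values[2], total, capped)


def pearson_corr(monthly_pairs: Sequence[tuple[float, float]]
                 ) -> tuple[float, float]:
    """Sample Pearson r of (EIPs, reported seizures) and two-sided p from the
    t transform. Requires >= 3 pairs and nonzero variance in both
    coordinates."""
    if len(monthly_pairs) < 3:
        raise ValueError("pearson_corr needs >= 3 pairs")
    x = np.array([p[0] for p in monthly_pairs], dtype=float)
    y = np.array([p[1] for p in monthly_pairs], dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in one coordinate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class HeterogeneitySummary:
    mean: float
    median: float
    q25: float
    q75: float
    min: float
    max: float
    n: int


def heterogeneity(values: Iterable[float | None]) -> HeterogeneitySummary:
    """Cross-patient/epoch spread of a metric: mean, median, quartiles
    (linear interpolation between order statistics), and range. Undefined
    values are ignored; raises when nothing is defined."""
    vals = np.array([v for v in values if v is not None and not math.isnan(v)],
                    dtype=float)
    if vals.size == 0:
        raise ValueError("heterogeneity of an empty collection")
    return HeterogeneitySummary(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        q25=float(np.quantile(vals, 0.25)),
        q75=float(np.quantile(vals, 0.75)),
        min=float(vals.min()),
        max=float(vals.max()),
        n=int(vals.size),
    )
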