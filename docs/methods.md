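# Methods

This note documents the statistical procedure, the simulator it is
validated against, the parameters that matter, and the design choices made
where the problem left the design open.

## Classification of reviewed snippets

Each stored ECoG recording carries an expert annotation (EIP present or
absent, EIP onset in seconds from recording start, laterality). One
confusion-matrix label is assigned per recording from the first episode:

- pattern-triggered, EIP present → **TP** in stratum
  (triggering Pattern, episode class); EIP absent → **FP** in the same
  stratum;
- scheduled, magnet and saturation recordings sample brain activity
  independently of the detector: EIP absent → **TN**, present → **FN**,
  both pooled (they carry no triggering Pattern).

Detection latency = first detection time − annotated EIP onset, recorded
for TPs only; recordings whose first episode was already in progress at
recording start are excluded from the latency pool but kept in the
confusion totals. Negative latencies are legal and meaningful — stimulation
of a false detection can immediately precede (or precipitate) the ictal
pattern. Magnet-triggered recordings are treated as detector-independent
observations, like scheduled ones: the magnet samples brain activity on the
patient's initiative, not the detector's.

Undefined metrics (empty denominators) are represented as missing values,
never coerced to 0 or 1; downstream weighting renormalizes around them.

## Negative attribution

Per-stratum accuracy and specificity need TN/FN counts in their
denominators, but pooled negatives belong to no stratum. Four policies are
implemented (`NegativeAttribution`):

- **`log_proportional`** (default). Stored snippet classes survive storage
  at different rates: with one slot per class, a class generating 2 events
  per interrogation interval keeps 50% of them while a class generating 10
  keeps 10%. The stored magnet-to-trigger ratio therefore misstates the
  true one, and that level error propagates into every stratum's
  sensitivity identically — no reweighting across strata can remove it. The
  Activity Log, however, counts both classes completely. Scaling
  magnet-class negatives by
  `(stored triggers / logged triggers) / (stored magnets / logged magnets)`
  restores the logged ratio before proportional attribution. This is the
  same principle as the weighting itself: snippet-derived fractions are
  unbiased within a storage class; levels should come from complete counts.
  Scheduled-class negatives are left at their stored level (the logs carry
  no scheduled-recording total). With exhaustive storage the factor is
  exactly 1 and the policy reduces to `proportional`.
- **`proportional`**: pooled negatives split across strata by trigger
  share. The convex combination of stratum accuracies under true-share
  weights then telescopes exactly to the pooled accuracy (numerator and
  denominator both scale with the stratum count); sensitivity and
  specificity do not telescope, which is one reason the level correction
  above matters.
- **`replicate`**: the full pooled counts are copied into every stratum.
  Kept for comparison; note it counts each negative once per stratum,
  inflating stratum accuracy and depressing stratum sensitivity relative to
  the pooled values.
- **`none`**: strata carry TP/FP only (accuracy degenerates to precision).

## Weighting

Raw stratum weights multiply the snippet trigger share by the history
share: episode strata use the pattern's share of total history pattern
counts, long-episode strata use the long-episode share of all episodes
(`LE/(LE+E)`). Days flagged `histogram_data_missing` are excluded from all
history sums, rates and dose.

The raw weights do not sum to one: the episode block is scaled by pattern
shares, the long-episode block by the long-episode share, and the two
blocks overlap. A literal weighted sum is therefore not a proportion and
can leave [0, 1]. The default mode renormalizes raw weights to unit sum
over surviving strata (zero-snippet-support strata are excluded and
listed); `literal` mode reproduces the unnormalized sum for auditability.
For each metric the weights are renormalized over the strata where that
metric is defined. A known consequence of the raw formula: even with
exhaustive storage the normalized weights are not the sample stratum shares
(the episode weight carries the pattern share where the episode share would
be needed), so the weighted and pooled values coincide exactly only in
degenerate regimes — a single stratum, or equal-size strata. The test suite
pins this behavior rather than hiding it.

Weighted latency combines per-stratum mean TP latencies with the weights
renormalized over latency-bearing strata. EIPs/month multiplies the
weighted EIP fraction (per-stratum TP/(TP+FP), weighted) by total history
episodes and divides by the epoch length in 30.44-day months.

## Rates and charge dose

Events/hour, pattern detections/hour, stimulations/episode and the
percentage of days reaching the daily therapy limit come directly from log
data; "total events" is pattern detections + saturations + magnet swipes,
and only days with histogram data count toward the daily-limit denominator.

Cumulative stimulation dose is single-phase charge density, the convention
of the device's programming interface: per pulse,
`current_mA × pulse_width_µs × 10⁻³ / electrode_area_cm² µC/cm²`;
per burst, times `⌊frequency × burst duration⌋` pulses; per delivered
therapy, summed over the therapy's one or two bursts and attributed to each
burst's hemisphere. Daily delivered-therapy counts are apportioned to
therapy slots in configured order — slot i fires in every episode that
received at least i therapies, so slot 1 absorbs up to one delivery per
episode before slot 2 receives any (the histogram does not break counts
down by slot). The default horizon is 8.5 × 30.44 days from the first
epoch start.

## Agreement statistics

The paired difference is fixed as **standard − weighted** everywhere.
Bland–Altman uses the n−1 standard deviation and a 1.96 multiplier for the
limits of agreement. The Wilcoxon signed-rank test drops zero differences,
uses the exact null distribution for ≤ 25 nonzero differences without rank
ties, and the normal approximation with continuity and tie corrections
otherwise. Clinical significance is a mean absolute difference > 5% (0.05),
a proportion-scale notion applied to accuracy/sensitivity/specificity only;
latency reports the mean absolute difference in seconds without a flag.
Epochs with either value undefined are dropped pairwise and counted.
Logging completeness is measured against the Activity Log as the source of
truth, capped at 100% with a flag. Heterogeneity summaries (mean, median,
quartiles, range) use linear interpolation between order statistics
(type-7), the numpy default. The EIP-vs-reported-seizure Pearson
correlation pairs monthly extrapolated EIP counts (epoch EIP fraction ×
that month's histogram episodes) with the patient's monthly report.

## The simulator

The simulator generates what the method needs to be tested against: a
complete labelled event stream, then its degradation through the device's
storage rules.

**Ground truth.** EIP onsets follow a Poisson process, optionally
modulated by a multidien sinusoid (rate × (1 + a·sin 2πt/P), a ∈ [0, 1)).
Each EIP is tested against the configured detectors in Pattern order
(first-configured wins); detection draws a latency from a shifted gamma
(default shift −0.5 s, shape 2, scale 1.5 — a small negative mass, clipped
to [−20, 25] s so onset and detection stay inside a 90-s snippet). Episode
class is Bernoulli(long_episode_prob), independent of Pattern. Each pattern
also emits false triggers as an independent Poisson process. Scheduled
recordings occur at fixed daily times; magnet swipes are background Poisson
events plus, with configured probability, a swipe 20–70 s after a *missed*
EIP — the channel through which false negatives become observable.
Therapies per episode are Poisson-distributed (clipped to the device's
maximum of five) and capped by the daily therapy limit. Monthly seizure
reports are Binomial(EIPs that month, report probability).

**True performance** is defined over the *recordable* universe: every event
that would generate a stored recording under unconstrained storage
(triggered episodes, scheduled recordings, magnet swipes). Missed EIPs
captured by no recording are tallied separately — they are invisible to any
storage policy, and no snippet-based method can be scored on them.

**Degradation.** Interrogations arrive at lognormal intervals (default
mean 30.3 h, σ = 0.35, giving a median near 24 h with a heavy right tail).
Between interrogations, recordable events compete for ECoG slots by
storage class (Pattern A, Pattern B, scheduled, magnet): reserved classes
keep their newest `r` events, unreserved classes share the remaining pool,
oldest-first overwritten. The event list keeps the oldest `capacity`
(default 700) episodes per interval — newer events are lost. Hourly
histogram counts saturate at the cap (default 255), dropping events beyond
it and flagging the whole day `histogram_data_missing`. The Activity Log is
always complete. Annotations are copied from truth, flipped with
probability `annotation_noise` (default 0: expert review is treated as
ground truth).

**What it does not emulate:** no waveforms (events and annotations only),
no saturation or noise-detector events, no hardware diagnostics, no
evolving seizure networks or detector drift within an epoch, one patient
per seed (cohorts are built by iterating seeds). Scheduled recordings
capture a missed EIP only when one falls within the snippet window, which
at realistic rates is rare — in real data, as here, the magnet is the main
FN channel. Passing the validation therefore shows the estimator corrects
*storage-composition* bias under stationary rates; it does not show
robustness to annotation error, non-stationarity (e.g. multidien phase
interacting with interrogation timing), or misconfigured schedules.

## Key parameters

| parameter | default | unit | why |
|---|---|---|---|
| `ecog_slots` / reservation | 4 / one per class | — | first-generation device storage |
| `event_list_capacity` | 700 | events | device event-list limit |
| `hourly_histogram_cap` | 255 | events/h | histogram counter saturation |
| `interrogation_interval_hours` | 30.3 (lognormal, σ 0.35) | h | observed cohort mean with median ≈ 24 h |
| `eip_rate_per_day` | 3 | /day | moderately active patient |
| `long_episode_prob` | 0.15 | — | minority of detections exceed the duration threshold |
| `therapies_per_episode_mean` | 1.1 | /episode | typical delivered-therapy rate |
| `daily_therapy_limit` | 2000 | /24 h | median programmed limit |
| `scheduled_recordings_per_day` | 2 | /day | common device schedule |
| latency shift/shape/scale | −0.5 / 2 / 1.5 | s | seconds-scale latency with small negative mass |
| dose horizon | 8.5 × 30.44 | days | common post-implant comparison point |
| burst defaults | 2 mA, 160 µs, 200 Hz, 100 ms, 0.08 cm² | — | typical programming ranges and contact area |

## Validation design

The bias-recovery validation (`heterogeneous_storage_config`) uses 20
seeds × 90 days. Per seed it draws a dominant detector (false triggers
2.5–8/day) and a quiet one (0.3–1.5/day) with independent EIP-detection
probabilities (0.1–0.9), randomly assigned to Pattern A1/B1, so the
better detector is sometimes the frequent one and sometimes not — the
snippet-only bias then varies in direction, as it must. Rates are chosen so
each storage class overflows its reserved slot by comparable factors: the
stored sample then distorts the *composition* across strata (which history
weighting corrects) more than the positive-to-negative balance within the
pool (which no snippet method can correct). At these rates the event-list
and histogram caps are enabled at device values but rarely bind; their
binding behavior is verified separately on constructed streams. Across the
20 configurations the weighted method's mean absolute error against ground
truth is clearly smaller for accuracy; for sensitivity the advantage is
real but small and can fall within noise on other seed sets — the residual
FN-level error shared by both methods dominates once composition bias is
corrected. The exhaustive-storage consistency check uses a single enabled
detector without long episodes, the regime in which the published weighting
formula is exactly consistent (see Weighting above); with unlimited slots
and caps disabled, standard, weighted and true metrics must agree exactly,
and do.

Problem sizes in the routine test suite (20 × 90-day simulations, 10-seed
equivalence runs, 10⁴-draw coverage checks, 2ⁿ sign enumerations to n = 10)
were chosen to exercise every mechanism at desk scale.

## Known limitations

- The published weight formula's episode block uses the pattern history
  share where a consistent joint decomposition would use the episode share;
  normalized weighting makes the result a proper convex combination but
  does not remove this tilt. Both normalized and literal values are
  reported.
- Sensitivity estimation inherits whatever false negatives the magnet and
  scheduled channels happen to capture; EIPs that neither the detector nor
  the patient notices are unknowable to every method, including this one.
- Weights assume within-epoch stationarity; multidien rhythms interacting
  with storage timing are simulated (as a stressor) but not corrected for.
- The charge-dose slot apportionment is an approximation forced by the
  histogram's daily granularity.
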