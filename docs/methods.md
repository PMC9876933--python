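# Methods

## Data model

A hypnogram is an immutable sequence of stage labels, one per 30-s epoch,
with seven admissible labels: AW (active wake), QW (quiet wake), N1/N2/N3
(non-REM), R (REM) and X (artifact). Epoch `i` covers the half-open
interval `[start + 30i s, start + 30(i+1) s)`; all analysis windows must
align to epoch boundaries, and misalignment is an error rather than a
silent truncation, since every protocol time involved (session starts,
20-min windows, 12-h splits) is a multiple of 30 s. Recordings are either
daytime (07:00–19:00) or nighttime (19:00–07:00, lights off at 19:00);
clock arithmetic wraps past midnight.

Artifact epochs are recoded to active wake before analysis (`X → AW`,
idempotent). Pooled stage sets are fixed: wake W = {AW, QW}, sleep =
{N1, N2, N3, R}, light sleep = {N1, N2}.

The file format is one epoch per line (`epoch_index,stage` with an
optional header, or a bare stage token per line), with recording metadata
(start time, light schedule, kind) in a YAML sidecar. This keeps data
files diffable and the metadata explicit.

## MSLT scoring

Each 20-min lights-off window (exactly 40 epochs) is scored
independently. Latency is the onset time of the first sleep epoch — a
window whose first epoch is sleep scores 0.0 min — and a sleep-free window
is censored at the full 20 min. A single 30-s sleep epoch counts for both
latency and incidence; no minimum-duration smoothing is applied. Session
REM latency is elapsed clock time from the first sleep epoch to the first
R epoch (not accumulated sleep time). Cohort summaries pool all lights-off
sessions; SEM denominators are the number of pooled sessions.

## Daytime/nighttime metrics

* **TST** = 0.5 min × number of sleep epochs.
* **SL** is measured from recording start (daytime) or lights-off
  (nighttime); a recording without sleep reports SL as absent and is
  excluded from the cohort SL mean.
* **REM latency** = first R onset − first sleep onset; cohort tables
  average it over recordings containing R and report the percentage of
  such recordings alongside.
* **Sleep efficiency** = 100 × TST / nocturnal time (720 min for a full
  night), reported to 1 decimal.
* **WASO** = sleep period time − TST, with sleep period time defined as
  recording end − first sleep onset. This convention needs no
  final-awakening heuristic and is consistent (within mean-of-means
  rounding) with the usual published presentation of the triple
  (SL, TST, WASO) over a 720-min night.
* **SOREMP**: sleep-onset events are starts of sleep episodes, where
  episodes are runs of sleep separated by ≥ 10 min of continuous wake (the
  reset gap prevents brief arousals from spawning spurious onsets; it is a
  package convention and is configurable). An event counts when an R epoch
  begins within 15 min of the onset and before the episode ends. The
  15-min window is elapsed clock time by default; an accumulated-sleep
  variant is available (`use_cumulative_sleep=True`).
* **Sleep cycles**: no standard primate definition exists, so the count is
  a configurable convention: a cycle requires ≥ 10 min of cumulative
  non-REM followed by ≥ 1 R epoch, and closes when the REM period ends and
  either ≥ 10 min of wake elapses or non-REM accumulation for the next
  cycle begins. Both thresholds are exposed as parameters.
* **Stage percentages** use total epochs after artifact recoding as the
  denominator (artifacts having been folded into AW), so they always sum
  to 100.

## Transition analysis

The stage shift index is the number of adjacent epoch pairs with differing
stage, per hour. By default it counts shifts in the 7-label scheme (an
AW↔QW change counts — it is a fragmentation measure and those
micro-transitions are informative); a pooled 5-state variant is available,
since the two conventions genuinely differ and the field is not explicit
about which is standard.

Transition matrices are first-order: 5×5 adjacent-pair counts (including
self-transitions) over W/N1/N2/N3/R, row-normalised; a source state never
visited keeps an all-zero row rather than an undefined one. Matrices are
estimated per recording, and condition contrasts test each (source,
destination) cell across recordings with a two-sided Wilcoxon rank-sum
test — the cohort, not the epoch, is the sampling unit. Cells whose source
row is empty in every recording of either cohort are reported as absent
(NaN). Raw p-values are reported by default; Benjamini–Hochberg over the
tested cells is available via `adjust="bh"`.

## Statistics

* Kruskal–Wallis H uses the tie-corrected rank formula (scipy), with
  Dunn's pairwise z-tests on mean ranks using the tie-corrected pooled
  variance. The Dunn family adjustment defaults to Holm (the common
  pairing in modern software); Bonferroni and unadjusted modes are
  available and the mode used is recorded in the result object.
* Fisher's exact test sums hypergeometric probabilities of tables no more
  probable than the one observed (two-sided).
* The Wilcoxon rank-sum test uses exact enumeration of all group
  assignments when the smaller sample has < 10 observations (ties
  half-counted in U; the permutation null is symmetric, so the two-sided p
  is the symmetric tail), capped at 2×10⁵ assignments, and a tie-corrected
  normal approximation with continuity correction otherwise. Degenerate
  inputs with zero rank variance return p = 1.

On null simulations the asymptotic variants hold their nominal 5% size to
within ±1 percentage point; Fisher's exact test, like any exact
conditional test on discrete small-sample tables, is conservative (its
empirical size is below nominal), which is the validity guarantee the test
offers.

## Charge density

Charge density per pulse = (V/R)·PW/A with V in volts, R in ohms, PW in
µs, A in mm²; A·µs = µC so units need no extra factor. Impedance, not a
separately measured current, is the input, because chronic DBS settings
record voltage and contact impedance. Reported to 2 decimals.

## Synthetic generator

Each condition profile is a time-inhomogeneous first-order Markov chain
over the 7 labels: six 2-h blocks per 12-h recording, each with its own
row-stochastic 7×7 matrix, sampled with numpy's PCG64 generator
(bit-reproducible given profile and seed; cohort member *i* uses seed
`base_seed + i`). Two-hour blocks are the simplest structure that places
morning naps, scattered naps, or consolidated stimulated wake at the right
times of day.

Matrix entries were set by dwell-time arithmetic (mean bout length
0.5/(1−p_self) min; first-passage ≈ 1/hazard) to land in realistic
macaque ranges and then frozen:

* `healthy_day`: AW-dominated wake with brief QW, nap pressure
  concentrated in the morning (two longer N1/N2 naps) with lighter, shorter
  afternoon naps; no daytime REM or N3. Typical cohort means: SL ~40 min,
  TST ~70 min, stage shift ~7/h.
* `parkinsonian_day`: higher wake→sleep hazard (raised further in the
  first morning block), elevated QW, fragmented naps all day, and small
  direct N1→R / N2→R entries so naps can reach REM near onset (SOREMP rate
  ~2/day). Typical: SL ~10 min, TST ~170–190 min, stage shift ~19/h.
* `parkinsonian_lfs_day`: strongly self-adherent AW (mean continuous AW
  bout ~14 min vs ~4 min parkinsonian), low sleep entry, fast nap exit, no
  REM — the wake-consolidation signature of low-frequency stimulation.
* `healthy_night`: a slower-entry settling block after lights-off
  (SL ~10–15 min) then consolidated sleep with N2→N3 depth and regular REM;
  cohort TST ~520–590 min, efficiency ~72–77%.
* `parkinsonian_night`: doubled wake pressure, shallow NREM, sparse
  N3/REM; TST ~230–320 min.
* `parkinsonian_postlfs_night`: intermediate consolidation; TST between
  the other two night profiles.

The generator emulates the *statistical* architecture the metrics consume
(latencies, bout-length distributions, stage mixtures, transition
structure). It does not model circadian or homeostatic drift within a
block, ultradian cycle periodicity beyond what Markov dwell times imply,
inter-animal differences, or scorer noise — so green pipeline tests
demonstrate correctness of the computations and the direction of condition
contrasts, not fidelity to any particular animal's numbers. Acceptance-
style checks therefore assert directions and orderings (parkinsonian SL <
healthy SL; stimulated W→W probability and AW-bout length above
parkinsonian; healthy-night TST above parkinsonian-night TST), never
equality with published animal values.

`estimate_profile` pools per-block adjacent-pair counts over a cohort and
row-normalises. Recovery checks compare estimated to generating rows only
where the data can support the tolerance: rows with at least 664 pooled
transitions, the count at which the worst-case 99% binomial confidence
half-width (2.576·√(0.25/n)) drops below the 0.05 tolerance. Rows for
states a profile cannot reach carry no information and are excluded by
construction.

## Problem sizes and numerical conventions

Simulated cohorts use 10 recordings per unstimulated condition and 5 for
the stimulated daytime condition, each 1440 epochs (12 h), matching the
study design the metrics serve. Null-size simulations use 10⁴ replicates.
Reported minutes and percentages round to 1 decimal; charge density to 2.
Ties in ranks use midranks throughout. Degenerate inputs (empty groups,
windows off epoch grid, sleepless nights for WASO) raise errors rather
than returning sentinel numbers.
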