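# hypnokit

Hypnogram analytics for nonhuman-primate polysomnography, built around the
question of excessive daytime sleepiness (EDS) in the MPTP parkinsonian
macaque and its modulation by low-frequency deep-brain stimulation (DBS) of
the pedunculopontine-nucleus area.

The package takes epoch-scored hypnograms — one stage label per 30-s epoch
among active wake (AW), quiet wake (QW), non-REM stages N1/N2/N3, REM (R)
and artifact (X) — anchored to a clock time and a 12-h light/dark schedule
(lights off 19:00), and provides:

- **Hypnogram I/O and primitives** (`hypnokit.core`): CSV parsing/writing,
  artifact recoding (X → AW), maximal-bout segmentation, clock-aligned
  window slicing.
- **Modified multiple sleep latency test scoring** (`hypnokit.mmslt`):
  three 20-min lights-off sessions at 10:00/11:00/12:00; latency to the
  first scorable sleep epoch, censored at 20 min; incidence of ≥ 30 s of
  sleep; session sleep duration; pooled cohort summaries (mean ± SEM).
- **12-h sleep-architecture metrics** (`hypnokit.metrics`): sleep latency
  SL, REM latency, sleep-onset REM periods (SOREMP = REM within 15 min of
  sleep onset, a narcolepsy marker), total sleep time TST, stage
  percentages, continuous active-wake bouts (daytime); WASO = sleep period
  time − TST, sleep efficiency = 100·TST/720, and sleep-cycle count
  (nighttime).
- **Markov stage-transition analysis** (`hypnokit.transitions`): the stage
  shift index (transitions/h, a fragmentation measure) and first-order
  transition matrices over five states (W = AW∪QW, N1, N2, N3, R), with
  row-stochastic probabilities *P(i→j) = n(i→j)/Σₖ n(i→k)* and all-zero
  rows for never-visited source states, compared cell-wise across cohorts
  with Wilcoxon rank-sum tests.
- **Nonparametric statistics** (`hypnokit.stats`): Kruskal–Wallis with
  Dunn's multiple-comparisons follow-up, Fisher's exact test, Wilcoxon
  rank sum (exact enumeration for small samples).
- **DBS charge density** (`hypnokit.stim`):
  charge density (µC/mm²) = (V/R) · PW / A for voltage V, impedance R,
  pulse width PW (µs) and contact area A (mm²).
- **Synthetic cohorts** (`hypnokit.synthetic`): seeded, block-wise Markov
  generators for six condition profiles (healthy / parkinsonian /
  stimulated, day and night) so the whole pipeline is testable without
  animal data.

## Worked example

Generate a parkinsonian daytime cohort and summarise it:

```
$ hypnokit synth --profile parkinsonian_day --n 10 --seed 42 --out demo/park_day
wrote 10 recordings to demo/park_day

$ hypnokit table1 --cohort demo/park_day | head -5
metric          mean    sem     n
SL (min)        6.75    1.78    10
REM latency (min)  149.15  59.15  10   (100.0% of recordings)
# SOREMP/day    1.7     0.45    10
TST (min)       175.8   9.95    10
```

The cohort falls asleep 6.75 min into the morning on average (the healthy
profile takes ~40 min), shows 1.7 sleep-onset REM periods per day, and
accumulates 175.8 min of daytime sleep — the EDS phenotype the daytime
metrics are designed to quantify.

Score the modified MSLT for one of those recordings:

```
$ hypnokit mmslt --hypnogram demo/park_day/parkinsonian_day_000.csv \
      --config demo/park_day/config.yml
session  latency_min  slept  sleep_duration_min  rem_present
1        0.0          True   5.5                 False
2        0.0          True   2.0                 False
3        0.0          True   14.5                True
mean_latency_min  0.0
incidence         1.0
```

This animal-day slept in every lights-off session (incidence 1.0) with
zero latency — severe sleepiness on the MSLT scale.

Charge density for 5.6 V across 1898 Ω at 60 µs on 1.2 mm² of contact:

```
$ hypnokit charge-density --voltage 5.6 --impedance 1898 --pulse-width 60 --area 1.2
0.15
```

i.e. 0.15 µC/mm², well below the 30 µC/cm²-range safety limits usually
cited for chronic stimulation.

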