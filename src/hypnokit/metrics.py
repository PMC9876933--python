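"""Sleep-architecture metrics for 12-h daytime and nighttime recordings.

Implements the standard polysomnographic summary set used for long-term
recordings: sleep latency, REM latency, sleep-onset REM periods (SOREMPs),
total sleep time, stage percentages, continuous active-wake bout durations
(daytime), and WASO, sleep efficiency and sleep-cycle count (nighttime).

Conventions
-----------
* Total sleep time (TST) counts every epoch of N1, N2, N3 or R at 0.5 min.
* Sleep efficiency is TST as a percentage of the 12-h nocturnal period.
* WASO is sleep period time minus TST, with sleep period time measured from
  the first sleep onset to the end of the recording.
* A SOREMP is a sleep-onset event whose episode contains an R epoch starting
  within 15 min of the onset; onsets are separated by at least 10 min of
  continuous wake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import (
    EPOCH_MINUTES,
    NREM,
    SLEEP,
    Bout,
    Hypnogram,
    HypnogramError,
    Stage,
    segment_bouts,
)

FULL_NIGHT_MIN = 720.0
REPORT_STAGES = (Stage.N1, Stage.N2, Stage.N3, Stage.R, Stage.AW, Stage.QW)


@dataclass(frozen=True)
class SleepMetrics:
    """The per-recording metric row for one 12-h recording."""

    kind: str
    sl_min: Optional[float]
    rem_latency_min: Optional[float]
    tst_min: float
    stage_pct: dict[Stage, float]
    soremp_per_day: Optional[int] = None          # daytime only
    continuous_aw_bout_min: Optional[tuple[float, ...]] = None  # daytime only
    waso_min: Optional[float] = None              # nighttime only
    sleep_efficiency_pct: Optional[float] = None  # nighttime only
    sleep_cycle_count: Optional[int] = None       # nighttime only


def total_sleep_time(h: Hypnogram) -> float:
    """Total sleep time (min): 0.5 x the number of N1/N2/N3/R epochs."""
    h.require_artifact_free()
    return EPOCH_MINUTES * sum(1 for s in h.stages if s in SLEEP)


def sleep_efficiency(tst_min: float, nocturnal_min: float = FULL_NIGHT_MIN) -> float:
    """TST as a percentage of the nocturnal period, to 1 decimal."""
    if not 0 <= tst_min <= nocturnal_min:
        raise ValueError(
            f"TST {tst_min} min must lie within [0, {nocturnal_min}] min"
        )
    return round(100.0 * tst_min / nocturnal_min, 1)


def first_sleep_latency(h: Hypnogram) -> Optional[float]:
    """Latency (min) to the first sleep epoch, or None when no sleep occurs.

    The reference time is the recording start for daytime recordings and
    lights-off for nighttime recordings (the study design makes these
    coincide at 19:00 for nights).
    """
    h.require_artifact_free()
    first = next((i for i, s in enumerate(h.stages) if s in SLEEP), None)
    if first is None:
        return None
    onset_min = first * EPOCH_MINUTES
    if h.kind == "nighttime":
        offset = h.minutes_from_start(h.lights_off)
        if offset > h.duration_minutes:  # lights_off not inside recording
            offset = 0.0
        return onset_min - offset
    return onset_min


def rem_latency(h: Hypnogram) -> Optional[float]:
    """Minutes from the first sleep epoch to the first R epoch; None if no R."""
    h.require_artifact_free()
    first_r = next((i for i, s in enumerate(h.stages) if s is Stage.R), None)
    if first_r is None:
        return None
    first_sleep = next(i for i, s in enumerate(h.stages) if s in SLEEP)
    assert first_sleep <= first_r, "R is sleep; first sleep cannot follow first R"
    return (first_r - first_sleep) * EPOCH_MINUTES


def _sleep_episodes(h: Hypnogram, new_onset_gap_min: float) -> list[tuple[int, int]]:
    """Group SLEEP bouts into episodes separated by >= gap of continuous wake.

    Returns (onset_epoch, end_epoch) pairs; end is the epoch one past the
    last sleep epoch of the episode.
    """
    gap_epochs = int(round(new_onset_gap_min / EPOCH_MINUTES))
    bouts = segment_bouts(h, SLEEP)
    episodes: list[tuple[int, int]] = []
    for b in bouts:
        if episodes and b.start_epoch - episodes[-1][1] < gap_epochs:
            episodes[-1] = (episodes[-1][0], b.end_epoch)
        else:
            episodes.append((b.start_epoch, b.end_epoch))
    return episodes


def count_soremp(
    h: Hypnogram,
    window_min: float = 15.0,
    new_onset_gap_min: float = 10.0,
    use_cumulative_sleep: bool = False,
) -> int:
    """Number of sleep-onset REM periods in a daytime recording.

    A sleep-onset event is the start of a sleep episode (episodes are runs of
    sleep separated by at least ``new_onset_gap_min`` of continuous wake). The
    event counts as a SOREMP when an R epoch begins within ``window_min`` of
    the onset and before the episode ends. By default the window is elapsed
    clock time; with ``use_cumulative_sleep`` it is accumulated sleep time.
    """
    h.require_artifact_free()
    count = 0
    for onset, end in _sleep_episodes(h, new_onset_gap_min):
        sleep_accum = 0.0
        for i in range(onset, end):
            s = h.stages[i]
            elapsed = (
                sleep_accum if use_cumulative_sleep else (i - onset) * EPOCH_MINUTES
            )
            if s is Stage.R:
                if elapsed <= window_min:
                    count += 1
                break
            if s in SLEEP:
                sleep_accum += EPOCH_MINUTES
    return count


def stage_percentages(h: Hypnogram) -> dict[Stage, float]:
    """Percent of total scoring time in each of N1, N2, N3, R, AW, QW."""
    h.require_artifact_free()
    n = h.n_epochs
    counts = h.counts()
    return {s: 100.0 * counts[s] / n for s in REPORT_STAGES}


def waso(h: Hypnogram) -> float:
    """Wake after sleep onset (min) = sleep period time - TST.

    Sleep period time runs from the first sleep onset to the end of the
    recording. Undefined (error) when the night contains no sleep.
    """
    h.require_artifact_free()
    sl = first_sleep_latency(h)
    if sl is None:
        raise HypnogramError("WASO is undefined for a recording with no sleep")
    first = next(i for i, s in enumerate(h.stages) if s in SLEEP)
    spt = h.duration_minutes - first * EPOCH_MINUTES
    return spt - total_sleep_time(h)


def continuous_active_wake_bouts(h: Hypnogram) -> list[float]:
    """Durations (min) of maximal active-wake-only runs; QW ends a run."""
    h.require_artifact_free()
    return [b.duration_min for b in segment_bouts(h, {Stage.AW})]


def sleep_cycle_count(
    h: Hypnogram,
    min_nrem_min: float = 10.0,
    rem_end_gap_min: float = 10.0,
) -> int:
    """Count NREM->REM sleep cycles in a nighttime recording.

    A cycle requires at least ``min_nrem_min`` of cumulative non-REM sleep
    followed by at least one R epoch; it closes when the REM period ends and
    either wake lasting ``rem_end_gap_min`` occurs or non-REM accumulation
    for the next cycle begins. The thresholds are a configurable convention:
    no standard primate rule exists.
    """
    h.require_artifact_free()
    min_nrem_epochs = min_nrem_min / EPOCH_MINUTES
    gap_epochs = rem_end_gap_min / EPOCH_MINUTES
    count = 0
    nrem_accum = 0
    awaiting_close = False  # a counted cycle's REM period ended; close it
    wake_run = 0
    for s in h.stages:
        if s is Stage.R:
            wake_run = 0
            if awaiting_close:
                continue  # same cycle's REM continues or resumes
            if nrem_accum >= min_nrem_epochs:
                count += 1
                awaiting_close = True
                nrem_accum = 0
        elif s in NREM:
            wake_run = 0
            if awaiting_close:
                awaiting_close = False  # new accumulation closes the cycle
            nrem_accum += 1
        else:  # wake
            wake_run += 1
            if awaiting_close and wake_run >= gap_epochs:
                awaiting_close = False
    return count


def compute_sleep_metrics(h: Hypnogram) -> SleepMetrics:
    """Full metric row for one 12-h recording, per its daytime/nighttime kind."""
    h.require_artifact_free()
    common = dict(
        kind=h.kind,
        sl_min=first_sleep_latency(h),
        rem_latency_min=rem_latency(h),
        tst_min=total_sleep_time(h),
        stage_pct=stage_percentages(h),
    )
    if h.kind == "daytime":
        return SleepMetrics(
            **common,
            soremp_per_day=count_soremp(h),
            continuous_aw_bout_min=tuple(continuous_active_wake_bouts(h)),
        )
    tst = common["tst_min"]
    has_sleep = common["sl_min"] is not None
    return SleepMetrics(
        **common,
        waso_min=waso(h) if has_sleep else None,
        sleep_efficiency_pct=sleep_efficiency(tst, h.duration_minutes),
        sleep_cycle_count=sleep_cycle_count(h),
    )


def _mean_sem(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def cohort_table(rows: Sequence[SleepMetrics]) -> pd.DataFrame:
    """Aggregate per-recording metrics to a mean +/- SEM summary table.

    One row per metric: for REM latency the mean is taken over recordings
    containing REM and the percentage of such recordings is reported
    alongside, mirroring the usual presentation.
    """
    if not rows:
        raise ValueError("cohort_table requires at least one recording")
    kind = rows[0].kind
    if any(r.kind != kind for r in rows):
        raise ValueError("cohort mixes daytime and nighttime recordings")
    out: list[dict] = []

    def add(metric: str, values: Sequence[float], n: int, pct_present=None):
        mean, sem = _mean_sem(values) if values else (float("nan"), float("nan"))
        row = {"metric": metric, "mean": mean, "sem": sem, "n": n}
        if pct_present is not None:
            row["pct_recordings_present"] = pct_present
        out.append(row)

    sls = [r.sl_min for r in rows if r.sl_min is not None]
    add("SL (min)", sls, len(sls))
    rems = [r.rem_latency_min for r in rows if r.rem_latency_min is not None]
    add("REM latency (min)", rems, len(rems),
        pct_present=100.0 * len(rems) / len(rows))
    if kind == "daytime":
        add("# SOREMP/day", [r.soremp_per_day for r in rows], len(rows))
    add("TST (min)", [r.tst_min for r in rows], len(rows))
    for s in (Stage.N1, Stage.N2, Stage.N3, Stage.R, Stage.AW, Stage.QW):
        label = {"N1": "% Stage 1", "N2": "% Stage 2", "N3": "% Stage 3",
                 "R": "% REM sleep", "AW": "% AW", "QW": "% QW"}[s.value]
        add(label, [r.stage_pct[s] for r in rows], len(rows))
    if kind == "daytime":
        bouts = [d for r in rows for d in (r.continuous_aw_bout_min or ())]
        add("Continuous AW bout (min)", bouts, len(bouts))
    else:
        wasos = [r.waso_min for r in rows if r.waso_min is not None]
        add("WASO (min)", wasos, len(wasos))
        add("Sleep efficiency (%)",
            [r.sleep_efficiency_pct for r in rows], len(rows))
        add("Sleep cycle number", [r.sleep_cycle_count for r in rows], len(rows))
    return pd.DataFrame(out)
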