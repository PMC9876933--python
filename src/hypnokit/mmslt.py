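"""Scoring for the modified multiple sleep latency test (mMSLT).

The test gives three 20-min lights-off nap opportunities at 10:00, 11:00 and
12:00 within a daytime recording. Sleep latency within a session is the onset
time of the first scorable sleep epoch (any of N1, N2, N3, R); when no sleep
occurs the latency is censored at the full 20 min. Active and quiet wake are
pooled. A single 30-s sleep epoch counts both for latency and for incidence.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .core import EPOCH_MINUTES, SLEEP, Hypnogram, HypnogramError, Stage, slice_window

SESSION_MINUTES = 20.0
SESSION_EPOCHS = 40
DEFAULT_SESSION_STARTS = ("10:00", "11:00", "12:00")


@dataclass(frozen=True)
class MsltSession:
    """Scored 20-min lights-off session."""

    session_index: int
    latency_min: float
    slept: bool
    sleep_duration_min: float
    rem_present: bool
    rem_latency_from_first_sleep_min: Optional[float]


@dataclass(frozen=True)
class MsltResult:
    """One test day: three sessions plus day-level aggregates."""

    sessions: tuple[MsltSession, ...]
    mean_latency_min: float
    incidence: float


def score_session(window: Hypnogram, session_index: int = 1) -> MsltSession:
    """Score one 20-min lights-off window.

    Latency is the onset time (minutes from window start) of the first epoch
    in SLEEP, or 20 min when the window is sleep-free. Sleep duration counts
    every SLEEP epoch at 0.5 min. REM latency, when REM is present, is the
    elapsed time from the first sleep epoch to the first R epoch.
    """
    window.require_artifact_free()
    if window.n_epochs != SESSION_EPOCHS:
        raise HypnogramError(
            f"mMSLT session must be exactly {SESSION_EPOCHS} epochs (20 min), "
            f"got {window.n_epochs}"
        )
    first_sleep = next(
        (i for i, s in enumerate(window.stages) if s in SLEEP), None
    )
    slept = first_sleep is not None
    latency = first_sleep * EPOCH_MINUTES if slept else SESSION_MINUTES
    duration = EPOCH_MINUTES * sum(1 for s in window.stages if s in SLEEP)
    first_rem = next((i for i, s in enumerate(window.stages) if s is Stage.R), None)
    rem_latency = (
        (first_rem - first_sleep) * EPOCH_MINUTES if first_rem is not None else None
    )
    return MsltSession(
        session_index=session_index,
        latency_min=latency,
        slept=slept,
        sleep_duration_min=duration,
        rem_present=first_rem is not None,
        rem_latency_from_first_sleep_min=rem_latency,
    )


def score_mmslt_day(
    h: Hypnogram,
    session_starts: Sequence[Union[str, _dt.time]] = DEFAULT_SESSION_STARTS,
) -> MsltResult:
    """Score a full test day: one session per lights-off start time."""
    h.require_artifact_free()
    sessions = []
    for k, start in enumerate(session_starts, start=1):
        start_min = h.minutes_from_start(start)
        end = h.clock_at(start_min + SESSION_MINUTES)
        window = slice_window(h, start, end)
        sessions.append(score_session(window, session_index=k))
    mean_latency = sum(s.latency_min for s in sessions) / len(sessions)
    incidence = sum(s.slept for s in sessions) / len(sessions)
    return MsltResult(tuple(sessions), mean_latency, incidence)


def _sem(values: Sequence[float]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var / n)


def pooled_mmslt_summary(days: Sequence[MsltResult]) -> dict:
    """Cohort summary pooling every lights-off session across test days.

    Returns per-session-slot and pooled mean +/- SEM latency, pooled
    incidence (%), and mean +/- SEM sleep duration. SEM denominators use the
    number of pooled sessions.
    """
    if not days:
        raise ValueError("pooled_mmslt_summary requires at least one test day")
    all_sessions = [s for d in days for s in d.sessions]
    latencies = [s.latency_min for s in all_sessions]
    durations = [s.sleep_duration_min for s in all_sessions]
    n_slots = len(days[0].sessions)
    per_session = {}
    for k in range(1, n_slots + 1):
        vals = [s.latency_min for d in days for s in d.sessions if s.session_index == k]
        per_session[k] = {
            "mean_latency_min": sum(vals) / len(vals),
            "sem_latency_min": _sem(vals),
            "n": len(vals),
        }
    return {
        "n_days": len(days),
        "n_sessions": len(all_sessions),
        "per_session": per_session,
        "pooled_mean_latency_min": sum(latencies) / len(latencies),
        "pooled_sem_latency_min": _sem(latencies),
        "incidence_pct": 100.0 * sum(s.slept for s in all_sessions) / len(all_sessions),
        "mean_sleep_duration_min": sum(durations) / len(durations),
        "sem_sleep_duration_min": _sem(durations),
    }
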