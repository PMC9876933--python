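"""Data model, I/O and epoch-level primitives for stage-labelled hypnograms.

A hypnogram is an ordered sequence of sleep/wake stage labels, one per 30-s
epoch, anchored to a recording start clock time and a light schedule. Seven
labels are admitted: active wake (AW), quiet wake (QW), the three non-REM
stages (N1, N2, N3), REM sleep (R) and artifact (X). Epoch-containing
artifacts are conventionally recoded to active wake before any analysis.

Epoch ``i`` spans the half-open interval ``[start + 30 i s, start + 30 (i+1) s)``.
All analysis windows must align to epoch boundaries; misalignment is an
error, never a silent truncation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

EPOCH_SECONDS = 30
EPOCH_MINUTES = 0.5


class Stage(str, Enum):
    """Epoch stage label (AASM-style scoring adapted to nonhuman primates)."""

    AW = "AW"  # active wake
    QW = "QW"  # quiet wake
    N1 = "N1"  # non-REM stage 1
    N2 = "N2"  # non-REM stage 2
    N3 = "N3"  # non-REM stage 3 (slow-wave)
    R = "R"    # REM sleep
    X = "X"    # artifact

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Pooled wake: active + quiet wake.
WAKE = frozenset({Stage.AW, Stage.QW})
#: Any scorable sleep.
SLEEP = frozenset({Stage.N1, Stage.N2, Stage.N3, Stage.R})
#: Light sleep (N1 + N2), the stages healthy daytime naps are made of.
LIGHT_SLEEP = frozenset({Stage.N1, Stage.N2})
#: Non-REM sleep.
NREM = frozenset({Stage.N1, Stage.N2, Stage.N3})


class HypnogramError(ValueError):
    """Invalid hypnogram data or an operation violating its preconditions."""


def _parse_clock(value: Union[str, _dt.time]) -> _dt.time:
    if isinstance(value, _dt.time):
        return value
    try:
        parts = [int(p) for p in str(value).split(":")]
    except ValueError as exc:
        raise HypnogramError(f"unparsable clock time {value!r}") from exc
    while len(parts) < 3:
        parts.append(0)
    return _dt.time(*parts[:3])


def _clock_seconds(t: _dt.time) -> int:
    return t.hour * 3600 + t.minute * 60 + t.second


@dataclass(frozen=True)
class Hypnogram:
    """Immutable 30-s-epoch hypnogram with clock anchoring and light schedule.

    Parameters
    ----------
    stages
        One :class:`Stage` per epoch, in recording order.
    start_time
        Clock time of epoch 0.
    lights_off, lights_on
        Light schedule (the study design uses a 12-h cycle, lights off at
        19:00).
    kind
        ``"daytime"`` (07:00-19:00) or ``"nighttime"`` (19:00-07:00); decides
        which metric menu applies.
    """

    stages: tuple[Stage, ...]
    start_time: _dt.time
    lights_off: _dt.time = _dt.time(19, 0)
    lights_on: _dt.time = _dt.time(7, 0)
    kind: str = "daytime"

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise HypnogramError("hypnogram must contain at least one epoch")
        if self.kind not in ("daytime", "nighttime"):
            raise HypnogramError(f"unknown recording kind {self.kind!r}")
        object.__setattr__(self, "stages", tuple(Stage(s) for s in self.stages))

    # -- basic geometry -------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_minutes(self) -> float:
        return EPOCH_MINUTES * self.n_epochs

    def epoch_onset_minutes(self, index: int) -> float:
        """Onset time of epoch ``index`` in minutes from recording start."""
        if not 0 <= index < self.n_epochs:
            raise HypnogramError(f"epoch index {index} out of range")
        return index * EPOCH_MINUTES

    def minutes_from_start(self, clock: Union[str, _dt.time]) -> float:
        """Minutes from recording start to ``clock``, wrapping past midnight.

        A nighttime recording starting 19:00 maps 01:30 to 390 minutes.
        """
        t = _parse_clock(clock)
        delta = _clock_seconds(t) - _clock_seconds(self.start_time)
        if delta < 0:
            delta += 24 * 3600
        return delta / 60.0

    def clock_at(self, minutes: float) -> _dt.time:
        total = (_clock_seconds(self.start_time) + round(minutes * 60)) % (24 * 3600)
        return _dt.time(total // 3600, (total % 3600) // 60, total % 60)

    # -- helpers --------------------------------------------------------
    def counts(self) -> dict[Stage, int]:
        c = {s: 0 for s in Stage}
        for s in self.stages:
            c[s] += 1
        return c

    def has_artifacts(self) -> bool:
        return Stage.X in self.stages

    def require_artifact_free(self) -> None:
        if self.has_artifacts():
            raise HypnogramError(
                "hypnogram contains artifact (X) epochs; run recode_artifacts first"
            )


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive epochs whose stages lie in a stage set."""

    stage_set: frozenset[Stage]
    start_epoch: int
    n_epochs: int

    @property
    def duration_min(self) -> float:
        return EPOCH_MINUTES * self.n_epochs

    @property
    def end_epoch(self) -> int:
        """One past the last epoch (half-open)."""
        return self.start_epoch + self.n_epochs


@dataclass(frozen=True)
class RecordingConfig:
    """Sidecar metadata for a hypnogram data file."""

    start_time: _dt.time
    lights_off: _dt.time = _dt.time(19, 0)
    lights_on: _dt.time = _dt.time(7, 0)
    epoch_length_s: int = 30
    recording_kind: str = "daytime"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RecordingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RecordingConfig":
        if "start_time" not in raw:
            raise HypnogramError("config missing required key 'start_time'")
        epoch_length = int(raw.get("epoch_length_s", 30))
        if epoch_length != EPOCH_SECONDS:
            raise HypnogramError(
                f"unsupported epoch length {epoch_length} s; only 30 s epochs are supported"
            )
        return cls(
            start_time=_parse_clock(raw["start_time"]),
            lights_off=_parse_clock(raw.get("lights_off", "19:00")),
            lights_on=_parse_clock(raw.get("lights_on", "07:00")),
            epoch_length_s=epoch_length,
            recording_kind=str(raw.get("recording_kind", "daytime")),
        )


def parse_hypnogram(path: Union[str, Path], config: RecordingConfig) -> Hypnogram:
    """Read a delimited-text hypnogram (one epoch per line).

    Accepted line formats: a bare stage token, or ``epoch_index,stage``.
    A single header line ``epoch,stage`` (any case) is skipped. Epoch
    indices, when present, must be consecutive from 0.
    """
    stages: list[Stage] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if lineno == 1 and fields[-1].lower() in ("stage", "label"):
                continue
            token = fields[-1]
            if len(fields) == 2:
                try:
                    idx = int(fields[0])
                except ValueError as exc:
                    raise HypnogramError(
                        f"{path}: line {lineno}: bad epoch index {fields[0]!r}"
                    ) from exc
                if idx != len(stages):
                    raise HypnogramError(
                        f"{path}: line {lineno}: non-consecutive epoch index {idx}"
                    )
            elif len(fields) != 1:
                raise HypnogramError(f"{path}: line {lineno}: too many fields")
            try:
                stages.append(Stage(token))
            except ValueError as exc:
                raise HypnogramError(
                    f"{path}: line {lineno}: unknown stage token {token!r}"
                ) from exc
    if not stages:
        raise HypnogramError(f"{path}: empty hypnogram file")
    return Hypnogram(
        stages=tuple(stages),
        start_time=config.start_time,
        lights_off=config.lights_off,
        lights_on=config.lights_on,
        kind=config.recording_kind,
    )


def write_hypnogram(h: Hypnogram, path: Union[str, Path]) -> None:
    """Write ``epoch,stage`` lines with a header; round-trips bit-identically."""
    with open(path, "w") as fh:
        fh.write("epoch,stage\n")
        for i, s in enumerate(h.stages):
            fh.write(f"{i},{s.value}\n")


def recode_artifacts(h: Hypnogram) -> Hypnogram:
    """Relabel every artifact (X) epoch as active wake; idempotent."""
    if not h.has_artifacts():
        return h
    stages = tuple(Stage.AW if s is Stage.X else s for s in h.stages)
    return replace(h, stages=stages)


def segment_bouts(h: Hypnogram, stage_set: Iterable[Stage]) -> list[Bout]:
    """Maximal runs of epochs whose stage is in ``stage_set``, in order.

    The returned bouts are non-overlapping and exactly cover the epochs
    whose stage belongs to the set.
    """
    sset = frozenset(Stage(s) for s in stage_set)
    if not sset:
        raise HypnogramError("stage_set must be non-empty")
    bouts: list[Bout] = []
    run_start = None
    for i, s in enumerate(h.stages):
        inside = s in sset
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            bouts.append(Bout(sset, run_start, i - run_start))
            run_start = None
    if run_start is not None:
        bouts.append(Bout(sset, run_start, h.n_epochs - run_start))
    return bouts


def slice_window(
    h: Hypnogram,
    start: Union[str, _dt.time],
    end: Union[str, _dt.time],
) -> Hypnogram:
    """Slice the epochs whose onset time t satisfies ``start <= t < end``.

    Both boundaries must align to 30-s epoch boundaries and lie within the
    recording. The slice keeps the parent light schedule and kind, with
    ``start_time`` updated to the window start.
    """
    start_min = h.minutes_from_start(start)
    end_min = h.minutes_from_start(end)
    if end_min <= start_min:
        raise HypnogramError("window end must be after window start")
    for name, m in (("start", start_min), ("end", end_min)):
        if (m * 60) % EPOCH_SECONDS != 0:
            raise HypnogramError(f"window {name} does not align to a 30-s epoch boundary")
    i0 = int(round(start_min / EPOCH_MINUTES))
    i1 = int(round(end_min / EPOCH_MINUTES))
    if i0 < 0 or i1 > h.n_epochs:
        raise HypnogramError(
            f"window [{start_min}, {end_min}) min lies outside the recording "
            f"({h.duration_minutes} min)"
        )
    return replace(
        h,
        stages=h.stages[i0:i1],
        start_time=h.clock_at(start_min),
    )
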