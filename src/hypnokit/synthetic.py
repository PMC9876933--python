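"""Synthetic hypnogram cohorts with the architecture the analysis assumes.

Recordings are sampled from time-inhomogeneous first-order Markov chains
over the 7 stage labels: a 12-h recording is divided into six 2-h blocks,
each with its own 7x7 transition matrix, which is the simplest structure
that can place long morning naps, scattered parkinsonian naps, and
consolidated stimulated wake at the right times of day.

Six named condition profiles are provided:

``healthy_day``
    Long consolidated wake; roughly two long morning naps and one or two
    short afternoon naps of light (N1/N2) sleep; no daytime REM.
``parkinsonian_day``
    Fragmented wake with naps scattered through the day, a short morning
    sleep latency, raised quiet-wake share, and direct nap REM entries
    producing sleep-onset REM periods.
``parkinsonian_lfs_day``
    Consolidated active wake under low-frequency stimulation: long
    continuous active-wake runs, long sleep latency, brief light naps and
    no REM.
``healthy_night``
    Consolidated night sleep (~75% of the night) with NREM depth and
    regular REM episodes.
``parkinsonian_night``
    Fragmented night: roughly doubled wake, shallow NREM, reduced N3/REM.
``parkinsonian_postlfs_night``
    Night following a stimulated day: intermediate consolidation.

The per-block matrix entries were chosen from dwell-time/hazard arithmetic
(mean bout length 0.5/(1 - self-probability) min) to land in realistic
ranges for macaque polysomnography and are fixed; they are the study
conditions, not tuning knobs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import EPOCH_MINUTES, Hypnogram, HypnogramError, Stage

#: Canonical state order of profile matrices.
STAGE_ORDER = (Stage.AW, Stage.QW, Stage.N1, Stage.N2, Stage.N3, Stage.R, Stage.X)
_IDX = {s: i for i, s in enumerate(STAGE_ORDER)}

BLOCK_MINUTES = 120.0
RECORDING_EPOCHS = 1440  # 12 h of 30-s epochs

PROFILE_NAMES = (
    "healthy_day",
    "parkinsonian_day",
    "parkinsonian_lfs_day",
    "healthy_night",
    "parkinsonian_night",
    "parkinsonian_postlfs_night",
)


def _rows(spec: Mapping[Stage, Mapping[Stage, float]]) -> np.ndarray:
    """Build a 7x7 row-stochastic matrix from sparse row dictionaries.

    Unlisted destination entries are zero. States without a row (never
    reachable under the profile) get a deterministic exit to quiet wake,
    except X which exits to active wake (artifact recoding convention).
    """
    m = np.zeros((7, 7))
    for src, dests in spec.items():
        for dst, p in dests.items():
            m[_IDX[src], _IDX[dst]] = p
    for i, s in enumerate(STAGE_ORDER):
        if m[i].sum() == 0.0:
            m[i, _IDX[Stage.AW if s is Stage.X else Stage.QW]] = 1.0
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        bad = [STAGE_ORDER[i].value for i in np.flatnonzero(
            ~np.isclose(m.sum(axis=1), 1.0, atol=1e-9))]
        raise HypnogramError(f"transition rows do not sum to 1 for: {bad}")
    return m


@dataclass(frozen=True)
class ConditionProfile:
    """Generative parameters for one experimental condition.

    ``blocks`` is an ordered tuple of (start offset in minutes, 7x7
    transition matrix); blocks must start at 0 and tile the recording.
    """

    name: str
    kind: str  # daytime | nighttime
    start_time: _dt.time
    blocks: tuple[tuple[float, np.ndarray], ...]
    initial: np.ndarray  # distribution over STAGE_ORDER at epoch 0

    def __post_init__(self) -> None:
        if not self.blocks or self.blocks[0][0] != 0.0:
            raise HypnogramError("blocks must start at offset 0")
        offsets = [b[0] for b in self.blocks]
        if offsets != sorted(offsets):
            raise HypnogramError("block offsets must be increasing")
        for _, m in self.blocks:
            if m.shape != (7, 7) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise HypnogramError("every block matrix row must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise HypnogramError("initial distribution must sum to 1")

    def block_index(self, epoch: int) -> int:
        minutes = epoch * EPOCH_MINUTES
        idx = 0
        for k, (off, _) in enumerate(self.blocks):
            if minutes >= off:
                idx = k
        return idx

    def matrix_at(self, epoch: int) -> np.ndarray:
        return self.blocks[self.block_index(epoch)][1]


def _start_in(stage: Stage) -> np.ndarray:
    v = np.zeros(7)
    v[_IDX[stage]] = 1.0
    return v


# ---------------------------------------------------------------------------
# Default condition profiles. Mean dwell time of a stage with self-probability
# p is 0.5/(1-p) min; wake-to-sleep entries set nap pressure and sleep latency.
# ---------------------------------------------------------------------------

def _healthy_day_blocks() -> tuple[tuple[float, np.ndarray], ...]:
    # healthy wake is dominated by active wake; quiet wake is brief
    morning = _rows({
        Stage.AW: {Stage.AW: 0.972, Stage.QW: 0.020, Stage.N1: 0.008},
        Stage.QW: {Stage.QW: 0.72, Stage.AW: 0.25, Stage.N1: 0.03},
        Stage.N1: {Stage.N1: 0.85, Stage.N2: 0.12, Stage.QW: 0.03},
        Stage.N2: {Stage.N2: 0.92, Stage.N1: 0.04, Stage.QW: 0.04},
    })
    midday = _rows({
        Stage.AW: {Stage.AW: 0.978, Stage.QW: 0.020, Stage.N1: 0.002},
        Stage.QW: {Stage.QW: 0.74, Stage.AW: 0.25, Stage.N1: 0.01},
        Stage.N1: {Stage.N1: 0.80, Stage.N2: 0.05, Stage.QW: 0.15},
        Stage.N2: {Stage.N2: 0.85, Stage.N1: 0.05, Stage.QW: 0.10},
    })
    afternoon = _rows({
        Stage.AW: {Stage.AW: 0.976, Stage.QW: 0.020, Stage.N1: 0.004},
        Stage.QW: {Stage.QW: 0.73, Stage.AW: 0.25, Stage.N1: 0.02},
        Stage.N1: {Stage.N1: 0.80, Stage.N2: 0.05, Stage.QW: 0.15},
        Stage.N2: {Stage.N2: 0.85, Stage.N1: 0.05, Stage.QW: 0.10},
    })
    return (
        (0.0, morning), (120.0, morning),
        (240.0, midday), (360.0, midday),
        (480.0, afternoon), (600.0, afternoon),
    )


def _parkinsonian_day_blocks() -> tuple[tuple[float, np.ndarray], ...]:
    def block(aw_to_n1: float, qw_to_n1: float) -> np.ndarray:
        return _rows({
            Stage.AW: {Stage.AW: 0.88 - (aw_to_n1 - 0.02), Stage.QW: 0.10,
                       Stage.N1: aw_to_n1},
            Stage.QW: {Stage.QW: 0.83 - (qw_to_n1 - 0.05), Stage.AW: 0.12,
                       Stage.N1: qw_to_n1},
            Stage.N1: {Stage.N1: 0.81, Stage.N2: 0.06, Stage.QW: 0.10,
                       Stage.AW: 0.02, Stage.R: 0.01},
            Stage.N2: {Stage.N2: 0.83, Stage.N1: 0.05, Stage.QW: 0.08,
                       Stage.N3: 0.02, Stage.R: 0.02},
            Stage.N3: {Stage.N3: 0.82, Stage.N2: 0.12, Stage.QW: 0.06},
            Stage.R: {Stage.R: 0.85, Stage.QW: 0.08, Stage.N1: 0.05,
                      Stage.AW: 0.02},
        })
    # first morning block carries the raised early-morning sleep pressure
    return (
        (0.0, block(0.04, 0.08)),
        (120.0, block(0.02, 0.05)),
        (240.0, block(0.02, 0.05)),
        (360.0, block(0.02, 0.05)),
        (480.0, block(0.02, 0.05)),
        (600.0, block(0.02, 0.05)),
    )


def _lfs_day_blocks() -> tuple[tuple[float, np.ndarray], ...]:
    m = _rows({
        Stage.AW: {Stage.AW: 0.965, Stage.QW: 0.030, Stage.N1: 0.005},
        Stage.QW: {Stage.QW: 0.82, Stage.AW: 0.16, Stage.N1: 0.02},
        Stage.N1: {Stage.N1: 0.82, Stage.QW: 0.10, Stage.AW: 0.02,
                   Stage.N2: 0.06},
        Stage.N2: {Stage.N2: 0.84, Stage.N1: 0.06, Stage.QW: 0.10},
    })
    return tuple((off, m) for off in (0.0, 120.0, 240.0, 360.0, 480.0, 600.0))


def _healthy_night_blocks() -> tuple[tuple[float, np.ndarray], ...]:
    # settling block: slower sleep entry right after lights off
    settling = _rows({
        Stage.AW: {Stage.AW: 0.92, Stage.QW: 0.05, Stage.N1: 0.03},
        Stage.QW: {Stage.QW: 0.85, Stage.AW: 0.05, Stage.N1: 0.10},
        Stage.N1: {Stage.N1: 0.76, Stage.N2: 0.16, Stage.QW: 0.05,
                   Stage.AW: 0.03},
        Stage.N2: {Stage.N2: 0.86, Stage.N3: 0.07, Stage.N1: 0.03,
                   Stage.R: 0.02, Stage.QW: 0.02},
        Stage.N3: {Stage.N3: 0.88, Stage.N2: 0.08, Stage.R: 0.03,
                   Stage.N1: 0.01},
        Stage.R: {Stage.R: 0.87, Stage.N1: 0.05, Stage.QW: 0.05,
                  Stage.AW: 0.03},
    })
    m = _rows({
        Stage.AW: {Stage.AW: 0.82, Stage.QW: 0.14, Stage.N1: 0.04},
        Stage.QW: {Stage.QW: 0.76, Stage.N1: 0.16, Stage.AW: 0.08},
        Stage.N1: {Stage.N1: 0.76, Stage.N2: 0.16, Stage.QW: 0.05,
                   Stage.AW: 0.03},
        Stage.N2: {Stage.N2: 0.87, Stage.N3: 0.07, Stage.N1: 0.03,
                   Stage.R: 0.02, Stage.QW: 0.01},
        Stage.N3: {Stage.N3: 0.88, Stage.N2: 0.08, Stage.R: 0.03,
                   Stage.N1: 0.01},
        Stage.R: {Stage.R: 0.88, Stage.N1: 0.05, Stage.QW: 0.05,
                  Stage.AW: 0.02},
    })
    return ((0.0, settling),) + tuple(
        (off, m) for off in (120.0, 240.0, 360.0, 480.0, 600.0))


def _parkinsonian_night_blocks() -> tuple[tuple[float, np.ndarray], ...]:
    m = _rows({
        Stage.AW: {Stage.AW: 0.86, Stage.QW: 0.11, Stage.N1: 0.03},
        Stage.QW: {Stage.QW: 0.78, Stage.AW: 0.14, Stage.N1: 0.08},
        Stage.N1: {Stage.N1: 0.80, Stage.N2: 0.08, Stage.QW: 0.08,
                   Stage.AW: 0.02, Stage.R: 0.02},
        Stage.N2: {Stage.N2: 0.84, Stage.N1: 0.08, Stage.QW: 0.06,
                   Stage.N3: 0.01, Stage.R: 0.01},
        Stage.N3: {Stage.N3: 0.80, Stage.N2: 0.12, Stage.QW: 0.08},
        Stage.R: {Stage.R: 0.82, Stage.QW: 0.10, Stage.N1: 0.06,
                  Stage.AW: 0.02},
    })
    return tuple((off, m) for off in (0.0, 120.0, 240.0, 360.0, 480.0, 600.0))


def _postlfs_night_blocks() -> tuple[tuple[float, np.ndarray], ...]:
    m = _rows({
        Stage.AW: {Stage.AW: 0.85, Stage.QW: 0.11, Stage.N1: 0.04},
        Stage.QW: {Stage.QW: 0.78, Stage.AW: 0.12, Stage.N1: 0.10},
        Stage.N1: {Stage.N1: 0.80, Stage.N2: 0.10, Stage.QW: 0.07,
                   Stage.AW: 0.01, Stage.R: 0.02},
        Stage.N2: {Stage.N2: 0.85, Stage.N1: 0.07, Stage.QW: 0.05,
                   Stage.N3: 0.015, Stage.R: 0.015},
        Stage.N3: {Stage.N3: 0.82, Stage.N2: 0.11, Stage.QW: 0.07},
        Stage.R: {Stage.R: 0.84, Stage.QW: 0.09, Stage.N1: 0.06,
                  Stage.AW: 0.01},
    })
    return tuple((off, m) for off in (0.0, 120.0, 240.0, 360.0, 480.0, 600.0))


def default_profile(name: str) -> ConditionProfile:
    """Return one of the six named default condition profiles."""
    builders = {
        "healthy_day": (_healthy_day_blocks, "daytime", _dt.time(7, 0)),
        "parkinsonian_day": (_parkinsonian_day_blocks, "daytime", _dt.time(7, 0)),
        "parkinsonian_lfs_day": (_lfs_day_blocks, "daytime", _dt.time(7, 0)),
        "healthy_night": (_healthy_night_blocks, "nighttime", _dt.time(19, 0)),
        "parkinsonian_night": (_parkinsonian_night_blocks, "nighttime",
                               _dt.time(19, 0)),
        "parkinsonian_postlfs_night": (_postlfs_night_blocks, "nighttime",
                                       _dt.time(19, 0)),
    }
    if name not in builders:
        raise ValueError(f"unknown profile {name!r}; choose from {PROFILE_NAMES}")
    build, kind, start = builders[name]
    return ConditionProfile(
        name=name,
        kind=kind,
        start_time=start,
        blocks=build(),
        initial=_start_in(Stage.AW),
    )


def generate_hypnogram(
    profile: ConditionProfile,
    n_epochs: int = RECORDING_EPOCHS,
    seed: int = 0,
) -> Hypnogram:
    """Sample one recording from a condition profile.

    Sampling is first-order Markov within each time block, driven by
    numpy's PCG64 generator, so output is bit-reproducible for a given
    (profile, seed) on any platform.
    """
    if n_epochs < 1:
        raise HypnogramError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    # precompute cumulative rows per block for inverse-CDF sampling
    cum_blocks = [np.cumsum(m, axis=1) for _, m in profile.blocks]
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=np.intp)
    states[0] = int(np.searchsorted(np.cumsum(profile.initial), u[0], side="right"))
    for t in range(1, n_epochs):
        cum = cum_blocks[profile.block_index(t - 1)]
        states[t] = int(np.searchsorted(cum[states[t - 1]], u[t], side="right"))
    stages = tuple(STAGE_ORDER[i] for i in states)
    return Hypnogram(
        stages=stages,
        start_time=profile.start_time,
        lights_off=_dt.time(19, 0),
        lights_on=_dt.time(7, 0),
        kind=profile.kind,
    )


def generate_cohort(
    profile: ConditionProfile,
    n_recordings: int,
    base_seed: int = 0,
    n_epochs: int = RECORDING_EPOCHS,
) -> list[Hypnogram]:
    """Independent recordings with seeds ``base_seed + i`` for i in 0..n-1."""
    if n_recordings < 1:
        raise HypnogramError("n_recordings must be >= 1")
    return [
        generate_hypnogram(profile, n_epochs=n_epochs, seed=base_seed + i)
        for i in range(n_recordings)
    ]


def estimate_profile(
    cohort: Sequence[Hypnogram],
    block_offsets_min: Sequence[float],
) -> list[dict]:
    """Pooled per-block transition estimates from a cohort.

    For each time block, adjacent-epoch transition counts (the pair (t, t+1)
    belongs to the block containing epoch t) are pooled over the cohort and
    row-normalised. Returns one dict per block with ``counts`` and ``probs``
    7x7 arrays in :data:`STAGE_ORDER`; rows never observed as a source stay
    all-zero.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    offsets = sorted(block_offsets_min)
    if not offsets or offsets[0] != 0.0:
        raise ValueError("block offsets must start at 0")
    counts = [np.zeros((7, 7), dtype=np.int64) for _ in offsets]

    def block_of(epoch: int) -> int:
        minutes = epoch * EPOCH_MINUTES
        k = 0
        for i, off in enumerate(offsets):
            if minutes >= off:
                k = i
        return k

    for h in cohort:
        idx = np.array([_IDX[s] for s in h.stages], dtype=np.intp)
        blocks = np.array([block_of(t) for t in range(len(idx) - 1)])
        for k in range(len(offsets)):
            mask = blocks == k
            np.add.at(counts[k], (idx[:-1][mask], idx[1:][mask]), 1)
    out = []
    for c in counts:
        sums = c.sum(axis=1)
        p = np.zeros((7, 7))
        visited = sums > 0
        p[visited] = c[visited] / sums[visited, None]
        out.append({"counts": c, "probs": p})
    return out
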