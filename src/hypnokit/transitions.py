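"""Stage-shift index and first-order Markov transition analysis.

Transitions between wake/sleep stages are modelled as a first-order Markov
chain over five states (W, N1, N2, N3, R), with active and quiet wake pooled
into W. The transition probability matrix is estimated per recording by
row-normalising adjacent-epoch pair counts; a row is all zeros when its
source state never occurs as a transition source, and sums to exactly 1
otherwise. Condition contrasts compare per-recording cell probabilities with
a two-sided Wilcoxon rank-sum test, treating recordings as the sample.

The stage-shift index (transitions per hour) is an overall fragmentation
measure; by default it counts shifts in the full 7-label scheme (so an
AW<->QW change counts), with a pooled 5-state variant available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import EPOCH_MINUTES, Hypnogram, HypnogramError, Stage
from .stats import wilcoxon_rank_sum

FIVE_STATES = ("W", "N1", "N2", "N3", "R")
_STATE_INDEX = {s: i for i, s in enumerate(FIVE_STATES)}
_POOL = {
    Stage.AW: "W",
    Stage.QW: "W",
    Stage.N1: "N1",
    Stage.N2: "N2",
    Stage.N3: "N3",
    Stage.R: "R",
}


@dataclass(frozen=True)
class TransitionMatrix:
    """5x5 transition counts and row-stochastic probabilities.

    ``probs`` row i sums to 1 when state i ever occurs as a transition
    source, and is all zeros otherwise.
    """

    counts: np.ndarray
    probs: np.ndarray
    states: tuple[str, ...] = FIVE_STATES

    def cell(self, src: str, dst: str) -> float:
        return float(self.probs[_STATE_INDEX[src], _STATE_INDEX[dst]])

    def row_visited(self, src: str) -> bool:
        return bool(self.counts[_STATE_INDEX[src]].sum() > 0)


def map_to_five_states(h: Hypnogram) -> list[str]:
    """Pool AW/QW into W; N1, N2, N3 and R map to themselves."""
    h.require_artifact_free()
    return [_POOL[s] for s in h.stages]


def stage_shift_index(h: Hypnogram, pooled: bool = False) -> float:
    """Stage shifts per hour: adjacent epoch pairs with differing stage.

    With ``pooled=False`` (default) shifts are counted in the 7-label scheme,
    so AW<->QW counts as a shift; ``pooled=True`` counts in the 5-state
    scheme used for the transition matrices.
    """
    h.require_artifact_free()
    if h.n_epochs < 2:
        raise HypnogramError("stage shift index requires at least 2 epochs")
    seq: Sequence = map_to_five_states(h) if pooled else h.stages
    shifts = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    return shifts / (h.duration_minutes / 60.0)


def transition_matrix(seq: Sequence[str]) -> TransitionMatrix:
    """Estimate the 5-state transition matrix from one stage sequence.

    Counts include self-transitions. Probabilities are row-normalised
    counts; a never-visited source row stays all zero.
    """
    if len(seq) < 2:
        raise HypnogramError("transition matrix requires at least 2 epochs")
    idx = np.array([_STATE_INDEX[s] for s in seq], dtype=np.intp)
    counts = np.zeros((5, 5), dtype=np.int64)
    np.add.at(counts, (idx[:-1], idx[1:]), 1)
    row_sums = counts.sum(axis=1)
    probs = np.zeros((5, 5), dtype=float)
    visited = row_sums > 0
    probs[visited] = counts[visited] / row_sums[visited, None]
    return TransitionMatrix(counts=counts, probs=probs)


def hypnogram_transition_matrix(h: Hypnogram) -> TransitionMatrix:
    """Convenience: pool to five states, then estimate the matrix."""
    return transition_matrix(map_to_five_states(h))


def compare_transition_matrices(
    cohort_a: Sequence[TransitionMatrix],
    cohort_b: Sequence[TransitionMatrix],
    adjust: Optional[str] = None,
) -> np.ndarray:
    """Per-cell two-sided Wilcoxon rank-sum p-values between two cohorts.

    Each recording contributes one probability per (source, destination)
    cell. Cells whose source row is all-zero in every recording of either
    cohort carry no information and are reported as NaN. ``adjust="bh"``
    applies a Benjamini-Hochberg correction over the tested cells; the
    default reports raw p-values.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("each cohort needs at least 2 recordings")
    pvals = np.full((5, 5), np.nan)
    tested: list[tuple[int, int]] = []
    for i, src in enumerate(FIVE_STATES):
        a_visited = any(m.row_visited(src) for m in cohort_a)
        b_visited = any(m.row_visited(src) for m in cohort_b)
        if not (a_visited and b_visited):
            continue
        for j in range(5):
            a = [float(m.probs[i, j]) for m in cohort_a]
            b = [float(m.probs[i, j]) for m in cohort_b]
            pvals[i, j] = wilcoxon_rank_sum(a, b)
            tested.append((i, j))
    if adjust == "bh" and tested:
        from statsmodels.stats.multitest import multipletests

        raw = np.array([pvals[i, j] for i, j in tested])
        adj = multipletests(raw, method="fdr_bh")[1]
        for (i, j), p in zip(tested, adj):
            pvals[i, j] = p
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return pvals
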