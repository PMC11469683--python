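"""Per-subject state-sequence dynamics: transitions, occupancy, probabilities.

A state sequence assigns every analysed frame to one connectivity state
(ids 1..k).  Its dynamics are summarised by the total number of
between-state switches, the fractional occupancy of each state, and the
directional k x k relative transition-probability matrix whose row i gives
the probability that a frame in state i is followed by each state j
(the diagonal is persistence).  Rows of states never visited among frames
1..T-1 are missing (NaN), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "StateSequence",
    "DynamicsSummary",
    "total_transitions",
    "fractional_occupancy",
    "transition_probabilities",
    "transition_counts",
    "summarize_dynamics",
]


@dataclass
class StateSequence:
    """Frame-wise state labels (1..k) for one subject."""

    subject_id: str
    labels: np.ndarray
    k: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise InvalidParameterError("labels must be a 1-D sequence")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise InvalidParameterError("state labels must lie in 1..k")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class DynamicsSummary:
    subject_id: str
    total_transitions: int
    fractional_occupancy: np.ndarray
    transition_probability: np.ndarray  # k x k, NaN rows for unvisited states


def _labels(seq: StateSequence, min_len: int) -> np.ndarray:
    if len(seq) < min_len:
        raise InvalidParameterError(f"sequence must contain >= {min_len} frames")
    return seq.labels


def total_transitions(seq: StateSequence) -> int:
    """Number of frame pairs where the state changes, s(t) != s(t+1)."""
    labels = _labels(seq, 2)
    return int(np.count_nonzero(labels[1:] != labels[:-1]))


def fractional_occupancy(seq: StateSequence) -> np.ndarray:
    """Fraction of frames spent in each state; length k, sums to 1."""
    labels = _labels(seq, 1)
    counts = np.bincount(labels, minlength=seq.k + 1)[1:]
    return counts / labels.size


def transition_counts(seq: StateSequence) -> np.ndarray:
    """Raw k x k counts of ordered consecutive pairs (i -> j), diagonal included."""
    labels = _labels(seq, 2)
    counts = np.zeros((seq.k, seq.k))
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    return counts


def transition_probabilities(seq: StateSequence) -> np.ndarray:
    """Row-normalised transition matrix; unvisited-state rows are NaN.

    Row i divides the ordered pair counts (i -> j), persistence included,
    by the total number of pairs starting in i.  A state with no outgoing
    pairs (never visited among frames 1..T-1) has a missing (NaN) row.
    """
    counts = transition_counts(seq)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_sums
    probs[row_sums[:, 0] == 0] = np.nan
    return probs


def summarize_dynamics(seq: StateSequence) -> DynamicsSummary:
    return DynamicsSummary(
        subject_id=seq.subject_id,
        total_transitions=total_transitions(seq),
        fractional_occupancy=fractional_occupancy(seq),
        transition_probability=transition_probabilities(seq),
    )
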