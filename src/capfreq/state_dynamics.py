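"""Temporal dynamics of CAP states from per-subject label sequences.

For a scan of N frames with N_A frames in state A:

* fraction of time  = N_A / N,
* counts            = number of maximal runs (episodes) of the state,
* persistence       = TR x mean episode length in frames (seconds),
* transition matrix = P(A -> B) = N_{A->B} / N_A over frames with a successor,
* resilience        = the transition matrix diagonal.

Runs truncated by the scan boundaries count as full episodes, which makes
the identity fraction * T * TR = counts * persistence hold exactly for every
subject and state.  A state a subject never visits has fraction and counts 0
but *undefined* (NaN) persistence, and is excluded from group means rather
than dragged in as an artificial zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_band import BandDefinition, band_center
from .cap_states import StateSequence

__all__ = [
    "DynamicsTable",
    "run_lengths",
    "fraction_of_time",
    "count_episodes",
    "persistence",
    "transition_matrix",
    "resilience",
    "normalized_persistence",
    "cohort_dynamics",
]


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label vector -> (run values, run lengths)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return labels[starts], ends - starts


def fraction_of_time(seq: StateSequence, n_states: int | None = None) -> np.ndarray:
    """Proportion of frames occupied by each state (sums to 1)."""
    k = n_states or seq.n_states
    counts = np.bincount(seq.labels, minlength=k + 1)[1 : k + 1]
    return counts / seq.n_frames


def count_episodes(seq: StateSequence, n_states: int | None = None) -> np.ndarray:
    """Number of maximal runs of each state within the scan."""
    k = n_states or seq.n_states
    values, _ = run_lengths(seq.labels)
    return np.bincount(values, minlength=k + 1)[1 : k + 1]


def persistence(
    seq: StateSequence, n_states: int | None = None, tr: float | None = None
) -> np.ndarray:
    """Mean episode duration of each state, in seconds (NaN if never visited)."""
    k = n_states or seq.n_states
    tr = tr if tr is not None else seq.tr
    values, lengths = run_lengths(seq.labels)
    total = np.bincount(values, weights=lengths, minlength=k + 1)[1 : k + 1]
    n_runs = np.bincount(values, minlength=k + 1)[1 : k + 1]
    with np.errstate(invalid="ignore"):
        out = tr * total / n_runs
    out[n_runs == 0] = np.nan
    return out


def transition_matrix(seq: StateSequence, n_states: int | None = None) -> np.ndarray:
    """(K, K) matrix of P(next frame in B | current frame in A).

    The last frame has no successor and is excluded from denominators; rows of
    states with no successor frames are NaN.
    """
    k = n_states or seq.n_states
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames for transitions")
    a, b = seq.labels[:-1] - 1, seq.labels[1:] - 1
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), 1.0)
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tm = counts / denom
    tm[denom.ravel() == 0] = np.nan
    return tm


def resilience(tm: np.ndarray) -> np.ndarray:
    """Within-state transition probability: the transition-matrix diagonal."""
    return np.diagonal(np.asarray(tm, dtype=float)).copy()


def normalized_persistence(pers_seconds: float | np.ndarray, band: BandDefinition):
    """Persistence expressed in cycles of the band's center frequency.

    Multiplying persistence (s) by the center frequency (Hz) yields a
    dimensionless dwell that discounts the slowing every narrow low band
    imposes on signals passed through it; residual band differences in this
    quantity are not explained by the filtering alone.
    """
    return np.asarray(pers_seconds, dtype=float) * band_center(band)


@dataclass
class DynamicsTable:
    """Per-subject, per-state dynamics plus per-subject transition matrices."""

    table: pd.DataFrame  # columns: subject_id, band, state, fraction, persistence_s, counts
    transitions: dict[str, np.ndarray]
    n_states: int
    tr: float
    band: BandDefinition | None = None

    def group_mean(self, column: str) -> pd.Series:
        """Per-state mean over subjects, ignoring undefined (NaN) entries."""
        return self.table.groupby("state")[column].mean()

    def group_sem(self, column: str) -> pd.Series:
        return self.table.groupby("state")[column].sem()

    def pivot(self, column: str) -> pd.DataFrame:
        """subjects x states matrix of one metric."""
        return self.table.pivot(index="subject_id", columns="state", values=column)


def cohort_dynamics(
    seqs: dict[str, StateSequence] | list[StateSequence],
    n_states: int,
    tr: float | None = None,
    band: BandDefinition | None = None,
) -> DynamicsTable:
    """Assemble the per-subject dynamics metrics of a cohort into one table.

    Metrics are computed per subject and only then aggregated; sequences are
    never concatenated across subjects (that would fabricate transitions at
    the seams).
    """
    seq_list = list(seqs.values()) if isinstance(seqs, dict) else list(seqs)
    if not seq_list:
        raise ValueError("no sequences given")
    tr = tr if tr is not None else seq_list[0].tr
    band = band if band is not None else seq_list[0].band
    rows = []
    transitions = {}
    band_name = band.name if band else "broadband"
    for seq in seq_list:
        frac = fraction_of_time(seq, n_states)
        cnt = count_episodes(seq, n_states)
        pers = persistence(seq, n_states, tr)
        transitions[seq.subject_id] = transition_matrix(seq, n_states)
        for k in range(n_states):
            rows.append(
                {
                    "subject_id": seq.subject_id,
                    "band": band_name,
                    "state": k + 1,
                    "fraction": frac[k],
                    "persistence_s": pers[k],
                    "counts": int(cnt[k]),
                }
            )
    return DynamicsTable(
        table=pd.DataFrame(rows),
        transitions=transitions,
        n_states=n_states,
        tr=tr,
        band=band,
    )
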