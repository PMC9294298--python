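"""Frame-wise clustering of ROI volumes into coactivation-pattern (CAP) states.

Each z-scored fMRI frame is a point in ROI space; K-means groups frames with
similar coactivation profiles into K recurring states.  A state's spatial map
is its Z-map: the per-ROI mean of member frames divided by their SD.  New
frames (e.g. from a patient cohort that never entered clustering) are assigned
to the state whose Z-map they correlate with most strongly, and CAP sets
estimated in different frequency bands are aligned with the Hungarian
algorithm on pairwise Pearson similarity.

Clustering geometry: frames are row-standardized (mean 0, unit SD across
ROIs) before K-means, so squared Euclidean distance between frames is a
monotone transform of 1 - Pearson r — the same similarity later used to
assign new frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .signal_band import BandDefinition, ROITimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CAPSet",
    "StateSequence",
    "Alignment",
    "cluster_caps",
    "compute_zmaps",
    "assign_frames",
    "silhouette_curve",
    "align_capsets",
    "relabel_states",
    "cross_band_similarity",
    "between_state_similarity",
]


@dataclass
class CAPSet:
    """K CAP states of one frequency band, each defined by a per-ROI Z-map."""

    zmaps: np.ndarray  # (K, R)
    band: BandDefinition | None = None
    roi_names: list[str] = field(default_factory=list)
    n_frames_per_state: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.zmaps = np.asarray(self.zmaps, dtype=float)
        if self.zmaps.ndim != 2 or self.zmaps.shape[0] < 2:
            raise ValueError("zmaps must be a (K>=2, R) matrix")
        if not np.all(np.isfinite(self.zmaps)):
            raise ValueError("zmaps contain non-finite values")

    @property
    def n_states(self) -> int:
        return self.zmaps.shape[0]

    @property
    def n_rois(self) -> int:
        return self.zmaps.shape[1]


@dataclass
class StateSequence:
    """One integer state label per frame for one subject (labels 1..K)."""

    subject_id: str
    labels: np.ndarray  # (T,) int, values in 1..K
    tr: float
    band: BandDefinition | None = None
    n_states: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.labels.min(initial=1) < 1:
            raise ValueError("state labels must be >= 1")
        if self.n_states is None:
            self.n_states = int(self.labels.max())
        elif self.labels.max(initial=1) > self.n_states:
            raise ValueError("label exceeds n_states")

    @property
    def n_frames(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class Alignment:
    """Bijection state k of set A -> state permutation[k] of set B."""

    permutation: np.ndarray  # (K,) int, 0-based indices into set B
    similarity: np.ndarray  # (K,) Pearson r of matched pairs, in A's order


def _standardize_rows(frames: np.ndarray) -> np.ndarray:
    """Row-wise (per-frame) standardization to mean 0, population SD 1."""
    mean = frames.mean(axis=1, keepdims=True)
    sd = frames.std(axis=1, ddof=0, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        raise ValueError(f"frame {flat[0]} has zero variance across ROIs")
    return (frames - mean) / sd


def _pool_frames(
    ts_list: Sequence[ROITimeSeries],
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    frames = np.vstack([ts.data for ts in ts_list])
    bounds, start = [], 0
    for ts in ts_list:
        bounds.append((ts.subject_id, start, start + ts.n_frames))
        start += ts.n_frames
    return frames, bounds


def compute_zmaps(frames: np.ndarray, labels: np.ndarray, n_states: int) -> np.ndarray:
    """Z-map of each state: mean of member frames / population SD, per ROI.

    Every state needs at least two member frames, and no ROI may be constant
    within a state (the SD in the denominator would vanish).
    """
    frames = np.asarray(frames, dtype=float)
    labels = np.asarray(labels, dtype=int)
    zmaps = np.empty((n_states, frames.shape[1]))
    for k in range(1, n_states + 1):
        members = frames[labels == k]
        if members.shape[0] < 2:
            raise ValueError(f"state {k} has {members.shape[0]} member frames (< 2)")
        sd = members.std(axis=0, ddof=0)
        dead = np.nonzero(sd == 0)[0]
        if dead.size:
            raise ValueError(f"state {k}: zero SD across members for ROI {dead[0]}")
        zmaps[k - 1] = members.mean(axis=0) / sd
    return zmaps


def cluster_caps(
    ts_list: Sequence[ROITimeSeries],
    n_states: int = 6,
    seed: int = 0,
    n_replicates: int = 10,
) -> tuple[CAPSet, dict[str, StateSequence]]:
    """Pool all frames of the reference cohort and K-means them into CAP states.

    Runs ``n_replicates`` k-means++ initializations and keeps the best by
    within-cluster cost.  Returns the CAP set (Z-maps built from the original
    z-scored frames) and each subject's frame-label sequence.  Only the
    reference (control) cohort should be passed here; other cohorts are
    projected onto the result with :func:`assign_frames`.
    """
    if not ts_list:
        raise ValueError("no subjects given")
    frames, bounds = _pool_frames(ts_list)
    if n_states > frames.shape[0]:
        raise ValueError(f"K={n_states} exceeds {frames.shape[0]} pooled frames")
    if n_states > frames.shape[1]:
        raise ValueError("K exceeds the number of ROIs")
    std_frames = _standardize_rows(frames)
    km = KMeans(
        n_clusters=n_states,
        n_init=n_replicates,
        random_state=seed,
        init="k-means++",
    ).fit(std_frames)
    labels = km.labels_ + 1
    counts = np.bincount(labels, minlength=n_states + 1)[1:]
    if (counts == 0).any():
        # k-means++ with replicates essentially never leaves a cluster empty;
        # sklearn relocates empty clusters internally, so this is a safeguard.
        raise RuntimeError("empty cluster in final K-means solution")
    zmaps = compute_zmaps(frames, labels, n_states)
    band = ts_list[0].band
    capset = CAPSet(
        zmaps=zmaps,
        band=band,
        roi_names=list(ts_list[0].roi_names),
        n_frames_per_state=counts,
        seed=seed,
    )
    seqs = {
        sid: StateSequence(
            subject_id=sid,
            labels=labels[a:b],
            tr=ts_list[0].tr,
            band=band,
            n_states=n_states,
        )
        for (sid, a, b) in bounds
    }
    return capset, seqs


def _frame_state_correlations(frames: np.ndarray, zmaps: np.ndarray) -> np.ndarray:
    """(T, K) Pearson correlation between each frame and each Z-map."""
    fz = _standardize_rows(np.asarray(frames, dtype=float))
    zz = _standardize_rows(np.asarray(zmaps, dtype=float))
    return fz @ zz.T / frames.shape[1]


def assign_frames(ts: ROITimeSeries, capset: CAPSet) -> StateSequence:
    """Label each frame with the CAP state of highest spatial similarity.

    Similarity is the Pearson correlation between the frame and each state's
    Z-map.  Exact ties go to the lowest state index (logged); a frame that is
    constant across ROIs has no defined correlation and raises.
    """
    if ts.n_rois != capset.n_rois:
        raise ValueError(
            f"ROI count mismatch: series has {ts.n_rois}, CAP set {capset.n_rois}"
        )
    r = _frame_state_correlations(ts.data, capset.zmaps)
    labels = np.argmax(r, axis=1)
    ties = (r == r.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info(
            "subject %s: %d frame(s) with tied similarity assigned to the "
            "lowest state index", ts.subject_id, int(ties.sum()),
        )
    return StateSequence(
        subject_id=ts.subject_id,
        labels=labels + 1,
        tr=ts.tr,
        band=capset.band,
        n_states=capset.n_states,
    )


def silhouette_curve(
    frames: np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
    n_replicates: int = 10,
) -> dict[int, float]:
    """Mean silhouette score of the K-means solution for each candidate K.

    The silhouette uses the same geometry as the clustering (Euclidean on
    row-standardized frames); the K maximizing the curve is the supported
    cluster number.
    """
    frames = np.asarray(frames, dtype=float)
    std_frames = _standardize_rows(frames)
    scores: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= frames.shape[0] - 1:
            raise ValueError(f"K={k} outside [2, n_frames-1]")
        km = KMeans(n_clusters=k, n_init=n_replicates, random_state=seed).fit(
            std_frames
        )
        scores[k] = float(silhouette_score(std_frames, km.labels_))
    return scores


def align_capsets(cap_a: CAPSet, cap_b: CAPSet) -> Alignment:
    """Hungarian matching of two CAP sets, maximizing total Pearson similarity."""
    if cap_a.n_states != cap_b.n_states:
        raise ValueError("CAP sets have different K")
    if cap_a.n_rois != cap_b.n_rois:
        raise ValueError("CAP sets have different ROI counts")
    sim = _frame_state_correlations(cap_a.zmaps, cap_b.zmaps)
    row, col = linear_sum_assignment(1.0 - sim)  # minimize cost = 1 - r
    perm = np.empty(cap_a.n_states, dtype=int)
    perm[row] = col
    return Alignment(permutation=perm, similarity=sim[np.arange(len(perm)), perm])


def relabel_states(seq: StateSequence, alignment: Alignment) -> StateSequence:
    """Renumber a sequence's states into the reference set's numbering.

    ``alignment`` must come from ``align_capsets(recovered, reference)``;
    state k of the recovered set becomes state ``permutation[k]`` of the
    reference.  Needed before comparing state-specific metrics across bands
    or against planted templates, since K-means numbering is arbitrary.
    """
    new_labels = alignment.permutation[seq.labels - 1] + 1
    return StateSequence(
        subject_id=seq.subject_id,
        labels=new_labels,
        tr=seq.tr,
        band=seq.band,
        n_states=seq.n_states,
    )


def cross_band_similarity(
    cap_a: CAPSet, cap_b: CAPSet, alignment: Alignment
) -> np.ndarray:
    """Per-state Pearson r between matched Z-maps of two (aligned) bands."""
    sim = _frame_state_correlations(cap_a.zmaps, cap_b.zmaps)
    return sim[np.arange(cap_a.n_states), alignment.permutation]


def between_state_similarity(capset: CAPSet) -> np.ndarray:
    """K x K Pearson correlation matrix between a set's Z-maps.

    Opposite CAP pairs show up as strongly negative entries.
    """
    return np.corrcoef(capset.zmaps)
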