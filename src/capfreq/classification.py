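"""Diagnostic classification from CAP spatial features.

Each subject is described by the activation level of every ROI in every CAP
state (K x R features per band; 6 x 408 = 2448 for the default parcellation).
Features are ranked inside each training fold by the F-score

    F_j = [(xbar+_j - xbar_j)^2 + (xbar-_j - xbar_j)^2] / (s2+_j + s2-_j),

where s2 are within-class sample variances, and a linear SVM (C = 1) is
trained on the top-n features for n swept over a grid; the smallest n
achieving the highest cross-validated accuracy is reported.  Cross-validation
is leave-one-pair-out (one patient and their matched control per fold) or
leave-one-out, and the hold-out experiment re-defines the CAP states on a
control subset disjoint from the classification sample to avoid circularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .cap_states import CAPSet, StateSequence, assign_frames, cluster_caps
from .signal_band import ROITimeSeries, SubjectMeta

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ClassifierConfig",
    "ClassificationReport",
    "state_feature_map",
    "build_feature_matrix",
    "f_score",
    "lopo_cv",
    "loo_cv",
    "holdout_experiment",
    "consensus_features",
    "match_controls",
    "classification_metrics",
]


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with (band, state, roi) feature names."""

    X: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing values")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear SVM and feature-sweep settings."""

    C: float = 1.0
    feature_grid: tuple[int, ...] = tuple(range(20, 1501, 20))
    seed: int = 0
    standardize_within_fold: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not self.feature_grid:
            raise ValueError("feature grid is empty")


@dataclass
class ClassificationReport:
    acc: float
    se: float
    sp: float
    auc: float
    chosen_feature_number: int | None = None
    per_repetition: list[dict] = field(default_factory=list)
    accuracy_by_n_features: dict[int, float] = field(default_factory=dict)
    selected_features: list[np.ndarray] = field(default_factory=list)


def state_feature_map(
    ts: ROITimeSeries, seq: StateSequence, n_states: int, mode: str = "mean"
) -> np.ndarray:
    """(K, R) subject-level spatial map: per-state summary of member frames.

    ``mode="mean"`` (default) averages the subject's z-scored frames assigned
    to each state; ``mode="zmap"`` additionally divides by the member-frame SD
    (a subject-level Z-map).  A state the subject never visits has no defined
    activation level and raises.
    """
    if seq.n_frames != ts.n_frames:
        raise ValueError("sequence length does not match frame count")
    out = np.empty((n_states, ts.n_rois))
    for k in range(1, n_states + 1):
        members = ts.data[seq.labels == k]
        if members.shape[0] == 0:
            raise ValueError(
                f"subject {ts.subject_id}: no frames assigned to state {k}"
            )
        if mode == "mean":
            out[k - 1] = members.mean(axis=0)
        elif mode == "zmap":
            sd = members.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError(
                    f"subject {ts.subject_id}: zero SD in state {k} feature map"
                )
            out[k - 1] = members.mean(axis=0) / sd
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def build_feature_matrix(
    subject_maps: Mapping[str, Sequence[tuple[str, np.ndarray]]],
) -> FeatureMatrix:
    """Concatenate per-band (K, R) state maps into one feature row per subject.

    ``subject_maps[sid]`` is a sequence of (band_name, K x R map); multi-band
    models simply list several bands.  Feature names are "band.sK.roiJ".
    """
    sids = list(subject_maps)
    if not sids:
        raise ValueError("no subjects")
    rows, names = [], None
    for sid in sids:
        blocks, block_names = [], []
        for band_name, m in subject_maps[sid]:
            m = np.asarray(m, dtype=float)
            blocks.append(m.ravel())
            block_names.extend(
                f"{band_name}.s{k + 1}.roi{j}"
                for k in range(m.shape[0])
                for j in range(m.shape[1])
            )
        rows.append(np.concatenate(blocks))
        if names is None:
            names = block_names
        elif names != block_names:
            raise ValueError(f"subject {sid}: inconsistent feature layout")
    return FeatureMatrix(np.vstack(rows), names, sids)


def f_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher-style F-score of each feature for a two-class problem.

    Undefined scores (both classes constant) come back NaN and are ranked
    last by :func:`rank_features`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    pos, neg = X[y == classes[1]], X[y == classes[0]]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each class needs at least 2 members")
    xbar = X.mean(axis=0)
    num = (pos.mean(axis=0) - xbar) ** 2 + (neg.mean(axis=0) - xbar) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = num / den
    undef = den == 0
    if undef.any():
        logger.info("%d feature(s) with undefined F-score ranked last",
                    int(undef.sum()))
        scores[undef] = np.nan
    return scores


def rank_features(scores: np.ndarray) -> np.ndarray:
    """Feature indices by decreasing score; NaN (undefined) scores last."""
    order = np.argsort(-np.nan_to_num(scores, nan=-np.inf), kind="stable")
    return order


def classification_metrics(
    truth: np.ndarray, predicted: np.ndarray, decision_values: np.ndarray
) -> ClassificationReport:
    """ACC/SE/SP from the confusion matrix (positive = patient) and rank AUC."""
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if truth.shape != predicted.shape:
        raise ValueError("length mismatch")
    if np.unique(truth).size < 2:
        raise ValueError("both classes must be present in the truth labels")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    return ClassificationReport(
        acc=(tp + tn) / truth.size,
        se=tp / (tp + fn),
        sp=tn / (tn + fp),
        auc=float(roc_auc_score(truth, np.asarray(decision_values, float))),
    )


def _run_cv(
    fm: FeatureMatrix,
    y: np.ndarray,
    folds: Sequence[np.ndarray],
    config: ClassifierConfig,
) -> ClassificationReport:
    """Generic fold runner: F-score selection inside each training fold only."""
    X = fm.X
    y = np.asarray(y).astype(int)
    grid = [n for n in config.feature_grid if n <= fm.n_features]
    if not grid:
        grid = [fm.n_features]
    n_sub = X.shape[0]
    all_idx = np.arange(n_sub)
    # predictions[g][i], decisions[g][i] for grid point g, subject i
    preds = np.full((len(grid), n_sub), -1, dtype=int)
    decs = np.full((len(grid), n_sub), np.nan)
    selected_per_fold: list[np.ndarray] = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        Xtr, ytr = X[train_idx], y[train_idx]
        if config.standardize_within_fold:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (X[test_idx] - mu) / sd
        else:
            Xte = X[test_idx]
        order = rank_features(f_score(Xtr, ytr))
        selected_per_fold.append(order[: max(grid)])
        for g, n_feat in enumerate(grid):
            cols = order[:n_feat]
            clf = SVC(kernel="linear", C=config.C)
            clf.fit(Xtr[:, cols], ytr)
            preds[g, test_idx] = clf.predict(Xte[:, cols])
            dv = clf.decision_function(Xte[:, cols])
            # decision_function sign follows class order; classes_ is sorted
            decs[g, test_idx] = dv if clf.classes_[1] == 1 else -dv
    acc_by_n = {n: float(np.mean(preds[g] == y)) for g, n in enumerate(grid)}
    best_acc = max(acc_by_n.values())
    chosen = min(n for n, a in acc_by_n.items() if a == best_acc)
    g = grid.index(chosen)
    report = classification_metrics(y, preds[g], decs[g])
    report.chosen_feature_number = chosen
    report.accuracy_by_n_features = acc_by_n
    report.selected_features = [s[:chosen] for s in selected_per_fold]
    return report


def lopo_cv(
    fm: FeatureMatrix,
    y: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    config: ClassifierConfig,
) -> ClassificationReport:
    """Leave-one-pair-out CV: each fold holds out one patient/control pair."""
    flat = [i for p in pairs for i in p]
    if len(set(flat)) != len(flat):
        raise ValueError("a subject appears in more than one pair")
    if sorted(flat) != list(range(fm.X.shape[0])):
        raise ValueError("pairs must partition the subjects")
    folds = [np.asarray(p, dtype=int) for p in pairs]
    return _run_cv(fm, y, folds, config)


def loo_cv(
    fm: FeatureMatrix, y: np.ndarray, config: ClassifierConfig
) -> ClassificationReport:
    """Leave-one-out CV (singleton test folds)."""
    folds = [np.array([i]) for i in range(fm.X.shape[0])]
    return _run_cv(fm, y, folds, config)


def random_pairs(
    y: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random patient-control pairing within a balanced cohort."""
    y = np.asarray(y).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size != neg.size:
        raise ValueError("pairing needs equal group sizes")
    return list(zip(pos, rng.permutation(neg)))


def match_controls(
    hc_meta: Sequence[SubjectMeta], sz_meta: Sequence[SubjectMeta]
) -> list[SubjectMeta]:
    """Select one age/sex-matched control per patient (greedy, no replacement).

    Matches within sex strata by nearest age, processing patients in age
    order; sex counts of the output equal the patient cohort's exactly.
    """
    matched: list[SubjectMeta] = []
    for sex in ("M", "F"):
        patients = sorted(
            (m for m in sz_meta if m.sex == sex), key=lambda m: m.age
        )
        pool = [m for m in hc_meta if m.sex == sex]
        if len(pool) < len(patients):
            raise ValueError(
                f"not enough {sex} controls: need {len(patients)}, have {len(pool)}"
            )
        for p in patients:
            best = min(pool, key=lambda m: abs(m.age - p.age))
            pool.remove(best)
            matched.append(best)
    return matched


def holdout_experiment(
    hc_ts: Mapping[str, ROITimeSeries],
    sz_ts: Mapping[str, ROITimeSeries],
    hc_meta: Sequence[SubjectMeta],
    sz_meta: Sequence[SubjectMeta],
    config: ClassifierConfig,
    n_states: int = 6,
    n_definition: int | None = None,
    n_classification: int | None = None,
    n_repetitions: int = 100,
    n_lopo_repeats: int = 10,
    n_kmeans_replicates: int = 10,
    feature_mode: str = "mean",
) -> tuple[list[ClassificationReport], list[list[np.ndarray]], list[str]]:
    """Hold-out CAP-definition experiment.

    Per repetition: randomly split the control pool into a CAP-definition set
    and a disjoint classification set; cluster CAPs on the definition set
    only; project the classification controls and the age/sex-matched
    patients onto those CAPs; build features; run LOPO (random pairings)
    ``n_lopo_repeats`` times and average.  Returns one averaged report per
    repetition, per-repetition lists of per-iteration selected-feature index
    arrays (for consensus extraction), and the feature names.
    """
    hc_ids = list(hc_ts)
    meta_by_id = {m.subject_id: m for m in hc_meta}
    if n_definition is None:
        n_definition = len(hc_ids) - (n_classification or len(sz_ts))
    if n_classification is None:
        n_classification = len(hc_ids) - n_definition
    if n_definition + n_classification > len(hc_ids):
        raise ValueError("definition + classification exceeds the control pool")
    rng = np.random.default_rng(config.seed)
    reports: list[ClassificationReport] = []
    selections: list[list[np.ndarray]] = []
    feature_names: list[str] = []
    for rep in range(n_repetitions):
        perm = rng.permutation(len(hc_ids))
        def_ids = [hc_ids[i] for i in perm[:n_definition]]
        cls_ids = [hc_ids[i] for i in perm[n_definition:n_definition + n_classification]]
        assert not set(def_ids) & set(cls_ids)
        capset, _ = cluster_caps(
            [hc_ts[s] for s in def_ids],
            n_states=n_states,
            seed=int(rng.integers(2**31 - 1)),
            n_replicates=n_kmeans_replicates,
        )
        cls_meta = [meta_by_id[s] for s in cls_ids]
        sz_matched = match_controls(list(sz_meta), cls_meta)  # patients matched
        # match_controls picks from its first arg; here select patients that
        # match the held-out controls' age/sex structure.
        subject_maps: dict[str, list[tuple[str, np.ndarray]]] = {}
        labels = []
        band_name = capset.band.name if capset.band else "broadband"
        for m in sz_matched:
            ts = sz_ts[m.subject_id]
            seq = assign_frames(ts, capset)
            subject_maps[m.subject_id] = [
                (band_name, state_feature_map(ts, seq, n_states, feature_mode))
            ]
            labels.append(1)
        for sid in cls_ids:
            ts = hc_ts[sid]
            seq = assign_frames(ts, capset)
            subject_maps[sid] = [
                (band_name, state_feature_map(ts, seq, n_states, feature_mode))
            ]
            labels.append(0)
        fm = build_feature_matrix(subject_maps)
        feature_names = fm.feature_names
        y = np.asarray(labels)
        rep_metrics = []
        rep_selected: list[np.ndarray] = []
        for _ in range(n_lopo_repeats):
            pairs = random_pairs(y, rng)
            rep_cfg = ClassifierConfig(
                C=config.C,
                feature_grid=config.feature_grid,
                seed=int(rng.integers(2**31 - 1)),
                standardize_within_fold=config.standardize_within_fold,
            )
            r = lopo_cv(fm, y, pairs, rep_cfg)
            rep_metrics.append((r.acc, r.se, r.sp, r.auc))
            rep_selected.extend(r.selected_features)
        acc, se, sp, auc = np.mean(rep_metrics, axis=0)
        reports.append(
            ClassificationReport(
                acc=float(acc), se=float(se), sp=float(sp), auc=float(auc),
                per_repetition=[
                    {"acc": a, "se": s, "sp": q, "auc": u}
                    for a, s, q, u in rep_metrics
                ],
            )
        )
        selections.append(rep_selected)
    return reports, selections, feature_names


def consensus_features(
    selections: Sequence[Sequence[np.ndarray]],
    n_features: int,
    within_threshold: float = 0.80,
    across_threshold: float = 0.80,
) -> np.ndarray:
    """Two-stage consensus: features selected in >= ``within_threshold`` of a
    repetition's iterations are flagged; features flagged in >=
    ``across_threshold`` of repetitions are the consensus set."""
    flags = np.zeros((len(selections), n_features), dtype=bool)
    for r, iteration_sets in enumerate(selections):
        if not iteration_sets:
            raise ValueError(f"repetition {r} has no iterations")
        counts = np.zeros(n_features)
        for sel in iteration_sets:
            counts[np.asarray(sel, dtype=int)] += 1
        flags[r] = counts / len(iteration_sets) >= within_threshold
    across = flags.mean(axis=0)
    return np.flatnonzero(across >= across_threshold)
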