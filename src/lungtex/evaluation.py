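"""Evaluation protocol: one-vs-rest point metrics, macro averaging,
confusion matrices, macro-averaged ROC, and the train/validation/test
construction.

Per-class metrics on the (heavily skewed) test set are

    SN = TP / (TP + FN)        SP = TN / (TN + FP)
    GM = sqrt(SN * SP)         BA = (SN + SP) / 2

computed one-vs-rest and macro-averaged as *unweighted* means over the
eight classes, so every pattern counts equally regardless of prevalence.
(The geometric mean is taken of SN and SP — the rate form — which is the
definition every published per-class row satisfies.)

The split construction: classes with >= 800 annotated points contribute
600 randomly chosen training points (at most 75% of the class); smaller
classes contribute ceil(0.75 * n) points which are then augmented
geometrically until the class roster reaches 600. All leftover points form
the test set. The balanced 4800-entry roster is partitioned into 10
stratified cross-validation folds. A subject-level variant holds out whole
subjects instead, so no subject contributes to both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .augment import RosterEntry, balance_classes
from .tissue import N_CLASSES, TissueClass
from .volume import AnnotatedPoint

METRIC_NAMES = ("SN", "SP", "GM", "BA")


class MetricError(ValueError):
    """A metric is undefined (e.g. a class absent from the true labels)."""


class SplitError(ValueError):
    pass


class ROCError(ValueError):
    pass


# ------------------------------------------------------------- confusion

@dataclass
class ConfusionMatrix:
    """8x8 integer counts; rows = true class, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected {(N_CLASSES, N_CLASSES)} counts, "
                             f"got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    def normalized(self) -> np.ndarray:
        """Rows divided by their sums (NaN for empty rows)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / sums

    def to_frame(self) -> pd.DataFrame:
        names = [c.name for c in TissueClass]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count-based confusion matrix over the eight classes."""
    t = np.asarray([int(x) for x in true_labels])
    p = np.asarray([int(x) for x in predicted_labels])
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    counts = _sk_confusion(t, p, labels=list(range(N_CLASSES)))
    return ConfusionMatrix(counts)


# --------------------------------------------------------------- metrics

@dataclass
class ClassMetrics:
    """Per-class and macro-averaged SN/SP/GM/BA."""

    per_class: Dict[TissueClass, Dict[str, float]]
    macro: Dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = {c.name: self.per_class[c] for c in self.per_class}
        rows["Macro"] = self.macro
        return pd.DataFrame(rows).T[list(METRIC_NAMES)]


def metrics_from_confusion(cm: ConfusionMatrix,
                           classes: Optional[Sequence[TissueClass]] = None
                           ) -> ClassMetrics:
    """One-vs-rest SN/SP/GM/BA per class plus unweighted macro averages.

    Raises :class:`MetricError` naming the class if any requested class
    has no true samples (its sensitivity would be undefined).
    """
    counts = cm.counts
    classes = list(classes) if classes is not None else list(TissueClass)
    total = counts.sum()
    per_class: Dict[TissueClass, Dict[str, float]] = {}
    for c in classes:
        i = int(c)
        row = counts[i].sum()
        if row == 0:
            raise MetricError(
                f"class {TissueClass(i).name} has no true samples; "
                f"sensitivity undefined")
        tp = counts[i, i]
        fn = row - tp
        fp = counts[:, i].sum() - tp
        tn = total - row - fp
        sn = tp / (tp + fn)
        if tn + fp == 0:
            raise MetricError(
                f"class {TissueClass(i).name}: specificity undefined "
                f"(no negative samples)")
        sp = tn / (tn + fp)
        per_class[TissueClass(i)] = {
            "SN": float(sn), "SP": float(sp),
            "GM": float(np.sqrt(sn * sp)), "BA": float(0.5 * (sn + sp)),
        }
    macro = {m: float(np.mean([per_class[c][m] for c in per_class]))
             for m in METRIC_NAMES}
    return ClassMetrics(per_class=per_class, macro=macro)


def metrics_from_rates(sn: float, sp: float) -> Dict[str, float]:
    """GM and BA from a sensitivity/specificity pair (worked-example
    arithmetic on printed per-class rates)."""
    return {"SN": float(sn), "SP": float(sp),
            "GM": float(np.sqrt(sn * sp)), "BA": float(0.5 * (sn + sp))}


# ------------------------------------------------------------------- ROC

def macro_roc(scores: np.ndarray, labels: np.ndarray,
              fpr_grid: Optional[np.ndarray] = None
              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Macro-averaged one-vs-rest ROC over the classes present.

    ``scores`` (N, C) are fused ensemble scores; each class's score is the
    renormalized share scores[:, c] / scores.sum(axis=1). Returns
    (fpr_grid, mean_tpr, auc) with trapezoidal AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    present = np.unique(labels)
    if len(present) < 2:
        raise ROCError("ROC needs at least two classes present")
    norm = scores.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(norm > 0, scores / norm, 0.0)
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for c in present:
        fpr, tpr, _ = _sk_roc_curve(labels == c, shares[:, int(c)])
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, fpr_grid))
    return fpr_grid, mean_tpr, auc


# ----------------------------------------------------------------- split

SPLIT_LARGE_CLASS_MIN = 800   # classes at/above this size contribute ...
SPLIT_TRAIN_PER_CLASS = 600   # ... exactly this many training points
SPLIT_TRAIN_FRACTION = 0.75   # smaller classes: ceil(0.75 n) train points
SPLIT_N_FOLDS = 10


@dataclass
class ClassSplit:
    train: List[AnnotatedPoint]
    test: List[AnnotatedPoint]
    needs_augmentation: bool


@dataclass
class SplitPlan:
    """Train/test allocation, balanced rosters and CV fold assignment."""

    level: str
    per_class: Dict[TissueClass, ClassSplit]
    rosters: Dict[TissueClass, List[RosterEntry]]
    fold_of: Dict[TissueClass, np.ndarray]
    test_subjects: Tuple[str, ...] = ()

    def train_points(self, cls: TissueClass) -> List[AnnotatedPoint]:
        return self.per_class[cls].train

    def test_points(self, cls: TissueClass) -> List[AnnotatedPoint]:
        return self.per_class[cls].test

    def roster_total(self) -> int:
        return sum(len(r) for r in self.rosters.values())

    def all_test_points(self) -> List[AnnotatedPoint]:
        out: List[AnnotatedPoint] = []
        for c in sorted(self.per_class, key=int):
            out.extend(self.per_class[c].test)
        return out

    def fold_rosters(self, fold: int) -> Tuple[List[RosterEntry], List[RosterEntry]]:
        """(train, validation) roster entries for one CV fold."""
        tr: List[RosterEntry] = []
        va: List[RosterEntry] = []
        for c in sorted(self.rosters, key=int):
            folds = self.fold_of[c]
            for entry, f in zip(self.rosters[c], folds):
                (va if f == fold else tr).append(entry)
        return tr, va


def _group_by_class(points: Sequence[AnnotatedPoint]
                    ) -> Dict[TissueClass, List[AnnotatedPoint]]:
    by: Dict[TissueClass, List[AnnotatedPoint]] = {c: [] for c in TissueClass}
    for p in points:
        by[p.label].append(p)
    return by


def make_split(points: Sequence[AnnotatedPoint], level: str = "point",
               rng_seed: int = 0, target: int = SPLIT_TRAIN_PER_CLASS,
               large_class_min: int = SPLIT_LARGE_CLASS_MIN,
               train_fraction: float = SPLIT_TRAIN_FRACTION,
               n_folds: int = SPLIT_N_FOLDS,
               n_test_subjects: int = 5) -> SplitPlan:
    """Construct the train/validation/test plan.

    Deterministic under ``rng_seed``; train and test are always disjoint,
    and at subject level no subject appears on both sides.
    """
    if level not in ("point", "subject"):
        raise SplitError(f"level must be 'point' or 'subject', got {level!r}")
    rng = np.random.default_rng(rng_seed)
    by_class = _group_by_class(points)
    empty = [c.name for c in TissueClass if not by_class[c]]
    if empty:
        raise SplitError(f"classes absent from the annotations: {empty}")

    per_class: Dict[TissueClass, ClassSplit] = {}
    if level == "point":
        for c in sorted(by_class, key=int):
            pts = by_class[c]
            n = len(pts)
            idx = rng.permutation(n)
            if n >= large_class_min:
                n_train = target
                aug = False
            else:
                n_train = int(np.ceil(train_fraction * n))
                aug = True
            train = [pts[i] for i in idx[:n_train]]
            test = [pts[i] for i in idx[n_train:]]
            per_class[c] = ClassSplit(train=train, test=test,
                                      needs_augmentation=aug)
        test_subjects: Tuple[str, ...] = ()
    else:
        subjects = sorted({p.subject_id for p in points})
        if len(subjects) <= n_test_subjects:
            raise SplitError("not enough subjects for a subject-level split")
        classes_of = {
            s: {p.label for p in points if p.subject_id == s} for s in subjects}
        chosen = None
        for _ in range(1000):
            cand = list(rng.choice(subjects, size=n_test_subjects, replace=False))
            covered = set().union(*(classes_of[s] for s in cand))
            if covered == set(TissueClass):
                chosen = cand
                break
        if chosen is None:
            raise SplitError(
                f"could not find {n_test_subjects} held-out subjects covering "
                f"all eight classes")
        test_set = set(chosen)
        for c in sorted(by_class, key=int):
            tr_pts = [p for p in by_class[c] if p.subject_id not in test_set]
            te_pts = [p for p in by_class[c] if p.subject_id in test_set]
            if not tr_pts:
                raise SplitError(f"class {c.name} has no training subjects")
            n = len(tr_pts)
            idx = rng.permutation(n)
            if n >= target:
                tr_pts = [tr_pts[i] for i in idx[:target]]
                aug = False
            else:
                aug = True
            per_class[c] = ClassSplit(train=tr_pts, test=te_pts,
                                      needs_augmentation=aug)
        test_subjects = tuple(chosen)

    rosters = balance_classes(
        {c: per_class[c].train for c in per_class}, target=target,
        rng_seed=int(rng.integers(2 ** 31)))
    fold_of: Dict[TissueClass, np.ndarray] = {}
    for c in sorted(rosters, key=int):
        n = len(rosters[c])
        folds = np.arange(n) % n_folds
        fold_of[c] = folds[rng.permutation(n)]
    return SplitPlan(level=level, per_class=per_class, rosters=rosters,
                     fold_of=fold_of, test_subjects=test_subjects)
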