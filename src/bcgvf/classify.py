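"""VF-vs-NVF classification with balanced training and two evaluation
paradigms: intra-subject 10-fold (systematic sampling) and inter-subject
leave-one-subject-out (LOSO).

VF is the positive class; SR and MA together form the negative (NVF)
class.  Training folds are balanced by seeded random undersampling of
the majority class; test folds are never resampled.  Confusion counts
are pooled over folds before the six metrics are computed, and the whole
procedure is repeated with derived seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

METRIC_NAMES = ("SEN", "SPE", "PRE", "F1", "bACC", "MCC")

POSITIVE = "VF"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricSet:
    sen: float
    spe: float
    pre: float
    f1: float
    bacc: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(METRIC_NAMES, (self.sen, self.spe, self.pre, self.f1, self.bacc, self.mcc)))


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, precision, F1, balanced accuracy, MCC.

    Any metric with a zero denominator is defined as 0 (logged).
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.info("zero denominator for %s; defined as 0", name)
            return 0.0
        return num / den

    sen = _ratio(c.tp, c.tp + c.fn, "SEN")
    spe = _ratio(c.tn, c.tn + c.fp, "SPE")
    pre = _ratio(c.tp, c.tp + c.fp, "PRE")
    f1 = _ratio(2 * sen * pre, sen + pre, "F1")
    bacc = (sen + spe) / 2.0
    mcc_den = np.sqrt(
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    mcc = _ratio(float(c.tp) * c.tn - float(c.fp) * c.fn, mcc_den, "MCC")
    return MetricSet(sen, spe, pre, f1, bacc, mcc)


def undersample(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by random undersampling of the majority class.

    All minority rows are kept; majority rows are sampled without
    replacement down to the minority count.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("undersampling needs exactly two classes present")
    i_min = int(np.argmin(counts))  # ties -> first class; the other is "majority"
    minority = classes[i_min]
    majority = classes[1 - i_min]
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    maj_idx = np.nonzero(y == majority)[0]
    keep = np.sort(
        np.concatenate([np.nonzero(y == minority)[0], rng.choice(maj_idx, n_min, replace=False)])
    )
    return X[keep], y[keep]


def kfold_splits(labels: np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Stratified folds by systematic sampling.

    Within each class the items are put in a seeded random order and the
    item at position i goes to fold ``i mod k``; fold class proportions
    are within one item of the global proportions.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < k:
        raise ValueError("need at least k items")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        for pos, item in enumerate(idx):
            folds[pos % k].append(int(item))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def loso_splits(subject_ids: np.ndarray) -> list[np.ndarray]:
    """One test fold per subject (appearance order); train is everyone else."""
    subject_ids = np.asarray(subject_ids)
    subjects = list(dict.fromkeys(subject_ids.tolist()))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    return [np.nonzero(subject_ids == s)[0] for s in subjects]


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    model: str = "rf",
    seed: int = 0,
) -> np.ndarray:
    """Fit LR or RF on standardized features; return hard test labels.

    Features are standardized using training-fold statistics only.
    Hyperparameters are library defaults pinned here (RF: 100 trees).
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (X_train - mu) / sd
    Xte = (np.asarray(X_test) - mu) / sd
    if model == "lr":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif model == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    else:
        raise ValueError("model must be 'lr' or 'rf'")
    clf.fit(Xtr, y_train)
    return clf.predict(Xte)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos_t = np.asarray(y_true) == POSITIVE
    pos_p = np.asarray(y_pred) == POSITIVE
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


@dataclass
class EvaluationReport:
    paradigm: str
    model: str
    repeats: int
    per_repeat: list[MetricSet] = field(default_factory=list)
    confusions: list[ConfusionCounts] = field(default_factory=list)

    @property
    def mean(self) -> dict[str, float]:
        arr = np.array([[*m.as_dict().values()] for m in self.per_repeat])
        return dict(zip(METRIC_NAMES, arr.mean(axis=0)))

    @property
    def sd(self) -> dict[str, float]:
        arr = np.array([[*m.as_dict().values()] for m in self.per_repeat])
        return dict(zip(METRIC_NAMES, arr.std(axis=0)))

    def as_dict(self) -> dict:
        return {
            "paradigm": self.paradigm,
            "model": self.model,
            "repeats": self.repeats,
            "per_repeat": [m.as_dict() for m in self.per_repeat],
            "confusions": [
                {"TP": c.tp, "FP": c.fp, "FN": c.fn, "TN": c.tn} for c in self.confusions
            ],
            "mean": self.mean,
            "sd": self.sd,
        }


def evaluate(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    model: str = "rf",
    paradigm: str = "kfold10",
    repeats: int = 10,
    seed: int = 0,
    k: int = 10,
) -> EvaluationReport:
    """Repeated cross-validated evaluation with pooled confusion counts.

    ``y`` holds the binary labels (VF vs anything else); per repeat the
    splits and the per-fold undersampling are regenerated from derived
    seeds, test confusion counts are summed over folds, and the six
    metrics computed from the pooled counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    y_bin = np.where(y == POSITIVE, POSITIVE, "NVF")
    subject_ids = np.asarray(subject_ids)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    report = EvaluationReport(paradigm=paradigm, model=model, repeats=repeats)
    master = np.random.SeedSequence(seed)
    for rep_seq in master.spawn(repeats):
        split_seq, fold_master = rep_seq.spawn(2)
        if paradigm == "kfold10":
            folds = kfold_splits(y_bin, k=k, seed=int(split_seq.generate_state(1)[0]))
        elif paradigm == "loso":
            folds = loso_splits(subject_ids)
        else:
            raise ValueError("paradigm must be 'kfold10' or 'loso'")
        fold_seqs = fold_master.spawn(len(folds))
        pooled = ConfusionCounts(0, 0, 0, 0)
        all_idx = np.arange(y_bin.size)
        for i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            fs = int(fold_seqs[i].generate_state(1)[0])
            Xb, yb = undersample(X[train_idx], y_bin[train_idx], seed=fs)
            y_pred = fit_predict(Xb, yb, X[test_idx], model=model, seed=fs)
            pooled = pooled + _confusion(y_bin[test_idx], y_pred)
        report.confusions.append(pooled)
        report.per_repeat.append(metrics(pooled))
    return report
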