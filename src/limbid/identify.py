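"""Identification analysis: day-fold CV, classifiers, ROC/EER/AUC.

Closed-set identification assigns each probe to the enrolled class
with the highest posterior score; evaluation uses day-stratified
cross-validation (one fold per measurement day, so train and test
never share a day and day-specific physiological state cannot leak).
Open-set operation thresholds the winning posterior: the ROC is traced
by sweeping the threshold over the pooled genuine (true-class) and
impostor (other-class) score populations, from which the equal error
rate and the area under the curve are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cnn import Conv1dNetClassifier
from .features import extract_features
from .records import StudyData

__all__ = [
    "FoldPlan",
    "make_fold_plan",
    "iter_folds",
    "accumulate_days",
    "make_classifier",
    "ScoreSet",
    "train_and_score",
    "cross_validated_scores",
    "cross_validated_accuracy",
    "RocResult",
    "roc_open_set",
    "confusion",
    "scalability_curve",
    "EvalReport",
    "evaluate",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("rf", "lda", "knn", "svm", "cnn")


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """One fold per distinct measurement day, in day order."""

    days: tuple[int, ...]
    assignment: dict[int, int]  # day_index -> fold id

    @property
    def n_folds(self) -> int:
        return len(self.days)


def make_fold_plan(data: StudyData | pd.DataFrame) -> FoldPlan:
    """Deterministic day-fold plan: fold id = rank of the day label."""
    meta = data.meta if isinstance(data, StudyData) else data
    days = np.sort(meta["day_index"].unique())
    if days.size < 2:
        raise ValueError("day-fold cross-validation needs at least 2 distinct days")
    return FoldPlan(days=tuple(int(d) for d in days),
                    assignment={int(d): k for k, d in enumerate(days)})


def iter_folds(data: StudyData, plan: FoldPlan | None = None
               ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (train_idx, test_idx) per fold; asserts no shared day."""
    plan = plan or make_fold_plan(data)
    day_col = data.meta["day_index"].to_numpy()
    for d in plan.days:
        test = np.flatnonzero(day_col == d)
        train = np.flatnonzero(day_col != d)
        assert not set(day_col[train]) & set(day_col[test]), "day leakage across folds"
        yield train, test


def accumulate_days(data: StudyData, d: int) -> StudyData:
    """Subset to the first ``d`` day labels (in sorted label order)."""
    days = data.days
    if not (2 <= d <= days.size):
        raise ValueError(f"d must be in [2, {days.size}], got {d}")
    keep = set(days[:d].tolist())
    return data.subset(data.meta["day_index"].isin(keep).to_numpy())


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def make_classifier(kind: str, random_state: int | None = None, **overrides):
    """Instantiate one of the five reference classifiers.

    rf: 150 trees, Gini, at most 150 splits per tree, min leaf 1.
    lda: least-squares solver with a fixed small shrinkage ridge
    (feature count typically exceeds desk-scale sample counts).
    knn: k = 1, Euclidean, distance weighting (moot at k = 1 but kept
    so k stays configurable).  svm: degree-2 polynomial kernel, C = 1,
    one-vs-one multiclass with OVR-shaped decision values.  cnn: the
    in-package numpy convnet.
    """
    if kind == "rf":
        params = dict(
            n_estimators=150, criterion="gini", max_leaf_nodes=151,
            min_samples_leaf=1, random_state=random_state,
        )
    elif kind == "lda":
        params = dict(solver="lsqr", shrinkage=1e-3)
    elif kind == "knn":
        params = dict(n_neighbors=1, weights="distance", metric="euclidean")
    elif kind == "svm":
        params = dict(kernel="poly", degree=2, C=1.0,
                      decision_function_shape="ovr", random_state=random_state)
    elif kind == "cnn":
        params = dict(random_state=random_state)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; expected {CLASSIFIER_KINDS}")
    params.update(overrides)
    cls = {
        "rf": RandomForestClassifier,
        "lda": LinearDiscriminantAnalysis,
        "knn": KNeighborsClassifier,
        "svm": SVC,
        "cnn": Conv1dNetClassifier,
    }[kind]
    return cls(**params)


@dataclass
class ScoreSet:
    """Pooled per-sample scores of one or more evaluation folds."""

    classes: np.ndarray           # enrolled class labels, sorted
    y_true: np.ndarray            # true labels (may include unenrolled)
    y_pred: np.ndarray            # argmax predictions
    proba: np.ndarray             # (n, n_classes) posterior-like scores

    @property
    def accuracy(self) -> float:
        """Pooled closed-set accuracy in percent."""
        return float(np.mean(self.y_pred == self.y_true) * 100.0)

    def genuine_impostor(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled genuine (true-class) and impostor (other-class) scores.

        Samples whose true class is not enrolled contribute all their
        scores to the impostor population.
        """
        class_pos = {c: i for i, c in enumerate(self.classes)}
        genuine, impostor = [], []
        for i, label in enumerate(self.y_true):
            j = class_pos.get(label)
            if j is None:
                impostor.extend(self.proba[i])
            else:
                genuine.append(self.proba[i, j])
                impostor.extend(np.delete(self.proba[i], j))
        return np.asarray(genuine, dtype=float), np.asarray(impostor, dtype=float)

    @staticmethod
    def concatenate(parts: Sequence["ScoreSet"]) -> "ScoreSet":
        classes = parts[0].classes
        for p in parts[1:]:
            if not np.array_equal(p.classes, classes):
                raise ValueError("score sets must share the class list")
        return ScoreSet(
            classes=classes,
            y_true=np.concatenate([p.y_true for p in parts]),
            y_pred=np.concatenate([p.y_pred for p in parts]),
            proba=np.vstack([p.proba for p in parts]),
        )


def _posterior_scores(clf, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-like per-class scores in [0, 1] summing to 1 per row."""
    if hasattr(clf, "predict_proba"):
        return clf.classes_, np.asarray(clf.predict_proba(X), dtype=float)
    d = np.asarray(clf.decision_function(X), dtype=float)
    if d.ndim == 1:  # binary margin
        d = np.column_stack([-d, d])
    lo = d.min(axis=1, keepdims=True)
    span = d.max(axis=1, keepdims=True) - lo
    span[span == 0.0] = 1.0
    p = (d - lo) / span
    total = p.sum(axis=1, keepdims=True)
    total[total == 0.0] = 1.0
    return clf.classes_, p / total


def train_and_score(clf, X_train, y_train, X_test, y_test,
                    all_classes: np.ndarray | None = None) -> ScoreSet:
    """Fit a classifier and score every test sample.

    ``all_classes`` widens the score matrix to classes absent from the
    training fold (their score is 0); a test sample from such a class
    is scored against the enrolled classes and counted as an error.
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training fold must contain at least 2 classes")
    model = clone(clf)
    model.fit(np.asarray(X_train, dtype=float), y_train)
    fold_classes, proba = _posterior_scores(model, np.asarray(X_test, dtype=float))
    y_pred = fold_classes[np.argmax(proba, axis=1)]
    if all_classes is None:
        classes, wide = fold_classes, proba
    else:
        classes = np.asarray(all_classes)
        wide = np.zeros((proba.shape[0], classes.size))
        pos = {c: i for i, c in enumerate(classes)}
        for j, c in enumerate(fold_classes):
            wide[:, pos[c]] = proba[:, j]
    return ScoreSet(classes=classes, y_true=np.asarray(y_test),
                    y_pred=y_pred, proba=wide)


def cross_validated_scores(
    data: StudyData,
    selection: str = "ratio+limb",
    kind: str = "rf",
    seed: int | None = 0,
    classifier=None,
    **overrides,
) -> ScoreSet:
    """Pooled day-fold cross-validation scores for one configuration."""
    clf = classifier if classifier is not None else make_classifier(
        kind, random_state=seed, **overrides
    )
    X = extract_features(data, selection, layout="flat")
    y = data.meta["subject_id"].to_numpy()
    all_classes = np.unique(y)
    parts = [
        train_and_score(clf, X[tr], y[tr], X[te], y[te], all_classes=all_classes)
        for tr, te in iter_folds(data)
    ]
    return ScoreSet.concatenate(parts)


def cross_validated_accuracy(
    data: StudyData, selection: str = "ratio+limb", kind: str = "rf",
    seed: int | None = 0, **overrides,
) -> float:
    """Pooled day-fold accuracy in percent (micro over all folds)."""
    return cross_validated_scores(data, selection, kind, seed, **overrides).accuracy


# ---------------------------------------------------------------------------
# open-set ROC / EER / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Threshold sweep over pooled genuine/impostor score populations."""

    thresholds: np.ndarray
    far: np.ndarray   # impostor acceptance rate per threshold
    frr: np.ndarray   # genuine rejection rate per threshold
    eer: float        # percent
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "far": self.far, "frr": self.frr}
        )


def roc_open_set(scores: ScoreSet | tuple[np.ndarray, np.ndarray],
                 thresholds: np.ndarray | None = None) -> RocResult:
    """ROC, EER and AUC of open-set acceptance by score threshold.

    A score is accepted at threshold ``t`` iff ``score >= t``.
    FAR(t) is the accepted fraction of impostor scores, FRR(t) the
    rejected fraction of genuine scores.  The EER is found by linear
    interpolation between the adjacent thresholds where FAR crosses
    FRR; the AUC integrates (FAR, 1 - FRR) by the trapezoidal rule.
    """
    if isinstance(scores, ScoreSet):
        genuine, impostor = scores.genuine_impostor()
    else:
        genuine, impostor = (np.asarray(s, dtype=float) for s in scores)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need non-empty genuine and impostor score populations")
    if thresholds is None:
        thresholds = np.unique(np.concatenate([genuine, impostor]))
    else:
        thresholds = np.sort(np.unique(np.asarray(thresholds, dtype=float)))
    # guarantee the (FAR=1, FRR=0) and (FAR=0, FRR=1) endpoints
    lo = thresholds[0] - 1.0
    hi = thresholds[-1] + 1.0
    t = np.concatenate([[lo], thresholds, [hi]])
    gs = np.sort(genuine)
    is_ = np.sort(impostor)
    far = 1.0 - np.searchsorted(is_, t, side="left") / is_.size
    frr = np.searchsorted(gs, t, side="left") / gs.size

    d = far - frr  # decreasing from +1 to -1
    if np.any(d == 0.0):
        k = int(np.flatnonzero(d == 0.0)[0])
        eer = far[k]
    else:
        k = int(np.flatnonzero(d < 0.0)[0]) - 1
        lam = d[k] / (d[k] - d[k + 1])
        eer = far[k] + lam * (far[k + 1] - far[k])
    tar = 1.0 - frr
    order = np.lexsort((tar, far))  # ties in FAR ordered by TAR: monotone polyline
    auc = float(np.trapezoid(tar[order], far[order]))
    return RocResult(thresholds=t, far=far, frr=frr, eer=float(eer * 100.0), auc=auc)


def confusion(scores: ScoreSet) -> pd.DataFrame:
    """Class-by-class prediction counts; trace/total equals accuracy."""
    labels = list(scores.classes)
    extra = sorted(set(scores.y_true) - set(labels))
    rows = labels + extra
    mat = pd.DataFrame(0, index=pd.Index(rows, name="true"),
                       columns=pd.Index(labels, name="predicted"))
    for t_lab, p_lab in zip(scores.y_true, scores.y_pred):
        mat.loc[t_lab, p_lab] += 1
    return mat


# ---------------------------------------------------------------------------
# scalability
# ---------------------------------------------------------------------------

def _accuracy_model(n: np.ndarray, a_inf: float, b: float, c: float) -> np.ndarray:
    # a(n) = a_inf + b * exp(-c * ln n) = a_inf + b * n^(-c)
    return a_inf + b * np.exp(-c * np.log(n))


def fit_accuracy_asymptote(counts: np.ndarray, accuracies: np.ndarray
                           ) -> tuple[float, float, float]:
    """Least-squares fit of ``a(n) = a_inf + b * n^(-c)``; returns (a_inf, b, c).

    Constrained to a decay toward an asymptote in the valid accuracy
    range (``0 <= a_inf <= 100``, ``b >= 0``, ``c > 0``); an unbounded
    fit is ill-posed on flat or near-saturated curves.
    """
    counts = np.asarray(counts, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 cohort sizes to fit the asymptote")
    p0 = (
        min(max(accuracies[-1], 0.0), 100.0),
        max(accuracies[0] - accuracies[-1], 1e-3),
        1.0,
    )
    popt, _ = curve_fit(
        _accuracy_model, counts, accuracies, p0=p0,
        bounds=([0.0, 0.0, 1e-9], [100.0, np.inf, np.inf]),
        maxfev=20000,
    )
    return tuple(float(v) for v in popt)


def scalability_curve(
    data: StudyData,
    subject_counts: Sequence[int],
    n_repeats: int = 10,
    kind: str = "rf",
    selection: str = "ratio+limb",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Accuracy vs enrolled-cohort size with random subject subsets.

    For each count, ``n_repeats`` random subject subsets are drawn
    (seeded) and day-fold accuracy computed; the full cohort is
    evaluated once (no subset randomness).  A decaying power law
    ``a(n) = a_inf + b * n^(-c)`` is fitted to the mean accuracies and
    its asymptote reported.
    """
    subjects = np.sort(data.subjects)
    rng = np.random.default_rng(seed)
    rows = []
    for count in subject_counts:
        if count > subjects.size:
            raise ValueError(
                f"requested {count} subjects but only {subjects.size} available"
            )
        reps = 1 if count == subjects.size else n_repeats
        accs = []
        for _ in range(reps):
            chosen = set(rng.choice(subjects, size=count, replace=False).tolist())
            sub = data.subset(data.meta["subject_id"].isin(chosen).to_numpy())
            accs.append(cross_validated_accuracy(sub, selection, kind, seed=seed))
        accs = np.asarray(accs)
        rows.append(
            {
                "n_subjects": count,
                "accuracy_mean": accs.mean(),
                "accuracy_sd": accs.std(ddof=1) if accs.size > 1 else 0.0,
                "n_repeats": reps,
            }
        )
    curve = pd.DataFrame(rows)
    a_inf, b, c = fit_accuracy_asymptote(
        curve["n_subjects"].to_numpy(), curve["accuracy_mean"].to_numpy()
    )
    return curve, {"a_inf": a_inf, "b": b, "c": c}


# ---------------------------------------------------------------------------
# one-call evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Everything measured for one feature/model/day-count configuration."""

    selection: str
    kind: str
    n_days: int
    accuracy: float            # percent
    eer: float                 # percent
    auc: float
    confusion: pd.DataFrame
    roc: pd.DataFrame
    n_test: int
    day_curve: pd.DataFrame | None = field(default=None)


def evaluate(
    data: StudyData,
    selection: str = "ratio+limb",
    kind: str = "rf",
    days: int | None = None,
    seed: int | None = 0,
    day_curve: bool = False,
    **overrides,
) -> EvalReport:
    """Day-fold evaluation of one configuration, with optional day curve."""
    if days is not None:
        data = accumulate_days(data, days)
    scores = cross_validated_scores(data, selection, kind, seed, **overrides)
    roc = roc_open_set(scores)
    curve = None
    if day_curve:
        rows = []
        for d in range(2, len(data.days) + 1):
            acc = cross_validated_accuracy(
                accumulate_days(data, d), selection, kind, seed, **overrides
            )
            rows.append({"n_days": d, "accuracy": acc})
        curve = pd.DataFrame(rows)
    return EvalReport(
        selection=selection,
        kind=kind,
        n_days=len(data.days),
        accuracy=scores.accuracy,
        eer=roc.eer,
        auc=roc.auc,
        confusion=confusion(scores),
        roc=roc.to_frame(),
        n_test=scores.y_true.size,
        day_curve=curve,
    )
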