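"""Evaluation protocol: stratified splits, greedy AUC feature selection,
test-set AUC, and the repeated end-to-end experiment.

Per repeat: samples are split 60/20/20 (stratified, seeded), the whole
scoring + walk + activity machinery is refit on the training samples
only, the top-ranked pathway features enter a greedy forward selection
driven by stratified 10-fold cross-validated AUC, and the optimised
classifier is scored on the untouched test split.  The validation split
is held out and unused by default.  Ten repeats with derived seeds give
the mean test AUC and the selection frequency of each pathway.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted

from .activity import EDRWActivity, PathwayActivityMatrix, rank_top_pathways

logger = logging.getLogger(__name__)

__all__ = [
    "SplitIndices",
    "RepeatRecord",
    "ExperimentResult",
    "make_classifier",
    "auc_score",
    "stratified_split",
    "greedy_forward_selection",
    "evaluate_test_auc",
    "EDRWClassifier",
    "run_repeated_experiment",
    "repeated_holdout_on_activity",
]

CLASSIFIERS = ("nb", "knn", "lr")


@dataclass
class SplitIndices:
    """Disjoint train/validation/test sample positions covering the cohort."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int | None = None


@dataclass
class RepeatRecord:
    repeat: int
    seed: int
    selected: list[str]
    cv_trajectory: list[float]
    test_auc: float
    ranked: list[str] = field(default_factory=list, repr=False)


@dataclass
class ExperimentResult:
    repeats: list[RepeatRecord]

    @property
    def test_aucs(self) -> np.ndarray:
        return np.array([rec.test_auc for rec in self.repeats])

    @property
    def mean_auc(self) -> float:
        return float(self.test_aucs.mean())

    @property
    def sd_auc(self) -> float:
        if len(self.repeats) < 2:
            return 0.0
        return float(self.test_aucs.std(ddof=1))

    def selection_frequency(self) -> Counter:
        freq: Counter = Counter()
        for rec in self.repeats:
            freq.update(rec.selected)
        return freq

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": [rec.repeat for rec in self.repeats],
                "seed": [rec.seed for rec in self.repeats],
                "test_auc": [rec.test_auc for rec in self.repeats],
                "cv_auc": [rec.cv_trajectory[-1] for rec in self.repeats],
                "n_selected": [len(rec.selected) for rec in self.repeats],
                "selected_pathways": [";".join(rec.selected) for rec in self.repeats],
            }
        )


def make_classifier(name: str, seed: int | None = None):
    """Base classifiers named in the protocol (NB, KNN with k=5, LR)."""
    if name == "nb":
        return GaussianNB()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "lr":
        return LogisticRegression(max_iter=1000)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _class1_scores(estimator, X) -> np.ndarray:
    proba = estimator.predict_proba(np.asarray(X))
    col = list(estimator.classes_).index(1)
    return proba[:, col]


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve of class-1 scores."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


def stratified_split(
    labels, fractions=(0.6, 0.2, 0.2), seed: int | None = None
) -> SplitIndices:
    """Per-class 60/20/20 split by seeded shuffle.

    Within each class of size n, n_train = round(0.6 n),
    n_val = round(0.2 n), and the remainder is the test set.
    """
    y = np.asarray(labels)
    f_train, f_val, _ = fractions
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in sorted(np.unique(y).tolist()):
        idx = np.flatnonzero(y == cls)
        n = len(idx)
        if n < 5:
            raise ValueError(f"class {cls} has only {n} samples (need >= 5)")
        n_train = int(np.rint(f_train * n))
        n_val = int(np.rint(f_val * n))
        n_test = n - n_train - n_val
        if n_test <= 0:
            raise ValueError(f"class {cls}: no samples left for the test set")
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        val.append(perm[n_train : n_train + n_val])
        test.append(perm[n_train + n_val :])
    return SplitIndices(
        train=np.sort(np.concatenate(train)),
        validation=np.sort(np.concatenate(val)),
        test=np.sort(np.concatenate(test)),
        seed=seed,
    )


def _cv_mean_auc(X, y, classifier: str, folds: int, seed: int | None) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        est = make_classifier(classifier)
        est.fit(X[tr], y[tr])
        aucs.append(auc_score(y[te], _class1_scores(est, X[te])))
    return float(np.mean(aucs))


def _activity_frame(activity) -> pd.DataFrame:
    """Accept a PathwayActivityMatrix (pathways x samples) or DataFrame
    already oriented samples x pathways."""
    if isinstance(activity, PathwayActivityMatrix):
        return activity.frame.T
    return activity


def greedy_forward_selection(
    activity,
    ranked: list[str],
    labels,
    train_idx=None,
    classifier: str = "nb",
    folds: int = 10,
    seed: int | None = None,
) -> tuple[list[str], list[float]]:
    """Greedy forward selection of pathway features by CV AUC.

    The ranked list is walked in order; the first pathway always
    initialises the feature set, and each later candidate is kept only if
    the mean stratified-k-fold AUC strictly increases.  The same seeded
    fold assignment is reused for every candidate so comparisons are
    paired.  Returns the selected ids and the strictly increasing AUC
    trajectory of kept features.
    """
    if not ranked:
        raise ValueError("ranked pathway list is empty")
    frame = _activity_frame(activity)
    y = np.asarray(labels)
    if train_idx is not None:
        train_idx = np.asarray(train_idx)
        frame = frame.iloc[train_idx]
        y = y[train_idx]
    counts = np.bincount(y)
    min_class = counts[counts > 0].min()
    if folds > min_class:
        raise ValueError(
            f"{folds}-fold CV impossible: smallest class has {min_class} "
            f"training samples (need >= {folds})"
        )

    selected = [ranked[0]]
    best = _cv_mean_auc(
        frame[selected].to_numpy(), y, classifier, folds, seed
    )
    trajectory = [best]
    for pid in ranked[1:]:
        candidate = selected + [pid]
        score = _cv_mean_auc(
            frame[candidate].to_numpy(), y, classifier, folds, seed
        )
        if score > best:
            selected, best = candidate, score
            trajectory.append(best)
    return selected, trajectory


def evaluate_test_auc(
    activity,
    features: list[str],
    labels,
    train_idx,
    test_idx,
    classifier: str = "nb",
) -> float:
    """Fit on training rows of the selected features, AUC on test rows."""
    if not features:
        raise ValueError("feature set is empty")
    frame = _activity_frame(activity)
    y = np.asarray(labels)
    train_idx, test_idx = np.asarray(train_idx), np.asarray(test_idx)
    if len(set(np.unique(y[test_idx]))) < 2:
        raise ValueError("test set contains a single class: AUC undefined")
    est = make_classifier(classifier)
    est.fit(frame[features].iloc[train_idx].to_numpy(), y[train_idx])
    scores = _class1_scores(est, frame[features].iloc[test_idx].to_numpy())
    return auc_score(y[test_idx], scores)


class EDRWClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end pathway-activity classifier.

    ``fit(X, y)`` (X: samples x genes DataFrame) fits an
    :class:`~edrw.activity.EDRWActivity` transformer on the training
    samples, greedily selects pathway features by cross-validated AUC,
    and fits the base classifier on the selected activities;
    ``predict_proba`` transforms new samples with the training-fitted
    pipeline.
    """

    def __init__(
        self,
        networks=None,
        pathways=None,
        classifier: str = "knn",
        restart_prob: float = 0.5,
        alpha: float = 0.05,
        top_k: int = 50,
        cv_folds: int = 10,
        w0_orientation: str = "literal",
        sign_adjust: bool = False,
        random_state: int | None = None,
    ):
        self.networks = networks
        self.pathways = pathways
        self.classifier = classifier
        self.restart_prob = restart_prob
        self.alpha = alpha
        self.top_k = top_k
        self.cv_folds = cv_folds
        self.w0_orientation = w0_orientation
        self.sign_adjust = sign_adjust
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.activity_ = EDRWActivity(
            networks=self.networks,
            pathways=self.pathways,
            restart_prob=self.restart_prob,
            alpha=self.alpha,
            top_k=self.top_k,
            w0_orientation=self.w0_orientation,
            sign_adjust=self.sign_adjust,
        ).fit(X, y)
        features = self.activity_.transform(X)
        self.selected_pathways_, self.cv_trajectory_ = greedy_forward_selection(
            features,
            list(self.activity_.feature_names_),
            y,
            classifier=self.classifier,
            folds=self.cv_folds,
            seed=self.random_state,
        )
        self.estimator_ = make_classifier(self.classifier)
        self.estimator_.fit(features[self.selected_pathways_].to_numpy(), y)
        self.classes_ = np.unique(y)
        return self

    def _selected_features(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.activity_.transform(X)[self.selected_pathways_].to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator_.predict_proba(self._selected_features(X))

    def predict(self, X) -> np.ndarray:
        return self.estimator_.predict(self._selected_features(X))

    def decision_function(self, X) -> np.ndarray:
        return _class1_scores(self.estimator_, self._selected_features(X))


def _derive_seeds(base_seed: int, repeats: int) -> list[int]:
    state = np.random.SeedSequence(base_seed).generate_state(repeats, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_repeated_experiment(
    expression: pd.DataFrame,
    labels: pd.Series,
    networks,
    pathways,
    classifier: str = "knn",
    restart_prob: float = 0.5,
    repeats: int = 10,
    base_seed: int = 0,
    top_k: int = 50,
    alpha: float = 0.05,
    cv_folds: int = 10,
    w0_orientation: str = "literal",
    sign_adjust: bool = False,
) -> ExperimentResult:
    """Repeat the split/fit/select/test protocol with derived seeds.

    ``expression`` is genes x samples (missing values are imputed once up
    front); everything downstream — scoring, entropy, walk, ranking and
    selection — is recomputed per repeat from that repeat's training
    split only.
    """
    from .preprocess import impute_row_mean

    if expression.isna().any().any():
        expression = impute_row_mean(expression).frame
    X = expression.T
    y = np.asarray(labels)
    records = []
    for i, seed in enumerate(_derive_seeds(base_seed, repeats)):
        split = stratified_split(y, seed=seed)
        clf = EDRWClassifier(
            networks=networks,
            pathways=pathways,
            classifier=classifier,
            restart_prob=restart_prob,
            alpha=alpha,
            top_k=top_k,
            cv_folds=cv_folds,
            w0_orientation=w0_orientation,
            sign_adjust=sign_adjust,
            random_state=seed,
        )
        clf.fit(X.iloc[split.train], y[split.train])
        if len(set(y[split.test])) < 2:
            raise ValueError("test split contains a single class")
        scores = clf.decision_function(X.iloc[split.test])
        test_auc = auc_score(y[split.test], scores)
        records.append(
            RepeatRecord(
                repeat=i,
                seed=seed,
                selected=list(clf.selected_pathways_),
                cv_trajectory=list(clf.cv_trajectory_),
                test_auc=test_auc,
                ranked=list(clf.activity_.feature_names_),
            )
        )
        logger.info("repeat %d: test AUC %.4f (%d features)",
                    i, test_auc, len(clf.selected_pathways_))
    return ExperimentResult(repeats=records)


def repeated_holdout_on_activity(
    activity: PathwayActivityMatrix,
    labels,
    classifier: str = "nb",
    repeats: int = 10,
    base_seed: int = 0,
    top_k: int = 50,
    cv_folds: int = 10,
) -> ExperimentResult:
    """Repeat ranking/selection/testing on a fixed activity matrix.

    Ranking and selection still use each repeat's training samples only,
    but the activity values themselves are taken as given (the lighter
    protocol backing ``edrw classify``; the full per-repeat refit lives in
    :func:`run_repeated_experiment`).
    """
    y = np.asarray(labels)
    records = []
    for i, seed in enumerate(_derive_seeds(base_seed, repeats)):
        split = stratified_split(y, seed=seed)
        ranked = rank_top_pathways(activity, y, train_idx=split.train, k=top_k)
        selected, trajectory = greedy_forward_selection(
            activity, ranked, y, train_idx=split.train,
            classifier=classifier, folds=cv_folds, seed=seed,
        )
        test_auc = evaluate_test_auc(
            activity, selected, y, split.train, split.test, classifier=classifier
        )
        records.append(
            RepeatRecord(
                repeat=i, seed=seed, selected=selected,
                cv_trajectory=trajectory, test_auc=test_auc, ranked=ranked,
            )
        )
    return ExperimentResult(repeats=records)
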