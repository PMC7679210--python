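"""Per-treatment binary classification from topic distributions.

Each treatment outcome gets its own binary k-nearest-neighbour classifier
over the document-topic matrix, evaluated by stratified cross-validation
with accuracy (TP+TN)/N, against a prevalence-matched random baseline
whose expected accuracy is p^2 + (1-p)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .textprep import TokenStream
from .topic_model import TopicModel, infer_theta

#: treatment outcome codes, in the study's order
TREATMENTS = ("O1", "O2", "O3", "O4", "O5", "O6", "O7", "O8", "O9")

TREATMENT_NAMES = {
    "O1": "orthopedic referral",
    "O2": "discharge",
    "O3": "injection",
    "O4": "nutritionist",
    "O5": "physiotherapy",
    "O6": "diagnostic imaging",
    "O7": "surgery",
    "O8": "review appointment",
    "O9": "any other referral",
}


@dataclass
class TriageDataset:
    X: np.ndarray  # D x K rows on the simplex
    Y: np.ndarray  # D x 9 binary outcomes
    doc_ids: list[str]
    treatments: tuple[str, ...] = TREATMENTS
    n_unlabeled: int = 0

    def column(self, treatment: str) -> np.ndarray:
        if treatment not in self.treatments:
            raise KeyError(f"unknown treatment code: {treatment!r}")
        return self.Y[:, self.treatments.index(treatment)]

    def prevalence(self, treatment: str) -> float:
        return float(self.column(treatment).mean())


def make_dataset(
    model: TopicModel,
    streams: Sequence[TokenStream],
    labels: Mapping[str, Sequence[str]],
    use_training_theta: bool = True,
) -> TriageDataset:
    """Pair each labeled document's topic distribution with its outcomes.

    Documents without a label entry are excluded (counted); unknown
    treatment codes are rejected.
    """
    for doc_id, codes in labels.items():
        for code in codes:
            if code not in TREATMENTS:
                raise KeyError(f"unknown treatment code {code!r} for doc {doc_id!r}")
    stream_by_id = {s.doc_id: s for s in streams}
    for doc_id in labels:
        if doc_id not in stream_by_id:
            raise KeyError(f"labeled document {doc_id!r} has no token stream")

    theta_by_id = dict(zip(model.doc_ids, model.theta))
    rows_x, rows_y, kept_ids = [], [], []
    n_unlabeled = 0
    for s in streams:
        if s.doc_id not in labels:
            n_unlabeled += 1
            continue
        if use_training_theta and s.doc_id in theta_by_id:
            x = theta_by_id[s.doc_id]
        else:
            x = infer_theta(model, s.surfaces())
        y = np.array(
            [1 if t in labels[s.doc_id] else 0 for t in TREATMENTS], dtype=np.int64
        )
        rows_x.append(x)
        rows_y.append(y)
        kept_ids.append(s.doc_id)
    if not rows_x:
        raise ValueError("no labeled documents: empty triage dataset")
    return TriageDataset(
        np.vstack(rows_x), np.vstack(rows_y), kept_ids, TREATMENTS, n_unlabeled
    )


@dataclass
class CVResult:
    treatment: str
    fold_accuracies: list[float]
    mean_accuracy: float
    baseline_accuracy: float
    seed: int
    confusion: tuple[int, int, int, int]  # TP, TN, FP, FN pooled over folds
    degenerate_folds: list[int] = field(default_factory=list)

    @property
    def accuracy_from_confusion(self) -> float:
        tp, tn, fp, fn = self.confusion
        return (tp + tn) / (tp + tn + fp + fn)


def crossval_knn(
    ds: TriageDataset,
    treatment: str,
    k: int = 5,
    folds: int = 10,
    seed: int = 0,
    metric: str = "euclidean",
) -> CVResult:
    """Stratified cross-validated kNN accuracy for one treatment column."""
    y = ds.column(treatment)
    X = ds.X
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds number of documents {len(y)}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes = np.unique(y)
    degenerate_all = len(classes) < 2

    fold_accs: list[float] = []
    degenerate: list[int] = []
    tp = tn = fp = fn = 0
    if degenerate_all:
        # constant labels: every classifier predicts the single class
        splitter = StratifiedKFold(folds, shuffle=True, random_state=seed)
        split = splitter.split(X, np.arange(len(y)) % 2)  # dummy stratification
    else:
        splitter = StratifiedKFold(folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)

    for i, (train_idx, test_idx) in enumerate(split):
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            pred = np.full(len(test_idx), y_train[0])
            degenerate.append(i)
        else:
            clf = KNeighborsClassifier(n_neighbors=k, metric=metric)
            clf.fit(X[train_idx], y_train)
            pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        fold_accs.append(float((pred == truth).mean()))
        tp += int(((pred == 1) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())

    return CVResult(
        treatment=treatment,
        fold_accuracies=fold_accs,
        mean_accuracy=float(np.mean(fold_accs)),
        baseline_accuracy=stratified_random_baseline(ds, treatment),
        seed=seed,
        confusion=(tp, tn, fp, fn),
        degenerate_folds=degenerate,
    )


def stratified_random_baseline(
    ds: TriageDataset,
    treatment: str,
    monte_carlo: bool = False,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Expected accuracy of prevalence-matched Bernoulli prediction.

    Analytic closed form p^2 + (1-p)^2; ``monte_carlo=True`` estimates the
    same quantity by simulation instead.
    """
    p = ds.prevalence(treatment)
    return expected_baseline_accuracy(p, monte_carlo, n_draws, seed)


def expected_baseline_accuracy(
    p: float, monte_carlo: bool = False, n_draws: int = 1_000_000, seed: int = 0
) -> float:
    if not monte_carlo:
        return p * p + (1.0 - p) * (1.0 - p)
    rng = np.random.default_rng(seed)
    truth = rng.random(n_draws) < p
    pred = rng.random(n_draws) < p
    return float((truth == pred).mean())
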