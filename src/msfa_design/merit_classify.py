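"""Classification merit functions: kNN, SVM, spectral angle mapper.

The merit of a candidate filter design is the accuracy with which tissue
classes can be recovered from the band measurements.  kNN and SVM are
supervised (trained on the 4:1 training split); the spectral angle mapper
(SAM) is reference-based and scale invariant: a spectrum is assigned the
class of the reference vector forming the smallest angle

    theta(t, r) = arccos( <t, r> / (|t| |r|) ).

Uncertainty across biological replicates is summarized by a per-patient
95% confidence interval: accuracies are first averaged within patient and
a t-interval is formed over the patient means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .filters import FilterSet, featurize
from .synthetic_spectra import LabeledSpectraDataset

__all__ = [
    "FeatureTable",
    "ClassifierSpec",
    "ClassificationResult",
    "knn_classify",
    "svm_classify",
    "sam_angle",
    "sam_classify",
    "class_mean_references",
    "accuracy",
    "per_patient_ci",
    "stratified_folds",
]


class ModelError(ValueError):
    pass


class UndefinedAngleError(ValueError):
    """Spectral angle is undefined for a zero vector."""


@dataclass
class FeatureTable:
    """Band features with class labels and patient ids."""

    X: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,) of str
    patients: np.ndarray  # (n_samples,) of str
    class_names: Tuple[str, ...]

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.patients = np.asarray(self.patients, dtype=object)
        if not (len(self.X) == len(self.labels) == len(self.patients)):
            raise ValueError("feature/label/patient lengths differ")
        unknown = set(self.labels) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
        self.class_names = tuple(self.class_names)

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_dataset(cls, dataset: LabeledSpectraDataset, fs: FilterSet) -> "FeatureTable":
        return cls(
            X=featurize(dataset, fs),
            labels=np.array([s.class_label for s in dataset.spectra], dtype=object),
            patients=np.array([s.patient_id for s in dataset.spectra], dtype=object),
            class_names=tuple(dataset.class_names),
        )

    def subset(self, idx) -> "FeatureTable":
        return FeatureTable(self.X[idx], self.labels[idx], self.patients[idx],
                            self.class_names)


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family and hyperparameters."""

    kind: str = "knn"  # knn | svm | sam
    k: int = 5
    C: float = 1000.0
    kernel: str = "rbf"

    def __post_init__(self):
        if self.kind not in ("knn", "svm", "sam"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class ClassificationResult:
    predicted: np.ndarray
    accuracy: float
    per_class: Optional[Dict[str, float]] = None
    per_patient: Optional[Dict[str, float]] = None


def _result(pred: np.ndarray, test: FeatureTable) -> ClassificationResult:
    correct = pred == test.labels
    per_class = {}
    for c in test.class_names:
        m = test.labels == c
        if m.any():
            per_class[c] = float(correct[m].mean())
    per_patient = {}
    for p in np.unique(test.patients):
        m = test.patients == p
        per_patient[p] = float(correct[m].mean())
    return ClassificationResult(
        predicted=pred,
        accuracy=float(correct.mean()),
        per_class=per_class,
        per_patient=per_patient,
    )


def knn_classify(train: FeatureTable, test: FeatureTable, k: int = 5) -> ClassificationResult:
    """k-nearest-neighbor classification by Euclidean distance.

    Majority vote among the k nearest training points; vote ties are
    broken by the smaller mean distance to the tied class's voters, then
    by class order.
    """
    if len(train) == 0:
        raise ModelError("empty training set")
    if k > len(train):
        raise ModelError(f"k={k} exceeds training size {len(train)}")
    nn = NearestNeighbors(n_neighbors=k).fit(train.X)
    dist, idx = nn.kneighbors(test.X)
    class_order = {c: i for i, c in enumerate(train.class_names)}
    pred = np.empty(len(test), dtype=object)
    for i in range(len(test)):
        votes: Dict[str, List[float]] = {}
        for d, j in zip(dist[i], idx[i]):
            votes.setdefault(train.labels[j], []).append(d)
        # (-count, mean distance, class order): most votes, then closest
        pred[i] = min(
            votes,
            key=lambda c: (-len(votes[c]), float(np.mean(votes[c])), class_order[c]),
        )
    return _result(pred, test)


def svm_classify(
    train: FeatureTable, test: FeatureTable, spec: ClassifierSpec = ClassifierSpec("svm")
) -> ClassificationResult:
    """Multi-class SVM with an RBF kernel (C = 1000 by default)."""
    if len(set(train.labels)) < 2:
        raise ModelError("SVM needs at least two classes in the training set")
    clf = SVC(C=spec.C, kernel=spec.kernel, gamma="scale", random_state=0)
    clf.fit(train.X, train.labels.astype(str))
    pred = clf.predict(test.X).astype(object)
    return _result(pred, test)


def sam_angle(t: np.ndarray, r: np.ndarray) -> float:
    """Spectral angle between two vectors, in radians, clamped to [0, pi]."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if t.shape != r.shape:
        raise ValueError("vectors must have the same length")
    nt = np.linalg.norm(t)
    nr = np.linalg.norm(r)
    if nt == 0 or nr == 0:
        raise UndefinedAngleError("spectral angle undefined for a zero vector")
    return float(np.arccos(np.clip(np.dot(t, r) / (nt * nr), -1.0, 1.0)))


def class_mean_references(table: FeatureTable) -> Dict[str, np.ndarray]:
    """Per-class mean feature vectors, the default SAM references."""
    return {
        c: table.X[table.labels == c].mean(axis=0)
        for c in table.class_names
        if (table.labels == c).any()
    }


def sam_classify(
    references: Mapping[str, np.ndarray], test: FeatureTable
) -> ClassificationResult:
    """Assign each row the class of its minimum-angle reference.

    Angle ties resolve to the first class in the reference order.
    """
    ref_names = list(references)
    R = np.array([references[c] for c in ref_names], dtype=float)
    norms = np.linalg.norm(R, axis=1)
    if np.any(norms == 0):
        raise UndefinedAngleError("a reference vector is zero")
    tn = np.linalg.norm(test.X, axis=1)
    if np.any(tn == 0):
        raise UndefinedAngleError("a test vector is zero")
    cosines = (test.X @ R.T) / np.outer(tn, norms)
    angles = np.arccos(np.clip(cosines, -1.0, 1.0))
    pred = np.array([ref_names[j] for j in np.argmin(angles, axis=1)], dtype=object)
    return _result(pred, test)


def accuracy(pred: Sequence, truth: Sequence) -> float:
    """Fraction of correctly classified items."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean(pred == truth))


def per_patient_ci(
    values: Sequence[float],
    patient_ids: Sequence,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Mean and t-interval half-width over per-patient averages.

    Per-item values (accuracies or errors) are first averaged within each
    patient; the returned interval is mean +/- t_{(1+level)/2, m-1} * sd / sqrt(m)
    over the m patient means.
    """
    values = np.asarray(values, dtype=float)
    patient_ids = np.asarray(patient_ids, dtype=object)
    patients = np.unique(patient_ids)
    if len(patients) < 2:
        raise ModelError("per-patient CI needs at least two patients")
    means = np.array([values[patient_ids == p].mean() for p in patients])
    m = len(means)
    mean = float(means.mean())
    if level <= 0:
        return mean, 0.0
    sd = float(means.std(ddof=1))
    t = stats.t.ppf(0.5 + level / 2.0, df=m - 1)
    return mean, float(t * sd / np.sqrt(m))


def stratified_folds(
    labels: Sequence, n_folds: int = 5, rng_seed: int = 0
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified K-fold (train_idx, test_idx) pairs."""
    labels = np.asarray(labels, dtype=object)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels.astype(str))]
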