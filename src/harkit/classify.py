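"""k-nearest-neighbour activity classification under the Manhattan metric.

The classifier follows the emulated study: per-sensor feature vectors,
Manhattan (city-block) distance, k selected by leave-one-out accuracy
(k = 1 in practice), and a random stratified learning/test split.  Ties
are resolved deterministically: equal distances prefer the lower training
row index, and tied votes go to the tied class owning the nearest
neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import HarkitError


@dataclass
class LabeledDataset:
    """Feature matrix with aligned labels and subject ids for one sensor."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    sensor: str

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise HarkitError("rows, labels and subject ids must align")

    def __len__(self) -> int:
        return len(self.X)

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.subjects[idx], self.sensor)


@dataclass
class SplitSpec:
    """Stratified learning/test split: ``n_train`` rows drawn without
    replacement, proportionally per activity."""

    n_train: int = 2400
    seed: int = 0
    stratify: bool = True


def manhattan(a: np.ndarray, b: np.ndarray) -> float:
    """City-block distance sum(|a_i - b_i|)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise HarkitError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def _vote(labels_sorted: np.ndarray, k: int):
    """Majority vote among the k nearest (pre-sorted) labels.

    Vote ties go to the tied class whose nearest member comes first.
    """
    top = labels_sorted[:k]
    classes, counts = np.unique(top, return_counts=True)
    best = counts.max()
    tied = set(classes[counts == best].tolist())
    for lab in top:
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def knn_classify(train: LabeledDataset, query: np.ndarray, k: int = 1):
    """Label of ``query`` by majority vote of its k nearest training rows.

    Distance ties are broken toward the lower training-row index (stable
    sort), so predictions are reproducible under any permutation of
    equidistant rows' content.
    """
    if len(train) == 0:
        raise HarkitError("training set is empty")
    if k > len(train):
        raise HarkitError(f"k={k} exceeds the training-set size {len(train)}")
    d = np.abs(train.X - np.asarray(query, dtype=float)).sum(axis=1)
    order = np.argsort(d, kind="stable")
    return _vote(train.y[order], k)


def knn_predict(train: LabeledDataset, X: np.ndarray, k: int = 1) -> np.ndarray:
    """Vectorized :func:`knn_classify` over the rows of ``X``."""
    if len(train) == 0:
        raise HarkitError("training set is empty")
    if k > len(train):
        raise HarkitError(f"k={k} exceeds the training-set size {len(train)}")
    d = cdist(np.asarray(X, dtype=float), train.X, metric="cityblock")
    order = np.argsort(d, axis=1, kind="stable")
    return np.array([_vote(train.y[order[i]], k) for i in range(len(X))])


def loo_select_k(data: LabeledDataset, k_candidates=(1, 3, 5, 7)
                 ) -> tuple[int, dict[int, float]]:
    """Leave-one-out accuracy per candidate k; best k (lower wins ties).

    Every row is classified from all remaining rows; the distance and vote
    tie rules match :func:`knn_classify` with the held-out row removed.
    """
    n = len(data)
    if n < 2:
        raise HarkitError("leave-one-out needs at least 2 rows")
    for k in k_candidates:
        if k >= n:
            raise HarkitError(f"candidate k={k} must be < dataset size {n}")
    d = cdist(data.X, data.X, metric="cityblock")
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    accuracies: dict[int, float] = {}
    for k in k_candidates:
        correct = sum(
            _vote(data.y[order[i]], k) == data.y[i] for i in range(n))
        accuracies[int(k)] = correct / n
    best_k = min(accuracies, key=lambda k: (-accuracies[k], k))
    return best_k, accuracies


def split_train_test(data: LabeledDataset, spec: SplitSpec
                     ) -> tuple[LabeledDataset, LabeledDataset, np.ndarray]:
    """Seeded stratified split into (train, test, train_index).

    The training set has exactly ``n_train`` rows drawn without
    replacement; with stratification the per-class allocation is
    proportional to class frequency (largest-remainder rounding).  The
    test set is the complement.
    """
    n = len(data)
    if not 0 < spec.n_train < n:
        raise HarkitError(f"n_train must lie in (0, {n}), got {spec.n_train}")
    rng = np.random.default_rng(spec.seed)
    if not spec.stratify:
        train_idx = np.sort(rng.choice(n, size=spec.n_train, replace=False))
    else:
        classes = np.unique(data.y)
        counts = np.array([(data.y == c).sum() for c in classes])
        exact = spec.n_train * counts / n
        alloc = np.floor(exact).astype(int)
        remainder = exact - alloc
        short = spec.n_train - alloc.sum()
        for c in np.argsort(-remainder, kind="stable")[:short]:
            alloc[c] += 1
        # a class cannot contribute more rows than it has
        over = alloc - counts
        if (over > 0).any():
            surplus = over.clip(min=0).sum()
            alloc = np.minimum(alloc, counts)
            room = counts - alloc
            for c in np.argsort(-room, kind="stable"):
                give = min(surplus, room[c])
                alloc[c] += give
                surplus -= give
                if surplus == 0:
                    break
        picks = []
        for c, cls in enumerate(classes):
            rows = np.flatnonzero(data.y == cls)
            picks.append(rng.choice(rows, size=alloc[c], replace=False))
        train_idx = np.sort(np.concatenate(picks))
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return data.take(train_idx), data.take(np.flatnonzero(~mask)), train_idx
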