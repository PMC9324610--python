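"""Per-subject reference stores and personalized inference.

A :class:`ReferenceStore` holds one subject's labeled reference vectors
(deep embeddings or scaled engineered features — the inference machinery is
identical). Classification is a k-nearest-neighbor majority vote (k=3,
Euclidean metric, uniform weights); a nearest-centroid alternative trades a
little accuracy for O(#classes) lookups. Out-of-distribution scoring uses
the mean distance to the 3 nearest reference rows (larger = more unfamiliar);
a local-outlier-factor scorer is available behind a switch for comparison.
Reference stores are strictly per-subject and never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .fcn import FCNModel, predict_softmax


@dataclass
class ReferenceStore:
    """One subject's labeled reference vectors."""

    subject_id: str
    rows: np.ndarray  # (n, dim)
    labels: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.rows.shape[0] < 1:
            raise ValueError("reference store needs at least one row")
        if self.rows.shape[0] != self.labels.shape[0]:
            raise ValueError("every reference row needs a class label")

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx) -> "ReferenceStore":
        idx = np.asarray(idx)
        return ReferenceStore(self.subject_id, self.rows[idx], self.labels[idx])


@dataclass
class Prediction:
    label: object
    neighbor_labels: np.ndarray
    neighbor_distances: np.ndarray  # sorted ascending


@dataclass
class OODScore:
    score: float


def _query_distances(store: ReferenceStore, query: np.ndarray) -> np.ndarray:
    query = np.asarray(query, dtype=float).reshape(1, -1)
    if query.shape[1] != store.rows.shape[1]:
        raise ValueError("query dimension does not match the reference store")
    return cdist(query, store.rows)[0]


def knn_classify(store: ReferenceStore, query: np.ndarray, k: int = 3) -> Prediction:
    """Majority vote over the k nearest reference rows (Euclidean, uniform).

    Vote ties are broken by the smallest summed neighbor distance among the
    tied classes, then by lowest class identifier.
    """
    if store.n < k:
        raise ValueError(f"store has {store.n} rows, fewer than k={k}")
    dists = _query_distances(store, query)
    nearest = np.argsort(dists, kind="stable")[:k]
    nb_labels = store.labels[nearest]
    nb_dists = dists[nearest]
    classes, counts = np.unique(nb_labels, return_counts=True)
    top = counts.max()
    tied = classes[counts == top]
    if tied.shape[0] == 1:
        label = tied[0]
    else:
        sums = np.array([nb_dists[nb_labels == c].sum() for c in tied])
        best = sums.min()
        label = np.sort(tied[sums == best])[0]
    return Prediction(label=label, neighbor_labels=nb_labels, neighbor_distances=nb_dists)


def nearest_centroid_classify(store: ReferenceStore, query: np.ndarray) -> Prediction:
    """Predict the class whose mean reference vector is nearest.

    Ties go to the lowest class identifier. The per-"neighbor" fields hold
    the candidate centroids sorted by distance.
    """
    classes = store.classes
    centroids = np.stack([store.rows[store.labels == c].mean(axis=0) for c in classes])
    query = np.asarray(query, dtype=float).reshape(1, -1)
    dists = cdist(query, centroids)[0]
    order = np.lexsort((classes, dists))  # distance first, class id second
    return Prediction(
        label=classes[order[0]],
        neighbor_labels=classes[order],
        neighbor_distances=dists[order],
    )


def knn_classify_batch(store: ReferenceStore, queries: np.ndarray, k: int = 3) -> np.ndarray:
    return np.asarray([knn_classify(store, q, k).label for q in np.atleast_2d(queries)])


def nearest_centroid_classify_batch(store: ReferenceStore, queries: np.ndarray) -> np.ndarray:
    return np.asarray([nearest_centroid_classify(store, q).label for q in np.atleast_2d(queries)])


def ood_score(store: ReferenceStore, query: np.ndarray, k: int = 3) -> OODScore:
    """Mean Euclidean distance to the k (default 3) nearest reference rows."""
    if store.n < k:
        raise ValueError(f"OOD scoring needs at least {k} reference rows")
    dists = np.sort(_query_distances(store, query), kind="stable")
    return OODScore(score=float(dists[:k].mean()))


def ood_score_batch(store: ReferenceStore, queries: np.ndarray, k: int = 3) -> np.ndarray:
    if store.n < k:
        raise ValueError(f"OOD scoring needs at least {k} reference rows")
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    dists = np.sort(cdist(queries, store.rows), axis=1)
    return dists[:, :k].mean(axis=1)


def lof_score_batch(store: ReferenceStore, queries: np.ndarray, n_neighbors: int = 3) -> np.ndarray:
    """Local-outlier-factor alternative scorer (larger = more OOD)."""
    from sklearn.neighbors import LocalOutlierFactor

    lof = LocalOutlierFactor(n_neighbors=min(n_neighbors, store.n - 1) or 1, novelty=True)
    lof.fit(store.rows)
    return -lof.score_samples(np.atleast_2d(queries))


def softmax_confidence(model: FCNModel, segments) -> np.ndarray:
    """Max-softmax confidence per segment (baseline OOD signal).

    ``1 - confidence`` orients the score like :func:`ood_score` (larger =
    more out-of-distribution).
    """
    return predict_softmax(model, segments).max(axis=1)
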