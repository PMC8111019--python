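"""Euclidean k-nearest-neighbour retrieval and the majority-vote likelihood.

The archive is searched exhaustively: for a query descriptor the Euclidean
distance to every archived code is computed and the ``k`` smallest are
returned in ascending order. Exact distance ties break by archive insertion
order, which makes retrieval deterministic and gives the prefix property
(enlarging ``k`` never drops a previously retrieved hit). If ``k`` exceeds
the archive size the retrieval is clipped to the whole archive and flagged.

A query is scored as the fraction ``m / k`` of retrieved neighbours carrying
the positive label (``m`` positives among the ``k`` effective hits), and
classified positive when that likelihood reaches the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .store import FeatureStore


@dataclass
class ArchiveIndex:
    """Searchable archive: codes with aligned ids and binary labels."""

    codes: np.ndarray
    ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.float32)
        self.ids = np.asarray(self.ids, dtype=str)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] < 1:
            raise ValueError("index needs a non-empty (n, d) code matrix")
        n = self.codes.shape[0]
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("ids/labels misaligned with code rows")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def dim(self) -> int:
        return self.codes.shape[1]


@dataclass
class RetrievalSet:
    """Ordered k-nearest hits for one query."""

    query_id: str
    k: int  # requested k
    indices: np.ndarray  # archive row numbers, ascending distance
    ids: np.ndarray
    distances: np.ndarray  # non-decreasing
    labels: np.ndarray
    truncated: bool = False  # k exceeded the archive size

    @property
    def m(self) -> int:
        """Count of positive labels among the hits."""
        return int((self.labels == 1).sum())


def build_index(codes: FeatureStore | np.ndarray,
                ids: np.ndarray | None = None,
                labels: np.ndarray | None = None) -> ArchiveIndex:
    """Index a code store (or raw matrix plus ids/labels) for search."""
    if isinstance(codes, FeatureStore):
        if len(codes) == 0:
            raise ValueError("cannot index an empty store")
        return ArchiveIndex(codes=codes.features, ids=codes.ids,
                            labels=codes.labels)
    return ArchiveIndex(codes=codes, ids=ids, labels=labels)


def knn_batch(index: ArchiveIndex, queries: np.ndarray, k: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised retrieval: distance and archive-row matrices of shape
    ``(n_queries, min(k, n))``, each row in ascending-distance order with
    ties broken by insertion order."""
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float32))
    if queries.shape[1] != index.dim:
        raise ValueError(f"query dim {queries.shape[1]} != index dim {index.dim}")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, index.n)
    d = cdist(queries, index.codes)
    order = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    return np.take_along_axis(d, order, axis=1), order


def knn(index: ArchiveIndex, query: np.ndarray, k: int,
        query_id: str = "") -> RetrievalSet:
    """Retrieve the k nearest archived items for one query."""
    dist, order = knn_batch(index, query, k)
    rows = order[0]
    return RetrievalSet(
        query_id=query_id, k=k, indices=rows, ids=index.ids[rows],
        distances=dist[0], labels=index.labels[rows],
        truncated=k > index.n)


def vote_likelihood(retrieval: RetrievalSet) -> float:
    """Positive-class likelihood ``m / k`` over the effective hits."""
    n_hits = len(retrieval.labels)
    if n_hits == 0:
        raise ValueError("empty retrieval has no vote")
    return retrieval.m / n_hits


def classify(likelihood: float, threshold: float) -> int:
    """Positive (1) iff ``likelihood >= threshold``; both in [0, 1]."""
    if not 0.0 <= likelihood <= 1.0:
        raise ValueError(f"likelihood {likelihood} outside [0, 1]")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return int(likelihood >= threshold)
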