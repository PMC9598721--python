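"""Content-based image retrieval: indexing, ranked search and scoring.

A database is a list of (identifier, class label, descriptor histogram)
entries.  Queries are answered by ranking entries by distance between
max-normalized histograms — plain L1 by default, chi-square optionally —
either across the whole database or with a classifier in the loop
(entries of the predicted class are ranked first, realizing the
classify-then-search architecture).

Retrieval quality is scored per query by

    precision = |relevant ∩ retrieved| / n_retrieved
    recall    = |relevant ∩ retrieved| / n_relevant

and aggregated over all queries as ARP (mean precision at a fixed depth,
10 by default) and ARR (mean recall at depth = number of relevant items,
with a floor of 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from avnlbp.descriptors import descriptor_histogram
from avnlbp.fam import FuzzyARTMAP

__all__ = [
    "ImageDatabase",
    "RetrievalResult",
    "RetrievalMetrics",
    "index_database",
    "retrieve",
    "precision_recall",
    "evaluate_retrieval",
    "histogram_distance",
]


@dataclass
class ImageDatabase:
    """Indexed image database: ids, class labels, and one histogram row per
    image (all rows the same length)."""

    ids: list
    labels: np.ndarray
    histograms: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.histograms = np.asarray(self.histograms, dtype=np.float64)
        if len(self.ids) == 0:
            raise ValueError("empty database")
        if not (len(self.ids) == len(self.labels) == len(self.histograms)):
            raise ValueError("ids, labels and histograms length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def normalized(self) -> np.ndarray:
        """Histograms scaled into [0, 1] by their per-row maximum."""
        peak = np.maximum(self.histograms.max(axis=1, keepdims=True), 1.0)
        return self.histograms / peak

    def to_frame(self) -> pd.DataFrame:
        cols = [f"h{k}" for k in range(self.histograms.shape[1])]
        frame = pd.DataFrame(self.histograms, columns=cols)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "id", self.ids)
        return frame


@dataclass
class RetrievalResult:
    """Ranked answer to one query: database indices, ids and distances in
    non-decreasing distance order."""

    indices: np.ndarray
    ids: list
    distances: np.ndarray


@dataclass
class RetrievalMetrics:
    """Per-query precision/recall and their ARP/ARR aggregates."""

    precision: np.ndarray
    recall: np.ndarray
    arp: float
    arr: float
    arp_depth: int = 10
    per_query: pd.DataFrame = field(default=None, repr=False)


def _normalize(h: np.ndarray) -> np.ndarray:
    return h / max(h.max(), 1.0)


def histogram_distance(a, b, metric: str = "l1") -> float:
    """Distance between two max-normalized histograms ('l1' or 'chi2')."""
    a = _normalize(np.asarray(a, dtype=np.float64))
    b = _normalize(np.asarray(b, dtype=np.float64))
    if metric == "l1":
        return float(np.abs(a - b).sum())
    if metric == "chi2":
        denom = a + b
        mask = denom > 0
        return float(((a - b)[mask] ** 2 / denom[mask]).sum())
    raise ValueError(f"unknown metric {metric!r}; use 'l1' or 'chi2'")


def index_database(images, labels, ids=None, p: int = 8, radius: int = 3,
                   variant: str = "avn", threshold: float = 1.0) -> ImageDatabase:
    """Compute one descriptor histogram per image and build the database.

    Deterministic given inputs; every class must be non-empty.
    """
    labels = np.asarray(labels)
    images = list(images)
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    if ids is None:
        ids = list(range(len(images)))
    hists = np.stack([
        descriptor_histogram(img, p=p, radius=radius, variant=variant,
                             threshold=threshold)
        for img in images
    ]).astype(np.float64)
    return ImageDatabase(list(ids), labels, hists)


def retrieve(db: ImageDatabase, query_histogram, k: int,
             classifier: FuzzyARTMAP | None = None,
             metric: str = "l1", within_class_only: bool = False) -> RetrievalResult:
    """Return the top-``k`` database entries for a query histogram.

    Without a classifier, all entries are ranked by ascending distance.
    With one, the query's class is predicted from its normalized histogram
    and same-class entries are ranked first (each block by distance);
    ``within_class_only=True`` restricts the answer to the predicted class.
    Ties are broken by database order.
    """
    if not 1 <= k <= len(db):
        raise ValueError(f"k must lie in [1, {len(db)}], got {k}")
    q = _normalize(np.asarray(query_histogram, dtype=np.float64))
    base = db.normalized()
    if metric == "l1":
        dists = np.abs(base - q).sum(axis=1)
    elif metric == "chi2":
        denom = base + q
        num = (base - q) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(denom > 0, num / denom, 0.0)
        dists = terms.sum(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    order_idx = np.arange(len(db))
    if classifier is not None:
        predicted = classifier.predict(q.reshape(1, -1))[0]
        same = db.labels == predicted
        if within_class_only:
            order_idx = order_idx[same]
            dists_key = dists[same]
            rank = np.lexsort((order_idx, dists_key))
            chosen = order_idx[rank][:k]
        else:
            # same-class block first, each block sorted by distance
            rank = np.lexsort((order_idx, dists, ~same))
            chosen = order_idx[rank][:k]
    else:
        rank = np.lexsort((order_idx, dists))
        chosen = order_idx[rank][:k]
    return RetrievalResult(chosen, [db.ids[i] for i in chosen], dists[chosen])


def precision_recall(result: RetrievalResult, query_label,
                     db: ImageDatabase) -> tuple[float, float]:
    """Per-query precision and recall of a retrieved set against the
    query's class."""
    relevant_total = int(np.count_nonzero(db.labels == query_label))
    if relevant_total == 0:
        raise ValueError(f"query class {query_label!r} absent from database; "
                         "recall undefined")
    hits = int(np.count_nonzero(db.labels[result.indices] == query_label))
    return hits / len(result.indices), hits / relevant_total


def evaluate_retrieval(db: ImageDatabase, query_histograms, query_labels,
                       classifier: FuzzyARTMAP | None = None,
                       metric: str = "l1", arp_depth: int = 10,
                       arr_min_depth: int = 10) -> RetrievalMetrics:
    """Score retrieval over a set of queries.

    ARP is the mean precision at depth ``arp_depth`` (capped at the
    database size).  ARR is the mean recall at depth
    ``max(n_relevant, arr_min_depth)`` per query.  Both depths are
    configurable (e.g. 25 for top-25 accuracy).
    """
    query_labels = np.asarray(query_labels)
    precisions, recalls, rows = [], [], []
    p_depth = min(arp_depth, len(db))
    for qh, ql in zip(query_histograms, query_labels):
        res_p = retrieve(db, qh, p_depth, classifier=classifier, metric=metric)
        prec, _ = precision_recall(res_p, ql, db)
        n_rel = int(np.count_nonzero(db.labels == ql))
        r_depth = min(max(n_rel, arr_min_depth), len(db))
        res_r = retrieve(db, qh, r_depth, classifier=classifier, metric=metric)
        _, rec = precision_recall(res_r, ql, db)
        precisions.append(prec)
        recalls.append(rec)
        rows.append({"label": ql, "precision": prec, "recall": rec,
                     "arp_depth": p_depth, "arr_depth": r_depth})
    if not precisions:
        raise ValueError("no queries to evaluate")
    return RetrievalMetrics(
        precision=np.array(precisions),
        recall=np.array(recalls),
        arp=float(np.mean(precisions)),
        arr=float(np.mean(recalls)),
        arp_depth=p_depth,
        per_query=pd.DataFrame(rows),
    )
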