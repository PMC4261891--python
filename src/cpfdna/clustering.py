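"""Euclidean distance and a seeded, repeatable k-means harness.

Sequence similarity is the Euclidean distance between feature vectors, and
clustering is Lloyd's k-means repeated from independent random
initialisations.  Because random initial centres dominate run-to-run
variation, each experiment is repeated (default 10 times) and evaluation
averages over the repeats; one master seed spawns per-repeat child seeds so
repeats are independent yet exactly reproducible.

Initialisation draws ``c`` distinct data points uniformly at random
(``init="random"``); greedy D^2 seeding is available as
``init="kmeans++"``.  Within one repeat, Lloyd is restarted from several
independent initialisations and the solution with the lowest within-cluster
sum of squares is kept — single random-point initialisations frequently
leave one true group without a centre and merge it into a neighbour, and
best-of-restarts by distortion is how the classic scipy k-means routine
handles this.  Ties in nearest-centre assignment break to the lowest centre
index, and clusters that empty during iteration are dropped (the effective
cluster count may fall below ``c``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ClusteringRun", "euclidean", "kmeans_cluster"]

#: Lloyd iteration stops when no centre moves more than this.
CONVERGENCE_TOL = 1e-8
MAX_ITER = 300


def euclidean(v1, v2) -> float:
    """Euclidean distance between two feature vectors.

    Accepts :class:`~cpfdna.entropy_features.FeatureVector` objects or
    plain arrays; vectors must have equal length, and FeatureVectors must
    share a model tag.
    """
    m1, m2 = getattr(v1, "model", None), getattr(v2, "model", None)
    if m1 is not None and m2 is not None and m1 != m2:
        raise ValueError(f"cannot compare vectors of different models: {m1!r} vs {m2!r}")
    a = np.asarray(getattr(v1, "values", v1), dtype=float)
    b = np.asarray(getattr(v2, "values", v2), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


@dataclass
class ClusteringRun:
    """Assignments of one repeated k-means experiment.

    ``labels[r, i]`` is the cluster index of sequence ``ids[i]`` in repeat
    ``r``; indices are contiguous from 0 but the effective number of
    clusters may be below ``c`` if clusters emptied.
    """

    ids: tuple[str, ...]
    c: int
    repeats: int
    seed: int
    labels: np.ndarray

    @property
    def assignments(self) -> list[dict[str, int]]:
        """One id -> cluster mapping per repeat."""
        return [
            {seq_id: int(lab) for seq_id, lab in zip(self.ids, row)}
            for row in self.labels
        ]


def _init_random(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    # Sample distinct rows: duplicate sequences would yield coincident
    # centres that empty immediately.  Falls back to raw rows when fewer
    # than c distinct points exist.
    unique = np.unique(X, axis=0)
    pool = unique if unique.shape[0] >= c else X
    idx = rng.choice(pool.shape[0], size=c, replace=False)
    return pool[idx].astype(float).copy()


def _init_kmeanspp(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(c - 1):
        d2 = cdist(X, np.asarray(centers)).min(axis=1) ** 2
        total = d2.sum()
        if total == 0:  # all remaining points coincide with a centre
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float).copy()


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    *,
    max_iter: int = MAX_ITER,
    tol: float = CONVERGENCE_TOL,
    wcss_trace: "list[float] | None" = None,
) -> np.ndarray:
    """Lloyd iteration from given centres; returns final labels.

    ``wcss_trace``, if supplied, collects the within-cluster sum of squares
    after each assignment step (non-increasing across iterations).
    """
    for _ in range(max_iter):
        dists = cdist(X, centers)
        labels = dists.argmin(axis=1)  # argmin ties -> lowest centre index
        if wcss_trace is not None:
            wcss_trace.append(float((dists[np.arange(X.shape[0]), labels] ** 2).sum()))
        used = np.unique(labels)
        if used.size < centers.shape[0]:  # drop emptied clusters
            remap = {int(old): new for new, old in enumerate(used)}
            labels = np.array([remap[int(lab)] for lab in labels])
            centers = centers[used]
        new_centers = np.vstack(
            [X[labels == j].mean(axis=0) for j in range(centers.shape[0])]
        )
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return labels


def kmeans_cluster(
    vectors,
    c: int,
    repeats: int = 10,
    seed: int = 0,
    *,
    init: str = "random",
    restarts: int = 10,
) -> ClusteringRun:
    """Repeated, seeded Lloyd's k-means over feature vectors.

    Parameters
    ----------
    vectors
        A sequence of :class:`~cpfdna.entropy_features.FeatureVector`, or a
        pair ``(ids, matrix)`` with one row per sequence.
    c
        Number of initial cluster centres (1 <= c <= number of vectors).
    repeats
        Independent runs from fresh random initialisations; default 10.
    seed
        Master seed; per-repeat child seeds derive from it deterministically,
        so the same inputs and seed reproduce identical assignments.
    init
        ``"random"`` (centres are data points drawn uniformly without
        replacement, the default) or ``"kmeans++"`` (greedy D^2 seeding).
    restarts
        Lloyd restarts within each repeat; the assignment with the lowest
        within-cluster sum of squares wins.  Default 10.

    Raises
    ------
    ValueError
        If ``c`` exceeds the number of vectors, or ``c < 1``.
    """
    if isinstance(vectors, tuple) and len(vectors) == 2:
        ids, X = vectors
        ids = tuple(ids)
        X = np.asarray(X, dtype=float)
    else:
        vectors = list(vectors)
        ids = tuple(v.source_id for v in vectors)
        X = np.asarray([v.values for v in vectors], dtype=float)
    if X.ndim != 2 or X.shape[0] != len(ids):
        raise ValueError("vectors must form an (n, d) matrix with one id per row")
    n = X.shape[0]
    if c < 1:
        raise ValueError("number of clusters c must be >= 1")
    if c > n:
        raise ValueError(f"c={c} exceeds the number of vectors ({n})")
    if init not in ("random", "kmeans++"):
        raise ValueError(f"init must be 'random' or 'kmeans++', got {init!r}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    init_fn = _init_random if init == "random" else _init_kmeanspp
    child_seeds = np.random.SeedSequence(seed).spawn(repeats)
    all_labels = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        rng = np.random.default_rng(child_seeds[r])
        best_labels, best_wcss = None, np.inf
        for _ in range(restarts):
            trace: list[float] = []
            labels = _lloyd(X, init_fn(X, c, rng), wcss_trace=trace)
            if trace[-1] < best_wcss:
                best_wcss, best_labels = trace[-1], labels
        all_labels[r] = best_labels
    return ClusteringRun(ids=ids, c=c, repeats=repeats, seed=seed, labels=all_labels)
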