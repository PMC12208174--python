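"""Separation-enforced clustering and optimal-transport cluster comparison.

The partition at threshold ``t`` is defined as the connected components of
the graph with an edge wherever ``d < t``.  This is exactly the
single-linkage cut at ``t``, and it carries a structural guarantee: for any
two distinct clusters A and B and pockets a ∈ A, b ∈ B, the distance
``d_ab`` is at least ``t``.  The components are built with an explicit
union-find rather than a dendrogram cut so the guarantee holds by
construction, with strict ``<`` for merging (a pair at exactly ``t`` stays
separated).

Two partitions of the same pockets are compared by optimal transport: a
one-to-one assignment between clusters maximizing the total Jaccard index,
with the similarity defined as the Jaccard sum over matched pairs divided
by the larger cluster count (so identity is the unique maximizer).  A
scrambled null retains cluster sizes but reshuffles the pocket labels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import IdMismatch
from .metric import DistanceMatrix


class UnionFind:
    """Plain union-find with path compression."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class Clustering:
    """A partition of pockets at threshold ``t``.  Labels are contiguous
    0..n_clusters-1, canonicalized by the order of each cluster's smallest
    member index (byte-stable across runs)."""

    ids: list[str]
    labels: np.ndarray
    t: float
    metric_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.ids),):
            raise ValueError("one label per id required")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be contiguous 0..k-1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.ids) else 0

    def members(self, label: int) -> list[str]:
        return [pid for pid, lab in zip(self.ids, self.labels) if lab == label]

    def clusters(self) -> list[frozenset[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_clusters)]
        for pid, lab in zip(self.ids, self.labels):
            out[lab].add(pid)
        return [frozenset(s) for s in out]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def label_of(self, pid: str) -> int:
        return int(self.labels[self.ids.index(pid)])

    @classmethod
    def from_clusters(
        cls, clusters: list[set[str] | frozenset[str]], t: float = 0.0,
        metric_id: str = "",
    ) -> "Clustering":
        ids = sorted(set().union(*clusters)) if clusters else []
        index = {pid: i for i, pid in enumerate(ids)}
        labels = np.full(len(ids), -1, dtype=int)
        order = sorted(range(len(clusters)),
                       key=lambda c: min(index[p] for p in clusters[c]))
        for new_lab, c in enumerate(order):
            for pid in clusters[c]:
                if labels[index[pid]] != -1:
                    raise ValueError("clusters overlap")
                labels[index[pid]] = new_lab
        if np.any(labels < 0):
            raise ValueError("clusters do not cover the id set")
        return cls(ids=ids, labels=labels, t=t, metric_id=metric_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "assignment": {pid: int(lab) for pid, lab in zip(self.ids, self.labels)},
                "t": self.t,
                "metric_id": self.metric_id,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Clustering":
        d = json.loads(text)
        ids = list(d["assignment"])
        labels = np.array([d["assignment"][pid] for pid in ids], dtype=int)
        return cls(ids=ids, labels=labels, t=d.get("t", 0.0),
                   metric_id=d.get("metric_id", ""))


def _canonical_labels(raw: list[int]) -> np.ndarray:
    """Relabel components by order of each component's smallest member."""
    first_seen: dict[int, int] = {}
    for i, r in enumerate(raw):
        first_seen.setdefault(r, i)
    order = sorted(first_seen, key=lambda r: first_seen[r])
    remap = {r: k for k, r in enumerate(order)}
    return np.array([remap[r] for r in raw], dtype=int)


def cluster_single_linkage(D: DistanceMatrix, t: float) -> Clustering:
    """Single-linkage cut at ``t``: components of the ``d < t`` graph.

    ``t = 0`` yields all singletons; every cross-cluster pair is guaranteed
    to have distance >= ``t``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    n = len(D)
    uf = UnionFind(n)
    ii, jj = np.nonzero(np.triu(D.D < t, k=1))
    for i, j in zip(ii, jj):
        uf.union(int(i), int(j))
    raw = [uf.find(i) for i in range(n)]
    return Clustering(
        ids=list(D.ids),
        labels=_canonical_labels(raw),
        t=t,
        metric_id=D.metric_id,
    )


@dataclass
class OTComparison:
    similarity: float
    matched_pairs: list[tuple[int, int, float]]  # (cluster_a, cluster_b, jaccard)
    null_similarity: float = float("nan")
    null_reps: int = 0
    include_singletons: bool = True
    denominator: str = "max"
    n_ids_used: int = 0


def _jaccard_matrix(
    A: list[frozenset[str]], B: list[frozenset[str]]
) -> np.ndarray:
    J = np.zeros((len(A), len(B)))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            inter = len(a & b)
            if inter:
                J[i, j] = inter / len(a | b)
    return J


def _drop_singleton_ids(
    A: "Clustering", B: "Clustering"
) -> tuple[list[frozenset[str]], list[frozenset[str]], int]:
    """Remove singleton clusters from both partitions and drop their
    members globally (from the other side's clusters too)."""
    drop: set[str] = set()
    for part in (A, B):
        for c in part.clusters():
            if len(c) == 1:
                drop |= set(c)
    kept_a = [frozenset(c - drop) for c in A.clusters() if c - drop]
    kept_b = [frozenset(c - drop) for c in B.clusters() if c - drop]
    n_used = len(set(A.ids) - drop)
    return kept_a, kept_b, n_used


def ot_cluster_similarity(
    A: Clustering,
    B: Clustering,
    include_singletons: bool = True,
    denominator: str = "max",
) -> OTComparison:
    """Average Jaccard index over the optimally matched cluster pairs.

    ``denominator='max'`` divides the matched Jaccard sum by
    ``max(K_A, K_B)`` (unmatched clusters contribute 0, identity is the
    unique maximizer); ``'matched'`` divides by the number of matched
    pairs, ``min(K_A, K_B)``.
    """
    if set(A.ids) != set(B.ids):
        raise IdMismatch("clusterings must partition the same id set")
    if denominator not in ("max", "matched"):
        raise ValueError("denominator must be 'max' or 'matched'")
    if include_singletons:
        ca, cb, n_used = A.clusters(), B.clusters(), len(A.ids)
    else:
        ca, cb, n_used = _drop_singleton_ids(A, B)
    if not ca or not cb:
        return OTComparison(
            similarity=0.0, matched_pairs=[],
            include_singletons=include_singletons,
            denominator=denominator, n_ids_used=n_used,
        )
    J = _jaccard_matrix(ca, cb)
    rows, cols = linear_sum_assignment(J, maximize=True)
    matched = [(int(i), int(j), float(J[i, j])) for i, j in zip(rows, cols)]
    total = float(J[rows, cols].sum())
    denom = max(len(ca), len(cb)) if denominator == "max" else len(rows)
    return OTComparison(
        similarity=total / denom,
        matched_pairs=matched,
        include_singletons=include_singletons,
        denominator=denominator,
        n_ids_used=n_used,
    )


def scrambled_null(
    A: Clustering,
    B: Clustering,
    reps: int = 100,
    seed: int = 0,
    include_singletons: bool = True,
    denominator: str = "max",
) -> float:
    """Mean OT similarity against scrambles of B that retain its cluster
    sizes but reshuffle which pocket carries which label."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if set(A.ids) != set(B.ids):
        raise IdMismatch("clusterings must partition the same id set")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        perm = rng.permutation(len(B.ids))
        scrambled = Clustering(
            ids=list(B.ids),
            labels=_canonical_labels([int(x) for x in B.labels[perm]]),
            t=B.t,
            metric_id=B.metric_id,
        )
        vals.append(
            ot_cluster_similarity(
                A, scrambled,
                include_singletons=include_singletons,
                denominator=denominator,
            ).similarity
        )
    return float(np.mean(vals))


def compare_clusterings(
    A: Clustering,
    B: Clustering,
    include_singletons: bool = True,
    null_reps: int = 100,
    seed: int = 0,
    denominator: str = "max",
) -> OTComparison:
    """OT similarity plus its scrambled-label null in one report."""
    cmp = ot_cluster_similarity(
        A, B, include_singletons=include_singletons, denominator=denominator
    )
    cmp.null_similarity = scrambled_null(
        A, B, reps=null_reps, seed=seed,
        include_singletons=include_singletons, denominator=denominator,
    )
    cmp.null_reps = null_reps
    return cmp
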