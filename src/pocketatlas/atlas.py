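"""The pocket atlas: a minimum spanning tree over clusters, plus spatial
coherence statistics.

Clusters become nodes; the edge weight between two clusters is the minimum
distance of approach (the smallest pocket–pocket distance across the two
clusters).  The MST over the complete cluster graph is the atlas backbone:
it links every cluster to its nearest context and supports branch-based
train/test splits.  Spatial coherence of per-cluster annotations is
measured with Moran's I against a permutation null.

2D layout is intentionally not computed here; the tree is exported as
GraphML (or an edge TSV) for external layout tools.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .clustering import Clustering
from .errors import (
    DegenerateVariance,
    EdgeNotFound,
    FormatError,
    IdMismatch,
    WeightError,
)
from .metric import DistanceMatrix


@dataclass
class PocketTree:
    """MST over cluster labels.  ``edges`` hold ``(u, v, weight)`` with
    ``u < v``; ``sizes`` maps label -> member count."""

    sizes: dict[int, int]
    edges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        nodes = set(self.sizes)
        if len(self.edges) != max(0, len(nodes) - 1):
            raise ValueError("a tree over k nodes needs k-1 edges")
        g = self.to_networkx()
        if nodes and not nx.is_connected(g):
            raise ValueError("tree must be connected")

    @property
    def nodes(self) -> list[int]:
        return sorted(self.sizes)

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for lab, size in self.sizes.items():
            g.add_node(int(lab), size=int(size))
        for u, v, w in self.edges:
            g.add_edge(int(u), int(v), weight=float(w))
        return g

    def has_edge(self, u: int, v: int) -> bool:
        return any({u, v} == {a, b} for a, b, _ in self.edges)


def cluster_min_distances(D: DistanceMatrix, C: Clustering) -> np.ndarray:
    """Cluster-level distance matrix: entry (A, B) is the minimum pocket
    distance across the two clusters ("minimum distance of approach");
    the diagonal is zero.  Rows/columns are ordered by cluster label."""
    if set(D.ids) != set(C.ids):
        raise IdMismatch("distance matrix and clustering id sets differ")
    pos = {pid: i for i, pid in enumerate(D.ids)}
    k = C.n_clusters
    idx_by_label = [
        np.array([pos[pid] for pid in C.members(lab)]) for lab in range(k)
    ]
    M = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            block = D.D[np.ix_(idx_by_label[a], idx_by_label[b])]
            M[a, b] = M[b, a] = float(block.min())
    return M


def build_mst(cluster_D: np.ndarray, sizes: dict[int, int] | None = None) -> PocketTree:
    """MST of the complete weighted cluster graph.  Ties are broken by
    preferring the lexicographically smaller (u, v) pair: edges are fed to
    Kruskal in (u, v) order and the sort on weight is stable."""
    cluster_D = np.asarray(cluster_D, dtype=float)
    k = cluster_D.shape[0]
    if k < 1:
        raise ValueError("need at least one cluster")
    if sizes is None:
        sizes = {lab: 1 for lab in range(k)}
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for u in range(k):
        for v in range(u + 1, k):
            g.add_edge(u, v, weight=float(cluster_D[u, v]))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted(
        (min(u, v), max(u, v), float(d["weight"]))
        for u, v, d in mst.edges(data=True)
    )
    return PocketTree(sizes={lab: sizes.get(lab, 1) for lab in range(k)}, edges=edges)


def tree_branch(
    tree: PocketTree, cut_edge: tuple[int, int]
) -> tuple[frozenset[int], frozenset[int]]:
    """Split the tree at a directed edge (u, v): the *branch* is the
    component containing v (the child side of the cut), the *remainder*
    the component containing u."""
    u, v = int(cut_edge[0]), int(cut_edge[1])
    if not tree.has_edge(u, v):
        raise EdgeNotFound(f"edge ({u}, {v}) is not in the tree")
    g = tree.to_networkx()
    g.remove_edge(u, v)
    comp_v = nx.node_connected_component(g, v)
    comp_u = nx.node_connected_component(g, u)
    return frozenset(comp_v), frozenset(comp_u)


@dataclass
class MoranReport:
    I: float
    I_null_mean: float
    I_null_std: float
    null_reps: int
    n_used: int
    weight_scheme: str
    null_samples: np.ndarray = field(default=None, repr=False)


def _moran_statistic(x: np.ndarray, W: np.ndarray) -> float:
    n = len(x)
    z = x - x.mean()
    denom = float((z * z).sum())
    num = float(z @ W @ z)       # W has zero diagonal
    return (n / W.sum()) * num / denom


def morans_i(
    values,
    cluster_D: np.ndarray,
    weight_scheme: str = "inverse-distance",
    null_reps: int = 999,
    seed: int = 0,
    tree: PocketTree | None = None,
) -> MoranReport:
    """Moran's I spatial autocorrelation of per-cluster values.

    I = (n / W) * sum_{i!=j} w_ij (x_i - xbar)(x_j - xbar)
                 / sum_i (x_i - xbar)^2

    with w_ij = 1/d_ij for ``inverse-distance`` (row-unnormalized) or
    w_ij = 1 on MST edges for ``mst-adjacency``.  The null is the
    permutation distribution of the values over clusters; its analytic
    mean is -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 clusters")
    if np.ptp(x) == 0:
        raise DegenerateVariance("values are constant across clusters")
    if weight_scheme == "inverse-distance":
        D = np.asarray(cluster_D, dtype=float)
        if D.shape != (n, n):
            raise ValueError("cluster distance matrix shape mismatch")
        off = ~np.eye(n, dtype=bool)
        if np.any(D[off] <= 0):
            raise WeightError(
                "zero off-diagonal cluster distance: duplicate pockets "
                "across clusters (impossible under the separation guarantee)"
            )
        W = np.zeros((n, n))
        W[off] = 1.0 / D[off]
    elif weight_scheme == "mst-adjacency":
        if tree is None:
            raise ValueError("mst-adjacency requires the tree")
        W = np.zeros((n, n))
        for u, v, _w in tree.edges:
            W[u, v] = W[v, u] = 1.0
    else:
        raise ValueError("weight_scheme must be 'inverse-distance' or 'mst-adjacency'")

    I = _moran_statistic(x, W)
    rng = np.random.default_rng(seed)
    samples = np.array(
        [_moran_statistic(x[rng.permutation(n)], W) for _ in range(null_reps)]
    )
    return MoranReport(
        I=I,
        I_null_mean=float(samples.mean()),
        I_null_std=float(samples.std(ddof=1)) if null_reps > 1 else float("nan"),
        null_reps=null_reps,
        n_used=n,
        weight_scheme=weight_scheme,
        null_samples=samples,
    )


def morans_i_per_category(
    labels,
    cluster_D: np.ndarray,
    weight_scheme: str = "inverse-distance",
    null_reps: int = 999,
    seed: int = 0,
    tree: PocketTree | None = None,
) -> dict[str, MoranReport]:
    """One-hot encode a categorical per-cluster annotation and report
    Moran's I per category (categories constant across clusters are
    skipped)."""
    labels = list(labels)
    out: dict[str, MoranReport] = {}
    for cat in sorted(set(labels)):
        x = np.array([1.0 if lab == cat else 0.0 for lab in labels])
        if np.ptp(x) == 0:
            continue
        out[str(cat)] = morans_i(
            x, cluster_D, weight_scheme=weight_scheme,
            null_reps=null_reps, seed=seed, tree=tree,
        )
    return out


def export_graph(
    tree: PocketTree,
    path,
    cluster_metadata: dict[int, dict] | None = None,
    fmt: str = "graphml",
) -> None:
    """Write the atlas tree for external layout.  Nodes carry size plus any
    annotation attributes; edges carry weights."""
    if fmt not in ("graphml", "edge-tsv"):
        raise FormatError(f"unknown export format {fmt!r}")
    g = tree.to_networkx()
    if cluster_metadata:
        for lab, attrs in cluster_metadata.items():
            if int(lab) in g:
                for key, val in attrs.items():
                    g.nodes[int(lab)][str(key)] = val
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\n")
            for u, v, w in tree.edges:
                fh.write(f"{u}\t{v}\t{w:.8g}\n")
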