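"""Debiased train/test splits from pocket clusterings and atlas trees.

Random splits of structure-derived data leak near-duplicate pockets across
the train/test boundary.  Because the separation-enforced clustering
guarantees that every cross-cluster pocket pair is at least ``t`` apart,
allocating *whole clusters* to either side yields a split whose minimum
train–test distance is at least ``t`` by construction.  Removing whole
branches of the atlas MST produces still harder splits that hold out an
entire region of pocket space.  :func:`validate_split` quantifies residual
leakage of any split against a distance matrix.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .atlas import PocketTree, tree_branch
from .clustering import Clustering
from .errors import EmptyTest, EmptyTrain, IdMismatch
from .metric import DistanceMatrix


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]
    method: str                      # "cluster" | "tree" | "random" | "homology-external"
    t: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids must be disjoint")
        if not self.train_ids or not self.test_ids:
            raise ValueError("both split sides must be non-empty")

    @property
    def test_fraction(self) -> float:
        n = len(self.train_ids) + len(self.test_ids)
        return len(self.test_ids) / n

    def to_json(self) -> str:
        return json.dumps(
            {
                "train": list(self.train_ids),
                "test": list(self.test_ids),
                "method": self.method,
                "t": self.t,
                "provenance": self.provenance,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        return cls(
            train_ids=d["train"], test_ids=d["test"], method=d["method"],
            t=d.get("t", 0.0), provenance=d.get("provenance", {}),
        )


@dataclass
class LeakageReport:
    n_violating_pairs: int
    min_cross_distance: float
    violating_examples: list[tuple[str, str, float]]
    t: float


def cluster_split(C: Clustering, test_fraction: float, seed: int = 0) -> SplitSpec:
    """Shuffle the clusters and assign them greedily to the test side until
    the test pocket count first reaches ``test_fraction * n``; the rest go
    to train.  At ``t = 0`` (all singletons) this reduces to a plain random
    split.  If a single cluster holds more than ``(1 - test_fraction) * n``
    pockets the target is unreachable; the split is still returned with
    ``provenance['infeasible'] = True``."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if C.n_clusters < 2:
        raise ValueError("need at least 2 clusters to split")
    n = len(C.ids)
    target = test_fraction * n
    sizes = C.sizes()
    infeasible = bool((sizes > (1 - test_fraction) * n).any())
    rng = np.random.default_rng(seed)
    order = rng.permutation(C.n_clusters)
    test_labels: list[int] = []
    count = 0
    for lab in order:
        if count >= target:
            break
        test_labels.append(int(lab))
        count += int(sizes[lab])
    test_set = set(test_labels)
    test_ids = [pid for pid, lab in zip(C.ids, C.labels) if lab in test_set]
    train_ids = [pid for pid, lab in zip(C.ids, C.labels) if lab not in test_set]
    if not train_ids:
        # greedy consumed everything (tiny inputs); hand the last cluster back
        last = test_labels.pop()
        test_set.discard(last)
        test_ids = [pid for pid, lab in zip(C.ids, C.labels) if lab in test_set]
        train_ids = [pid for pid, lab in zip(C.ids, C.labels) if lab not in test_set]
        infeasible = True
    return SplitSpec(
        train_ids=train_ids,
        test_ids=test_ids,
        method="cluster" if C.t > 0 else "random",
        t=C.t,
        provenance={
            "seed": seed,
            "test_clusters": sorted(test_set),
            "target_fraction": test_fraction,
            "achieved_fraction": len(test_ids) / n,
            "infeasible": infeasible,
        },
    )


def tree_split(
    tree: PocketTree, C: Clustering, cut_edges: list[tuple[int, int]]
) -> SplitSpec:
    """Hold out whole MST branches: the test set is the union of the
    pockets in all removed branches (the child side of each directed cut),
    applied sequentially on the shrinking remainder tree."""
    if not cut_edges:
        raise EmptyTest("no cut edges: the test side would be empty")
    remaining = set(tree.nodes)
    test_labels: set[int] = set()
    current = tree
    for u, v in cut_edges:
        branch, remainder = tree_branch(current, (u, v))
        test_labels |= set(branch)
        remaining = set(remainder)
        # rebuild the remainder tree for subsequent cuts
        edges = [
            (a, b, w) for a, b, w in current.edges
            if a in remaining and b in remaining
        ]
        current = PocketTree(
            sizes={lab: current.sizes[lab] for lab in remaining}, edges=edges
        )
    if not remaining:
        raise EmptyTrain("the cut branches cover every cluster")
    test_ids = [pid for pid, lab in zip(C.ids, C.labels) if lab in test_labels]
    train_ids = [pid for pid, lab in zip(C.ids, C.labels) if lab in remaining]
    return SplitSpec(
        train_ids=train_ids,
        test_ids=test_ids,
        method="tree",
        t=C.t,
        provenance={"cut_edges": [list(e) for e in cut_edges],
                    "test_clusters": sorted(test_labels)},
    )


def balance_to_size(
    split: SplitSpec,
    C: Clustering,
    target_test_fraction: float,
    tolerance: float = 0.05,
) -> SplitSpec:
    """Move whole clusters between sides until the test fraction is within
    ``target +/- tolerance`` where feasible.  Each move picks the single
    cluster whose transfer minimizes the remaining deviation (ties by the
    smallest cluster label); a cluster is never divided.  Infeasibility is
    flagged in provenance, never silently resolved by splitting a
    cluster."""
    if not 0 < target_test_fraction < 1:
        raise ValueError("target_test_fraction must be in (0, 1)")
    n = len(C.ids)
    sizes = C.sizes()
    side_of = {}                      # cluster label -> "train" | "test"
    test_ids = set(split.test_ids)
    for lab in range(C.n_clusters):
        members = set(C.members(lab))
        if members <= test_ids:
            side_of[lab] = "test"
        elif members & test_ids:
            raise ValueError("split does not respect cluster boundaries")
        else:
            side_of[lab] = "train"

    def frac() -> float:
        return sum(sizes[lab] for lab, s in side_of.items() if s == "test") / n

    moved = []
    while abs(frac() - target_test_fraction) > tolerance:
        current = frac()
        donor = "test" if current > target_test_fraction else "train"
        sign = -1 if donor == "test" else +1
        best = None
        for lab in sorted(side_of):
            if side_of[lab] != donor:
                continue
            # never empty a side completely
            if sum(1 for s in side_of.values() if s == donor) == 1:
                continue
            new = current + sign * sizes[lab] / n
            dev = abs(new - target_test_fraction)
            if best is None or dev < best[0] - 1e-12:
                best = (dev, lab)
        if best is None or best[0] >= abs(current - target_test_fraction) - 1e-12:
            break
        _, lab = best
        side_of[lab] = "train" if donor == "test" else "test"
        moved.append(int(lab))

    test_labels = {lab for lab, s in side_of.items() if s == "test"}
    new_test = [pid for pid, lab in zip(C.ids, C.labels) if lab in test_labels]
    new_train = [pid for pid, lab in zip(C.ids, C.labels) if lab not in test_labels]
    achieved = len(new_test) / n
    prov = dict(split.provenance)
    prov.update(
        {
            "balanced_to": target_test_fraction,
            "achieved_fraction": achieved,
            "moved_clusters": moved,
            "infeasible": abs(achieved - target_test_fraction) > tolerance,
        }
    )
    return SplitSpec(
        train_ids=new_train, test_ids=new_test,
        method=split.method, t=split.t, provenance=prov,
    )


def validate_split(
    split: SplitSpec, D: DistanceMatrix, t: float, max_examples: int = 20
) -> LeakageReport:
    """Count train–test pocket pairs closer than ``t`` — residual leakage
    the split failed to remove.  Splits built from whole clusters at
    threshold ``t`` report zero violations by the separation guarantee."""
    all_ids = set(D.ids)
    if not (set(split.train_ids) <= all_ids and set(split.test_ids) <= all_ids):
        raise IdMismatch("split ids missing from the distance matrix")
    pos = {pid: i for i, pid in enumerate(D.ids)}
    tr = np.array([pos[p] for p in split.train_ids])
    te = np.array([pos[p] for p in split.test_ids])
    block = D.D[np.ix_(tr, te)]
    viol = np.argwhere(block < t)
    examples = [
        (split.train_ids[i], split.test_ids[j], float(block[i, j]))
        for i, j in viol[:max_examples]
    ]
    return LeakageReport(
        n_violating_pairs=int(len(viol)),
        min_cross_distance=float(block.min()),
        violating_examples=examples,
        t=t,
    )
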