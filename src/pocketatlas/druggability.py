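"""Per-residue ligandability labels and a small train/evaluate harness.

Every residue of a complex receives a binary label: 1 if any of its heavy
atoms lies within the contact radius (default 4.0 Å — the conventional
heavy-atom contact cutoff, deliberately distinct from the 6.0 Å
tessellation truncation) of any ligand heavy atom, else 0.  A multilayer
perceptron on the per-residue embedding rows predicts these labels; pooled
ROC-AUC over the residues of the train or test side of a split measures
performance.  Comparing the test AUC across progressively harder splits
(random -> cluster-based -> tree-branch) quantifies how much of a model's
apparent performance rests on near-duplicate pockets straddling the split.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from .embedding import ResidueEmbeddingMatrix
from .errors import DegenerateLabels, IdMismatch, UndefinedAUC
from .splits import SplitSpec
from .structure_io import PocketComplex


@dataclass
class ResidueLabelSet:
    complex_id: str
    labels: np.ndarray
    contact_radius: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (128, 64)
    max_epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    class_weighting: str = "balanced"     # "balanced" | "none"

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ValueError("need at least one hidden layer")


@dataclass
class TrainReport:
    train_auc: float
    n_train_residues: int
    positive_fraction: float
    seed: int


@dataclass
class ResidueClassifier:
    model: MLPClassifier
    embedder_id: str
    dim: int

    def scores(self, matrix: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(matrix))[:, 1]


def label_residues(cplx: PocketComplex, contact_radius: float = 4.0) -> ResidueLabelSet:
    """1 iff any residue heavy atom is within ``contact_radius`` of any
    ligand heavy atom.  Monotone in the radius: growing it never flips a
    1 to 0."""
    if contact_radius < 0:
        raise ValueError("contact_radius must be >= 0")
    lig = cplx.ligand_coords()
    labels = np.array(
        [int(cdist(r.coords(), lig).min() <= contact_radius) for r in cplx.residues]
    )
    return ResidueLabelSet(
        complex_id=cplx.complex_id, labels=labels, contact_radius=contact_radius
    )


def _gather_rows(
    embeddings: list[ResidueEmbeddingMatrix],
    labels: list[ResidueLabelSet],
    ids: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    emb_by_id = {m.complex_id: m for m in embeddings}
    lab_by_id = {l.complex_id: l for l in labels}
    missing = [cid for cid in ids if cid not in emb_by_id or cid not in lab_by_id]
    if missing:
        raise IdMismatch(f"no embedding/labels for: {missing[:5]}")
    X, y = [], []
    for cid in ids:
        m, l = emb_by_id[cid], lab_by_id[cid]
        if len(m) != len(l.labels):
            raise IdMismatch(
                f"{cid}: embedding length {len(m)} != label length {len(l.labels)}"
            )
        X.append(m.matrix)
        y.append(l.labels)
    return np.concatenate(X), np.concatenate(y)


def train_residue_classifier(
    embeddings: list[ResidueEmbeddingMatrix],
    labels: list[ResidueLabelSet],
    cfg: MLPConfig,
    split: SplitSpec,
) -> tuple[ResidueClassifier, TrainReport]:
    """Fit the per-residue MLP on the train side of the split only.

    Contacted residues are a small minority, so with
    ``class_weighting='balanced'`` the minority class is deterministically
    oversampled to approximate inverse-frequency weighting (the MLP itself
    accepts no per-sample weights).  Deterministic for a fixed seed."""
    X, y = _gather_rows(embeddings, labels, list(split.train_ids))
    if len(np.unique(y)) < 2:
        raise DegenerateLabels("training residues contain a single class")
    X_fit, y_fit = X, y
    if cfg.class_weighting == "balanced":
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        minority = 1 if n_pos < n_neg else 0
        factor = max(n_pos, n_neg) // max(1, min(n_pos, n_neg))
        if factor > 1:
            rows = np.nonzero(y == minority)[0]
            extra = np.tile(rows, factor - 1)
            X_fit = np.concatenate([X, X[extra]])
            y_fit = np.concatenate([y, y[extra]])
    model = MLPClassifier(
        hidden_layer_sizes=tuple(cfg.hidden_sizes),
        max_iter=cfg.max_epochs,
        learning_rate_init=cfg.learning_rate,
        random_state=cfg.seed,
    )
    model.fit(X_fit, y_fit)
    clf = ResidueClassifier(
        model=model,
        embedder_id=embeddings[0].embedder_id,
        dim=embeddings[0].dim,
    )
    report = TrainReport(
        train_auc=float(roc_auc_score(y, clf.scores(X))),
        n_train_residues=int(len(y)),
        positive_fraction=float(y.mean()),
        seed=cfg.seed,
    )
    return clf, report


def evaluate_auc(
    classifier: ResidueClassifier,
    embeddings: list[ResidueEmbeddingMatrix],
    labels: list[ResidueLabelSet],
    split: SplitSpec,
    side: str = "test",
) -> float:
    """Pooled ROC-AUC over all residues of the requested side's complexes
    (trapezoidal rank formulation; ties get average rank)."""
    if side not in ("train", "test"):
        raise ValueError("side must be 'train' or 'test'")
    ids = split.train_ids if side == "train" else split.test_ids
    X, y = _gather_rows(embeddings, labels, list(ids))
    if len(np.unique(y)) < 2:
        raise UndefinedAUC(f"{side} side holds a single class")
    return float(roc_auc_score(y, classifier.scores(X)))
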