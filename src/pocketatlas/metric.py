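"""Pocket–pocket distances, normalization, sequence baseline, and the
onset/global rank-correlation analysis.

The pocket metric is the Euclidean distance between pooled pocket
embeddings.  Because two similarity measures typically only agree where at
least one of them considers a pair *similar*, the comparison protocol
reports two Spearman coefficients: ``rho_global`` over all pairs and
``rho_onset`` restricted to the onset region — pairs strictly below either
metric's maximum clustering threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .errors import (
    DegenerateScale,
    EmbedderMismatch,
    EmptyInput,
    ShapeError,
)
from .embedding import PocketEmbedding


@dataclass
class DistanceMatrix:
    """Symmetric pocket–pocket distance matrix with zero diagonal."""

    ids: list[str]
    D: np.ndarray
    metric_id: str = "euclidean"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape must match id count")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("distances must be finite")
        if np.any(self.D < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, pid: str) -> int:
        return self.ids.index(pid)

    def off_diagonal(self) -> np.ndarray:
        n = len(self)
        iu = np.triu_indices(n, k=1)
        return self.D[iu]

    def condensed(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Row-major upper triangle (i<j) of the id-sorted matrix, so two
        metrics over the same ids align pair-for-pair."""
        order = np.argsort(np.array(self.ids, dtype=object))
        ids_sorted = [self.ids[i] for i in order]
        M = self.D[np.ix_(order, order)]
        n = len(ids_sorted)
        pairs, vals = [], []
        for i in range(n):
            for j in range(i + 1, n):
                pairs.append((ids_sorted[i], ids_sorted[j]))
                vals.append(M[i, j])
        return pairs, np.array(vals)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            D=self.D[np.ix_(idx, idx)],
            metric_id=self.metric_id,
            normalized=self.normalized,
        )

    # --- TSV round trip ----------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["\t".join(["id"] + self.ids)]
        for i, pid in enumerate(self.ids):
            lines.append(
                "\t".join([pid] + [f"{x:.8g}" for x in self.D[i]])
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, metric_id: str = "external") -> "DistanceMatrix":
        rows = [ln.split("\t") for ln in text.strip().splitlines()]
        ids = rows[0][1:]
        D = np.array([[float(x) for x in row[1:]] for row in rows[1:]])
        return cls(ids=ids, D=D, metric_id=metric_id)


@dataclass
class NormalizationMap:
    """Native -> min–max normalized threshold map."""

    dmin: float
    dmax: float

    def to_normalized(self, t: float) -> float:
        return (t - self.dmin) / (self.dmax - self.dmin)

    def to_native(self, x: float) -> float:
        return self.dmin + x * (self.dmax - self.dmin)


@dataclass
class CorrelationReport:
    rho_onset: float          # NaN marks "undefined" (onset subset < 3 pairs)
    rho_global: float
    n_onset: int
    n_total: int
    thresholds: tuple[float, float] = (math.inf, math.inf)


def pairwise_distances(vectors: list[PocketEmbedding]) -> DistanceMatrix:
    """Euclidean distances between pocket vectors; exact symmetry comes from
    computing each unordered pair once (condensed form)."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 pocket vectors")
    embedder_ids = {v.embedder_id for v in vectors}
    dims = {v.dim for v in vectors}
    if len(embedder_ids) > 1 or len(dims) > 1:
        raise EmbedderMismatch(
            f"mixed embedders/dimensions: {sorted(embedder_ids)} dims={sorted(dims)}"
        )
    X = np.array([v.vector for v in vectors])
    D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(
        ids=[v.pocket_id for v in vectors],
        D=D,
        metric_id=f"euclidean:{vectors[0].embedder_id}",
    )


def minmax_normalize(D: DistanceMatrix) -> tuple[DistanceMatrix, NormalizationMap]:
    """Map off-diagonal distances linearly onto [0, 1]; the diagonal stays
    zero.  Also returns the native->normalized threshold map."""
    off = D.off_diagonal()
    if off.size == 0:
        raise ValueError("need at least 2 pockets")
    dmin, dmax = float(off.min()), float(off.max())
    if math.isclose(dmin, dmax):
        raise DegenerateScale("all off-diagonal distances are equal")
    M = (D.D - dmin) / (dmax - dmin)
    np.fill_diagonal(M, 0.0)
    out = DistanceMatrix(
        ids=list(D.ids),
        D=M,
        metric_id=D.metric_id + ":minmax",
        normalized=True,
    )
    return out, NormalizationMap(dmin, dmax)


_ALIGNER = None


def _get_aligner(gap_open: float, gap_extend: float):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def sequence_distance(
    seq_a: str, seq_b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """1 - identity under global (Needleman–Wunsch) alignment, BLOSUM62
    scoring, identity = identical aligned positions / alignment length
    including gaps."""
    if not seq_a or not seq_b:
        raise EmptyInput("sequences must be non-empty")
    aligner = _get_aligner(gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    identity = identical / len(a_row)
    return 1.0 - identity


def onset_correlation(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    t_max_a: float = math.inf,
    t_max_b: float = math.inf,
) -> CorrelationReport:
    """Spearman rank correlation globally and over the onset region: pairs
    strictly below either metric's maximum clustering threshold.  With both
    thresholds infinite the onset reduces exactly to the global
    correlation.  An onset subset of fewer than 3 pairs yields NaN (an
    explicit undefined marker, not 0)."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("distance arrays must be 1-D and equal length")
    if a.size < 3:
        raise ShapeError("need at least 3 pairs")
    rho_global = float(spearmanr(a, b).statistic)
    mask = (a < t_max_a) | (b < t_max_b)
    n_onset = int(mask.sum())
    if n_onset < 3:
        rho_onset = float("nan")
    else:
        rho_onset = float(spearmanr(a[mask], b[mask]).statistic)
    return CorrelationReport(
        rho_onset=rho_onset,
        rho_global=rho_global,
        n_onset=n_onset,
        n_total=int(a.size),
        thresholds=(t_max_a, t_max_b),
    )


def threshold_from_largest_gap(
    D: DistanceMatrix, min_frac: float = 0.10, max_frac: float = 0.75
) -> float:
    """Pick a clustering threshold from the distance histogram: the
    midpoint of the largest gap between consecutive sorted off-diagonal
    distances.  With well-separated within-group and between-group
    distances this lands inside the empty band between the two modes.

    Only gaps with a fraction of values below them in
    ``[min_frac, max_frac]`` are considered, so that a sparse tail of
    near-duplicate pairs at distance ~0 (or a few extreme outliers) cannot
    capture the threshold."""
    off = np.sort(D.off_diagonal())
    if off.size < 2:
        raise ValueError("need at least 2 off-diagonal distances")
    gaps = np.diff(off)
    below = (np.arange(1, off.size)) / off.size
    ok = (below >= min_frac) & (below <= max_frac)
    if not ok.any():
        ok = np.ones_like(gaps, dtype=bool)
    k = int(np.flatnonzero(ok)[np.argmax(gaps[ok])])
    return float((off[k] + off[k + 1]) / 2.0)
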