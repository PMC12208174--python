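"""Per-residue embeddings and pocket-vector pooling.

Embeddings are always computed on the *full chain sequence* and only then
indexed by the interface residues — never on the interface subsequence
alone — so each residue vector carries global sequence context.  Mean
pooling of the per-residue vectors over the interface residues yields the
pocket embedding, the pocket's coordinate in metric space.

Two embedders are provided behind one interface:

* ``mock`` — a fully deterministic hash embedder for tests and CI.
  Component ``k`` of residue ``(letter a, position p)`` is the 64-bit
  FNV-1a hash of the bytes ``(a, p mod 64, k_lo, k_hi)`` mapped linearly to
  ``[-1, 1]``.  Integer hashing means the matrix is bit-identical across
  platforms and runs.  A window variant averages positions ``p-1..p+1`` to
  give the mock weak context sensitivity.
* ``external-plm`` — an adapter for a real protein language model
  (final-layer per-residue representations, special tokens stripped).  If
  the model stack is not installed the adapter raises
  :class:`EmbedderUnavailable`; it never silently substitutes the mock.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlphabetError,
    EmbedderUnavailable,
    EmptyInterface,
    IndexMismatch,
)

ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


@dataclass(frozen=True)
class EmbedderSpec:
    kind: str = "mock"            # "mock" | "external-plm"
    dim: int = 32
    model_id: str | None = None
    window: bool = False          # mock context window p-1..p+1

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.kind not in ("mock", "external-plm"):
            raise ValueError("kind must be 'mock' or 'external-plm'")

    @property
    def embedder_id(self) -> str:
        if self.kind == "mock":
            return f"mock-d{self.dim}" + ("-w" if self.window else "")
        return f"plm:{self.model_id}"


@dataclass
class ResidueEmbeddingMatrix:
    complex_id: str
    matrix: np.ndarray            # (L, D)
    embedder_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (L x D)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix must be finite")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PocketEmbedding:
    pocket_id: str
    vector: np.ndarray
    n_interface_residues: int
    embedder_id: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.n_interface_residues < 1:
            raise ValueError("n_interface_residues must be >= 1")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("pocket vector must be finite")

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


def _fnv1a64(data: bytes) -> int:
    h = _FNV_OFFSET
    for b in data:
        h ^= b
        h = (h * _FNV_PRIME) & _MASK64
    return h


def _avalanche(h: int) -> int:
    # splitmix64 finalizer: plain FNV-1a is affine in changes to trailing
    # bytes, which would make the components of one residue vector nearly
    # collinear; full avalanche decorrelates them
    h ^= h >> 30
    h = (h * 0xBF58476D1CE4E5B9) & _MASK64
    h ^= h >> 27
    h = (h * 0x94D049BB133111EB) & _MASK64
    h ^= h >> 31
    return h


def _mock_component(letter: str, pos: int, k: int) -> float:
    h = _avalanche(
        _fnv1a64(bytes([ord(letter), pos % 64, k & 0xFF, (k >> 8) & 0xFF]))
    )
    # top 53 bits -> exactly representable float in [0, 1) -> [-1, 1)
    return (h >> 11) / float(1 << 53) * 2.0 - 1.0


def _mock_matrix(sequence: str, dim: int, window: bool) -> np.ndarray:
    base = np.array(
        [[_mock_component(a, p, k) for k in range(dim)]
         for p, a in enumerate(sequence)]
    )
    if not window:
        return base
    out = np.empty_like(base)
    L = len(sequence)
    for p in range(L):
        lo, hi = max(0, p - 1), min(L, p + 2)
        out[p] = base[lo:hi].mean(axis=0)
    return out


def window_slices(length: int, max_len: int = 1022, overlap: int = 200):
    """Overlapping windows used by the external adapter for sequences longer
    than the model context; rows in the overlap are averaged."""
    if length <= max_len:
        return [(0, length)]
    step = max_len - overlap
    slices = []
    start = 0
    while start + max_len < length:
        slices.append((start, start + max_len))
        start += step
    slices.append((length - max_len, length))
    return slices


def merge_windows(length: int, dim: int, windows, arrays) -> np.ndarray:
    """Average per-residue rows over overlapping window arrays."""
    acc = np.zeros((length, dim))
    cnt = np.zeros(length)
    for (lo, hi), arr in zip(windows, arrays):
        acc[lo:hi] += arr
        cnt[lo:hi] += 1
    return acc / cnt[:, None]


def _embed_external(sequence: str, spec: EmbedderSpec) -> np.ndarray:
    try:
        import esm  # type: ignore  # noqa: F401
        import torch  # type: ignore  # noqa: F401
    except ImportError as exc:
        raise EmbedderUnavailable(
            f"external PLM {spec.model_id!r} requires the 'esm' and 'torch' "
            "packages; install them or use the mock embedder explicitly"
        ) from exc
    model, alphabet = esm.pretrained.load_model_and_alphabet(spec.model_id)
    model.eval()
    converter = alphabet.get_batch_converter()
    final_layer = model.num_layers
    outs = []
    slices = window_slices(len(sequence))
    for lo, hi in slices:
        _, _, tokens = converter([("seq", sequence[lo:hi])])
        with torch.no_grad():
            rep = model(tokens, repr_layers=[final_layer])
        arr = rep["representations"][final_layer][0, 1 : hi - lo + 1].numpy()
        outs.append(arr)
    return merge_windows(len(sequence), outs[0].shape[1], slices, outs)


def embed_sequence(sequence: str, spec: EmbedderSpec) -> ResidueEmbeddingMatrix:
    """Per-residue embedding matrix (row i = residue at seq_index i)."""
    if not sequence:
        raise AlphabetError("sequence is empty")
    bad = set(sequence) - ALPHABET
    if bad:
        raise AlphabetError(f"unknown sequence characters: {sorted(bad)}")
    if spec.kind == "mock":
        matrix = _mock_matrix(sequence, spec.dim, spec.window)
    else:
        matrix = _embed_external(sequence, spec)
    return ResidueEmbeddingMatrix(
        complex_id="", matrix=matrix, embedder_id=spec.embedder_id
    )


def embed_complex(cplx, spec: EmbedderSpec) -> ResidueEmbeddingMatrix:
    """Embed a complex's chain sequence, tagging the matrix with its id."""
    mat = embed_sequence(cplx.sequence, spec)
    mat.complex_id = cplx.complex_id
    return mat


def pool_pocket_embedding(
    residues: ResidueEmbeddingMatrix, interface
) -> PocketEmbedding:
    """Mean-pool embedding rows over the interface residues.

    ``interface`` may be an :class:`~pocketatlas.tessellation.InterfaceResidueSet`
    or any iterable of residue indices.
    """
    indices = getattr(interface, "residue_indices", interface)
    idx = sorted(set(int(i) for i in indices))
    if not idx:
        raise EmptyInterface("cannot pool over an empty interface")
    L = len(residues)
    if idx[0] < 0 or idx[-1] >= L:
        raise IndexMismatch(
            f"interface index {idx[-1] if idx[-1] >= L else idx[0]} outside "
            f"embedding matrix of length {L} — sequence/structure misaligned?"
        )
    vector = residues.matrix[idx].mean(axis=0)
    return PocketEmbedding(
        pocket_id=residues.complex_id,
        vector=vector,
        n_interface_residues=len(idx),
        embedder_id=residues.embedder_id,
    )


def save_embeddings(path, matrices: list[ResidueEmbeddingMatrix]) -> None:
    """Dense archive: ids + row-major matrices, 32-bit floats on disk."""
    arrays = {f"mat_{m.complex_id}": m.matrix.astype(np.float32) for m in matrices}
    arrays["ids"] = np.array([m.complex_id for m in matrices])
    arrays["embedder_id"] = np.array([matrices[0].embedder_id])
    np.savez(path, **arrays)


def load_embeddings(path) -> list[ResidueEmbeddingMatrix]:
    with np.load(path, allow_pickle=False) as npz:
        embedder_id = str(npz["embedder_id"][0])
        return [
            ResidueEmbeddingMatrix(
                complex_id=str(cid),
                matrix=npz[f"mat_{cid}"].astype(float),
                embedder_id=embedder_id,
            )
            for cid in npz["ids"]
        ]
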