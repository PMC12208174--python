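"""Independent brute-force oracles the tests check the production paths
against.  Nothing here imports the implementation modules it oversees."""
import itertools

import numpy as np


def brute_force_delaunay_edges(points: np.ndarray, tol: float = 1e-9) -> set:
    """All Delaunay edges of a 3D point set in general position, from first
    principles: a 4-subset forms a Delaunay tetrahedron iff its circumsphere
    contains no other point; an edge exists iff some such tetrahedron
    contains both endpoints.  O(n^5) — small inputs only."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    combs = np.array(list(itertools.combinations(range(n), 4)))
    for chunk in np.array_split(combs, max(1, len(combs) // 20000)):
        P = pts[chunk]                                     # (m, 4, 3)
        A = 2.0 * (P[:, 1:] - P[:, :1])                    # (m, 3, 3)
        b = (P[:, 1:] ** 2).sum(-1) - (P[:, :1] ** 2).sum(-1)
        det = np.linalg.det(A)
        good = np.abs(det) > 1e-10
        centers = np.full((len(chunk), 3), np.nan)
        if good.any():
            centers[good] = np.linalg.solve(A[good], b[good][..., None])[..., 0]
        radii = np.linalg.norm(P[:, 0] - centers, axis=-1)
        dists = np.linalg.norm(pts[None, :, :] - centers[:, None, :], axis=-1)
        member = np.zeros((len(chunk), n), dtype=bool)
        member[np.arange(len(chunk))[:, None], chunk] = True
        inside = (dists < radii[:, None] - tol) & ~member
        empty = good & ~inside.any(axis=1)
        for comb in chunk[empty]:
            for i, j in itertools.combinations(sorted(int(x) for x in comb), 2):
                edges.add((i, j))
    return edges


def brute_force_interface(prot_xyz, prot_res, lig_xyz, radius) -> set:
    """Interface residues via the brute-force Delaunay oracle + distance
    truncation."""
    pts = np.vstack([prot_xyz, lig_xyz])
    n_p = len(prot_xyz)
    edges = brute_force_delaunay_edges(pts)
    out = set()
    for i, j in edges:
        if (i < n_p) != (j < n_p):
            p, l = (i, j) if i < n_p else (j, i)
            if np.linalg.norm(pts[p] - pts[l]) <= radius:
                out.add(int(prot_res[p]))
    return out


def connected_components_clusters(D: np.ndarray, t: float) -> list[frozenset[int]]:
    """Clusters as connected components of the d < t graph, via scipy's
    sparse graph machinery (independent of the union-find path)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix((D < t) & ~np.eye(len(D), dtype=bool))
    _, labels = connected_components(adj, directed=False)
    k = labels.max() + 1
    return [frozenset(np.nonzero(labels == c)[0]) for c in range(k)]


def set_partitions(items: list):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_ot_similarity(clusters_a, clusters_b, denominator="max") -> float:
    """Best one-to-one cluster matching by exhaustive enumeration of all
    injective assignments of the smaller side into the larger."""
    A = [frozenset(c) for c in clusters_a]
    B = [frozenset(c) for c in clusters_b]
    ka, kb = len(A), len(B)
    J = np.zeros((ka, kb))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            if a & b:
                J[i, j] = len(a & b) / len(a | b)
    small, big = (ka, kb) if ka <= kb else (kb, ka)
    best = 0.0
    for cols in itertools.permutations(range(big), small):
        total = sum(
            (J[i, c] if ka <= kb else J[c, i]) for i, c in enumerate(cols)
        )
        best = max(best, total)
    denom = max(ka, kb) if denominator == "max" else min(ka, kb)
    return best / denom


def exhaustive_scramble_null(clusters_a, clusters_b, ids) -> tuple[float, float]:
    """Mean and std of the OT similarity under every distinct reshuffling of
    which id carries which cluster label in B (cluster sizes retained).
    Feasible for n <= 8."""
    label_of = {}
    for lab, c in enumerate(clusters_b):
        for pid in c:
            label_of[pid] = lab
    base = tuple(label_of[pid] for pid in ids)
    seen = set()
    vals = []
    for perm in itertools.permutations(base):
        if perm in seen:
            continue
        seen.add(perm)
        k = max(perm) + 1
        clusters = [frozenset(pid for pid, lab in zip(ids, perm) if lab == c)
                    for c in range(k)]
        vals.append(brute_force_ot_similarity(clusters_a, clusters))
    return float(np.mean(vals)), float(np.std(vals))


def prufer_trees(n: int):
    """All labeled trees on n nodes via Prüfer sequences (n >= 2)."""
    if n == 1:
        yield []
        return
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        seq = list(seq)
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        edges = []
        work = list(seq)
        avail = sorted(i for i in range(n) if degree[i] == 1)
        import heapq

        heap = list(avail)
        heapq.heapify(heap)
        deg = degree[:]
        for x in work:
            leaf = heapq.heappop(heap)
            edges.append((min(leaf, x), max(leaf, x)))
            deg[x] -= 1
            if deg[x] == 1:
                heapq.heappush(heap, x)
        u, v = sorted([heapq.heappop(heap), heapq.heappop(heap)])
        edges.append((u, v))
        yield edges


def brute_force_mst_weight(W: np.ndarray) -> float:
    """Minimum spanning-tree weight by enumerating every labeled tree."""
    n = len(W)
    best = np.inf
    for edges in prufer_trees(n):
        w = sum(W[u, v] for u, v in edges)
        best = min(best, w)
    return float(best)


def brute_force_global_alignment(a: str, b: str, matrix, gap_open: float,
                                 gap_extend: float):
    """Enumerate every global alignment of two short strings and return
    (best score, set of identity values among the optimal alignments).
    The first position of a gap run costs gap_open, each later one
    gap_extend (the PairwiseAligner convention)."""
    best_score = -np.inf
    best_idents: set[float] = set()

    def walk(i, j, score, ident, length, prev):
        nonlocal best_score, best_idents
        if i == len(a) and j == len(b):
            if score > best_score + 1e-9:
                best_score = score
                best_idents = {ident / length}
            elif abs(score - best_score) <= 1e-9:
                best_idents.add(ident / length)
            return
        if i < len(a) and j < len(b):
            s = matrix[a[i], b[j]]
            walk(i + 1, j + 1, score + s, ident + (a[i] == b[j]), length + 1, "M")
        if i < len(a):
            cost = gap_extend if prev == "D" else gap_open
            walk(i + 1, j, score - cost, ident, length + 1, "D")
        if j < len(b):
            cost = gap_extend if prev == "I" else gap_open
            walk(i, j + 1, score - cost, ident, length + 1, "I")

    walk(0, 0, 0.0, 0, 0, "")
    return best_score, best_idents
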