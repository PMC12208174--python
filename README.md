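# pocketatlas

Alignment-free similarity analysis for protein–ligand binding sites, built
on per-residue protein-language-model embeddings.

Binding sites (pockets) are the interfaces that determine a protein's
activity, and comparing them across the PDB underpins target discovery,
ligand transfer, druggability modelling, and — increasingly — the honest
benchmarking of pocket-centric machine-learning models, whose train/test
splits leak badly when near-duplicate pockets straddle the boundary.
Alignment-based pocket comparison is accurate but expensive; sequence
identity is cheap but blind to 3D similarity. `pocketatlas` implements a
middle path: a pocket is represented by the mean of per-residue
language-model embedding vectors over its *interface residues*, and pockets
are compared by plain Euclidean distance between those vectors.

## Method

For a protein–ligand complex with chain sequence *s* and per-residue
embedding matrix *E ∈ ℝ^{L×D}* (computed on the full chain, so every row
carries global sequence context):

1. **Interface residues.** A radially truncated Voronoi tessellation of the
   union point set (all protein heavy atoms + all ligand heavy atoms)
   defines contacts: protein atom *i* contacts ligand atom *j* iff their
   Voronoi cells share a facet **and** ‖xᵢ − xⱼ‖ ≤ r (default r = 6 Å). A
   residue is in the interface 𝓘 iff one of its atoms is in contact. The
   facet condition excludes residues that are within range but buried
   behind the first shell.
2. **Pocket vector.** v = (1/|𝓘|) Σ_{i∈𝓘} Eᵢ, and the pocket metric is
   d(a, b) = ‖vₐ − v_b‖₂.
3. **Clustering with a separation guarantee.** The partition at threshold
   *t* is the set of connected components of the graph with an edge
   wherever d < t (the single-linkage cut), so for any two clusters A ≠ B
   and pockets a ∈ A, b ∈ B, d(a, b) ≥ t holds structurally.
4. **Pocket atlas.** Clusters become nodes of a minimum spanning tree
   weighted by the minimum distance of approach between clusters. Spatial
   coherence of per-cluster annotations is scored with Moran's I against a
   permutation null (E[I] = −1/(n−1)).
5. **Debiased splits.** Whole clusters (or whole MST branches) are
   allocated to train or test, which upper-bounds leakage by construction;
   `validate_split` counts any residual train–test pairs below *t*. A
   per-residue ligand-contact MLP harness quantifies split hardness by
   pooled ROC-AUC.

Two partitions of the same pockets are compared with an optimal-transport
score: the one-to-one cluster matching that maximizes the total Jaccard
index, normalized by the larger cluster count, with a scrambled-label null
(cluster sizes kept, pocket labels reshuffled).

Embedders are pluggable: a deterministic mock (integer hashing, for tests
and CI) and an adapter for external protein language models such as ESM-2
(final-layer per-residue representations; raises a clear error when the
model stack is not installed). Real PDB complexes are parsed with gemmi;
a synthetic-complex generator plants interface ground truth (plus buried
decoys) for validation.

## Worked example

Thirty synthetic pockets in three planted families, clustered at a
threshold read off the distance histogram:

```python
from pocketatlas import (
    generate_pocket_families, compute_interface_residues, TessellationParams,
    EmbedderSpec, embed_complex, pool_pocket_embedding, pairwise_distances,
    threshold_from_largest_gap, cluster_single_linkage, Clustering,
    ot_cluster_similarity, scrambled_null, cluster_split, validate_split,
)
from pocketatlas.clustering import _canonical_labels

members = generate_pocket_families(
    n_superfamilies=3, families_per_superfamily=1,
    members_per_family=10, seed=42,
)
spec = EmbedderSpec(kind="mock", dim=32)
vectors = []
for m in members:
    interface = compute_interface_residues(m.truth.complex, TessellationParams(6.0))
    vectors.append(pool_pocket_embedding(embed_complex(m.truth.complex, spec), interface))

D = pairwise_distances(vectors)
t = threshold_from_largest_gap(D)
clusters = cluster_single_linkage(D, t)
planted = Clustering(ids=list(D.ids),
                     labels=_canonical_labels([m.family for m in members]), t=0.0)
comparison = ot_cluster_similarity(clusters, planted)
null = scrambled_null(clusters, planted, reps=200, seed=0)
split = cluster_split(clusters, test_fraction=0.3, seed=0)
leakage = validate_split(split, D, t)

print(f"pockets: {len(D.ids)}   threshold t = {t:.2f}")
print(f"clusters found: {clusters.n_clusters}")
print(f"OT similarity vs planted families: {comparison.similarity:.3f} "
      f"(scrambled null {null:.3f})")
print(f"cluster split: {len(split.train_ids)} train / {len(split.test_ids)} test, "
      f"{leakage.n_violating_pairs} leaking pairs below t "
      f"(min cross distance {leakage.min_cross_distance:.2f})")
```

Output:

```
pockets: 30   threshold t = 1.08
clusters found: 3
OT similarity vs planted families: 1.000 (scrambled null 0.300)
cluster split: 20 train / 10 test, 0 leaking pairs below t (min cross distance 1.44)
```

The threshold found in the gap of the distance histogram recovers the three
planted families exactly (optimal-transport similarity 1.0 against the
planted partition, versus 0.30 for size-preserving label scrambles), and
the cluster-based split has zero train–test pairs closer than *t* — the
separation guarantee at work.

The same pipeline is available from the shell (`pocketatlas --help`):
`extract`, `ligands`, `interface`, `embed`, `pool`, `dist`, `correlate`,
`cluster`, `compare`, `atlas`, `moran`, `split cluster|tree|validate`,
`label`, `drugmodel`.

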