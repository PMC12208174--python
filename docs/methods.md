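# Methods

## Pocket representation

A pocket is represented by the arithmetic mean of per-residue embedding
vectors over its interface residues. Two assumptions matter:

* **Embeddings are computed on the full chain sequence** and only then
  indexed by interface position. Pooling a subsequence embedding would
  discard the global sequence context that makes language-model vectors
  informative, and would break the 1:1 row↔residue correspondence with the
  structure. Consequently the sequence holds only resolved residues (no gap
  characters for missing density), residues are indexed 0-based within the
  extracted chain concatenation, and a `(chain, author number, insertion
  code) → seq_index` table keeps structure and sequence aligned.
* **Interfaces come from geometry, not from the embedding.** A protein atom
  and a ligand atom are in contact iff their Voronoi cells (over the union
  of all protein and ligand heavy atoms) share a facet *and* they are within
  the truncation radius. Adjacency is computed as Delaunay-edge adjacency,
  which is the exact dual statement. The radius suppresses the long-range
  facets of unbounded boundary cells; the facet condition removes residues
  that are within range but occluded by the first shell. Only heavy atoms
  participate; hydrogens are dropped on input.

The test suite pins this construction to a from-first-principles oracle
(every 4-subset with an empty circumsphere is a Delaunay tetrahedron) rather
than to a second library call. During development we found that SciPy's
`Voronoi.ridge_points` omits some hull–hull adjacencies that the exact
enumeration (and SciPy's own `Delaunay`) contains, which is why the
production path and the oracle are both Delaunay-based.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| truncation radius | 6.0 Å | Voronoi contact cutoff for interface residues; conventional in tessellation-based interface analysis, exposed everywhere |
| contact radius (labels) | 4.0 Å | heavy-atom cutoff for the binary per-residue ligand-contact labels; deliberately tighter than the interface truncation |
| embedder dim (mock) | 32 | mock embedding width; the external-PLM adapter uses the model's native width |
| gap open / extend | 10 / 0.5 | global-alignment penalties for the sequence-distance baseline (BLOSUM62; identity = identical columns / alignment length incl. gaps) |
| clustering threshold *t* | data-driven | native (un-normalized) distance units; larger *t* → fewer, more diverse clusters |
| scrambled-null reps | 100 | mean OT similarity over size-preserving label reshuffles |
| Moran null reps | 999 | permutation null of annotation values over clusters |

The onset region of the two-metric correlation analysis contains pairs
*strictly below* either metric's maximum clustering threshold ("fall below"
⇒ `<`, boundary pairs excluded); Spearman ties get average ranks; an onset
subset smaller than 3 pairs reports NaN, never 0.

## Clustering and separation

The partition at *t* is computed as connected components (union-find) of
the graph with edges where d < *t*, not by cutting a dendrogram: the
separation guarantee — every cross-cluster pair at distance ≥ *t* — is then
a structural property rather than a library behaviour. Merging uses strict
`<`, so a pair at exactly *t* stays separated. Cluster labels are assigned
by order of each cluster's smallest member index, making outputs
byte-stable.

OT cluster similarity divides the maximal one-to-one matched Jaccard sum by
`max(K_A, K_B)`; this makes identity the unique maximizer and is inert when
cluster counts are matched. `denominator="matched"` (divide by the number
of matched pairs) is available. Excluding singletons removes size-1
clusters from both partitions and drops their members globally before
matching.

## Atlas and Moran's I

Cluster-level distances are minimum distances of approach; the atlas is the
MST of the complete cluster graph (Kruskal on edges inserted in (u, v)
order, so equal weights resolve to the lexicographically smallest tree).
Moran's I uses row-unnormalized inverse-distance weights by default, with
an MST-adjacency (0/1) alternative; categorical annotations are one-hot
encoded and reported per category. The permutation null's analytic mean
−1/(n−1) is used as a cross-check in the tests. Layout is delegated to
external tools via GraphML export; no 2D projection is computed here.

## Splits and the hardness progression

Cluster-based splits shuffle clusters (seeded) and assign them to the test
side until the test count first reaches the target fraction; whole clusters
only, overshoot allowed. Tree-based splits remove whole MST branches
(directed cuts, applied sequentially on the shrinking remainder; the parent
side always stays in train). `balance_to_size` moves whole clusters to
approach a target fraction and flags infeasibility instead of ever dividing
a cluster. `validate_split` counts residual train–test pairs below *t*;
for cluster splits at their own threshold this is zero by construction.

The druggability harness trains a scikit-learn `MLPClassifier` (hidden
layers 128/64, ≤200 epochs, fixed seed) on per-residue embedding rows.
Because `MLPClassifier` accepts no per-sample weights, the inverse-frequency
class weighting is implemented as deterministic integer oversampling of the
minority class; reported train AUC is computed on the un-oversampled rows.
AUC is the pooled ROC-AUC over all residues of a split side.

## Mock embedder

Component *k* of residue (letter *a*, position *p*) is a 64-bit FNV-1a hash
of the bytes `(a, p mod 64, k_lo, k_hi)` passed through a splitmix64
avalanche finalizer and mapped linearly onto [−1, 1]. The finalizer is
essential: FNV-1a alone is affine in changes to the trailing (component)
bytes, which makes the components of one residue vector nearly collinear
and collapses pocket-vector geometry. Integer hashing end to end means the
matrix is bit-identical across platforms and runs. A window variant
averages positions p−1..p+1 for weak context sensitivity. The external
adapter contract is: final-layer per-residue representations, special
tokens stripped, sequences beyond the model context split into 1022-wide
windows with 200-residue overlap and averaged on the overlap; it raises
`EmbedderUnavailable` rather than substituting the mock.

## Synthetic data: what it emulates, and what it does not

`generate_synthetic_complex` builds a helix-like chain (consecutive CA
atoms ≈3.8 Å apart where radial geometry permits, one side-chain
pseudo-atom per residue) around a 3–8 atom ligand such that, by
construction and post-hoc verification: planted interface residues have an
atom within 0.6·r of a ligand atom; all other residues except the decoys
keep every atom beyond r; buried decoys sit within r but directly behind a
first-shell atom on the segment to their nearest ligand atom. Candidate
geometries failing any constraint (including a tessellation check of the
decoy occlusion) are rebuilt with fresh jitter; generation is deterministic
per seed. At most 8 interface residues are supported (one dedicated ligand
atom each).

`generate_pocket_families` arranges such pockets in a two-level hierarchy:
superfamilies share an ancestral sequence and interface position set;
families relocate a fraction of interface positions (overlap 0.375 of 8 by
default) and diverge ~8% in sequence, each with its own fold; members share
the family fold and differ by one designated hypervariable interface site
(mutated with probability 0.7) plus two non-interface mutations. With the
position-hashed mock embedder this yields three well-separated distance
bands — within-family < sibling-family < cross-superfamily — so that
histogram-gap thresholding, exact family recovery, MST branch structure,
and the random < cluster < branch split-hardness progression are genuine,
testable consequences of the geometry rather than tuned outcomes. Problem
sizes in the tests and the acceptance script (tens of pockets of ~48
residues, mock dimension 32) were chosen so the full pipeline, including
classifier training, runs in seconds on one CPU.

What the synthetic data does **not** emulate: real side-chain chemistry and
packing, solvent, crystallographic artefacts (altlocs and insertion codes
are exercised by hand-written PDB fixtures instead), multi-chain
interfaces, and — most importantly — the semantic content of real PLM
embeddings. The mock embedder has position-letter granularity and no
long-range context, so passing tests demonstrate the correctness of the
geometry, pooling, metric, clustering, graph, and split machinery, not that
language-model embeddings themselves resolve binding-site similarity; that
claim can only be assessed with the external-PLM adapter on real
structures.

## Numerical choices and degenerate inputs

* Coplanar/collinear point sets raise `DegenerateGeometry`; an explicit
  seeded jitter flag (default off) or the distance-only fallback are the
  sanctioned escapes — nothing is perturbed silently.
* Min–max normalization is over off-diagonal entries only, keeps the
  diagonal at zero, errors on constant off-diagonals, and returns the
  native→normalized threshold map alongside the matrix.
* Distance matrices are computed once per unordered pair (condensed form),
  so symmetry is exact, not approximate.
* `threshold_from_largest_gap` restricts candidate gaps to those with an
  interior fraction of values below them (10–75%), so a handful of
  identical pockets at distance ≈0, or extreme outliers, cannot capture
  the threshold.
* Moran's I with inverse-distance weights rejects zero off-diagonal cluster
  distances (`WeightError`) — impossible under the separation guarantee and
  therefore a symptom of duplicated pockets.
* Pocket vectors are stored as 32-bit floats on disk; distances are
  computed in 64-bit.

## Known limitations

* mmCIF input is out of scope (PDB fixed-column only); multimeric pockets
  are handled by a single-chain default or an explicit concatenation flag,
  and the right treatment of ligands bridging two chains is an open
  question flagged for sensitivity testing.
* The facet condition is binary; no minimum facet-area filter is
  implemented.
* Homology-based splits are accepted as external id lists, not computed.
* The external-PLM path is code-identical to the mock path but cannot be
  exercised in environments without the model stack.
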