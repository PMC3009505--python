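# Methods

## Glycan model

A glycan is a rooted tree whose nodes carry monosaccharide labels and
whose edges carry glycosidic bond labels of the grammar
`[anomer][donor]-[acceptor]` (each part optional: `b1-4`, `-6`, `b1-`,
`-`).  The root is the reducing end; each node has at most four
children (exceeding four is a validation warning by default, an error
under strict validation, since database entries occasionally violate
the biological bound).  Sibling order is chemically meaningless, so
trees are semantically unordered; a canonical child order — (bond code,
child mono code, child node id) — is imposed wherever determinism
matters (serialization, enumeration).  The *layer* of a node is its
linkage distance from the root (root = 0).  The root has no parent
bond; operations that need one use a reserved wildcard label `*` whose
similarity to any bond is 1, which keeps q-gram tuples uniform without
penalizing root comparisons.

File I/O uses a KCF dialect (`ENTRY`/`NODE`/`EDGE` blocks, `///`
separators).  Only node index, mono label and bond label are semantic;
2-D layout columns are ignored on input and written as zeros.  Writing
renumbers nodes 1..n in canonical pre-order, so serialization is
deterministic and write→parse is label-isomorphic to the input.

## q-grams

A q-gram is a connected q-node subtree in which every node has at most
two neighbors inside the subtree.  On a rooted tree such a "path" is
either a straight ancestor→descendant chain or bends at a unique apex
(its shallowest node) with two descending arms; this is the only
reading under which the structure-shape descriptor σ is non-trivial
for path subtrees, and a straight-only mode is kept behind a flag for
comparison.  The shape is σ = (len_first, len_second): (q, 0) for
straight chains, (1+a, b) for an apex with arms of a and b nodes.

Canonicalization: traversal starts at the apex, walks the first chain
top-down, then the second.  The two arms are ordered by (length
descending, then mono-label sequence, then bond-label sequence).  For
arms with lengths a = b+1 the shape could ambiguously be read as
(a+1, b) or (b+1, a); the arm-ordering rule fixes (1+len(arm1),
len(arm2)) deterministically.  The identity key of a q-gram is
(q, σ, monos, bonds); the apex layer is carried per occurrence but
excluded from the key — otherwise identical substructures at different
depths would never co-count and the weighted method could not reduce
to the classical q-gram method.  Layers enter only similarity scoring;
each indexed key is assigned its corpus-representative layer, the most
frequent layer of that key (ties toward the root), the least arbitrary
single value when one l must represent a key.

Enumeration is apex-wise: all downward chains of q nodes, plus, for
bent grams, all pairs of downward chains through distinct children
(O(nodes × q × degree²)).  It is validated exactly against a
brute-force oracle that enumerates every node subset, checks
connectivity and internal degree, and canonicalizes independently.

The count matrix builder is `strict` by default — a q-gram key missing
from the index raises, guarding against silent feature-space leakage
between corpora — with an `extend` policy for train/test workflows.

## Linkage (LK) similarity

Two q-grams with different shapes are totally dissimilar (score 0).
For equal shapes, the score combines, under the canonical position
alignment (no re-matching across chains, which would silently change
the feature map):

* layer similarity S^l(l_i, l_j) = 1/(1 + |l_i − l_j|).  The exact
  functional form is a design choice constrained to be 1 at distance 0
  and strictly decreasing in layer distance; the reciprocal form also
  induces a PSD matrix on integer layers.  An exponential alternative
  (0.5^Δl) is available.
* monosaccharide similarity: identity by default; a user TSV (e.g.
  SIMCOMP-derived scores) can replace it.  Identical labels score 1
  even when unlisted; distinct unlisted pairs score 0.
* bond similarity: the shipped 15×15 table over the most frequent
  bonds, symmetrized with unit diagonal.  Fallbacks are conservative:
  unlisted identical bonds → 1, unlisted distinct pairs → 0, wildcard
  root bond → 1.

The combination rule is the product (a `mean` switch exists): any
totally dissimilar component annihilates the match, consistent with
the shape gate, and products of PSD component structures favor
positive semidefiniteness (Schur product theorem).  With identity
mono/bond tables the LK matrix over an index is exactly the identity
matrix, so the weighted kernel reduces to the plain q-gram kernel — a
tested invariant.

## KCaM-style alignment (KM, LKM)

The aligner is an approximate-matching dynamic program over node pairs:

    Q[u][v] = max( w(u,v) + best injective children assignment Σ Q[c_u][c_v],
                   max_cu Q[c_u][v] − gap,  max_cv Q[u][c_v] − gap,  0 )

Children assignments are solved exactly by exhaustion (≤ 4! = 24
injections at glycan degrees).  The gap penalty defaults to 0 (skips
free), mirroring approximate matching's tolerance of skipped nodes.
Global mode (default for q-gram similarity: q-grams are whole
substructures) reads the score at the root pair; local mode maximizes
over all pairs.  On small trees the DP provably equals exhaustive
search over injective node mappings that preserve ancestry in both
directions and keep disjoint child subtrees disjoint (lca
consistency) — a tested oracle equivalence.

Node scoring: `exact` (KM) scores 1 iff mono labels and parent bonds
are equal (wildcard at roots matches anything) — structure identity
only; `linkage` (LKM) scores mono × bond × layer similarity, with each
materialized q-gram's apex placed at its representative layer.
Published score matrices for this algorithm's monosaccharide/linkage
weighting are not available as data; LKM deliberately reuses the LK
component tables instead.

Normalization: score(s,t) = 100·raw(s,t)/√(raw(s,s)·raw(t,t)), clamped
to [0,100] — 100 on self, symmetric, and bounded since node scores are
≤ 1 with unit self-scores.  Degenerate zero self-scores raise a
configuration error.  Matrices over a q-gram index are rescaled to
[0,1] for kernel use.

## Kernels

K_q = X_qᵀX_q; K_wq = X_qᵀW_qX_q (the feature-space square root of W_q
is never materialized — the quadratic form is equivalent and cheaper);
K_Q = Σ_q K_q; K_αwQ = Σ_q α_q K_wq.  Alignment similarity matrices are
not guaranteed PSD, so W_q is revised: symmetrize, clip negative
eigenvalues to zero (the Frobenius-nearest PSD matrix), add a 1e−9
ridge; a diagonal-shift alternative (`shift`) preserves off-diagonals
exactly.  Each weight matrix carries a provenance report (min
eigenvalue before/after, ridge, method).  Every emitted kernel is
checked symmetric within 1e−10 and PSD within −1e−8.

Cosine normalization (K_st/√(K_ss K_tt)) is available and off by
default; it is recommended before comparing or combining kernels
across q because raw count scales grow with d_q.

## Classification protocol

Soft-margin SVM (scikit-learn SVC, `kernel="precomputed"`), cost fixed
at 1 by default since no hyperparameter tuning is part of the
protocol.  Stratified 5-fold cross-validation repeated 50 times by
default; fold splits are seeded `seed + repeat` so repeats are
independent yet reproducible.  AUC is the midrank Mann–Whitney
statistic; per-repeat AUC averages the fold AUCs, and the result
aggregates repeats (pooling over folds instead is a one-line change
and was not adopted as the default).  Samples are internally ordered
by glycan id before splitting, making results invariant to
simultaneous permutation of kernel and labels.

Multiple-kernel weighting uses centered kernel-target alignment —
each kernel's Frobenius alignment with yyᵀ after double-centering,
floored at 0, normalized to sum 1, with a uniform fallback — a
deterministic, dependency-light weighting adequate for combining a
handful of kernels; it is a simpler scheme than full MKL optimization
of the SVM objective.

## Synthetic data

The generator grows trees top-down: each of `max_children` slots is
filled with probability `branch_prob`, truncated at `max_depth`; node
and bond labels are drawn from configured frequency tables; trees are
rejection-sampled (cap 10,000 attempts) to the node-count range.
Defaults: the 24 most frequent monosaccharides and bonds of the KEGG
glycan database census with their occurrence frequencies (renormalized;
non-sugar labels such as S, P, Cer, Asn and * are kept as ordinary
node labels), 5–15 nodes, max 3 children, branch probability 0.3, max
depth 7 — a slightly subcritical branching process whose trees look
like common N-/O-glycans in size and branchiness.

Planted-motif datasets graft a small fragment into each positive: a
uniformly chosen node at a layer in `graft_layer_range` is replaced by
the motif root (keeping the original parent bond), and displaced child
subtrees are reattached below the motif's deepest leaf while degree
permits, else dropped.  Every positive is verified to embed the motif
by exhaustive subtree search.

What the generator does **not** emulate: biosynthetic pathway
constraints (real glycans reuse a small set of core structures),
label–label correlations along paths, database annotation noise, and
class structure beyond a single planted motif.  Passing benchmarks on
this data therefore demonstrates mechanical correctness and the
intended statistical behavior of the kernels, not classification
performance on curated glycan databases.

## Benchmark problem sizes

Chosen as the package's standing desk-scale study conditions:

* signal recovery: 100 positives (sialyl-motif Neu5Ac-a2-3-Gal-b1-4-
  GlcNAc planted) vs 100 negatives, 2-gram kernel, 5-fold × 10-repeat
  CV; the motif trisaccharide is rare in the background, so mean AUC
  is expected ≥ 0.9, and permuted labels fall to chance (0.4–0.6).
* linkage-weighting benefit: positives scarce by design — per
  replicate, 8 positives carrying GlcNAc←Man b1-4 plus 8 carrying the
  bond-perturbed b1-3 variant against 84 negatives, cosine-normalized
  2-gram kernels, 5-fold × 5-repeat CV, 10 seeded replicates.  With so
  few positives per variant an SVM cannot reliably weight both variant
  features separately, whereas the LK weight matrix couples them
  (bond similarity 0.9) a priori; this is exactly the regime where
  encoding chemical similarity should pay off, and the LK kernel is
  expected to beat the plain kernel in at least 8 of 10 replicates.
  With abundant positives the two kernels tie — the advantage of the
  prior vanishes when the data can speak for itself.

## Numerical and degenerate-input choices

* PSD tolerances: symmetry 1e−10, minimum eigenvalue −1e−8, ridge 1e−9.
* Ties: arm ordering and layer representatives break ties
  deterministically (lexicographic; smallest layer); AUC uses midranks.
* Empty corpus → empty index (d_q = 0), not an error; q larger than a
  glycan → zero column; single-node glycans have no q ≥ 2 grams.
* Alignment traceback resolves ties toward matching the current pair.
* Unknown bond codes that do not parse into the grammar are kept
  verbatim (open vocabulary) and compared by string equality plus
  table lookup.

## Known limitations

* LK similarity cost grows with the square of the number of distinct
  q-grams and, for large q, with the label-combination diversity;
  matrices beyond q ≈ 3 get large on diverse corpora (the classical
  trade-off that restricts the linkage method to small q).
* The KCaM variant implemented is the gap-free approximate-matching
  recursion; it does not reproduce the exact scoring of any specific
  published web-service release.
* Representative layers compress a key's layer distribution to its
  mode; corpora where the same substructure recurs at very different
  depths lose that spread.
* The MKL weighting is alignment-based, not an SVM-objective
  optimizer.
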