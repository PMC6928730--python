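# Methods

This note documents the models and procedures implemented in cavity2vec,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish about real data.

## Cavity sentences and canonical node IDs

A cavity extracted by a Voronoi-based tool is an ordered chain of
spheres from the active site to the protein surface. Each pathway point
corresponds to a Voronoi vertex, which in 3-D is determined by four
non-coplanar atoms — here, the four atoms closest to the sphere center.
The point's identity is carried by those atoms: the **node ID** is the
dot-join of the four atom serials sorted ascending, so all 24 orderings
of the same quadruple collapse to one token and distinct sorted
quadruples map to distinct tokens (the dot-join of integers is
unambiguous). A duplicate serial in the quadruple is rejected as
degenerate rather than silently deduplicated.

Open choices, and how they were resolved:

* **Distance definition.** "Closest four atoms" is computed per sphere
  against the sphere center. Two modes exist: `center` (Euclidean
  center-to-center; the default) and `surface` (center distance minus
  the atom's van-der-Waals radius, as MOLE-style samplers use). Both
  are exposed because extractors differ; per-sphere selection matches
  the four-atoms-per-node data model.
* **Ties** at equal distance break toward the lower serial — an
  arbitrary but deterministic rule.
* **Consecutive duplicate tokens are kept.** Two adjacent spheres lined
  by the same four atoms yield two identical tokens; collapsing them
  would distort token frequencies, which the embedding model uses.
* **Node IDs use atom serials**, not residue numbers; serials are the
  finest identity an extractor reports and keep IDs unique.

## Skip-gram embeddings

Node vectors are trained with a from-scratch skip-gram model. For a
token stream w_1..w_T the objective is the average log probability

    J = (1/T) Σ_t Σ_{-c≤j≤c, j≠0} log p(w_{t+j} | w_t)

with the softmax conditional p(o|i) = exp(v'_o·v_i) / Σ_w exp(v'_w·v_i)
over the W-token vocabulary, computed with max-subtraction for overflow
safety. Windows are truncated at sentence boundaries and fixed by
default (word2vec's per-center random window shrinking exists behind a
flag but is off, so pair enumeration is reproducible by hand).

Two regimes share one training loop:

* **Exact softmax** (`negative=0`): per-pair gradient ascent at
  O(W·d) per update. Retained because it is analytically transparent —
  the analytic gradient is verified against central differences, and a
  full-batch variant (`full_batch_ascent`) must never decrease J with a
  small fixed learning rate, which the tests assert.
* **Negative sampling** (`negative=k>0`, default k=5): the practical
  regime, since the softmax gradient cost grows with W. Each positive
  pair is contrasted with k noise tokens drawn from the unigram
  distribution raised to the 0.75 power (standard word2vec noise).
  Collisions between a noise draw and the positive target are allowed,
  as in the reference implementation; the per-pair objective and its
  analytic gradient are exposed separately and checked against central
  differences with the noise draws held fixed.

Numerical and reproducibility choices: input vectors initialize uniform
in [−0.5/d, 0.5/d], output vectors at zero; learning rate decays
linearly from 0.025 to 0.0001 across all updates; training is
single-threaded, all randomness flows from one seeded generator, and
identical seed+config+corpus reproduces the vector tables bit for bit.
Defaults: d=128 (cavity corpora are well represented above ~100
dimensions), window c=5, 15 epochs, min_count=1 (cavity vocabularies
are small, so nothing is discarded by default; dropped tokens, when
min_count>1, are removed from sentences without a placeholder).
Frequent-token subsampling is deliberately absent. Tests train at
d=8–32 with 2-token windows, which is ample for vocabularies of a few
hundred node IDs.

## Cavity vectors and similarity

A cavity's vector is the plain unweighted mean of its nodes' *input*
vectors (the learned embedding matrix; output vectors are an artifact of
the training objective). No radius- or length-weighting is applied.
Tokens dropped by min_count are skipped and counted (`oov_policy=
"skip"`); a strict policy raises instead; a cavity with no in-vocabulary
token at all is an error naming the cavity. An optional flag
L2-normalizes cavity vectors — cosine-based analyses are scale-invariant
either way, so the default is raw means.

Similarity is the cosine, clamped to [−1, 1] against rounding; a
zero-norm vector has no direction and raises rather than comparing as 0.
Threshold queries use a half-open interval, open below and closed above,
so "similarity larger than 0.9" is (0.9, 1.0] and "between 0 and 0.1" is
(0, 0.1]; both bounds are explicit arguments, so either reading of an
inclusive/exclusive boundary is expressible. Results sort by descending
similarity with cavity-ID tie-breaks.

## Clustering, projection, profiles

* **Hierarchical**: average-link agglomeration on 1 − cosine
  (scipy backend), cut either at a target cluster count or at a
  cophenetic distance threshold — both exposed because neither is
  canonical. The linkage matrix is kept on the result for dendrogram
  inspection. Merge heights are validated against an independent
  O(n³) brute-force recomputation in the tests.
* **K-means**: Lloyd's algorithm (scikit-learn) on L2-normalized
  vectors, so squared Euclidean distance is monotone in cosine distance
  and both clustering routes use the same similarity notion; k-means++
  seeding, best of n_init=10 restarts, seeded and deterministic.
  K-means runs on the full-dimensional vectors, never on t-SNE
  coordinates: the 2-D projection distorts distances and is suitable
  only for choosing k visually.
* **t-SNE** (scikit-learn, PCA initialization, fixed seed) produces the
  2-D inspection view; it requires n > 3·perplexity and is never fed
  back into clustering.
* **Length–width profiles**: cumulative center-to-center arc length
  against sphere radius, starting at 0; the bottleneck is the first
  radius minimum. At zero generator noise these reproduce the template
  radius profiles exactly.
* **Amino-acid profiles**: per cavity, each distinct residue
  (chain + residue number) contributing at least one lining atom counts
  once, tallied by 3-letter code; HID (delta-protonated histidine, a
  simulation naming convention) stays distinct from HIS. A flag switches
  to counting lining atoms instead of distinct residues. Cluster
  profiles are arithmetic means of member-cavity counts.

## The synthetic generator

Real corpora come from a Voronoi extractor run over an MD trajectory;
this package's generator emulates only the *statistical shape* of that
output, with ground truth attached:

* a **molecule** of n_atoms hard spheres placed uniformly in a box
  (default 400 atoms in 40 Å³), with protein-like element frequencies,
  residues of ~4 atoms drawn from the 20 standard codes plus HID, and
  Bondi vdW radii (H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 Å);
* k **channel templates**: correlated random walks of 10–40 waypoints at
  1.5 Å spacing that reflect off the box walls, each with a smooth
  radius profile in [0.8, 3] Å carrying one forced bottleneck dip; each
  waypoint's node is the canonical ID of its four nearest atoms (a
  template whose waypoint has fewer than four atoms within the 10 Å
  search radius fails loudly, naming the template);
* **trajectories**: each of the n_per_template snapshots copies the
  template walk and applies independent per-node noise — *dropout*
  removes the node (if every node would drop, the first is kept so the
  sequence stays non-empty), and *swap* replaces the node's quadruple
  with four distinct random atoms while keeping the sphere geometry, so
  token noise does not corrupt geometric profiles.

Sequence lengths of 10–40 nodes are a free choice (no published length
statistics exist for the reference corpora) and are exposed as a
parameter. The standard benchmark conditions used by the tests and the
acceptance script are 3 templates × 50 trajectories with dropout 0.1
and swap 0.05 — a regime where roughly one node in seven carries noise —
trained at d=16, c=2, 5 negative samples, 50 epochs. These sizes keep a
full ten-seed recovery experiment to a few minutes on one CPU while
leaving the vocabulary (~150 node IDs) large enough to be non-trivial.

What passing these tests shows — and does not. The generator plants
channels whose token vocabularies barely overlap and whose noise is
unstructured; perfect recovery (ARI 1.0) under these conditions
demonstrates that the representation and pipeline are implemented
correctly and separate topologically distinct pathways, not that real
cavity ensembles — where channels share lining atoms, drift gradually,
and branch — would be recovered as cleanly. No force field, solvent, or
real protein geometry is modelled.

## Pipeline and reproducibility

The `run_pipeline` driver chains synth → encode → train → embed →
cluster/project/profile from one hierarchical config; unknown keys are
rejected before any stage runs, every stage failure is re-raised with
the stage name, and all randomness derives from a single global seed
through per-stage seeds (below 2³¹). The effective config and a
manifest with a SHA-256 per artifact are written next to the outputs;
re-running the same config reproduces every artifact bit for bit, which
the test suite asserts by comparing manifests.

## Known limitations

* Cavity extraction itself (Voronoi diagram, pathway search) is out of
  scope; the package consumes extracted spheres or pre-tokenized
  sentences.
* The mean-of-nodes cavity vector ignores node order beyond what the
  context window captured during training; two cavities traversing the
  same nodes in different orders embed identically.
* Absolute spatial position is deliberately not represented: cavities
  with the same lining topology at different locations are similar by
  construction.
* Exact-softmax training is O(W·d) per pair and is practical only for
  small vocabularies; use negative sampling beyond a few thousand
  tokens.
* t-SNE coordinates are seed-reproducible but not comparable across
  runs with different inputs; they support visual inspection only.
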