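# Methods

## Molecular graphs from sequences

Peptides are modeled as heavy-atom graphs: hydrogens are not nodes but a
per-atom `total_hydrogens` count, the convention under which "number of
attached hydrogens" is itself a node feature.  Each of the 20 standard
residues has a hand-authored template (PDB atom names, fixed atom order);
a chain is assembled by condensation — residue *i*'s hydroxyl oxygen and
its C–O bond are deleted and a C(i)–N(i+1) amide bond added, the amide
nitrogen keeping one hydrogen (zero for proline).  Template fidelity is
pinned in tests by comparing node/edge counts, element multisets,
aromatic-atom counts, degree sequences and hydrogen counts against an
independent cheminformatics toolkit for all residues and random peptides.

Chemistry choices, made once and documented rather than inferred:

* **Neutral protonation everywhere** — free N-terminal amine, free
  C-terminal carboxylic acid; Lys/Arg/Asp/Glu/His side chains uncharged.
  Arginine is the neutral guanidine (NE–CZ single, CZ=NH1 double);
  histidine is the NE2–H imidazole tautomer.
* **Aromaticity** — His, Phe, Tyr, Trp rings carry aromatic atoms and
  aromatic bonds; hybridization is sp2 for aromatic/carbonyl atoms and
  sp3 otherwise; all bond stereo is `none` (a linear sequence carries no
  E/Z annotation; the field exists for feature-configuration parity).
* **Determinism** — residues in sequence order, atoms in template order,
  so identical strings give bit-identical graphs.

## WL documents and the embedding model

Iteration-0 labels serialize the enabled node attributes in a fixed key
order (or a constant token in the non-attributed, structure-only
configuration).  One refinement step replaces a node's label with a
BLAKE2b-128 digest of (own label, sorted neighbor descriptors); a
neighbor descriptor is the neighbor's label, prefixed with the serialized
bond attributes when edge labels are enabled.  The digest is keyless and
unsalted, so token vocabularies are stable across processes and
platforms.  A graph's document contains the labels of *all* iterations
0..k (making k = 0 meaningful); every token occurrence records its root
atom, the root's residue index and the residue set of its t-hop ball, so
tokens can be mapped back to sequence windows.

Embeddings are trained with the distributed bag-of-words scheme: each
document vector predicts its own tokens, the softmax over the vocabulary
estimated by negative sampling (default 5 negatives, unigram^0.75 noise).
Implementation notes that matter for reproducibility and quality:

* Vocabulary pruning `min_count=5`: at WL height 5 most tokens are
  one-off hashes of idiosyncratic context; they carry no shared signal
  and only add variance.  Tiny corpora where pruning would empty the
  vocabulary fall back to the full one.
* Word2vec-style frequent-token down-sampling is available but **off by
  default**: at the text-scale threshold (1e-4) every token of a
  thousand-document molecular corpus counts as frequent and the
  heuristic deletes the shared signal (measured as a sign flip of the
  isomorphic-block similarity margin).
* SGD runs in shuffled mini-batches with accumulated `np.add.at`
  updates, at least 16 batches per epoch (a single full-batch step at
  the per-occurrence learning rate oscillates on small corpora), linear
  learning-rate decay 0.025 → 1e-4, stable sigmoid, float32, one
  worker.  Given (corpus order, seed) the result is bitwise
  reproducible.
* Defaults k = 5, d = 256, epochs = 10.  Pooled training over TCRs and
  epitopes together is the default (matching how the method is used);
  an infer-only mode (frozen token vectors, gradient steps on the new
  document vector only) is provided for leakage-sensitive settings,
  since pooled training lets test-set structure shape the space.

## Classification protocol

Epitopes with fewer than `min_tcrs` distinct cognate TCRs are dropped
(default 1000, matching repertoire-scale practice; desk-scale examples
set 1).  The 80/20 split is similarity-guided per epitope: random seed
CDR3s pull their exact nearest neighbors (L2 on one-hot encodings,
group size 10) into the test side until the quota is met.  Splitting
operates on distinct CDR3 strings, so duplicates never straddle the
boundary; exact k-NN replaces approximate search (identical contract, no
approximation error).  Negatives are generated after the split,
independently per side, at ratio 1:1 by default — shuffling onto
non-cognate epitopes or swapping across antigen groups — never
duplicating an observed positive.  The classifier is a random forest
(500 trees, unlimited depth, fixed seed); auROC is the Mann-Whitney rank
statistic with ties counted ½, verified against brute-force pair
enumeration.  Cross-validation stratifies folds by epitope and trains
one pooled embedding per (k, d) grid cell; the down-sampling experiment
subsamples train and test at the same ratio after the split and re-runs
embedding and classification from scratch.

## Clustering and its metrics

Embeddings are reduced by PCA to 24 dimensions (classical
double-centered MDS for distance-matrix input, exact for Euclidean
matrices of intrinsic dimension ≤ n) and clustered by DBSCAN, Manhattan
metric, ε log-spaced over [0.01, 20] (50 points), `min_points` m = 5; a
point is core when its ε-ball including itself holds ≥ m points.
c-Precision is reported both size-weighted (the headline) and
unweighted.  In c-CSI, noise points are excluded from Σ|C_i| but counted
in Σ|L_j| — the only reading under which the score rewards the
proportion of well-clustered points.  All-noise clusterings have
undefined precision (NaN) and c-CSI 0.

## Motif mining

TF-IDF uses the natural logarithm (configurable) and a minimum document
frequency.  Documents are epitope pools by default — tokens of all
member TCR graphs pooled per annotated group, which is where
cluster-discriminative chemistry is interpretable — and any assignment
vector (e.g. a DBSCAN labeling) can be supplied instead.  Tokens ranked
by TF-IDF must occur in ≥ 5 distinct TCRs of their group and ≥ 20
distinct TCRs corpus-wide.  A surviving token's motif is the consensus
of the 5-residue windows centered on its occurrence roots (the root
residue is the most informative position, position 0): a position shows
its modal residue when ≥ 50% conserved, '%' otherwise, '-' when past the
sequence end.  Consensus windows selected by more than one group are
removed from all of them.  Exact-window support was rejected as the
selection unit: with short planted motifs each exact window carries
random flanking residues and is near-unique, so no window could meet the
support thresholds even when the underlying subgraph token is carried by
hundreds of TCRs.

## CDR3 distance

Trim 3 N-terminal and 2 C-terminal residues (the conserved flanks);
per-residue cost max(0, min(4, 4 − BLOSUM62(a,b))) — the clamp at 0
makes every self-distance zero, including cysteine whose self-score
exceeds 4; unequal trimmed lengths are center-gapped (⌊n/2⌋ leading
residues aligned from the N-terminal end, the rest from the C-terminal
end, ties placing the gap toward the N-terminus) at 4 per gap.  The
substitution matrix is frozen in-package and cross-checked against an
independently distributed BLOSUM62 in tests.  A weight multiplier
(default 1) scales the summed distance.

## Synthetic repertoires

The generator emulates epitope-annotated repertoires: each epitope is a
random 9-mer; its CDR3s wear β-chain flanks `CASS`…`F` (so N/C trimming
interacts with the planted signal realistically), draw total lengths
uniformly in 12–16, and carry a distinct planted k-mer (default length
3) at the center of the loop with probability `motif_fidelity`
(non-carriers are pure background).  Defaults for the desk-scale study:
4 epitopes × 250 TCRs, fidelity 0.9.  What the generator does **not**
model: V(D)J recombination statistics, generation probability, length
correlations with epitope, shared public clones, or partial/degenerate
motifs — so green tests show the pipeline recovers planted signal, not
that it matches real-repertoire performance.  A Gaussian-blob testbed
(centers at mutual distance `separation` on orthogonal axes) isolates
clustering and classifier behavior from the embedding trainer.

## Problem sizes and what the checks show

The test and acceptance workloads use 4 × 250 repertoires with k = 5 and
d = 64 — the embedding dimensionality scaled down from the 256 used at
repertoire scale, which keeps a full pipeline run around a minute.  At
these study conditions the supervised branch is strong (test auROC
≈ 0.98 across seeds) and per-epitope motif mining recovers every planted
3-mer.  The unsupervised branch is honestly weak: the best ε attains
c-CSI ≈ 0.15 (fragmented pure clusters or one merged blob).  The cause
is measurable: 3-residue motifs contribute only ~5% of a document's
token mass, and chance-shared background tokens dominate the embedding
variance; restricting the bag-of-words to the label-concentrated tokens
(an oracle selection no unsupervised method has) raises c-CSI to ~0.84,
and lengthening planted motifs to 6 residues lets the default pipeline
itself reach c-CSI ≈ 0.82 — the regime the clustering recovery property
test exercises.  Real repertoires sit between these extremes.

## Known limitations

* Chemistry is constitutional only: no 3-D conformations, protonation
  equilibria, post-translational modifications or non-standard residues.
* Pooled embedding training mixes train and test structure; use the
  infer-only mode when that matters.
* The motif miner reports consensus windows, not statistically tested
  motifs; no multiple-testing control is applied.
* DBSCAN border-point assignment follows discovery order (input order),
  the standard deterministic convention; brute-force density-reachability
  admits either owner for a border point reachable from two clusters.
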