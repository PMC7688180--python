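# Methods

## Scope and data model

`ppifunc` predicts GO Biological Process (BP) terms for proteins from
undirected interaction networks. Annotation sets are always *propagated*:
a protein annotated with a term also carries every is_a ancestor, so term
sets are closed under the hierarchy and term counts are monotone from
child to parent. Only is_a edges participate in propagation; part_of and
other relations are ignored (a deliberate conservative choice — is_a is
the one relation for which ancestor transfer is uncontroversial).
Annotations with the GAF `NOT` qualifier are dropped, and only
experimental and curator-reviewed evidence codes are kept by default
(`EXP, IDA, IPI, IMP, IGI, IEP, IBA, IBD, IKR, IRD, TAS`); electronically
inferred annotations (IEA) are excluded because they are themselves partly
derived from sequence similarity and would contaminate the comparison
with similarity-based prediction. The namespace defaults to BP and is
configurable.

Information content is measured in bits,
`ic(t) = −log2(count(t) / count(root))`, with the denominator the number
of proteins annotated with the namespace root in the *training* set of the
current fold, so `ic(root) = 0` and IC is anti-monotone along is_a edges.

## Network construction

- **Experimental edges** come from a BIOGRID TAB-style table; rows whose
  experimental system type is "genetic" are dropped (physical
  interactions only), self-loops removed, duplicate pairs collapsed.
  From STRING's experimental channel, pairs scoring strictly above the
  median of non-zero scores are kept.
- **Predicted channels** (STRING-style per-source scores, raw 0–1000
  divided by 1000 on read) are thresholded per source to the top half of
  non-zero scores — `⌈n/2⌉` pairs, with all values tied at the cutoff
  retained so the rule is deterministic and threshold-monotone. The
  "database" and "database transferred" channels are excluded by default:
  they are partly derived from GO annotations and would let label
  information leak into the features. Channels whose thresholded edges
  are all already experimental can be pruned.
- **Integration** across channels follows the STRING probabilistic rule:
  each score is corrected for the random-association prior
  (`s' = max(0, (s − p) / (1 − p))`, default prior 0.041, configurable),
  complements are multiplied, and the prior is added back. With prior 0
  the rule is commutative, associative, and bounded below by the largest
  input.
- **Combination** of binary networks is an element-wise logical OR of
  adjacency matrices; the weighted variant keeps experimental edges at
  weight 1 and predicted pairs at their integrated score (max on
  conflict).
- **Restriction**: evaluation networks contain exactly the annotated
  proteins, keeping annotated proteins with no interactions as degree-0
  nodes (they count against coverage). A flag retains unannotated nodes
  for the unsupervised embedding stage.

## Classifiers

GBA, weighted GBA, the naive frequency baseline, maximum-identity
transfer and noisy-OR fusion are implemented exactly as in the README's
formulas. Undefined posteriors are exactly 0. Sequence identities are
treated as fractions in [0, 1] so that fused scores remain probabilities.

The embedding classifier runs node2vec walks (second-order bias: weight
∝ 1/p to return, 1 to a common neighbour of the previous node, 1/q
otherwise, multiplied by edge weight) and trains skip-gram with negative
sampling (SGNS). The SGNS trainer is a vectorised numpy implementation:
window pairs are enumerated symmetrically, negatives are drawn from the
unigram distribution raised to 3/4, and minibatch SGD applies the *mean*
gradient per embedding row, which bounds the per-row step by the learning
rate and keeps training stable when the vocabulary is much smaller than
the batch. The batch size is auto-scaled so training takes ~2000
minibatches regardless of corpus size; learning rate 0.1 with linear
decay. Training is single-threaded and bit-reproducible under the seed.
Nodes absent from all walks (isolated proteins) receive the zero vector.

Embedding classification uses kNN (Euclidean distance by default, cosine
optional; distance ties broken by stable training-row order) or
multi-output ridge via the closed form `W* = (XᵀX + λI)⁻¹XᵀY` with labels
in {−1, +1}, no intercept, features mean-centered (flag-controlled), and
a sigmoid applied to the linear scores. Ridge predictions are not
post-processed, so they may violate hierarchy consistency; the
fraction-based classifiers (naive, GBA, kNN) are hierarchy-consistent by
construction because closed annotation sets are nested.

## Evaluation protocol

5-fold cross-validation: seeded shuffle, contiguous partition, fold sizes
differing by at most one; each fold records an inner 80/20 split of its
training set for hyperparameter tuning (the winner by validation Fmax,
ties to the earliest grid point, is retrained on the full training set).
Per fold, terms without a positive example in both training and test sets
are discarded. Fmax and Smin scan thresholds 0.01…1.00 in steps of 0.01;
precision at a threshold averages over proteins with at least one
prediction there (thresholds where no protein predicts are skipped;
all-zero prediction tables score Fmax 0), recall averages over all test
proteins; Smin is the minimum of `√(ru² + mi²)` with ru/mi the mean
missed/spurious IC per protein. Root terms are excluded from scoring by
default (they are trivially predicted; flag-controlled). Method
comparisons use a paired t-test per method pair with Benjamini–Hochberg
correction over the family of all pairs in the experiment; a Wilcoxon
rank-sum variant is available for unpaired per-protein bins. Zero-variance
paired differences are handled explicitly: identical vectors give p = 1,
a constant non-zero shift gives p = 0 with an infinite statistic.

## Downsampling study

Edges are removed either uniformly at random or degree-biased: edges are
drawn one at a time with probability ∝ 1/min(deg(u), deg(v)) using the
degrees of the current, partially stripped graph, so low-degree proteins
lose their few edges first — a model of study bias. Exactly
`round(f·|E|)` edges are removed (round half away from zero), nodes are
retained, and both schemes are bit-reproducible under the seed. The exact
degree-biased scheme is one concrete choice among several defensible
ones; it is isolated behind a single function and swappable.

## Synthetic data generator

The generator emulates the joint structure the analysis needs, not any
particular organism:

- a single-root random DAG (each term draws 1–2 parents among earlier
  terms, acyclic by construction);
- per-protein annotations: 1–3 leaf terms drawn with depth-weighted
  probabilities (weight 2^(−depth/2) times a random per-leaf popularity),
  then ancestral closure — giving the frequency skew real GO corpora
  show, shallow terms common and deep terms rare;
- a network with edge probability `q0 + q1·J(i,j)`, where J is the
  Jaccard similarity of the two proteins' non-root term sets — `q1`
  plants the guilt-by-association signal, `q1 = 0` yields Erdős–Rényi;
- per-source score channels `clip01(0.8·edge + N(0, σ))` with per-pair
  dropout, independent across sources;
- a sequence-identity surrogate `clip01(0.3 + 0.5·J + N(0, σ))` on a
  random subset of pairs.

Defaults: 150 proteins, 40 terms, `q0 = 0.01`, `q1 = 0.6`, 4 sources,
score noise σ = 0.1, dropout 0.5, identity noise 0.1 over 30% of pairs —
a small, densely annotated interactome with a strong planted functional
signal, sized so a full cross-validated experiment runs in well under a
second. All draws flow from one root seed through named substreams
(ontology, annotations, network, sources, identity), so artifacts can be
regenerated independently and the whole dataset is reproducible from its
config.

What the generator does *not* emulate: scale-free degree distributions,
realistic ontology depth/width (real BP has tens of thousands of terms),
correlated noise across STRING channels, or actual sequences. Passing
tests therefore demonstrate that the machinery is correct and that the
qualitative phenomena (GBA advantage under functional coupling, its loss
under decoupling, steeper degradation under degree-biased edge removal)
emerge when their causes are present — not that any particular organism
would show a particular Fmax.

## Problem sizes and numerical choices

Test and acceptance runs use 30–150 proteins, 10–40 terms, and 10-seed
Monte-Carlo averages for the stochastic claims; the oracle equivalence
suites use exhaustive scans on instances of ≤ 10 proteins (metrics) and
≤ 30 nodes (GBA) where brute force is exact and instant. Ridge agreement
with a generic least-squares solver is asserted to 1e−8. Edge-removal
counts use round-half-away-from-zero. Degenerate inputs are defined
explicitly throughout: empty score tables threshold to empty graphs (with
a warning for the median rule), single scores yield no edges under the
strict-median rule, λ = 0 ridge raises a numerical error advising
regularisation when the normal equations are singular, and
`PA` is undefined (error) when the naive loss is 0.

## Known limitations

- The degree-biased removal scheme and the STRING prior are conventions,
  exposed as parameters, not fitted to data.
- The SGNS trainer is deliberately compact; it trades the asynchronous
  throughput of large word2vec implementations for determinism, which
  matters more here (graphs are small and experiments must be
  bit-reproducible).
- The combination sweep is exhaustive (2^k − 1 subsets) and meant for
  k ≤ 12 channels.
- BLAST itself is not run and sequence-based interaction scores are not
  computed; both enter as externally produced tables.
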