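# Methods

## Problem and model

The task is five-way (or four-way) classification of lncRNA transcripts into
subcellular compartments from sequence alone.  The model treats each dataset
as a graph: nodes are sequences, node features are compositional encodings,
and edges connect compositionally similar sequences.  Classification of a
node uses its ego graph — the node, its direct neighbors, and its incident
edges — as the input sample, so prediction aggregates the neighborhood's
composition as well as the node's own.

**Features.** The default encoding is the k-mer frequency vector: counts of
each of the `4^k` length-k words over the `L−k+1` sliding windows, divided
by the window count.  Normalizing by window count (rather than raw counts or
sequence length) makes vectors length-invariant, which matters because edge
construction compares sequences of different lengths by cosine similarity.
Indexing is lexicographic over A<C<G<T and fixed for serialization.  U is
canonicalized to T before counting so RNA and DNA spellings agree.  Two
alternatives are provided: RevKmer (k-mer counts pooled over
reverse-complement pairs, keyed by the lexicographically smaller member) and
PseDNC (16 dinucleotide frequencies plus λ sequence-order correlation
factors weighted by ω; the correlation factors use six B-DNA dinucleotide
step parameters — twist, tilt, roll, shift, slide, rise — shipped as module
constants and standardized to zero mean / unit variance across the 16
dinucleotides).  PCA reduction is available but off by default: on this task
it discards discriminative composition signal.

**Balancing.** SMOTE runs in feature space *before* graph construction, so
synthetic samples become graph nodes.  Every class is raised to the majority
count; each synthetic point is `x_c + u (x_n − x_c)` with `u ~ U[0,1]`,
`x_c` a class member and `x_n` a same-class Euclidean nearest neighbor.  Two
neighbor policies exist: `standard` (classic SMOTE — centers drawn across
the class, each paired with one of its k=5 nearest neighbors, repeated until
the deficit is filled) and `single_center` (an opt-in variant: one
random center donates one synthetic per nearest neighbor, deficit-many at a
time).  `standard` is the default.  Parentage (both parent indices and u) is
recorded for every synthetic row so the convex-combination geometry is
auditable.  A class needing synthesis with fewer than two members is an
error — no line segment exists.

**Graph.** Edge rule: `e_ij = 1` iff `cos(l_i, l_j) ≥ τ`; ties at exactly τ
create the edge.  Similarity features and node features default to the same
matrix but are independently configurable.  Isolated nodes are permitted.
Reported statistics are the isolated-node count, edge count, and the
*key-edge fraction*, defined here as the fraction of edges whose endpoints
share a compartment label (an interpretation: it rises toward 1 as τ grows
and tracks how label-consistent the neighborhood structure is).  Ego graphs
come in two depths: 1-layer (center + neighbors, only center-incident edges
— a star) and 2-layer (adds neighbors' neighbors and the edges linking the
first layer outward).  1-layer is the default: it is far cheaper and at
least as accurate in our experiments.

**Classifier.** A two-layer GCN
`Y = softmax(Â · ReLU(Â X W₁) · W₂)`, `Â = D′^(−1/2)(A+I)D′^(−1/2)`,
no biases, Glorot-uniform initialization.  The sample's prediction is the
center node's output row (the readout had to be chosen; the center row is
the natural one for ego-graph samples).  The loss is multiclass
cross-entropy of the center row.  Node features are row-normalized to unit
L2 norm by default, which keeps pre-activation scales independent of the
feature dimension.  Because the per-sample ego graphs all index one global
feature matrix, a batch costs two large matrix products (X W₁ once, and
Xᵀ ΔP once for the gradient) plus sparse per-graph propagation; ego graphs
store member indices, not feature copies.

**Meta-learning.** Training is episodic: a task holds `|C|·(k_s + k_q)`
samples, `k_s` support and `k_q` query shots per class, drawn without
replacement within a task and with replacement across tasks.  The inner loop
runs `inner_steps` of plain gradient descent on the support loss from the
shared initialization θ; the outer loop sums the adapted models' query
losses over the m tasks of a meta-batch and takes one gradient step on θ.
The second-order meta-gradient pulls the query gradient back through each
inner step via `(I − α H_support)`; Hessian-vector products are evaluated by
central finite differences of the analytic gradient with step
`ε = eps_machine^(1/3) · (1+‖θ‖)/‖v‖` — exact for quadratics, `O(ε²)`
otherwise, and verified against full finite differences of the composite
objective to 1e−4 on a two-parameter toy with non-constant curvature.  A
first-order switch drops the curvature terms.  With `inner_steps = 0` the
procedure degenerates exactly to gradient descent on the query loss (tested
to 1e−5).  At meta-test time the initialization θ′ is fine-tuned on the test
task's support set (`fine_tune_steps`, default = `inner_steps`) and scored
on its query set.

**Metrics.** Accuracy is the fraction of correct multiclass predictions
(the pooled one-vs-rest form of the binary accuracy formula double-counts
and is not what a multiclass accuracy conventionally means; this divergence
is deliberate and documented).  Macro F1 averages per-class harmonic means
of precision and recall; macro recall averages per-class recalls;
sensitivity ≡ recall; specificity = TN/(TN+FP); MCC uses the binary formula
on one-vs-rest counts.  Any per-class metric with a zero denominator is
reported as 0 and flagged — few-shot query sets can miss classes.  A
`real_test_only` switch recomputes metrics on real-provenance query samples
only, excluding SMOTE synthetics from scoring (see Limitations).

## Parameters

| parameter | default | notes |
|---|---|---|
| k (k-mer) | 7 (library), 5 (benchmark configs) | dimension `4^k`; larger k is more expressive and much costlier |
| λ, ω (PseDNC) | 150, 0.3 | correlation depth and weight; needs sequences ≥ λ+2 nt |
| τ | 0.7 | edge threshold in [−1,1]; optionally selected on validation from a grid |
| layers | 1 | ego-graph depth |
| hidden width | 64 | GCN hidden layer |
| inner_lr / outer_lr | 0.01 / 0.001 | conventional library defaults, not tuned to any dataset |
| inner_steps / m / k_s / k_q | 5 / 8 / 5 / 5 | episode shape |
| meta_iterations | 1000 | library default |
| SMOTE neighbors | 5 | standard mode |

The scaled benchmark configuration used by the test suite and the
acceptance script (chosen once as this package's own study size) is:
5-mer features, τ selected from {0.5, 0.7, 0.9} on validation,
inner_lr 0.5, outer_lr 0.05, 1 inner step, 30 meta-iterations, m = 4,
5 support / 5 query shots, 10 fine-tune steps, 80/10/10 stratified split.
The larger learning rates compensate for the small pre-activation scale of
row-normalized k-mer features; 30 iterations suffice because the benchmark
signal is strong by construction.

## τ selection on validation

Selecting τ by meta-training one model per grid point is disproportionate,
so the pipeline uses a neighbor-vote proxy: for each candidate τ, every
validation node is classified by the majority label of its training
neighbors in the τ-graph, with "no training neighbor" counting as wrong.
This uses only validation labels and penalizes both over-sparse graphs
(no votes) and impure ones (wrong votes) — the same trade-off the full model
faces between connectivity and key-edge purity.  Ties prefer the smaller τ.

## Synthetic benchmark

The generator emulates the *shape* of curated lncRNA localization sets:
class counts 292/149/91/43/25 (five compartments, ~11.7× imbalance),
417/153/43/30, and an independent-set shape 198/82/99/16; lengths uniform in
200–500 nt (200 nt being the defining lncRNA minimum; real transcripts run
longer, but composition statistics at a few hundred nt already behave like
the real feature vectors).  Class signal is injected as compositional bias:
each class's dinucleotide-Markov transition logits are the shared (uniform)
base perturbed by `separation · d_c` with a class-specific direction `d_c`.
The directions are unit-norm, mutually orthogonalized, and have zero
diagonal.  Zero diagonal because a class identity expressed through
self-transitions degenerates into homopolymer repeats at high separation,
and two classes sharing a poly-base attractor become indistinguishable;
orthogonalization makes "separation" move every class away from every other
rather than letting two classes drift along nearly collinear axes.
Separation 0 gives statistically identical classes; an order-0
(mononucleotide) variant is available.

What the generator does **not** emulate: secondary structure, motif grammar,
splice/genomic context, length–compartment correlations, and annotation
noise.  Passing the end-to-end tests therefore shows that the pipeline
recovers compositional class signal through the graph + meta-learning
machinery — not that it would reach any particular accuracy on curated
transcript data.

## Numerical choices

- Tie at `S_ij = τ`: edge created (≥ rule).
- Cosine similarity of a zero vector is an error, not 0.
- Softmax rows are max-shifted before exponentiation; log-probabilities are
  floored at 1e−300 inside the loss.
- Dropout (off by default) draws its masks from an explicit seed so that the
  repeated gradient evaluations inside finite-difference curvature products
  see the same stochastic network.
- Stratified splits use largest-remainder allocation, so per-class split
  sizes are within one sample of exact proportionality; fold mode delegates
  to stratified k-fold with a fixed seed.
- Every stochastic stage draws its seed from the run seed through a seed
  tree; one configuration reproduces byte-identical metrics.
- Non-finite training loss aborts with a diagnostic rather than continuing.

## Known limitations

- SMOTE synthetics participate in the graph and, under the default
  configuration, in test queries.  Because synthetic points lie between
  same-class parents, they leak label geometry: even at separation 0 the
  pipeline scores well above the 0.2 chance level on synthetic-inclusive
  queries.  The `real_test_only` switch exists precisely to quantify this;
  both scores are reported by the cross-validation driver.
- The episodic trainer supports the two-layer GCN; deeper stacks are
  available only through the reference per-graph forward pass.
- Second-order meta-gradients cost two extra gradient evaluations per inner
  step per task (finite-difference Hessian-vector products); for large
  models the first-order switch is markedly cheaper.
- The PseDNC property table is a consensus B-DNA step-parameter set; any
  standardized six-property table yields the same tested invariants
  (dimension, normalization, ω → 0 limit), but numeric feature values depend
  on the table chosen.
- k-fold cross-validation of the full meta-learning model meta-trains once
  per fold and is correspondingly expensive; the pipeline's default
  evaluation protocol is the single stratified train/val/test split with a
  single meta-test task.
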