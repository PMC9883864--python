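# lncloc

Predicting the subcellular localization of long non-coding RNAs
(Cytoplasm, Nucleus, Cytosol, Ribosome, Exosome) from sequence alone, using
a sequence-similarity graph and a graph convolutional classifier trained
under a meta-learning regime.

lncRNA localization datasets are small (a few hundred transcripts) and
heavily imbalanced, which defeats ordinary deep classifiers.  This package
addresses both problems the way the strongest graph-based approaches in this
area do:

1. **Low-level features.** Each sequence becomes a k-mer frequency vector
   (`4^k` sliding-window frequencies; RevKmer and PseDNC encodings are also
   provided).
2. **Class balancing.** SMOTE raises every minority compartment to the
   majority count: each synthetic sample is `x_c + u·(x_n − x_c)` for a
   class member `x_c`, a same-class nearest neighbor `x_n`, and `u ~ U[0,1]`.
3. **Similarity graph.** Nodes are sequences; an edge joins `i, j` whenever
   `cos(l_i, l_j) = l_i·l_j / (‖l_i‖‖l_j‖) ≥ τ`.  Each node's ego graph
   (the node, its neighbors, and its incident edges) is one classification
   sample.
4. **GCN + MAML.** A two-layer GCN,
   `Y = softmax(Â · ReLU(Â X W₁) · W₂)` with
   `Â = D′^(−1/2)(A + I)D′^(−1/2)`, reads out the center node's row.
   Training is episodic (N-way, k-shot support/query tasks): an inner loop
   adapts the weights on each task's support set, an outer loop updates the
   shared initialization θ′ from the summed post-adaptation query losses
   (second-order meta-gradients by default).  At meta-test time θ′ is
   fine-tuned on a small support set and scored on the query set.
5. **Evaluation.** Accuracy, macro F1/recall, and per-class
   sensitivity/specificity/MCC, plus a stratified k-fold driver.

A synthetic-data module generates labeled lncRNA-like datasets with the
benchmark class-count shapes and a tunable class-separation knob, so the
whole pipeline is exercisable and testable without any download.

## Worked example

Run the full pipeline on a synthetic five-class benchmark (class counts
292/149/91/43/25, moderate class separation):

```bash
cat > example.yaml <<'YAML'
data:
  synthetic_preset: dataset1-like
  separation: 1.5
features:
  method: kmer
  k: 5
graph:
  tau: 0.7
  tau_grid: [0.5, 0.7, 0.9]
meta:
  inner_lr: 0.5
  outer_lr: 0.05
  inner_steps: 1
  meta_iterations: 30
  m: 4
  k_support: 5
  k_query: 5
  fine_tune_steps: 10
seed: 1
outdir: example_out
YAML
lncloc run --config example.yaml
```

which prints

```json
{
  "accuracy": 0.975,
  "macro_f1": 0.9749019607843138,
  "macro_recall": 0.975,
  "tau": 0.5,
  "edges": 44184,
  "isolated": 249
}
```

Reading the output: after SMOTE the 600 generated sequences become 1460
balanced samples; τ = 0.5 was selected on the validation split from the
configured grid; the similarity graph has 44,184 edges and 249 isolated
nodes (isolated nodes are legal — they are how sequences with no close
relative enter the graph); fine-tuning the meta-learned initialization on 5
support shots per class classifies 97.5% of the held-out test queries into
the right compartment (chance is 20%).  `example_out/` holds the metrics,
graph statistics, training log, final parameters, and a manifest with every
seed used.

Individual stages are available as subcommands (`simulate`, `featurize`,
`balance`, `build-graph`, `evaluate` for k-fold cross-validation,
`validate`), and the same functionality is importable from `lncloc.*`
modules.

## Layout

```
src/lncloc/
  sequence_io.py    FASTA/label-TSV reading, validation, filtering policies
  features.py       k-mer / RevKmer / PseDNC encodings, optional PCA
  balancing.py      SMOTE with parentage tracking
  graph.py          cosine-similarity threshold graph, ego-graph extraction
  model_meta.py     NumPy GCN, episodic sampling, MAML inner/outer loops
  evaluation.py     confusion counts, metric set, stratified k-fold driver
  synthetic_data.py labeled synthetic lncRNA-like benchmark generator
  pipeline.py       end-to-end orchestration + run manifest
  cli.py            `lncloc` command-line interface
```

See `docs/methods.md` for the model, its assumptions, parameter defaults,
and the design choices behind the synthetic benchmark.
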