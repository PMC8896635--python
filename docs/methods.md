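# Methods

## The model

`textkg` trains one transformer jointly over a two-modality input built
from a *text-triple pair*: a knowledge-graph triple (head, relation, tail)
together with the evidence sentence it was extracted from.  The combined
input sequence has a fixed total length split into two halves:

- **Text half** — the evidence sentence tokenized to `[CLS] tokens [SEP]`
  and padded/truncated to the half length (truncation keeps the leading
  tokens; evidence is sentence-level, so the relation mention sits early).
- **KG half** — the triple rendered as a *sequence*: a random walk started
  at the head node, a `[SEP]` entry, a random walk started at the tail
  node, and a final `[SEP]`.  With walk length L this occupies 2L + 2
  positions, so L is co-designed with the half length (L = 127 fills the
  full-scale 256-position half; the desk profile uses L = 15 for a
  32-position half).  An alternative *translational* input replaces the
  walks with the 3-sequence (e_head, e_relation, e_tail) from a TransE
  model, right-padded and unattended beyond position 3.

Segment embeddings (0 = text, 1 = KG) distinguish the halves; position ids
run 0..max_len−1 across the whole combined sequence, the convention the
encoder geometry inherits.  Attention spans both halves, so every hidden
state can mix textual and graph context without any entity-linking step.

Pre-training optimizes the sum of three objectives, L_total = L_MLM +
L_MEM + L_NSP:

- **MLM** — standard masked-token prediction over the text half.
- **MEM** — the entity analogue over the KG half: masked positions are
  predicted against the node vocabulary, which includes the KG-side
  `[SEP]` so separator positions are themselves maskable and reachable as
  labels.
- **NSP** — a binary head on the `[CLS]` hidden state deciding whether the
  sentence and triple belong together.  The training stream is *augmented*
  (not replaced) with `round(0.25 · N)` negatives, each combining the
  evidence of one pair with the triple of a different pair; a negative
  never reproduces an existing (evidence, triple) combination.  Negative
  examples still contribute to MLM/MEM — the simplest reading of
  augmentation, and the one the loss accounting assumes.

Masking follows the 15% / 80-10-10 recipe: each maskable position is
selected independently with probability 0.15; of the selected, 80% are
replaced by `[MASK]`, 10% by a random id from that half's vocabulary, 10%
kept.  In the KG half the `[MASK]` replacement *embedding* is the
text-side `[MASK]` vector, which ties the two embedding spaces together.
Each loss term is the mean cross-entropy over its own supervised positions
only; a term with no supervised positions is exactly 0.  The `no_nsp`
variant drops the NSP term from the sum.

Fine-tuning pools the `[CLS]` hidden state through one linear + softmax
head and updates **all** parameters (backbone and head), for the cross
encoder and the text baseline alike.  The KG baseline is deliberately
static: triple sequences are pooled by dimension-wise maximum into one
vector and only a multinomial logistic head is fit.

## Baselines and the benchmark

Three models are compared under identical conditions: the cross encoder,
a text-only transformer of the same geometry (the NLP baseline; at desk
scale it trains from scratch during fine-tuning, standing in for a large
pre-trained biomedical language model), and the static KG baseline
(node2vec-style walk embeddings, or TransE).  Evaluation is stratified
k-fold cross-validation with deterministic, seed-fixed splits shared by
every model on a task, scored by weighted F1 (per-class F1 weighted by
true-instance counts; zero-denominator classes score 0).  Models whose
input directly encodes the relation type (translational input) are
excluded from relation-type tasks and marked as such in the results.
Summary tables report mean F1 per model × task plus absolute and relative
gains of the best variant over the best baseline
(100 · (best − baseline) / baseline).

## The synthetic corpus

The generator emulates the shape of a large assembled biomedical KG corpus
at desk scale: grounded namespace-prefixed node identifiers (`toy:0017`)
distinct from surface names (`g17`), typed directed edges, one
template-rendered evidence sentence per triple ("<head> <verb-phrase>
<tail> <filler…> <keyword?>"), and a configurable annotated minority.

The graph is a stochastic-block-model-style layout: tails are drawn from
the head's block (`id mod n_blocks`) with probability `homophily` (default
0.85, 2 blocks), so a node's neighborhood — and therefore its walk
sequences and skip-gram embedding — encodes its block.  This is the
synthetic analogue of identifier-encoded side information in real KGs
(e.g. species-specific namespaces making species recoverable from node
identity alone), and it is what makes node-dependent tasks *generalizable*
rather than memorizable: an arbitrary per-node attribute on an
unstructured graph can only be looked up, not inferred, for rarely-seen
nodes.

Task label functions control which modality carries signal:

- `text_determined` — label = an injected keyword token (`ctx3`),
  independent of the nodes; only the sentence helps.
- `node_determined` — label = head-node attribute (`id mod n`); the
  sentence carries no keyword.
- `relation_determined` — label = relation type, whose verb phrase also
  appears in the sentence; both modalities can recover it.
- `fused` — keyword and node attribute jointly determine the label.  For
  composite n the label is the product code `kw · b + attr` over an
  (a, b) factorization (4 → 2×2, 6 → 2×3, …), so the keyword selects a
  block of classes and the attribute the member; for prime n it is
  `(kw + attr) mod n`.  Either way each unimodal Bayes accuracy is
  strictly below 1 (1/b from the keyword, 1/a from the attribute), while
  both modalities together determine the label exactly.

Defaults (120 nodes, 4 relations, mean total degree 6, 2000 pairs, filler
vocabulary 200, annotation fraction 0.5) define the package's desk-scale
study conditions.  The annotated fraction in full-scale corpora of this
kind is far smaller (~1.6%); the desk default is raised so fine-tuning
folds are non-trivial at 2000 pairs, and the minority regime is exercised
in tests by configuration.  What the generator does **not** model:
realistic biomedical language, reader noise or extraction errors,
degree-skewed scale-free topology, multi-sentence evidence, or duplicated
evidence across triples.  Passing desk-scale tests therefore demonstrates
mechanism (the pipeline learns what it should from where it should), not
performance on real corpora.

## Numerical and design choices

- **Neural core.** The transformer, its objectives and AdamW run on a
  small tape-based reverse-mode autodiff engine over float64 numpy arrays
  (`textkg.nn`), gradient-checked against central finite differences.
  Encoder layers are post-norm with tanh-approximation GELU, matching the
  classic encoder recipe.  Attention masking is additive (−1e9 on padded
  keys), so pad content cannot leak into attended positions (asserted in
  tests to 1e-8).
- **Walks.** Second-order biased walks with p = q = 1 by default (the
  uniform special case keeps oracle tests exact) and undirected edge
  traversal; dead ends repeat the current node so sequences stay
  fixed-length.  One walk per node is cached per epoch, seeded by
  (seed, crc32(node)), making triple sequences order-independent and
  reproducible; callers can opt into per-epoch resampling.
- **Skip-gram.** Negative sampling (5 negatives, unigram^0.75 noise),
  window 5, walks-per-node 10, linearly decaying SGD from 0.025,
  single-threaded vectorized minibatches for determinism.
- **TransE.** Margin ranking loss (margin 1.0, L2 norm), uniform
  head-or-tail corruption, entity renormalization each epoch — the
  standard recipe.
- **Embedding-space handoff.** KG-half token embeddings are a trainable
  table initialized from the node2vec matrix (a `freeze` flag keeps them
  static); when the table dimension differs from the hidden size the
  initialization is projected through a fixed seeded random map, and
  translational input vectors pass through a learned linear projection.
- **Optimizer.** AdamW (β = 0.9/0.999, ε = 1e-8, decoupled weight decay
  0.01) with a linear decay to zero over the scheduled steps; no early
  stopping anywhere — epoch and step budgets are fixed by configuration.
- **Reference fine-tuning profile.** `default_finetune_config()` is
  5 epochs, batch 16, lr 5e-5 — the standard recipe for fine-tuning a
  large pre-trained encoder.  The desk profiles use their own rates
  (tiny: pre-train lr 1e-3 for 300 steps; fine-tune lr 1e-3, 10 epochs,
  batch 16), because a 64-dimensional model trained from scratch barely
  moves at 5e-5 in 5 epochs; these were fixed from pilot runs before the
  test suite was finalized and are recorded in `textkg/profiles.py`.
- **CV.** Stratified k-fold with a fixed seed protects small multi-class
  tasks; fold scores come from training on the other k−1 folds with no
  nested validation; fold averaging is the arithmetic mean.
- **Degenerate inputs.** Unknown nodes map to a dedicated `[UNK]`
  embedding (an `[UNK]`-filled span when a walk cannot start); unknown
  entities/relations in translational mode hit `[UNK]` rows and are
  logged; per-class F1 with zero denominator is 0; `relative_gain` with a
  zero baseline is reported as missing rather than a number.

## Problem sizes

Desk-scale runs used throughout the tests and the acceptance script:
120-node/≈360-edge graphs, 2000 text-triple pairs (1000 unannotated for
pre-training), 300 pre-training steps at batch 16, 600-pair fine-tuning
datasets under 2-fold CV, and a 64-position combined input (hidden 64,
2 layers, 4 heads).  Masking statistics aggregate ≥ 10,000 maskable
positions; oracle equivalences run on 1000 random cases.

## Known limitations

- The from-scratch text baseline is a stand-in for a pre-trained
  biomedical encoder; absolute F1 values at desk scale are not comparable
  to published full-scale numbers, only the qualitative orderings are
  meaningful (multimodal ≥ unimodal on fused tasks; text-only over
  KG-only on text-determined tasks).
- node2vec walks carry no relation information; relation types enter the
  walk-mode cross encoder only through the evidence sentence.
- The whitespace tokenizer has no subword fallback: unseen words collapse
  to `[UNK]` (a pluggable interface accepts an external vocabulary and
  embedding matrix).
- Single-threaded float64 execution is chosen for bit-reproducibility
  over speed; the engine is not suitable for corpus-scale pre-training.
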