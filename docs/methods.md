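# Methods

This note records the models implemented in `relex`, the assumptions behind
them, the choices made where the underlying designs were open, and what the
synthetic test bed does and does not establish.

## Problem setting

Sentence-level relation extraction over biomedical text, cast as
classification of candidate entity pairs. Two corpus families are modelled:

* **Drug–drug interactions (DDI).** Every unordered pair of drug mentions in
  a sentence is a candidate; annotated pairs carry one of four positive
  classes (`DDI-advise`, `DDI-effect`, `DDI-int`, `DDI-mechanism`) and all
  remaining pairs are `DDI-false`. The 4-class evaluation trains and tests
  on positive pairs only; the 5-class evaluation includes the negative
  class, and a "-false" accuracy can additionally be reported on the subset
  whose gold label is not `DDI-false`.
* **Chemical–protein relations (CPR).** Only annotated chemical–protein
  pairs form instances. Fine relation types (e.g. `INHIBITOR`,
  `AGONIST-ACTIVATOR`) group into CPR classes; the five evaluated groups are
  CPR:3, CPR:4, CPR:5, CPR:6 and CPR:9, which together own 13 fine types.
  Classification can target either the groups or the fine types.

Instances mark the target pair in the sentence text with separator tokens —
`**` around drug and gene/protein mentions, `##` around the chemical mention
of a chemical–protein pair (the assignment of `##` to the chemical is fixed
by entity class so instance construction is deterministic). With entity
masking on, every mention is replaced by its class placeholder (`@DRUG$`,
`@CHEM$`, `@PROT$`), which forces the classifier to use context rather than
lexical identity. Masking proceeds right-to-left by character offset so
earlier offsets stay valid, and is idempotent. Overlapping mentions drop the
shorter span with a warning. Character offsets are 0-based and
end-exclusive everywhere in memory; the DDI XML dialect's inclusive end
offsets are converted at the boundary.

ChemProt-style abstracts are split into sentences by a deterministic
rule-based splitter (sentence-final punctuation followed by whitespace and
an uppercase letter or digit, with an abbreviation stoplist). Cross-sentence
relations are dropped with a logged count; unannotated chemical–protein
pairs generate no instance.

## Transformer encoder

A standard post-norm encoder implemented from scratch over a small
reverse-mode autodiff engine (`relex.autodiff`):

* scaled dot-product attention `softmax(QK^T/sqrt(d_k))V` with optional
  key masking; multi-head form concatenates per-head outputs and projects;
* sinusoidal positional encodings (even dimensions sine, odd cosine);
* position-wise FFN `max(0, xW1 + b1)W2 + b2`;
* every sublayer wrapped as `LayerNorm(x + Sublayer(x))` with epsilon 1e-5
  (guards constant rows; configurable).

Tokenization for from-scratch models is whitespace-based with a
frequency-capped vocabulary and character fallback for out-of-vocabulary
words; reserved tokens (class placeholders, separators, whole-label tokens)
are atomic and never split. Initialization draws embeddings and value/output
projections from a seeded normal(0, 0.02); query/key projections use a
1/sqrt(d_model) scale so attention logits are O(1) at initialization — with
a uniformly tiny init the attention softmax starts degenerate-uniform and
attention patterns never break symmetry at these model sizes. All
randomness flows from the configuration seed; evaluation mode is
bit-deterministic. Dropout, when enabled, applies to each sublayer output
before the residual add.

## Graph-attention model (encoder + dependency graph)

A dependency parse (consumed as CoNLL-U; the package never runs a parser)
becomes a binary adjacency matrix: an edge in either direction for every
head–dependent link, plus self-loops. Dependency type labels are ignored;
punctuation stays in the graph; there is no shortest-path or
lowest-common-ancestor pruning — the whole-graph attention is the point,
since pruning can discard context (negation, conjunction) that decides a
relation. The root's head-0 link creates no edge.

Because the encoder operates on model tokens rather than parse words, the
word-level matrix is projected: each sub-word inherits all of its word's
edges (expanded over the neighbour's sub-words), sub-words of one word form
a clique, and sequence specials get self-loops only. This rule preserves
reachability of the word graph under any split and is order-independent.
Masked multi-word entities are single nodes. One package-specific wiring
choice: the pair separator tokens are attached to the entity span they
wrap, so the graph itself marks the classification targets.

The GAT sublayer scores each edge with a single-layer feed-forward
attention mechanism, `e_ij = LeakyReLU(a^T [W h_i || W h_j])`, restricted
to one-hop neighbourhoods (which include the node itself); scores are
normalized by a masked softmax and neighbour features aggregated per head.
The default multi-head output is the averaged form followed by LeakyReLU
(negative slope 0.2, the conventional value); the concatenating form is
available for ablation. There is deliberately no `sqrt(d)` scaling in GAT
scores. The sublayer is fused as `LayerNorm(x + GAT(x))` and sits on top of
the full encoder stack (default one GAT layer, configurable).

**Classification head.** The plain encoder classifier reads the
sequence-start token. For the GAT model this package pools the two target
entity spans (mean over each span's final states, concatenated) into a
linear softmax layer instead: with GAT stacked on top of the encoder and
specials carrying self-loops only, the start token is graph-isolated — no
graph information could reach a CLS-only head, as the identity-adjacency
ablation check makes explicit. Entity-span pooling is the standard
relation-classification head and is the reading consistent with the
architecture's intent. Both poolings (and plain mean pooling) are
available via a constructor flag.

## Slim decoder and autoregressive baseline

The slim decoder adapts an encoder–decoder architecture to single-label
classification by deleting the decoder's self-attention sublayer. A single
learned query embedding cross-attends over the encoder output (decoder-side
Q, encoder-side K and V), passes the FFN sublayer with residual + LayerNorm,
and a linear + softmax head scores the label vocabulary. Labels are whole
atomic tokens ("DDI-effect", "AGONIST" — lexically meaningful strings, not
opaque group codes), so one step emits one label. The forward pass has no
input for previously generated tokens; non-autoregression is structural,
not a decoding flag. The learned start-token query is used at inference
(conditioning on a gold-label embedding would leak the answer at test
time; the model learns the mapped embedding for this token). One decoder
block by default; argmax ties break to the lowest label index.

The baseline is a minimal standard decoder block (causal self-attention +
cross-attention + FFN) over the same label vocabulary plus start/end
symbols, trained with teacher forcing and decoded greedily (beam width 1;
causality is verified by perturbation rather than assumed).

## Training and evaluation

AdamW with decoupled weight decay and cross-entropy loss; seeded shuffling;
linear learning-rate warmup over the first 100 steps (post-norm stacks are
unstable without it). Tiny-scale defaults, chosen once for the synthetic
task sizes below: the graph models train 15 epochs at learning rate 3e-3,
the decoder heads 20 epochs at 1e-3 (attention-pooled heads need the
gentler rate), batch size 8, weight decay 0.01. When a held-out set is
supplied the best-held-out-accuracy snapshot is restored (micro-F1 equals
accuracy here, so the selection metric is accuracy).

Evaluation computes per-class precision/recall/F1/support from confusion
counts, with macro (unweighted mean), weighted (support-weighted mean) and
micro (pooled counts) aggregation. Zero denominators yield 0.0, matching
the convention used for classes with no correct predictions. Reports round
to 4 decimals; full precision is kept internally. In single-label
classification micro-P/R/F1 equal accuracy; `prf1` returns the harmonic
mean as exactly `P` when `P == R` so the identity holds bit-exactly.

## Synthetic planted-structure corpus

The generator emulates the structural core of the task with none of the
linguistic surface: each sentence is a chain of templated clauses over 2–4
entities — one transitive pair clause at a chain end whose verb either is a
label-specific trigger word (probability 0.6) or a neutral verb, plus
intransitive solo clauses — with projective single-rooted dependency trees
by construction. The gold label of a pair is determined by the unique
trigger on the tree path between the entities (negative if none). With
probability 0.5 (the default study condition) a conflicting trigger is
attached as a leaf child of a clause verb, immediately before or after it
in linear order. A leaf never lies on a path, so tree structure always
recovers the label, while in the flat token stream the distractor and the
true verb are adjacent in random order — a purely sequential reader faces
irreducible ambiguity exactly where the graph disambiguates. Entity
surfaces come from a closed synthetic lexicon ("drugA17") so entity masking
is meaningful.

Standard experiment sizes: 200 training and 100 held-out sentences
(roughly 660 and 300 candidate pairs), 5-class scheme with entity masking,
encoder d_model 32, 2 heads, 2 layers, one GAT sublayer with 2 heads.
These sizes keep a full from-scratch training run around half a minute on
one CPU while leaving the structural effect large: the graph model reaches
near-perfect held-out accuracy, the identity-adjacency ablation plateaus
near the sequence-ambiguity ceiling.

What passing these experiments shows: the GAT sublayer can exploit exactly
the information the adjacency matrix adds, and the slim decoder matches a
standard autoregressive head at equal parameter budget on a task where the
label is a single token. What it does not show: anything about parser
errors, lexical sparsity, class imbalance at corpus scale, or pretrained
initialization — real-corpus behaviour is explicitly out of this package's
desk-scale scope.

## Numerical and degenerate-input conventions

* Masked attention positions receive an additive -1e30 logit; a query with
  every key masked is an error, not a NaN.
* GAT neighbourhoods are never empty (self-loop invariant asserted).
* Softmax subtracts a detached row max; LayerNorm guards variance with
  epsilon 1e-5; constant rows normalize to zero.
* Overlong sequences raise an explicit error rather than truncating.
* Empty training sets, empty label sets and empty encoder outputs raise
  errors naming the condition.

## Known limitations

* The autodiff engine is eager and per-instance; it is sized for desk-scale
  experiments, not corpus-scale fine-tuning.
* Sub-word projection assumes contiguous sub-word runs per word, which the
  built-in tokenizer guarantees; external tokenizers must respect it.
* The exact sub-word edge rule used with pretrained sub-word vocabularies
  is one defensible choice among several; alternatives (e.g. first-sub-word
  only) are not implemented.
* ChemProt-style reading assumes document text is title + single space +
  abstract with offsets into that concatenation.
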