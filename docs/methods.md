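# Methods

## Problem setting and assumptions

`cidrex` extracts document-level chemical-induced-disease (CID) relations as
`<Chemical ID, Disease ID>` pairs of MeSH identifiers. It assumes input
documents arrive pre-annotated (PubTator format: title, abstract, entity
mentions with 0-based half-open character offsets over `title + " " +
abstract`); named-entity recognition and normalization are out of scope.
Weak labels come from a knowledge-base fact table: a candidate pair is
positive iff curated with the Marker/Mechanism tag (comparison is
case-insensitive; other tags are preserved on the fact but treated as
non-positive). The multi-instance premise is the at-least-one assumption: a
truly related pair has at least one instance that expresses the relation,
while other instances in its bag may be noise. The attention unit exists to
down-weight that noise.

## Alignment

Candidate pairs are the Cartesian product of a document's distinct chemical
and disease ids, in lexicographic order. A pair with at least one sentence
containing mentions of both ids becomes an intra-sentence bag whose instances
are *all* co-located mention pairs (two chemical mentions and one disease
mention in a sentence yield two instances — this is forced by the worked
example's count of three). All remaining pairs become one inter-sentence
instance each; the nearest mention pair (minimum absolute global-token
distance, ties to the earliest chemical mention) is recorded for
traceability, while features aggregate over all mentions. The two cases
partition the candidate pairs exactly, and `align_document` asserts this.
Negative pairs are all non-curated candidates; no subsampling is applied by
default.

## Text processing

Normalization lowercases, maps every maximal digit run to the single token
`<num>`, removes characters outside printable ASCII and collapses whitespace;
it is idempotent. Tokenization happens on raw text (so offsets stay valid)
and token strings are normalized afterwards; a token that normalizes to the
empty string becomes `<unk>`. Sentence segmentation is rule-based and
deterministic: the title is sentence 0; the abstract splits after
sentence-final punctuation followed by whitespace and an uppercase letter or
digit, except after a protected abbreviation (i.e., e.g., Fig., etc.) or when
the split would cut through an annotated mention. Location markers take four
values — title, first, last, middle abstract sentence — with priority
T > A_Fst > A_Lst > A_Mdl, so a one-sentence abstract is "first".

Relative-position codes are `clip(i − anchor, ±max_dist)` with the anchor at
the first token of the mention; `max_dist` defaults to 30 (61 codes). The
position table is shared between the chemical- and disease-relative codes.
The hyponym tag of a concept is 1 iff no other concept in the same document
carries a MeSH tree number that strictly extends (proper dotted prefix) one
of its tree numbers; concepts missing from the tree default to 1 with a
warning. Mention frequency per document is bucketed as
`min(floor(log2(count)), 7)`.

## Models and training

Both networks are implemented in float64 NumPy with hand-written analytic
gradients; test suites check every component against scalar-loop reference
implementations and every gradient against central finite differences. The
LSTM uses logistic input/forget/output gates and a tanh candidate with no
peephole terms in the gates. Concatenated forward/backward states are
mean-pooled into the instance representation. Attention scores are
`v·tanh(W_s s + W_m m + W_r r + b_s)`; the number of rows of the scoring
matrices (`attention_dim`) is a free choice, default 100 — large enough to be
expressive, small relative to the 2×hidden instance representation. The
output is binary (CID vs. not): the task defines a single positive class.
The decision threshold is 0.5, with ≥ counting as positive.

Training minimizes the mean negative log likelihood of the weak labels plus
λ‖θ‖² (λ default 1e-4, exposed) by RMSprop (ρ = 0.9, ε = 1e-8) over
mini-batches of bags/instances. A log floor of 1e-12 guards degenerate
probabilities. Inverted dropout (default rate 0.3) is applied only to the
intra hidden vector z and the inter decoder output j, and only in training;
with rate 0 train and test modes agree exactly. Lookup tables are initialized
N(0, 0.01²), weight matrices Glorot-uniform, biases zero; a pre-trained
word-vector file may initialize the word tables. Unknown words and concepts
map to reserved index-0 columns. One tenth of the training set (seeded split)
serves as a development set for early stopping with best-parameter restore;
the epoch budget defaults to 15 (intra) / 20 (inter). All randomness —
initialization, shuffling, dropout — flows from a single `random_state`, so
identical seeds reproduce identical parameter trajectories on one thread.

The stacked auto-encoder is, despite its name, purely supervised: there is no
reconstruction loss, just encoder → decoder → softmax. The
frequency-embedding dimension (absent from the production hyper-parameter
table) defaults to 50 to match the other small embeddings.

## Merging and evaluation

Positive predictions from both levels are unioned on the id triple; when both
levels predict the same pair the higher score and its source win (an intra
negative does not veto an inter positive). Precision, recall and F1 use exact
set matching with the zero conventions for empty denominators. The
precision–recall sweep thresholds on the distinct scores, thinned to evenly
spaced quantiles; recall is non-increasing along the sweep by nestedness.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
natural language: documents are templated token sequences (letter-only entity
and filler tokens, so `<num>` normalization cannot collapse them). Per
document it samples 1–2 chemicals and 1–2 diseases; each candidate pair
co-occurs intra-sententially with probability 0.65 (1–3 co-occurrence
sentences, occasionally with a duplicated chemical mention to exercise
mention-pair instances) or else is split across two dedicated sentences.
Expressing instances of positive pairs carry a trigger token strictly between
the mentions — a position-dependent signal the BiLSTM can learn; a fraction ν
(default 0.3) of the non-first instances in positive bags carry only
distractors, with the first instance always expressing (at-least-one
guarantee). Positive inter-sentence pairs attach a shared relational marker
token to both entity mentions so the document-level lexical features are
learnable. The knowledge base is a global sample of the concept grid (rate
0.35) plus a couple of non-positive facts; gold pairs are exactly the
positive candidate pairs. A toy MeSH tree plants parent–child chains so both
hyponym outcomes occur. Triggers and distractors share one character length,
so `corrupt_bags` can rewrite triggers in place without disturbing offsets
while protecting one expressing instance per pair.

What passing on this corpus shows: the implementation learns, the attention
mechanism concentrates weight on expressing instances under planted noise,
and the whole pipeline composes correctly end to end. What it does not show:
performance on real biomedical language, whose relation expressions are not
single triggers, whose entity annotations contain NER errors, and whose
inter-sentence relations hinge on discourse rather than marker tokens.
Benchmark-corpus results therefore cannot be inferred from these numbers.

## Problem sizes

The reference experiment (`run_synthetic_experiment`, also driven by
`scripts/acceptance.py`) uses 200 documents with ν = 0.3, an 80/20 document
split, and compact model dimensions (32-d word, 24 LSTM hidden units for the
intra model; 16-d word, 16/8 encoder/decoder nodes with λ = 3e-3 and a longer
epoch budget for the inter model). These sizes are matched to the synthetic
vocabulary (~100 types) — production-scale dimensions would be badly
over-parameterized for it and would memorize pair identities instead of
generalizing from lexical evidence; the production defaults remain on the
estimators. On this corpus the merged document-level F1 on the held-out split
is typically 0.95–1.0 across seeds.

## Known limitations

Rule-based segmentation approximates a learned splitter; multi-word mention
anchoring uses the first token; inter-sentence "bags" contain a single
instance per pair (the nearest-mention construction defines one instance; the
implementation does not invent multi-instance inter bags). Class imbalance
handling is limited to an optional negative cap at alignment time; no
calibration of scores is performed.
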