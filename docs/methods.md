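# Methods

This note documents the models and procedures implemented in `emrkg`, the
parameters that matter, the numerical choices, and what the synthetic test
bed does and does not establish.

## Corpus handling

Annotations use 0-based, end-exclusive character offsets (the BRAT standoff
convention).  The parser validates every entity record against the document
text: offsets must lie inside the text and, in strict mode, the recorded
surface string must equal the text substring (lenient mode logs a warning
and trusts the text).  Overlapping spans are rejected with an error naming
both spans; a `repair_overlaps` mode keeps the longest span of each
overlapping group, since the conceptual layer has no nested-entity
semantics.  Relation/attribute standoff records are ignored.

BIO is the canonical labelling scheme: the first token overlapping a span
gets `B-<type>`, later overlapping tokens `I-<type>`, and conversion back
from labels is exact for character tokenization — the default, standard for
Chinese clinical text.  The tokenizer is a pluggable boundary function so
subword schemes can be substituted; sequence/label alignment is the caller's
contract then.  Spans may not cross sentence boundaries (sentences split on
`。` and newline).  Text normalisation is an ordered list of regex rules
(whitespace collapse, date unification `2015年3月5日 → 2015-03-05` by
default) and is idempotent.  De-identification is rule-based replacement of
configured identifier patterns with generated stable patient IDs — no
ML-based PHI detection is attempted, and no guarantee of complete scrubbing
is implied.

Dataset splits are document-level, seeded, with floor-plus-largest-remainder
size allocation (so 10 documents at 0.8/0.1/0.1 give exactly 8/1/1) and a
guard that no nonzero-ratio partition comes out empty when avoidable.

## DERM augmentation

One uniform random number per sequence (per pass) selects the branch:

| branch  | condition          | effect |
|---------|--------------------|--------|
| replace | RN < 0.3           | every entity surface replaced by a uniformly drawn same-type dictionary term; tokens and labels re-aligned to the new length |
| mask    | 0.3 ≤ RN < 0.6     | every entity token becomes `[MASK]`; labels unchanged |
| keep    | RN ≥ 0.6           | sequence unchanged |

Design choices: the per-sequence RN governs all mentions in the sequence
uniformly (a per-mention mode exists behind a flag); replacement excludes
the original surface when alternatives exist, to avoid no-op draws; masking
is per-token and length-preserving, which keeps label alignment trivial and
mirrors BERT-style masking.  Non-entity tokens are never touched and outputs
are always BIO-valid.  Whether augmentation is re-sampled every epoch or
applied once is an open choice; the trainer supports both
(`TrainConfig.augment_each_epoch`, default on, since augmentation "during
training" is most naturally per-epoch).  An injectable `rng_value` makes
every branch unit-testable deterministically.

## Encoder

The contract is `token sequence → context vectors H = [H_CLS, H_1…H_n,
H_SEP]`.  Input vectors are elementwise sums of token, position and segment
embeddings; all inputs are single sentences, so the segment id is constant 0.
Each layer applies multi-head scaled dot-product attention
(softmax(QKᵀ/√d_k)V, heads concatenated then projected by W_o) followed by a
position-wise feed-forward sublayer.  Residual connections and post-layer
normalisation are included even though attention and feed-forward maps alone
define the contract — without them the stack does not train stably; this is
an engineering completion, documented as such.

Pretrained weights are out of scope.  The trainable stack runs at desk
scale: defaults d_model = 16, 2 layers, 2 heads, d_ff = 32 (a production
analogue would stack 24 wide pretrained layers).  A `LookupEncoder`
(embedding-only, equivalent to a zero-layer stack) serves fast tests and is
the natural adapter point for externally computed vectors.  Tokenization is
character-level by default; the vocabulary is pluggable so BPE vocabularies
drop in unchanged.

All differentiable computation runs on a small reverse-mode autodiff core
(`emrkg.autograd`) written for this package: float64 NumPy arrays, the ~20
operations the models need, and an Adam optimizer.  Gradient correctness is
tested against central finite differences for every operation.

## BiLSTM-CRF labeler

Context vectors (excluding `[CLS]`/`[SEP]`, which carry no labels) feed a
bidirectional LSTM; per position the forward and backward states are
concatenated, hᵢ ∈ R²ʰ (default h = 16).  Emissions are affine,
Sᵢ = W hᵢ + b ∈ Rᵏ over the k BIO labels.  The CRF scores a label sequence
as Σᵢ S[i, yᵢ] + Σᵢ T[yᵢ, yᵢ₊₁] plus trainable start/end boundary vectors
(on by default).  Numerical choices:

* the partition function is computed by the forward algorithm in log space
  with log-sum-exp stabilisation, never by enumeration (enumeration is the
  *test oracle* at n ≤ 5, k ≤ 4);
* BIO transition constraints (`I-x` only after `B-x`/`I-x`, no initial
  `I-x`) are additive −∞ masks, on by default, so decoded sequences are
  always valid;
* Viterbi ties break toward the lowest label index at each backtrack step,
  making decoding reproducible;
* training gradients are the exact expectation-minus-observation form from
  forward–backward unary/pairwise marginals, bridged into the autodiff graph
  as a custom node.

Training is mini-batch Adam (defaults: 12 epochs, lr 0.01, batch 32,
gradient-norm clip 5) on sequences bucketed by exact length, so batches need
no padding.  These defaults are this package's own choices for the synthetic
corpus; no claim is made that they match any particular published training
setup.  Divergence (non-finite loss) raises immediately with the epoch
number.  Fixed seeds give bitwise-identical parameters.

## Exact-match evaluation

A predicted entity is a true positive only when a gold entity matches its
type *and* boundaries; wrong-type-right-boundary costs one FP and one FN.
Micro-averaging (pooled counts) is the default aggregate; per-type rows are
also emitted.  0/0 ratios (no predictions, or no gold) are defined as 0 with
a logged warning.

## Knowledge fusion

Each reference terminology entry is one document.  Features are character
n-grams, default range (1, 2): single characters capture stem overlap and
bigrams capture local order, which matches how Chinese clinical term
variants share substrings.  Weights follow TF(t,d) = f_{t,d}/f_d and
IDF(t) = ln(N/df(t)) with no smoothing — the literal formulas — guarded by
an optional +1 document-frequency smoothing flag for corpora where an
unseen feature would otherwise divide by zero.  Queries are vectorized with
the reference-fitted IDF (features outside the reference vocabulary are
dropped); this is the standard choice and is an assumption, since nothing
forces queries to be weighted that way.

Cosine similarity is dot product over norm product, defined as 0 when either
norm is 0; values within 1e−12 of 0 or 1 are snapped to the exact bound so a
term matched against itself scores exactly 1.  Tier boundaries are exact:
strictly > 0.75 auto, closed [0.6, 0.75] review, strictly < 0.6 reject; ties
between reference terms break lexicographically.  Review-tier decisions go
to a queue file and are never auto-merged.  Disease/symptom entities route
to the website-derived reference corpus, treatment/operation entities to the
terminology standard; unrouted types pass through unmapped.

## Graph assembly, export, retrieval

The conceptual layer (11 entity types, 18 relations + 1 hub relation) ships
as editable YAML (`emrkg/data/schema.yaml`).  Domain/range pairs for the
`rels_*` family are patient → entity-type links — fixed by the retrieval
pattern patient → `rels_disease` → disease → `accompany_with` →
complication — and the website relations connect clinical entity types
(disease → symptom/drug/food/examination/department).  Two relations named
`rels_disease` and `rels_diseases` both exist in the inventory; they are
registered verbatim (the former patient-linked, the latter
disease-to-related-disease).  The spelling `acompany_with` is accepted as an
alias of `accompany_with`.

Node identity is (entity_type, canonical name); patients are keyed by
generated ID, with attribute maps (nation/age/sex) carried separately.
Triples are validated against domain/range before insertion; failures are
collected with reasons, never silently dropped, and duplicates collapse (the
store is a set).  Assembly links each patient to its fused entities directly
by default; a proxy-hub mode materialises one per-category hub node per
patient (hub typed as its members, linked by `category_member`), matching
visualisations that group a patient's entities by category.

Exports: one bulk-import CSV per entity type (`id:ID,name,:LABEL,attrs…`)
plus a relationships CSV (`:START_ID,:END_ID,:TYPE`), and a Cypher file of
MERGE statements.  Both round-trip to an equal store, with standard CSV
quoting and backslash escaping in Cypher.  Multi-hop retrieval follows an
exact relation sequence from a start entity, returning a lexicographically
sorted frontier; it agrees with a networkx-based traversal oracle in tests.

## Quality auditing

`stratified_sample` draws the requested number of triples per relation
stratum uniformly without replacement, seeded.  Labels (Correct / Incorrect
/ InsufficientContext) come from annotators or the synthetic generator — the
tool never auto-labels.  Accuracy is correct/(sampled − IC) per stratum; the
overall row pools counts across strata rather than averaging stratum
accuracies.  Whether stratum sizes should be proportional to relation
frequency is left to the user: sizes are free configuration.  Reported
percentages round half-up to two decimals (the convention of printed audit
tables); full precision is kept internally.

## Synthetic test bed: what it shows and what it does not

The generator emulates the *structure* of annotated Chinese EMR data: typed
dictionaries (terms of 2–10 characters, weighted toward the 4–8 range
typical of clinical terms), documents embedding dictionary terms in carrier
text with exact recorded offsets, single-edit surface variants (drop-last,
character doubling, substitution, suffix addition — each pair's rule is
logged), and stratified labelled triples with configured accuracy 0.93 and
insufficient-context rate 0.02.  Each entity type draws from its own
disjoint character pool and carrier text from another, giving strong lexical
cues.  Defaults: 100 documents × 5 mentions over 7 EMR-sourced types, 50
terms per dictionary.

This means passing tests establish that the machinery is correct — exact
round-trips, calibrated augmentation rates, a CRF that matches enumeration,
a trainable stack that recovers planted entities, fusion that recovers
single-edit variants — not that the models reach any particular accuracy on
real clinical text, which has ambiguous boundaries, shared vocabulary across
types, spelling noise and genuine linguistic structure that the generator
deliberately does not model.  Published F1 scores for large pretrained
encoders on private clinical corpora are out of scope here and are not
reproduced.

## Known limitations

* The autodiff core is minimal by design: float64 only, no graph reuse, no
  vectorised multi-sequence CRF across different lengths (batches are
  same-length buckets).
* Character-level tokenization is assumed throughout the defaults; subword
  vocabularies work but receive no special alignment help.
* De-identification is pattern-based only.
* TF-IDF fusion is lexical: true synonyms with no shared substrings land in
  the reject tier by construction; semantic (embedding-based) linking is
  deliberately out of scope.
* The Cypher export targets the bulk-load/MERGE convention and is not a
  general Cypher emitter.
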