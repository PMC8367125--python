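# Methods

## Data model

The graph is typed: eleven entity types (disease, symptom, examination,
surgery, medicine, body structure, treatment, plus the four disease
attributes pathogeny, department, English name, alternative name) and a
closed inventory of ten relation signatures with fixed head/tail types
(e.g. `Diseases_rel_Symptom`: disease → symptom).  Validation is strict:
unknown labels or mistyped endpoints are rejected at load time with the
offending line.

Surface forms are normalized once, at entry: Unicode NFKC, surrounding
whitespace stripped, internal whitespace collapsed; English-name
attribute values are additionally case-folded.  CJK strings are not
case-folded (no case exists) and no further canonicalization is applied —
the similarity features are supposed to see real spelling variation.
Entity ids are SHA-1 content hashes of (source, type, normalized
surface), so identical inputs give identical graphs across runs, and
entities are automatically deduplicated within a source on normalized
surface.  This exact-surface dedup is the only *intra*-source merging
performed; semantic merging is deliberately reserved for the cross-source
fusion stages.

Triples are unordered and unique per (head, relation, tail); provenance
is a sorted set of source tags per triple rather than duplicate edges.
Merging is represented as an idempotent entity→canonical map built by
union-find; the canonical representative of a component is chosen
deterministically (preferred source — `web` by default, as web portals
carry curated terminology — then longer surface, then smallest id).
Applying a merge rewrites endpoints and collapses duplicates, so triple
counts are monotone non-increasing, and re-applying the same map is a
no-op.

## Translational embeddings

TransE, TransH and TransR are implemented in plain NumPy and share one
trainer: minibatch SGD (batch 128) on the margin ranking loss
Σ max(0, γ + f(h,r,t) − f(h′,r,t′)) with γ = 1, one corrupted triple per
positive, entity vectors projected to the unit ball after each batch,
TransH normals re-normalized, TransR projections initialized at identity
(so an untrained TransR scores exactly like TransE).  Initialization is
uniform in ±6/√dim; relation vectors are unit-normalized at start.
Defaults: dim 50, 500 epochs, learning rate 0.01.

Three numerical choices deserve mention:

* **Filtered, type-constrained corruption.**  Negatives replace the head
  or tail (equal probability) with a uniform entity of the same type;
  with a closed schema, cross-type corruptions would be trivially easy.
  A corrupted triple that happens to be a true triple is resampled:
  with 1-N relations a raw draw hits a true tail a few percent of the
  time, which puts an irreducible floor under the ranking loss.
  Candidate ranking in hits@k remains *raw* (true triples are not
  filtered from the candidate list).
* **Inverse-time learning-rate decay**, lr_t = lr/(1 + 0.05·epoch), so
  late-epoch parameter jitter shrinks and the monitored loss converges
  almost monotonically instead of bouncing around a plateau.
* **Deterministic loss monitoring.**  The recorded per-epoch loss is
  evaluated on one fixed corruption per positive, drawn up front — a
  deterministic function of the parameters.  The SGD updates themselves
  use freshly resampled corruptions each epoch.

One embedding is trained on the disjoint union of the two source views
(ids are source-disjoint); the two sources end up in one vector space
tied together by the shared relation labels, which is what makes
cross-source cosine similarity meaningful as a classifier feature.

hits@k ranks the true tail among all embedded entities of the relation's
tail type by ascending distance, ties broken by entity id.  It is
evaluated over the trained graph's own triples — the protocol that
matches evaluating "representation ability" of a whole graph — not over
a held-out split: the synthetic generator assigns tails uniformly at
random, so a held-out edge is statistically independent of the training
data and *no* model can beat chance on it.  Passing scores here
demonstrate that the models represent the graph they were trained on,
not that they generalize to unseen links.

## Similarity features

* `jaccard_chars` — Jaccard over unique characters of the two surfaces
  (multiplicity and order ignored; set semantics).  Empty operands are
  rejected.
* `jaccard_sets` — Jaccard over the *pooled* characters of all member
  strings of each set (used on tail-surface sets in head fusion); the
  empty/empty case is defined as 0.
* `semantic_score` — delegates to a pluggable scorer whose contract is
  symmetry, range [0,1] and score(x,x)=1.  The shipped default is cosine
  over character-bigram count vectors: deterministic, dependency-free,
  and a reasonable stand-in for short CJK strings where bigrams carry
  most lexical identity.  A fine-tuned transformer pair classifier (pair
  encoded jointly, pooled vector through two dense layers, tanh then
  softmax) satisfies the same contract; no neural weights ship with the
  package.
* `same_tail_count` — number of shared tail ids adjacent to two heads
  over non-attribute relations, counted after rewriting through the tail
  merge map.  This is why tail fusion is a hard precondition of head
  fusion.  It is left unnormalized (classifiers standardize internally).

Entities missing from the embedding vocabulary get cosine 0 (neutral)
plus a missing flag; feature rows are always finite.

## Fusion stages

Candidate pairs are blocked on identical entity type and cross-source
membership; an optional cheap prefilter (both Jaccard and semantic zero)
bounds the quadratic blow-up but is off by default.  The three pair
classifiers are scikit-learn models behind one interface: logistic
regression, decision tree (min leaf 2), and an MLP with one hidden layer
of 16 units, 200 epochs.  Features are z-scored on the training split;
the labeled pairs are split 80/20 stratified; metrics are reported on
the held-out fifth.

Scored pairs above the decision threshold (default 0.5) are matched
greedily one-to-one in descending score with id tie-breaks — near-optimal
here, O(n log n), and deterministic.  Matches are closed by union-find.

Head fusion runs attribute alignment first: two diseases merge if any
normalized name value (primary surface, alternative name, English name —
the latter case-insensitively) coincides across sources.  Primary-surface
matches are recorded with provenance `exact`, attribute matches as
`attribute`; exact-name matching is folded into this stage rather than
invented as a separate one.  A value naming two distinct diseases within
one source is a conflict: it is logged and skipped, never guessed about.
Diseases already aligned are excluded from the structural stage, so
attribute merges cannot be overturned.  The combination of the three
structural features is left entirely to the classifier; no hand-set
weights.

## The synthetic benchmark

The generator emulates the statistical situation the fusion model
assumes: one ground-truth disease-centred graph; an `emr` view that is
symptom-rich and attribute-free; a `web` view that carries all attribute
triples plus treatments; a configurable fraction of relational tail
entities present in both views (`overlap`, default 0.6); shared entities
surface-corrupted in exactly one view with probability `variant_rate`
(default 0.3); and alternative/English names on a fraction
`attr_coverage` (default 0.3) of diseases.  Per-disease tail counts are
Poisson with means proportional to the relation-frequency profile of a
disease-centred clinical graph, scaled to desk size (symptom mean 8,
others in proportion ≈ 57 : 1 : 4.5 : 8 : 2 : 2.2 : 1.3; one body
structure per distinct symptom; every disease keeps at least one
symptom).  Surfaces are unique random 2–6 character strings over a
CJK-range alphabet so character Jaccard behaves as on Chinese clinical
text; an ASCII alphabet can be configured for debugging.

Corruption applies exactly one operator per corrupted entity, drawn
uniformly from {single-character substitution, affix add (感/症/状/样),
affix drop (length > 2), synonym replacement (on lexicon hit)}, with
inapplicable draws falling back to substitution.  One operator — not a
compound — keeps `variant_rate` interpretable as the fraction of
non-trivial alignment cases.

When a disease's surface is corrupted and the disease has attribute
coverage, the web view records the emr spelling as an alternative name —
the mechanism by which attribute alignment can recover spelling-variant
diseases, mirroring how curated portals list clinical synonyms.

Labeled alignment pairs are emitted within entity type only (the same
blocking the fusion uses): all cross-view positives, plus sampled
same-type negatives at a 1:1 ratio by default (the ratio is exposed as
`neg_ratio` rather than fixed).

What the generator does **not** model: realistic Chinese clinical
language, segmentation or annotation noise, correlated disease–symptom
structure (tails are sampled independently per disease), many-to-one
synonymy within a source, or attribute noise.  Consequently, passing
scores on this benchmark demonstrate the machinery end-to-end under
controlled corruption — they do not predict absolute performance on real
clinical corpora, where the semantic scorer would need to be a trained
language model and the candidate space is larger and messier.

## Degenerate inputs and edge cases

Training on an empty graph, zero-probability configs, single-class
training labels, k < 1 in hits@k, empty Jaccard operands and zero-vector
cosines all raise explicit errors.  A relation whose head or tail slot
offers no alternative entity of the right type falls back to untyped
corruption with a warning, so trivially small graphs still train.
Classifier thresholds at the extremes yield empty merge maps rather than
errors.  Pipeline stages abort with the stage name on failure; reruns
with identical config are byte-identical (no timestamps inside result
files).

## Problem sizes

Default experiments use 50 diseases (≈ 690 truth triples, ≈ 1 000 union
triples, ≈ 490 union entities), dim-50 embeddings and 200–500 epochs;
the proportion-sanity check of the generator uses 200 diseases.  These
sizes were chosen so the full pipeline runs in seconds on one CPU while
every relation type is populated well enough to exercise the schema.
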