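# kgfuse

Head-and-tail entity fusion for disease-centred medical knowledge graphs.

## The problem

Medical knowledge graphs are typically assembled from heterogeneous
sources — structured extractions from electronic medical records on one
side, curated web portals on the other.  The same concept appears in both
under different surface forms (头痛 vs. 头疼 for *headache*; a disease
name in one source that is only an *alternative name* in the other), so
the raw union of the two triple sets is full of duplicated entities and
redundant edges.  `kgfuse` merges such graphs in two stages:

1. **Tail entity fusion** — symptoms and examinations are aligned across
   sources by a binary pair classifier over three similarity features:
   a pluggable short-text *semantic* score (character-bigram cosine by
   default; a transformer adapter satisfies the same contract), the
   *cosine similarity of translational graph embeddings*, and the
   *Jaccard coefficient* over surface-form characters,
   J(t₁,t₂) = |t₁∩t₂| / (|t₁|+|t₂|−|t₁∩t₂|).
2. **Head entity fusion** — diseases are first aligned by exact name and
   by alternative/English-name attributes; the remainder go through a
   structural classifier over (Sₐ, Jaccard, cos): the number of shared
   canonical tail nodes, the pooled-character Jaccard of the two tail
   sets, and embedding cosine.  Tail fusion runs first so that shared
   tails are counted on canonical ids.

Pair decisions above the probability threshold are matched greedily
one-to-one, closed by union-find into an idempotent merge map, and applied
to the graph (entities rewritten to canonical ids, duplicate triples
collapsed — the triple count never increases).

The embeddings are the classical translation family, trained by
margin-ranking SGD with type-constrained, filtered negative sampling:

* **TransE** f(h,r,t) = ‖h + r − t‖
* **TransH** f(h,r,t) = ‖h⊥ + d_r − t⊥‖, x⊥ = x − (wᵣᵀx)wᵣ
* **TransR** f(h,r,t) = ‖Mᵣh + r − Mᵣt‖

with f evaluated by raw tail ranking (hits@k) against all same-type
candidates.

Because real clinical corpora are private, the package ships a
first-class synthetic benchmark generator: a ground-truth disease-centred
graph under the fixed 10-relation schema, two overlapping corrupted
source views (`emr` symptom-rich, `web` attribute-rich), and exhaustively
labeled cross-view alignment pairs.  Everything is deterministic given a
seed.

## Worked example

`examples/04_full_fusion.py` runs the whole pipeline through the library
API:

```text
tail fusion: held-out F1 1.000, vs ground truth F1 0.971
head fusion: held-out F1 1.000, vs ground truth F1 0.970
entities 491 -> 358, triples 1038 -> 792
merges by stage: {'tail_model': 84, 'exact': 31, 'attribute': 6, 'head_model': 12}
```

Line by line: both pair classifiers separate their held-out labeled pairs
perfectly; measured against the generator's ground-truth alignment, the
merge maps reach F1 ≈ 0.97 under 30 % surface corruption.  Fusion shrinks
the union graph from 491 to 358 entities and removes 246 duplicate
triples.  Of the merged diseases, 31 matched by exact name, 6 through an
alternative-name attribute, and 12 by the structural model; the 84 tail
merges come from the feature classifier.

The other examples are single-capability walkthroughs: loading/exporting
(`01`), the benchmark generator (`02`), and embedding training with
hits@10 evaluation (`03`).  A thin CLI wraps the same stages:

```sh
kgfuse simulate --seed 42 --out bench/
kgfuse embed bench/view_emr.tsv bench/view_web.tsv --model transR --out emb/
kgfuse run --out run1/          # full pipeline with default config
```

Exports are Neo4j bulk-import CSV pairs (`nodes.csv`,
`relationships.csv`) and RDF N-Triples (attribute values as literals);
both round-trip back through the loaders.  A user-supplied ICD dictionary
annotates canonical diseases via `map_icd`.

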