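"""Per-pair similarity features for the tail and head fusion classifiers.

Tail-entity pairs (symptoms, examinations compared across sources) are
described by three features: a semantic similarity from a pluggable short-
text scorer, the cosine similarity of the two entities' translational
embeddings, and the Jaccard coefficient over the characters of the two
surface forms.  Head (disease) pairs are described by the number of shared
canonical tail nodes, a Jaccard coefficient over the pooled characters of
their tail surface sets, and embedding cosine.

All features are symmetric in the pair; Jaccard is computed over unique
characters (multiplicity ignored), matching set semantics.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol

from .graph import KnowledgeGraph, MergeMap


def jaccard_chars(a: str, b: str) -> float:
    """Jaccard coefficient |A∩B| / |A∪B| over the unique characters of two strings."""
    if not a or not b:
        raise ValueError("jaccard_chars operands must be non-empty")
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    return inter / (len(sa) + len(sb) - inter)


def jaccard_sets(A: Iterable[str], B: Iterable[str]) -> float:
    """Jaccard over the pooled characters of all member strings per set.

    Word order and multiplicity inside each set are ignored; two empty sets
    have similarity 0.0 by convention.
    """
    ca = set().union(*(set(s) for s in A)) if A else set()
    cb = set().union(*(set(s) for s in B)) if B else set()
    union = ca | cb
    if not union:
        return 0.0
    return len(ca & cb) / len(union)


def same_tail_count(
    h1: str,
    h2: str,
    kg1: KnowledgeGraph,
    kg2: KnowledgeGraph,
    merges: MergeMap,
) -> int:
    """Number of identical (canonical) tail nodes shared by two head entities.

    Tails are compared after rewriting through ``merges`` — this is why tail
    fusion must run before head fusion — and only structural (non-attribute)
    relations count.
    """
    t1 = {merges.resolve(t) for t in kg1.tails_of(h1, relational_only=True)}
    t2 = {merges.resolve(t) for t in kg2.tails_of(h2, relational_only=True)}
    return len(t1 & t2)


class SemanticScorer(Protocol):
    """Contract for pluggable pair scorers: symmetric, score(x, x) == 1, range [0, 1].

    A transformer-based adapter (e.g. a fine-tuned Chinese BERT pair
    classifier: pooled [CLS] vector through two dense layers, tanh then
    softmax) satisfies the same contract; no neural weights ship with this
    package.
    """

    def __call__(self, a: str, b: str) -> float: ...


def _char_bigrams(s: str) -> Counter:
    if len(s) < 2:
        return Counter({s: 1})
    return Counter(s[i : i + 2] for i in range(len(s) - 1))


def bigram_cosine(a: str, b: str) -> float:
    """Default semantic scorer: cosine of character-bigram count vectors.

    Deterministic and dependency-free; length-1 strings fall back to the
    string itself as a single token so score(x, x) is always 1.
    """
    ca, cb = _char_bigrams(a), _char_bigrams(b)
    dot = sum(v * cb[k] for k, v in ca.items())
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def semantic_score(a: str, b: str, scorer: SemanticScorer | None = None) -> float:
    """Semantic similarity of two surface forms via the pluggable scorer."""
    scorer = scorer or bigram_cosine
    try:
        return float(scorer(a, b))
    except Exception as exc:
        raise RuntimeError(f"semantic scorer failed on ({a!r}, {b!r}): {exc}") from exc


# ---------------------------------------------------------------------------
# Feature assembly


@dataclass(frozen=True)
class TailFeatureVector:
    semantic: float
    transr_cos: float
    jaccard: float
    embedding_missing: bool = False

    def as_row(self) -> tuple[float, float, float]:
        return (self.semantic, self.transr_cos, self.jaccard)

    NAMES = ("semantic", "transr_cos", "jaccard")


@dataclass(frozen=True)
class HeadFeatureVector:
    same_tails: int
    set_jaccard: float
    transr_cos: float
    embedding_missing: bool = False

    def as_row(self) -> tuple[float, float, float]:
        return (float(self.same_tails), self.set_jaccard, self.transr_cos)

    NAMES = ("same_tails", "set_jaccard", "transr_cos")


def _safe_cos(embedding, a: str, b: str) -> tuple[float, bool]:
    # entities absent from the embedding vocabulary get a neutral cosine
    if embedding is None or not embedding.has(a) or not embedding.has(b):
        return 0.0, True
    return embedding.cosine(a, b), False


def tail_features(
    left_surface: str,
    right_surface: str,
    left_id: str,
    right_id: str,
    embedding=None,
    scorer: SemanticScorer | None = None,
) -> TailFeatureVector:
    cos, missing = _safe_cos(embedding, left_id, right_id)
    return TailFeatureVector(
        semantic=semantic_score(left_surface, right_surface, scorer),
        transr_cos=cos,
        jaccard=jaccard_chars(left_surface, right_surface),
        embedding_missing=missing,
    )


def head_features(
    h1: str,
    h2: str,
    kg1: KnowledgeGraph,
    kg2: KnowledgeGraph,
    merges: MergeMap,
    embedding=None,
) -> HeadFeatureVector:
    tails1 = [kg1.entity(t).surface for t in kg1.tails_of(h1, relational_only=True)]
    tails2 = [kg2.entity(t).surface for t in kg2.tails_of(h2, relational_only=True)]
    cos, missing = _safe_cos(embedding, h1, h2)
    return HeadFeatureVector(
        same_tails=same_tail_count(h1, h2, kg1, kg2, merges),
        set_jaccard=jaccard_sets(tails1, tails2),
        transr_cos=cos,
        embedding_missing=missing,
    )


def write_feature_tsv(path, rows: Iterable[tuple]) -> None:
    """Audit dump: ``left_id  right_id  f1  f2  f3  [label]`` per row."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
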