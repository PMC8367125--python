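"""Head-entity (disease) fusion: attribute alignment, then structural model.

Diseases are aligned across the two sources in two stages, in this order:

1. **Attribute alignment** — two diseases are the same concept if any of
   their normalized name values coincide: primary surface (recorded with
   provenance ``exact``), alternative name, or English name (compared
   case-insensitively; provenance ``attribute``).  A value naming two
   distinct diseases *within* one source is a conflict: the value is
   skipped and logged rather than guessed about.

2. **Structural model** — the remaining unmatched disease pairs are scored
   by a pair classifier on structural features (shared canonical tail
   count, pooled-character Jaccard of the tail surface sets, embedding
   cosine) and merged by greedy one-to-one matching, exactly as in tail
   fusion.  Tail fusion must run first: the shared-tail count is computed
   over canonical (post-tail-fusion) ids.

Attribute merges are never overturned by the structural stage — diseases
already matched in stage 1 are excluded from stage 2's candidate set.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .features import head_features
from .graph import KnowledgeGraph, MergeBuilder, MergeMap, apply_merge, union_graphs
from .schema import ATTRIBUTE_LABELS, EntityType
from .tail_fusion import (
    FusionMetrics,
    PairClassifier,
    alignment_metrics,
    greedy_one_to_one,
)

logger = logging.getLogger(__name__)

_NAME_ATTRS = ("Diseases_attr_Alternative name", "Diseases_attr_English name")


def _name_values(kg: KnowledgeGraph, disease_id: str) -> set[str]:
    """Primary surface plus alternative/English name values, normalized."""
    vals = {kg.entity(disease_id).surface}
    attrs = kg.attribute_values(disease_id, _NAME_ATTRS)
    for lst in attrs.values():
        vals.update(lst)
    # English names were case-folded at load; fold everything else too so a
    # surface-vs-English-name match is case-insensitive as well
    return {v.casefold() for v in vals}


def _value_index(kg: KnowledgeGraph, source_name: str) -> dict[str, str]:
    """value -> unique disease id; conflicting values are dropped with a log line."""
    index: dict[str, str] = {}
    conflicts: set[str] = set()
    for d in kg.entities_of_type(EntityType.DISEASE):
        for v in sorted(_name_values(kg, d.id)):
            if v in index and index[v] != d.id:
                conflicts.add(v)
            else:
                index.setdefault(v, d.id)
    for v in conflicts:
        logger.warning(
            "attribute value %r names multiple diseases in source %s; skipped",
            v, source_name,
        )
        index.pop(v, None)
    return index


def align_by_attribute(kg_a: KnowledgeGraph, kg_b: KnowledgeGraph) -> MergeMap:
    """Merge disease pairs sharing any normalized name value across sources.

    Pairs whose *primary surfaces* match get provenance ``exact``; pairs
    matched through an alternative or English name get ``attribute``.
    """
    idx_a = _value_index(kg_a, "A")
    idx_b = _value_index(kg_b, "B")
    ents = dict(kg_a.entities)
    ents.update(kg_b.entities)
    builder = MergeBuilder(ents)
    for v in sorted(set(idx_a) & set(idx_b)):
        da, db = idx_a[v], idx_b[v]
        exact = (
            kg_a.entity(da).surface.casefold() == v
            and kg_b.entity(db).surface.casefold() == v
        )
        builder.union(da, db, "exact" if exact else "attribute")
    return builder.build()


def fuse_heads(
    kg_a: KnowledgeGraph,
    kg_b: KnowledgeGraph,
    tail_merges: MergeMap,
    embedding,
    classifier: PairClassifier,
    threshold: float | None = None,
    attr_merges: MergeMap | None = None,
    reference_pairs: set[frozenset[str]] | None = None,
) -> tuple[MergeMap, FusionMetrics | None, list[tuple[str, str, float]]]:
    """Structural head fusion on top of attribute alignment.

    Returns the combined closed merge map (attribute + structural stages),
    metrics against ``reference_pairs`` when supplied, and the structurally
    matched scored pairs.
    """
    threshold = classifier.config.decision_threshold if threshold is None else threshold
    if attr_merges is None:
        attr_merges = align_by_attribute(kg_a, kg_b)

    already: set[str] = {
        eid for eid, canon in attr_merges.mapping.items()
    }
    cands = [
        (da, db)
        for da in kg_a.entities_of_type(EntityType.DISEASE)
        for db in kg_b.entities_of_type(EntityType.DISEASE)
        if da.id not in already and db.id not in already
    ]
    scored: list[tuple[str, str, float]] = []
    if cands:
        X = np.array(
            [
                head_features(da.id, db.id, kg_a, kg_b, tail_merges, embedding).as_row()
                for da, db in cands
            ]
        )
        probs = classifier.predict_proba(X)
        scored = [(da.id, db.id, float(p)) for (da, db), p in zip(cands, probs)]
    matched = greedy_one_to_one(scored, threshold)

    ents = dict(kg_a.entities)
    ents.update(kg_b.entities)
    builder = MergeBuilder(ents)
    for eid, canon in attr_merges.mapping.items():
        if eid != canon:
            builder.union(eid, canon, attr_merges.provenance.get(eid, "attribute"))
    for left, right, _ in matched:
        builder.union(left, right, "head_model")
    merges = builder.build()

    metrics = None
    if reference_pairs is not None:
        predicted = {
            frozenset((l, r)) for l, r, _ in matched
        } | attr_merges.merged_pairs()
        metrics = alignment_metrics(predicted, reference_pairs)
    return merges, metrics, matched


def labeled_head_pairs(
    benchmark,
    tail_merges: MergeMap,
    embedding=None,
) -> list[tuple]:
    """Featurize a benchmark's labeled head alignment pairs for training."""
    return [
        (
            head_features(
                p.left_id, p.right_id,
                benchmark.view_emr, benchmark.view_web,
                tail_merges, embedding,
            ),
            p.label,
        )
        for p in benchmark.head_alignments
    ]


def fusion_report(
    benchmark,
    merges: MergeMap,
    tail_metrics: FusionMetrics | None = None,
    head_metrics: FusionMetrics | None = None,
) -> dict:
    """Per-relation triple counts before/after fusion plus alignment scores.

    "Before" counts the disjoint union of the two views; "after" counts the
    graph with every endpoint rewritten to its canonical id and duplicates
    collapsed.  Alignment precision/recall/F1 are measured against the
    benchmark's ground-truth positive pairs, per fusion stage.
    """
    union = union_graphs(benchmark.view_emr, benchmark.view_web)
    fused = apply_merge(union, merges)
    before, after = union.relation_counts(), fused.relation_counts()
    labels = sorted(set(before) | set(after))
    report: dict = {
        "relation_counts": {
            lab: {"before": before.get(lab, 0), "after": after.get(lab, 0)}
            for lab in labels
        },
        "n_entities": {"before": union.n_entities(), "after": fused.n_entities()},
        "n_triples": {"before": union.n_triples(), "after": fused.n_triples()},
        "n_merged_entities": merges.n_merged(),
        "merges_by_stage": _stage_counts(merges),
    }
    predicted = merges.merged_pairs()
    for which in ("tail", "head"):
        truth = benchmark.positive_pairs(which)
        m = alignment_metrics(
            {p for p in predicted if _pair_is_type(benchmark, p, which)}, truth
        )
        report[f"{which}_alignment"] = m.as_dict()
    if tail_metrics is not None:
        report["tail_classifier_heldout"] = tail_metrics.as_dict()
    if head_metrics is not None:
        report["head_classifier_heldout"] = head_metrics.as_dict()
    return report


def _stage_counts(merges: MergeMap) -> dict[str, int]:
    counts: dict[str, int] = {}
    for eid, stage in merges.provenance.items():
        counts[stage] = counts.get(stage, 0) + 1
    return counts


def _pair_is_type(benchmark, pair: frozenset[str], which: str) -> bool:
    ids = list(pair)
    ents = dict(benchmark.view_emr.entities)
    ents.update(benchmark.view_web.entities)
    types = {ents[i].etype for i in ids if i in ents}
    if which == "head":
        return types == {EntityType.DISEASE}
    return types <= {EntityType.SYMPTOM, EntityType.EXAMINATION} and len(ids) == 2
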