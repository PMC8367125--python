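"""Shared fixtures: small hand-built graphs and the standard benchmark.

Expensive artifacts (the default benchmark, a trained embedding) are
session-scoped so the suite trains each model once.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

import kgfuse as k
from kgfuse.schema import EntityType, RelationType

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def build_kg(rows):
    """Construct a graph from (head_surface, head_type, relation, tail_surface,
    tail_type, source) tuples."""
    kg = k.KnowledgeGraph()
    for hs, ht, rel, ts, tt, src in rows:
        h = kg.add_entity(hs, EntityType.parse(ht), src)
        t = kg.add_entity(ts, EntityType.parse(tt), src)
        kg.add_triple(h, RelationType.parse(rel), t, [src])
    return kg


@pytest.fixture
def tiny_kg():
    """Two diseases sharing a symptom, one examination — single source."""
    return build_kg(
        [
            ("垂体泌乳素腺瘤", "disease", "Diseases_rel_Symptom", "头痛", "symptom", "emr"),
            ("垂体无功能腺瘤", "disease", "Diseases_rel_Symptom", "头痛", "symptom", "emr"),
            ("垂体泌乳素腺瘤", "disease", "Diseases_rel_Examination", "磁共振", "examination", "emr"),
        ]
    )


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (seed 42, 50 diseases)."""
    return k.default_benchmark()


@pytest.fixture(scope="session")
def union_kg(benchmark):
    return k.union_graphs(benchmark.view_emr, benchmark.view_web)


@pytest.fixture(scope="session")
def transr_embedding(benchmark, union_kg):
    """One TransR model trained on the benchmark union graph, reused suite-wide."""
    return k.train(union_kg, k.EmbeddingConfig(model="transR", dim=50, epochs=200, seed=0))


@pytest.fixture(scope="session")
def tail_classifier(benchmark, transr_embedding):
    pairs = k.tail_fusion.labeled_tail_pairs(benchmark, transr_embedding)
    clf, metrics = k.train_classifier(pairs, k.PairClassifierConfig(model="mlp", seed=0))
    return clf, metrics


@pytest.fixture(scope="session")
def tail_merge_result(benchmark, transr_embedding, tail_classifier):
    clf, _ = tail_classifier
    return k.fuse_tails(
        benchmark.view_emr,
        benchmark.view_web,
        clf,
        embedding=transr_embedding,
        reference_pairs=benchmark.positive_pairs("tail"),
    )
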