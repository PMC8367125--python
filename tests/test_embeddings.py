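"""Translational embeddings: scoring, training, ranking evaluation."""

import numpy as np
import pytest

import kgfuse as k
from conftest import build_kg
from kgfuse.embeddings import EmbeddingConfig, KGEmbedding, hits_at_k, train


def make_embedding(model, rng, entity_ids, entity_types, relations, dim):
    n_e, n_r = len(entity_ids), len(relations)
    E = rng.normal(size=(n_e, dim))
    R = rng.normal(size=(n_r, dim))
    if model == "transH":
        P = rng.normal(size=(n_r, dim))
        P /= np.linalg.norm(P, axis=1, keepdims=True)
    elif model == "transR":
        P = rng.normal(size=(n_r, dim, dim))
    else:
        P = np.repeat(np.eye(dim)[None], n_r, axis=0)
    cfg = EmbeddingConfig(model=model, dim=dim, epochs=0)
    return KGEmbedding(cfg, entity_ids, entity_types, relations, E, R, P)


def naive_score(emb, h, r, t):
    """Reference reimplementation with explicit loops."""
    hv = emb.vector(h).tolist()
    tv = emb.vector(t).tolist()
    rv = emb.relation_vector(r).tolist()
    r_i = emb.relation_labels.index(r)
    dim = len(hv)

    def project(x):
        if emb.config.model == "transE":
            return list(x)
        if emb.config.model == "transH":
            w = emb.P[r_i].tolist()
            dot = sum(w[i] * x[i] for i in range(dim))
            return [x[i] - dot * w[i] for i in range(dim)]
        M = emb.P[r_i].tolist()
        return [sum(M[i][j] * x[j] for j in range(dim)) for i in range(dim)]

    hp, tp = project(hv), project(tv)
    return sum((hp[i] + rv[i] - tp[i]) ** 2 for i in range(dim)) ** 0.5


@pytest.mark.parametrize("model", ["transE", "transH", "transR"])
def test_score_matches_naive_loops(model):
    rng = np.random.default_rng(17)
    ents = [f"e{i}" for i in range(6)]
    types = ["disease"] * 3 + ["symptom"] * 3
    rels = ["Diseases_rel_Symptom", "Diseases_rel_Examination"]
    for _ in range(35):
        emb = make_embedding(model, rng, ents, types, rels, dim=5)
        h, t = ents[int(rng.integers(6))], ents[int(rng.integers(6))]
        r = rels[int(rng.integers(2))]
        assert emb.score_triple(h, r, t) == pytest.approx(
            naive_score(emb, h, r, t), abs=1e-10
        )


def test_perfect_translation_scores_zero():
    rng = np.random.default_rng(0)
    emb = make_embedding("transR", rng, ["a", "b"], ["disease", "disease"], ["r"], dim=3)
    emb.P[0] = np.eye(3)
    emb.E[1] = emb.E[0]
    emb.R[0] = np.zeros(3)
    assert emb.score_triple("a", "r", "b") == 0.0


def test_transe_exact_arithmetic():
    emb = make_embedding("transE", np.random.default_rng(0), ["h", "t"],
                         ["disease", "symptom"], ["r"], dim=2)
    emb.E[0] = [1.0, 0.0]
    emb.E[1] = [1.0, 1.0]
    emb.R[0] = [0.0, 1.0]
    assert emb.score_triple("h", "r", "t") == 0.0


def test_transr_with_identity_projection_equals_transe():
    rng = np.random.default_rng(23)
    ents = [f"e{i}" for i in range(5)]
    types = ["symptom"] * 5
    r = ["Diseases_rel_Symptom"]
    e_t = make_embedding("transE", np.random.default_rng(1), ents, types, r, dim=4)
    e_r = make_embedding("transR", np.random.default_rng(1), ents, types, r, dim=4)
    e_r.E, e_r.R = e_t.E.copy(), e_t.R.copy()
    e_r.P = np.repeat(np.eye(4)[None], 1, axis=0)
    for a in ents:
        for b in ents:
            assert e_r.score_triple(a, r[0], b) == pytest.approx(
                e_t.score_triple(a, r[0], b), abs=1e-12
            )


def test_cosine_basic_properties():
    rng = np.random.default_rng(3)
    emb = make_embedding("transE", rng, ["a", "b", "z"], ["symptom"] * 3, ["r"], dim=2)
    emb.E[0] = [1.0, 0.0]
    emb.E[1] = [0.0, 1.0]
    emb.E[2] = [0.0, 0.0]
    assert emb.cosine("a", "a") == pytest.approx(1.0)
    assert emb.cosine("a", "b") == pytest.approx(0.0)
    with pytest.raises(ValueError):
        emb.cosine("a", "z")
    with pytest.raises(KeyError):
        emb.cosine("a", "missing")


# ---------------------------------------------------------------------------
# Training


def test_zero_epochs_returns_seeded_initialization():
    kg = build_kg([("D疾", "disease", "Diseases_rel_Symptom", "S症", "symptom", "emr")])
    cfg = EmbeddingConfig(model="transE", dim=8, epochs=0, seed=5)
    e1, e2 = train(kg, cfg), train(kg, cfg)
    assert np.array_equal(e1.E, e2.E) and np.array_equal(e1.R, e2.R)
    bound = 6.0 / np.sqrt(8)
    assert np.all(np.abs(e1.E) <= bound)


def test_training_is_bit_reproducible():
    kg = build_kg(
        [("D疾", "disease", "Diseases_rel_Symptom", f"S{i}症", "symptom", "emr")
         for i in range(6)]
    )
    cfg = EmbeddingConfig(model="transR", dim=6, epochs=30, seed=2)
    e1, e2 = train(kg, cfg), train(kg, cfg)
    assert np.array_equal(e1.E, e2.E)
    assert np.array_equal(e1.P, e2.P)
    assert e1.loss_history == e2.loss_history


def test_single_triple_becomes_separable():
    kg = build_kg([("D疾", "disease", "Diseases_rel_Symptom", "S症", "symptom", "emr")])
    with pytest.warns(UserWarning, match="falling back"):
        emb = train(kg, EmbeddingConfig(model="transE", dim=8, epochs=200, seed=0))
    ids = {e.surface: e.id for e in kg.entities.values()}
    pos = emb.score_triple(ids["D疾"], "Diseases_rel_Symptom", ids["S症"])
    # the only possible corrupted head is the tail entity itself
    neg = emb.score_triple(ids["S症"], "Diseases_rel_Symptom", ids["S症"])
    assert pos < neg


def test_entity_norms_bounded_after_training(transr_embedding):
    norms = np.linalg.norm(transr_embedding.E, axis=1)
    assert np.all(norms <= 1.0 + 1e-9)


def test_loss_mostly_non_increasing(transr_embedding):
    loss = transr_embedding.loss_history
    drops = sum(1 for a, b in zip(loss, loss[1:]) if b <= a + 1e-9)
    assert drops / (len(loss) - 1) >= 0.90


def _chain_kg(n_pairs=10):
    rows = []
    for i in range(n_pairs):
        rows.append((f"D{i}疾", "disease", "Diseases_rel_Symptom", f"S{i}症", "symptom", "emr"))
        if i + 1 < n_pairs:
            rows.append((f"D{i+1}疾", "disease", "Diseases_rel_Symptom", f"S{i}症", "symptom", "emr"))
    return build_kg(rows)


def test_chain_graph_positives_beat_corrupted():
    """On a 20-entity disease–symptom chain, the mean score of true links is
    below the mean score of randomly corrupted links in nearly every run."""
    wins, runs = 0, 100
    for seed in range(runs):
        kg = _chain_kg(10)
        trs = list(kg.triples())
        rng = np.random.default_rng(seed)
        emb = train(kg, EmbeddingConfig(model="transE", dim=8, epochs=120, seed=seed))
        pos = np.mean(
            [emb.score_triple(t.head_id, t.relation.label, t.tail_id) for t in trs]
        )
        symptoms = [e.id for e in kg.entities_of_type(k.EntityType.SYMPTOM)]
        negs = []
        for t in trs:
            others = [s for s in symptoms if s != t.tail_id]
            negs.append(
                emb.score_triple(
                    t.head_id, t.relation.label, others[int(rng.integers(len(others)))]
                )
            )
        wins += pos < np.mean(negs)
    assert wins >= 95, wins


def test_duplicated_entity_has_high_cosine():
    """An entity duplicated with identical neighborhoods embeds nearby."""
    wins, runs = 0, 50
    for seed in range(runs):
        b = k.generate(k.GeneratorConfig(seed=seed, n_diseases=8))
        kg = b.truth.copy()
        symptoms = kg.entities_of_type(k.EntityType.SYMPTOM)
        rng = np.random.default_rng(seed)
        orig = symptoms[int(rng.integers(len(symptoms)))]
        dup = kg.add_entity(orig.surface + "复", k.EntityType.SYMPTOM, "truth")
        for tr in list(kg.triples()):
            if tr.tail_id == orig.id:
                kg.add_triple(kg.entity(tr.head_id), tr.relation, dup, tr.sources)
            if tr.head_id == orig.id:
                kg.add_triple(dup, tr.relation, kg.entity(tr.tail_id), tr.sources)
        emb = train(kg, EmbeddingConfig(model="transR", dim=16, epochs=150, seed=seed))
        dup_cos = emb.cosine(orig.id, dup.id)
        others = [e.id for e in kg.entities_of_type(k.EntityType.SYMPTOM)
                  if e.id not in (orig.id, dup.id)]
        rand_cos = sorted(
            emb.cosine(orig.id, o) for o in others
        )
        median = rand_cos[len(rand_cos) // 2]
        wins += dup_cos > median
    assert wins >= 45, wins  # >= 90% of runs


# ---------------------------------------------------------------------------
# hits@k


def test_hits_at_k_validation_and_saturation():
    rng = np.random.default_rng(0)
    kg = build_kg(
        [("D疾", "disease", "Diseases_rel_Symptom", f"S{i}症", "symptom", "emr")
         for i in range(4)]
    )
    emb = train(kg, EmbeddingConfig(model="transE", dim=4, epochs=0, seed=0))
    trs = list(kg.triples())
    with pytest.raises(ValueError):
        hits_at_k(emb, trs, 0)
    assert hits_at_k(emb, trs, 100) == 1.0  # k >= n candidates


def test_hits_at_k_non_decreasing_in_k(transr_embedding, union_kg):
    trs = list(union_kg.triples())[:80]
    values = [hits_at_k(transr_embedding, trs, kk) for kk in (1, 3, 10, 30, 100)]
    assert values == sorted(values)


def test_untrained_hits_matches_uniform_expectation():
    """With random vectors the true tail's rank is uniform: hits@k ≈ k/n."""
    n_sym, kk, trials = 40, 5, 200
    hits = []
    for seed in range(trials):
        rng = np.random.default_rng(seed)
        ents = [f"s{i:02d}" for i in range(n_sym)] + ["d"]
        types = ["symptom"] * n_sym + ["disease"]
        emb = make_embedding("transE", rng, ents, types, ["Diseases_rel_Symptom"], dim=8)
        tail = ents[int(rng.integers(n_sym))]

        class _T:
            head_id = "d"
            tail_id = tail
            relation = k.RELATIONS["Diseases_rel_Symptom"]

        hits.append(hits_at_k(emb, [_T()], kk))
    p = kk / n_sym
    sigma = np.sqrt(p * (1 - p) / trials)
    assert abs(np.mean(hits) - p) < 3 * sigma


# ---------------------------------------------------------------------------
# Persistence


def test_save_load_round_trip(tmp_path, transr_embedding):
    transr_embedding.save(tmp_path / "emb")
    loaded = KGEmbedding.load(tmp_path / "emb")
    assert loaded.entity_ids == transr_embedding.entity_ids
    assert np.array_equal(loaded.E, transr_embedding.E)
    assert np.array_equal(loaded.P, transr_embedding.P)
    h = transr_embedding.entity_ids[0]
    r = transr_embedding.relation_labels[0]
    t = transr_embedding.entity_ids[-1]
    assert loaded.score_triple(h, r, t) == transr_embedding.score_triple(h, r, t)
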