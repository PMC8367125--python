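"""Graph container: loading, merging, ICD mapping and both export formats."""

import numpy as np
import pytest

import kgfuse as k
from conftest import build_kg
from kgfuse.graph import MergeBuilder
from kgfuse.schema import RELATIONS, EntityType, SchemaError

# a character pool that exercises quoting/escaping in both export formats
_POOL = list("abcxyz头痛瘤腺体泌乳素磁共振") + [",", '"', "'"]


def random_kg(rng: np.random.Generator) -> k.KnowledgeGraph:
    """Small random schema-valid graph over awkward surface forms."""

    def surf(lo=2, hi=6):
        n = int(rng.integers(lo, hi + 1))
        s = "".join(_POOL[int(i)] for i in rng.integers(0, len(_POOL), size=n))
        return s if s.strip(" ,\"'") else s + "x"

    kg = k.KnowledgeGraph()
    rels = list(RELATIONS.values())
    sources = ["emr", "web"]
    for _ in range(int(rng.integers(3, 15))):
        rel = rels[int(rng.integers(len(rels)))]
        src = sources[int(rng.integers(2))]
        h = kg.add_entity(surf(), rel.head_type, src)
        t = kg.add_entity(surf(), rel.tail_type, src)
        kg.add_triple(h, rel, t, [src])
    return kg


# ---------------------------------------------------------------------------
# Loading


def test_load_minimal_tsv(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text(
        "head_surface\thead_type\trelation\ttail_surface\ttail_type\tsource\n"
        "垂体泌乳素腺瘤\tdisease\tDiseases_rel_Symptom\t头痛\tsymptom\temr\n",
        encoding="utf-8",
    )
    kg = k.load_triples(p)
    assert kg.n_entities() == 2
    assert kg.n_triples() == 1


def test_duplicate_rows_collapse(tmp_path):
    row = "垂体泌乳素腺瘤\tdisease\tDiseases_rel_Symptom\t头痛\tsymptom\temr\n"
    p = tmp_path / "t.tsv"
    p.write_text(
        "head_surface\thead_type\trelation\ttail_surface\ttail_type\tsource\n" + row + row,
        encoding="utf-8",
    )
    assert k.load_triples(p).n_triples() == 1


def test_type_mismatch_is_schema_error_naming_the_line(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text(
        "head_surface\thead_type\trelation\ttail_surface\ttail_type\tsource\n"
        "垂体泌乳素腺瘤\tdisease\tDiseases_rel_Symptom\t青霉素\tmedicine\temr\n",
        encoding="utf-8",
    )
    with pytest.raises(SchemaError, match=":2"):
        k.load_triples(p)


def test_unknown_relation_rejected(tmp_path):
    p = tmp_path / "t.jsonl"
    p.write_text(
        '{"head_surface": "x", "head_type": "disease", "relation": "Nope",'
        ' "tail_surface": "y", "tail_type": "symptom", "source": "emr"}\n',
        encoding="utf-8",
    )
    with pytest.raises(SchemaError, match="Nope"):
        k.load_triples(p, dialect="jsonl")


def test_intra_source_dedup_on_normalized_surface(tmp_path):
    # NFKC + whitespace collapse makes these two rows the same tail entity
    p = tmp_path / "t.tsv"
    p.write_text(
        "head_surface\thead_type\trelation\ttail_surface\ttail_type\tsource\n"
        "x\tdisease\tDiseases_attr_English name\tGH  adenoma\tenglish_name\tweb\n"
        "x\tdisease\tDiseases_attr_English name\tgh adenoma \tenglish_name\tweb\n",
        encoding="utf-8",
    )
    kg = k.load_triples(p)
    assert kg.n_entities() == 2  # one disease + one english name
    assert kg.n_triples() == 1


def test_tsv_jsonl_round_trip_equivalence(tmp_path, tiny_kg):
    for dialect in ("tsv", "jsonl"):
        p = tmp_path / f"t.{dialect}"
        k.save_triples(tiny_kg, p, dialect=dialect)
        assert k.load_triples(p, dialect=dialect).signature() == tiny_kg.signature()


# ---------------------------------------------------------------------------
# Merging


def _merge_map(kg, pairs, stage="tail_model"):
    b = MergeBuilder(dict(kg.entities))
    for a, bb in pairs:
        b.union(a, bb, stage)
    return b.build()


def test_apply_merge_full_collapse():
    kg = build_kg(
        [
            ("D1疾病", "disease", "Diseases_rel_Symptom", "S1症", "symptom", "emr"),
            ("D2疾病", "disease", "Diseases_rel_Symptom", "S2症", "symptom", "web"),
        ]
    )
    ids = {e.surface: e.id for e in kg.entities.values()}
    mm = _merge_map(kg, [(ids["S1症"], ids["S2症"]), (ids["D1疾病"], ids["D2疾病"])])
    fused = k.apply_merge(kg, mm)
    assert fused.n_triples() == 1
    assert fused.n_entities() == 2


def test_apply_merge_identity_and_idempotence(tiny_kg):
    empty = k.MergeMap()
    assert k.apply_merge(tiny_kg, empty).signature() == tiny_kg.signature()
    kg = build_kg(
        [
            ("D1疾病", "disease", "Diseases_rel_Symptom", "S1症", "symptom", "emr"),
            ("D1疾病", "disease", "Diseases_rel_Symptom", "S2症", "symptom", "emr"),
        ]
    )
    ids = {e.surface: e.id for e in kg.entities.values()}
    mm = _merge_map(kg, [(ids["S1症"], ids["S2症"])])
    once = k.apply_merge(kg, mm)
    twice = k.apply_merge(once, mm)
    assert once.signature() == twice.signature()


def test_merge_never_increases_triple_count():
    rng = np.random.default_rng(7)
    for _ in range(20):
        kg = random_kg(rng)
        ents = list(kg.entities.values())
        b = MergeBuilder(dict(kg.entities))
        for e in ents:
            others = [o for o in ents if o.etype is e.etype and o.id != e.id]
            if others and rng.random() < 0.5:
                b.union(e.id, others[int(rng.integers(len(others)))].id, "tail_model")
        fused = k.apply_merge(kg, b.build())
        assert fused.n_triples() <= kg.n_triples()


def test_merge_rejects_mixed_types(tiny_kg):
    ids = {e.surface: e.id for e in tiny_kg.entities.values()}
    b = MergeBuilder(dict(tiny_kg.entities))
    with pytest.raises(k.MergeError):
        b.union(ids["头痛"], ids["磁共振"], "tail_model")


def test_canonical_surface_prefers_web_source():
    kg = build_kg(
        [
            ("D", "disease", "Diseases_rel_Symptom", "头疼", "symptom", "emr"),
            ("D", "disease", "Diseases_rel_Symptom", "头痛", "symptom", "web"),
        ]
    )
    ids = {(e.surface, e.source): e.id for e in kg.entities.values()}
    mm = _merge_map(kg, [(ids[("头疼", "emr")], ids[("头痛", "web")])])
    canon = mm.resolve(ids[("头疼", "emr")])
    assert kg.entity(canon).source == "web"


# ---------------------------------------------------------------------------
# Exports


def test_neo4j_export_counts(tmp_path, tiny_kg):
    paths = k.export_neo4j_csv(tiny_kg, tmp_path)
    nodes = paths["nodes"].read_text(encoding="utf-8").strip().splitlines()
    rels = paths["relationships"].read_text(encoding="utf-8").strip().splitlines()
    assert len(nodes) == 1 + tiny_kg.n_entities()
    assert len(rels) == 1 + tiny_kg.n_triples()
    assert nodes[0].startswith("id:ID,label:LABEL,surface")


def test_neo4j_round_trip_with_commas(tmp_path):
    kg = build_kg(
        [("肿瘤, 垂体", "disease", "Diseases_rel_Symptom", '头"痛', "symptom", "emr")]
    )
    k.export_neo4j_csv(kg, tmp_path)
    assert k.import_neo4j_csv(tmp_path).signature() == kg.signature()


def test_ntriples_single_line_and_empty(tmp_path, tiny_kg):
    p = k.export_ntriples(tiny_kg, tmp_path / "g.nt")
    assert len(p.read_text(encoding="utf-8").strip().splitlines()) == tiny_kg.n_triples()
    empty = k.KnowledgeGraph()
    p2 = k.export_ntriples(empty, tmp_path / "e.nt")
    assert p2.read_text(encoding="utf-8") == ""


def test_ntriples_validates_with_independent_parser(tmp_path):
    import rdflib

    kg = build_kg(
        [
            ("垂体泌乳素腺瘤", "disease", "Diseases_rel_Symptom", "头痛", "symptom", "emr"),
            ("垂体泌乳素腺瘤", "disease", "Diseases_attr_Pathogeny", '泌乳素"过高', "pathogeny", "web"),
        ]
    )
    p = k.export_ntriples(kg, tmp_path / "g.nt")
    g = rdflib.Graph()
    g.parse(str(p), format="nt")  # hand-written serialization, independent parser
    assert len(g) == 2
    literals = [o for _, _, o in g if isinstance(o, rdflib.Literal)]
    assert [str(o) for o in literals] == ['泌乳素"过高']


def test_export_round_trips_on_random_graphs(tmp_path):
    rng = np.random.default_rng(11)
    for i in range(10):
        kg = random_kg(rng)
        d = tmp_path / f"csv{i}"
        k.export_neo4j_csv(kg, d)
        assert k.import_neo4j_csv(d).signature() == kg.signature()
        p = tmp_path / f"g{i}.nt"
        k.export_ntriples(kg, p)
        assert k.import_ntriples(p).signature() == kg.signature()


# ---------------------------------------------------------------------------
# ICD mapping


def test_map_icd_lookup_and_unmapped(tiny_kg):
    out = k.map_icd(tiny_kg, {"垂体泌乳素腺瘤": "D35.2"})
    codes = {out.entity(i).surface: c for i, c in out.icd_codes.items()}
    assert codes["垂体泌乳素腺瘤"] == "D35.2"
    assert codes["垂体无功能腺瘤"] == "unmapped"
    out2 = k.map_icd(tiny_kg, {})
    assert set(out2.icd_codes.values()) == {"unmapped"}


def test_icd_attached_to_canonical_after_alternative_name_merge():
    # web knows the disease under its canonical name plus the emr spelling as
    # an alternative name; after attribute fusion the ICD code lands on the
    # canonical entity
    kg_emr = build_kg(
        [("泌乳素瘤", "disease", "Diseases_rel_Symptom", "头痛", "symptom", "emr")]
    )
    kg_web = build_kg(
        [
            ("垂体泌乳素腺瘤", "disease", "Diseases_attr_Alternative name", "泌乳素瘤", "alternative_name", "web"),
        ]
    )
    mm = k.align_by_attribute(kg_emr, kg_web)
    union = k.union_graphs(kg_emr, kg_web)
    fused = k.apply_merge(union, mm)
    fused = k.map_icd(fused, {"垂体泌乳素腺瘤": "D35.2"})
    diseases = fused.entities_of_type(EntityType.DISEASE)
    assert len(diseases) == 1
    assert fused.icd_codes[diseases[0].id] == "D35.2"
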