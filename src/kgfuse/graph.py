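"""Typed knowledge-graph container, triple I/O, merge application and export.

The data model is the one used throughout disease-centred knowledge-graph
construction: typed entities (``disease``, ``symptom``, ...) carrying a
surface form and a source tag, connected by triples drawn from a closed
relation inventory (:mod:`kgfuse.schema`).  Entities are deduplicated
within a source on their normalized surface form; entity identifiers are
stable hashes of ``(source, etype, surface)`` so repeated runs produce
identical graphs.

Merging is expressed as a :class:`MergeMap` — an idempotent entity-id →
canonical-id mapping obtained by union-find closure over pairwise merge
decisions.  :func:`apply_merge` rewrites every triple endpoint to its
canonical id and collapses the duplicates this creates, so the triple
count never increases.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping
from urllib.parse import quote, unquote

from .schema import (
    EntityType,
    RelationType,
    SchemaError,
    validate_signature,
)

_WS = re.compile(r"\s+")

#: Base IRI under which entities and relations are minted for RDF export.
BASE_IRI = "http://kgfuse.example/"

TSV_COLUMNS = ("head_surface", "head_type", "relation", "tail_surface", "tail_type", "source")


def normalize_surface(surface: str, etype: EntityType) -> str:
    """Canonicalize a surface form.

    Unicode NFKC, surrounding whitespace stripped, internal whitespace
    collapsed to single spaces.  English-name attributes are additionally
    case-folded (CJK has no case; folding other types would be a no-op at
    best and lossy at worst).
    """
    s = unicodedata.normalize("NFKC", surface)
    s = _WS.sub(" ", s.strip())
    if etype is EntityType.ENGLISH_NAME:
        s = s.casefold()
    if not s:
        raise SchemaError(f"surface {surface!r} empty after normalization")
    return s


def entity_id(source: str, etype: EntityType, surface: str) -> str:
    """Stable content hash so graph construction is reproducible."""
    h = hashlib.sha1(f"{source}\x00{etype.value}\x00{surface}".encode("utf-8"))
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class Entity:
    id: str
    surface: str
    etype: EntityType
    source: str

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity up to internal id relabeling."""
        return (self.source, self.etype.value, self.surface)


@dataclass(frozen=True)
class Triple:
    head_id: str
    relation: RelationType
    tail_id: str
    sources: tuple[str, ...]  # sorted, distinct provenance tags

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.head_id, self.relation.label, self.tail_id)


class KnowledgeGraph:
    """Entities plus a set of schema-valid triples.

    Triples are unordered and unique per (head, relation, tail); provenance
    is kept as a sorted set of source tags on each triple rather than as
    duplicate edges.
    """

    def __init__(self) -> None:
        self._entities: dict[str, Entity] = {}
        self._triples: dict[tuple[str, str, str], tuple[str, ...]] = {}
        self.icd_codes: dict[str, str] = {}
        self._adj: dict[str, list[str]] | None = None  # relational adjacency cache

    # -- construction -------------------------------------------------

    def add_entity(self, surface: str, etype: EntityType, source: str) -> Entity:
        if not source:
            raise SchemaError("entity source tag must be non-empty")
        surface = normalize_surface(surface, etype)
        eid = entity_id(source, etype, surface)
        existing = self._entities.get(eid)
        if existing is None:
            existing = Entity(eid, surface, etype, source)
            self._entities[eid] = existing
        return existing

    def add_triple(
        self,
        head: Entity,
        relation: RelationType,
        tail: Entity,
        sources: Iterable[str],
    ) -> None:
        validate_signature(relation, head.etype, tail.etype)
        if head.id not in self._entities or tail.id not in self._entities:
            raise SchemaError("triple endpoints must be added to the graph first")
        key = (head.id, relation.label, tail.id)
        merged = set(self._triples.get(key, ())) | set(sources)
        if not merged:
            raise SchemaError("triple requires at least one source tag")
        self._triples[key] = tuple(sorted(merged))
        self._adj = None

    # -- access -------------------------------------------------------

    @property
    def entities(self) -> Mapping[str, Entity]:
        return self._entities

    def entity(self, eid: str) -> Entity:
        try:
            return self._entities[eid]
        except KeyError:
            raise KeyError(f"unknown entity id {eid!r}") from None

    def triples(self) -> Iterator[Triple]:
        for (h, rl, t), src in sorted(self._triples.items()):
            yield Triple(h, RelationType.parse(rl), t, src)

    def n_triples(self) -> int:
        return len(self._triples)

    def n_entities(self) -> int:
        return len(self._entities)

    def entities_of_type(self, etype: EntityType, source: str | None = None) -> list[Entity]:
        out = [e for e in self._entities.values() if e.etype is etype]
        if source is not None:
            out = [e for e in out if e.source == source]
        return sorted(out, key=lambda e: e.id)

    def tails_of(self, head_id: str, relational_only: bool = True) -> list[str]:
        """Tail entity ids adjacent to ``head_id``."""
        if head_id not in self._entities:
            raise KeyError(f"unknown entity id {head_id!r}")
        if relational_only:
            if self._adj is None:
                adj: dict[str, list[str]] = {}
                for (h, rl, t) in self._triples:
                    if not RelationType.parse(rl).is_attribute:
                        adj.setdefault(h, []).append(t)
                self._adj = {h: sorted(ts) for h, ts in adj.items()}
            return list(self._adj.get(head_id, []))
        return sorted(t for (h, _rl, t) in self._triples if h == head_id)

    def attribute_values(self, head_id: str, labels: Iterable[str]) -> dict[str, list[str]]:
        """Normalized attribute tail surfaces of ``head_id`` per relation label."""
        wanted = set(labels)
        out: dict[str, list[str]] = {lab: [] for lab in wanted}
        for (h, rl, t) in self._triples:
            if h == head_id and rl in wanted:
                out[rl].append(self._entities[t].surface)
        return out

    def relation_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for (_, rl, _) in self._triples:
            counts[rl] = counts.get(rl, 0) + 1
        return counts

    def signature(self) -> tuple[frozenset, frozenset]:
        """Graph identity up to internal id relabeling (for equality tests)."""
        ents = frozenset(e.key for e in self._entities.values())
        trs = frozenset(
            (self._entities[h].key, rl, self._entities[t].key, src)
            for (h, rl, t), src in self._triples.items()
        )
        return ents, trs

    def copy(self) -> "KnowledgeGraph":
        kg = KnowledgeGraph()
        kg._entities = dict(self._entities)
        kg._triples = dict(self._triples)
        kg.icd_codes = dict(self.icd_codes)
        return kg


# ---------------------------------------------------------------------------
# Merge maps


class MergeError(ValueError):
    """A merge decision violates a graph invariant (e.g. mixes entity types)."""


@dataclass
class MergeMap:
    """Closed entity → canonical-entity mapping with per-entity provenance.

    ``mapping`` is idempotent (``mapping[mapping[x]] == mapping[x]``) and
    canonical ids map to themselves.  ``provenance`` records, for each
    non-canonical entity, the fusion stage that merged it away:
    ``exact`` | ``attribute`` | ``tail_model`` | ``head_model``.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def resolve(self, eid: str) -> str:
        return self.mapping.get(eid, eid)

    def is_identity(self) -> bool:
        return all(k == v for k, v in self.mapping.items())

    def n_merged(self) -> int:
        return sum(1 for k, v in self.mapping.items() if k != v)

    def merged_pairs(self) -> set[frozenset[str]]:
        """All unordered pairs of distinct ids sharing a canonical id."""
        groups: dict[str, list[str]] = {}
        for k, v in self.mapping.items():
            groups.setdefault(v, []).append(k)
        pairs: set[frozenset[str]] = set()
        for v, members in groups.items():
            members = sorted(set(members) | {v})
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add(frozenset((a, b)))
        return pairs

    def validate(self) -> None:
        for k, v in self.mapping.items():
            if self.mapping.get(v, v) != v:
                raise MergeError(f"mapping not closed at {k!r} -> {v!r}")


class MergeBuilder:
    """Union-find accumulator producing a closed :class:`MergeMap`.

    Canonical representative per component is chosen deterministically:
    prefer the configured source (websites use curated terminology, so
    ``web`` by default), then the longer surface, then the smaller id.
    """

    STAGES = ("exact", "attribute", "tail_model", "head_model")

    def __init__(self, entities: Mapping[str, Entity], prefer_source: str = "web") -> None:
        self._entities = entities
        self._prefer = prefer_source
        self._parent: dict[str, str] = {}
        self._stage: dict[frozenset[str], str] = {}

    def _find(self, x: str) -> str:
        root = x
        while self._parent.get(root, root) != root:
            root = self._parent[root]
        while self._parent.get(x, x) != x:  # path compression
            self._parent[x], x = root, self._parent[x]
        return root

    def union(self, a: str, b: str, stage: str) -> None:
        if stage not in self.STAGES:
            raise ValueError(f"unknown merge stage {stage!r}")
        ea, eb = self._entities[a], self._entities[b]
        if ea.etype is not eb.etype:
            raise MergeError(
                f"cannot merge {ea.surface!r} ({ea.etype.value}) with "
                f"{eb.surface!r} ({eb.etype.value}): different entity types"
            )
        self._stage[frozenset((a, b))] = stage
        ra, rb = self._find(a), self._find(b)
        if ra != rb:
            self._parent[rb] = ra

    def _canon_key(self, eid: str) -> tuple:
        e = self._entities[eid]
        # min() picks: preferred source first, then longer surface, then smaller id
        return (e.source != self._prefer, -len(e.surface), e.id)

    def build(self) -> MergeMap:
        groups: dict[str, list[str]] = {}
        for x in self._parent:
            groups.setdefault(self._find(x), []).append(x)
        mapping: dict[str, str] = {}
        provenance: dict[str, str] = {}
        for root, members in groups.items():
            comp = sorted(set(members) | {root})
            canon = min(comp, key=self._canon_key)
            for m in comp:
                mapping[m] = canon
                if m != canon:
                    provenance[m] = self._member_stage(m, comp)
        mm = MergeMap(mapping, provenance)
        mm.validate()
        return mm

    def _member_stage(self, member: str, comp: list[str]) -> str:
        stages = [
            s for pair, s in self._stage.items() if member in pair and pair <= set(comp)
        ]
        # earliest pipeline stage wins for reporting
        for s in self.STAGES:
            if s in stages:
                return s
        return "exact"


def apply_merge(kg: KnowledgeGraph, merges: MergeMap) -> KnowledgeGraph:
    """Rewrite every triple endpoint to its canonical id and collapse duplicates.

    Non-merged entities are untouched; the triple count never increases.
    """
    merges.validate()
    for eid, canon in merges.mapping.items():
        if eid in kg.entities and canon in kg.entities:
            if kg.entities[eid].etype is not kg.entities[canon].etype:
                raise MergeError(f"merge {eid!r}->{canon!r} joins different entity types")
    out = KnowledgeGraph()
    dropped = {
        eid for eid, canon in merges.mapping.items() if eid != canon and eid in kg.entities
    }
    for eid, ent in kg.entities.items():
        if eid not in dropped:
            out._entities[eid] = ent
    for (h, rl, t), src in kg._triples.items():
        h2, t2 = merges.resolve(h), merges.resolve(t)
        key = (h2, rl, t2)
        merged = set(out._triples.get(key, ())) | set(src)
        out._triples[key] = tuple(sorted(merged))
    for eid, code in kg.icd_codes.items():
        out.icd_codes[merges.resolve(eid)] = code
    return out


def union_graphs(kg_a: KnowledgeGraph, kg_b: KnowledgeGraph) -> KnowledgeGraph:
    """Disjoint union of two graphs (entity ids are source-disjoint by
    construction, so no rewriting is needed)."""
    out = KnowledgeGraph()
    for kg in (kg_a, kg_b):
        out._entities.update(kg._entities)
        for key, src in kg._triples.items():
            merged = set(out._triples.get(key, ())) | set(src)
            out._triples[key] = tuple(sorted(merged))
        out.icd_codes.update(kg.icd_codes)
    return out


# ---------------------------------------------------------------------------
# Triple I/O


def _add_record(
    kg: KnowledgeGraph,
    head_surface: str,
    head_type: str,
    relation: str,
    tail_surface: str,
    tail_type: str,
    source: str,
    where: str,
) -> None:
    try:
        rel = RelationType.parse(relation)
        ht = EntityType.parse(head_type)
        tt = EntityType.parse(tail_type)
        validate_signature(rel, ht, tt)
        if not source.strip():
            raise SchemaError("empty source tag")
        head = kg.add_entity(head_surface, ht, source.strip())
        tail = kg.add_entity(tail_surface, tt, source.strip())
        kg.add_triple(head, rel, tail, [source.strip()])
    except SchemaError as exc:
        raise SchemaError(f"{where}: {exc}") from None


def load_triples(path: str | Path, dialect: str = "tsv") -> KnowledgeGraph:
    """Load a triple file into a schema-validated graph.

    ``dialect='tsv'``: six tab-separated columns with a header row
    (``head_surface head_type relation tail_surface tail_type source``).
    ``dialect='jsonl'``: one JSON object per line with the same keys.
    Entities are deduplicated within a source on (normalized surface, type);
    duplicate triples collapse.
    """
    path = Path(path)
    kg = KnowledgeGraph()
    if dialect == "tsv":
        with path.open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != TSV_COLUMNS:
                raise SchemaError(f"{path}:1: bad header {header!r}, expected {TSV_COLUMNS}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise SchemaError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
                _add_record(kg, *parts, where=f"{path}:{lineno}")
    elif dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                try:
                    parts = [obj[k] for k in TSV_COLUMNS]
                except KeyError as exc:
                    raise SchemaError(f"{path}:{lineno}: missing key {exc}") from None
                _add_record(kg, *parts, where=f"{path}:{lineno}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return kg


def save_triples(kg: KnowledgeGraph, path: str | Path, dialect: str = "tsv") -> None:
    """Inverse of :func:`load_triples`: one row per (triple, source tag)."""
    path = Path(path)
    rows = []
    for tr in kg.triples():
        h, t = kg.entity(tr.head_id), kg.entity(tr.tail_id)
        for src in tr.sources:
            rows.append(
                (h.surface, h.etype.value, tr.relation.label, t.surface, t.etype.value, src)
            )
    rows.sort()
    with path.open("w", encoding="utf-8") as fh:
        if dialect == "tsv":
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        elif dialect == "jsonl":
            for row in rows:
                fh.write(json.dumps(dict(zip(TSV_COLUMNS, row)), ensure_ascii=False) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Neo4j bulk-import CSV


def export_neo4j_csv(kg: KnowledgeGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write the graph as a Neo4j bulk-import CSV pair.

    ``nodes.csv``: ``id:ID,label:LABEL,surface,source,icd`` — the label is
    the entity type.  ``relationships.csv``:
    ``:START_ID,:END_ID,:TYPE,sources`` with provenance tags joined by
    ``|``.  Fields are quoted per RFC 4180, so commas inside surface forms
    round-trip.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / "nodes.csv"
    rels_path = out_dir / "relationships.csv"
    with nodes_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id:ID", "label:LABEL", "surface", "source", "icd"])
        for eid in sorted(kg.entities):
            e = kg.entities[eid]
            w.writerow([e.id, e.etype.value, e.surface, e.source, kg.icd_codes.get(eid, "")])
    with rels_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([":START_ID", ":END_ID", ":TYPE", "sources"])
        for tr in kg.triples():
            w.writerow([tr.head_id, tr.tail_id, tr.relation.label, "|".join(tr.sources)])
    return {"nodes": nodes_path, "relationships": rels_path}


def import_neo4j_csv(in_dir: str | Path) -> KnowledgeGraph:
    """Reload a graph from its bulk-import CSV pair (round-trip of export)."""
    in_dir = Path(in_dir)
    kg = KnowledgeGraph()
    by_csv_id: dict[str, Entity] = {}
    with (in_dir / "nodes.csv").open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            cid, label, surface, source, icd = row
            ent = kg.add_entity(surface, EntityType.parse(label), source)
            by_csv_id[cid] = ent
            if icd:
                kg.icd_codes[ent.id] = icd
    with (in_dir / "relationships.csv").open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for start, end, rtype, sources in reader:
            kg.add_triple(
                by_csv_id[start],
                RelationType.parse(rtype),
                by_csv_id[end],
                sources.split("|"),
            )
    return kg


# ---------------------------------------------------------------------------
# RDF N-Triples


def _entity_iri(e: Entity) -> str:
    return (
        f"{BASE_IRI}e/{quote(e.source, safe='')}/"
        f"{e.etype.value}/{quote(e.surface, safe='')}"
    )


def _predicate_iri(label: str, source: str) -> str:
    return f"{BASE_IRI}rel/{quote(label, safe='')}?src={quote(source, safe='')}"


def _escape_literal(s: str) -> str:
    return (
        s.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n").replace("\r", "\\r")
    )


def export_ntriples(kg: KnowledgeGraph, out: str | Path) -> Path:
    """Serialize the graph as N-Triples under a fixed base IRI scheme.

    Entity IRIs percent-encode (source, type, surface), so the graph is
    reconstructible from the serialization alone.  Attribute relations
    (disease attributes) are serialized with the tail surface as a plain
    literal; one statement is emitted per provenance tag, carried in the
    predicate IRI query string.
    """
    out = Path(out)
    lines = []
    for tr in kg.triples():
        h, t = kg.entity(tr.head_id), kg.entity(tr.tail_id)
        for src in tr.sources:
            pred = _predicate_iri(tr.relation.label, src)
            if tr.relation.is_attribute:
                obj = f'"{_escape_literal(t.surface)}"'
            else:
                obj = f"<{_entity_iri(t)}>"
            lines.append(f"<{_entity_iri(h)}> <{pred}> {obj} .")
    out.write_text("\n".join(sorted(lines)) + ("\n" if lines else ""), encoding="utf-8")
    return out


def import_ntriples(path: str | Path) -> KnowledgeGraph:
    """Parse an N-Triples export back into a graph (uses rdflib's parser).

    Attribute tails were serialized as literals, so their entity source is
    reconstructed from the statement's provenance tag — exact round-trip is
    guaranteed for graphs in which attribute tails share their triple's
    source, which holds for any freshly loaded or generated graph.
    """
    import rdflib

    g = rdflib.Graph()
    g.parse(str(path), format="nt")
    kg = KnowledgeGraph()

    def parse_entity_iri(iri: str) -> tuple[str, EntityType, str]:
        rest = iri[len(BASE_IRI) + 2:]
        source, etype, surface = rest.split("/", 2)
        return unquote(source), EntityType.parse(etype), unquote(surface)

    for s, p, o in g:
        s_src, s_t, s_surf = parse_entity_iri(str(s))
        pred = str(p)[len(BASE_IRI) + 4:]
        label, _, src = pred.partition("?src=")
        label, src = unquote(label), unquote(src)
        rel = RelationType.parse(label)
        head = kg.add_entity(s_surf, s_t, s_src)
        if isinstance(o, rdflib.Literal):
            tail = kg.add_entity(str(o), rel.tail_type, src)
        else:
            o_src, o_t, o_surf = parse_entity_iri(str(o))
            tail = kg.add_entity(o_surf, o_t, o_src)
        kg.add_triple(head, rel, tail, [src])
    return kg


# ---------------------------------------------------------------------------
# ICD mapping


def map_icd(kg: KnowledgeGraph, icd_table: Mapping[str, str]) -> KnowledgeGraph:
    """Annotate disease entities with ICD codes by canonical-surface lookup.

    Table keys are normalized like disease surfaces.  Diseases whose surface
    is absent from the table are annotated ``"unmapped"``, never dropped.
    """
    table = {
        normalize_surface(k, EntityType.DISEASE): v for k, v in icd_table.items()
    }
    out = kg.copy()
    for e in kg.entities_of_type(EntityType.DISEASE):
        out.icd_codes[e.id] = table.get(e.surface, "unmapped")
    return out
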