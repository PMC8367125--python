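"""Synthetic two-source benchmark for entity fusion.

Real inputs to the fusion pipeline are two overlapping views of one
underlying disease-centred knowledge graph: a clinical-record view (rich in
symptom mentions, no curated attributes) and a web view (curated
terminology, attributes such as alternative and English names, treatments).
The same real-world concept appears in both views, often under a spelling
variant (頭痛-style one-character substitutions, added or dropped affixes,
synonyms).

This module generates exactly that situation with known ground truth: a
canonical truth graph, an ``emr`` view and a ``web`` view whose shared
entities are surface-corrupted at a configurable rate, plus exhaustively
labeled cross-view alignment pairs for tail entities (symptoms,
examinations) and head entities (diseases).  Identical seed and config give
byte-identical benchmarks.

Surfaces are short (2–6 character) strings over a CJK-range alphabet by
default so that character-set Jaccard behaves as it does on Chinese
clinical text; an ASCII alphabet can be configured for debugging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .graph import KnowledgeGraph, save_triples
from .schema import EntityType, RelationType

#: Default per-head mean tail counts, proportional to the relation-frequency
#: profile of a disease-centred clinical graph (symptoms dominate) but scaled
#: to desk size: the symptom mean is 8 and the others keep their relative
#: frequencies (ratios 3154 : 55 : 245 : 437 : 110 : 122 : 71 for symptom,
#: surgery, medicine, examination, treatment, pathogeny, department; body
#: structures average one per distinct symptom).
DEFAULT_TAILS_PER_RELATION: dict[str, float] = {
    "Diseases_rel_Symptom": 8.0,
    "Diseases_rel_Surgery": 8.0 * 55 / 3154,
    "Diseases_rel_Medicines": 8.0 * 245 / 3154,
    "Diseases_rel_Examination": 8.0 * 437 / 3154,
    "Diseases_rel_Treatment": 8.0 * 110 / 3154,
    "Diseases_attr_Pathogeny": 8.0 * 122 / 3154,
    "Diseases_attr_Department": 8.0 * 71 / 3154,
    "Symptoms_rel_Body structure": 1.0,
}

_DISEASE_HEADED = tuple(l for l in DEFAULT_TAILS_PER_RELATION if l.startswith("Diseases"))

DEFAULT_ALPHABET = "".join(chr(0x4E00 + i) for i in range(800))
_ASCII_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

#: Fixed affix pool for the affix-add corruption operator.
AFFIXES = ("感", "症", "状", "样")

#: Tail-entity types whose view assignment leans towards the EMR source when
#: not shared; attributes are web-only (clinical records carry no curated
#: attribute fields).
_EMR_AFFINITY: dict[EntityType, float] = {
    EntityType.SYMPTOM: 0.8,
    EntityType.BODY_STRUCTURE: 0.8,
    EntityType.EXAMINATION: 0.5,
    EntityType.SURGERY: 0.5,
    EntityType.MEDICINE: 0.5,
    EntityType.TREATMENT: 0.1,
}

_POOL_SIZING: dict[EntityType, tuple[float, int]] = {
    EntityType.SYMPTOM: (2.5, 10),
    EntityType.EXAMINATION: (0.8, 8),
    EntityType.SURGERY: (0.3, 5),
    EntityType.MEDICINE: (0.6, 6),
    EntityType.TREATMENT: (0.3, 5),
    EntityType.BODY_STRUCTURE: (0.5, 6),
    EntityType.PATHOGENY: (0.6, 6),
    EntityType.DEPARTMENT: (0.15, 4),
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 42
    n_diseases: int = 50
    tails_per_relation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAILS_PER_RELATION)
    )
    overlap: float = 0.6        # fraction of relational tail entities in both views
    variant_rate: float = 0.3   # P(shared entity's surface corrupted in one view)
    attr_coverage: float = 0.3  # fraction of diseases with alt/English names (web)
    neg_ratio: float = 1.0      # labeled negatives per positive alignment pair
    alphabet: str = DEFAULT_ALPHABET
    synonym_lexicon: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n_diseases < 1:
            raise ValueError("n_diseases must be >= 1")
        for name in ("overlap", "variant_rate", "attr_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.neg_ratio < 0:
            raise ValueError("neg_ratio must be >= 0")
        if len(set(self.alphabet)) < 10:
            raise ValueError("alphabet must contain at least 10 distinct characters")


@dataclass(frozen=True)
class AlignmentPair:
    """A labeled cross-view candidate pair (the unit of classifier training)."""

    left_id: str       # emr-view entity id
    right_id: str      # web-view entity id
    left_surface: str
    right_surface: str
    etype: EntityType
    label: int         # 1 = same truth entity


@dataclass
class SyntheticBenchmark:
    config: GeneratorConfig
    truth: KnowledgeGraph
    view_emr: KnowledgeGraph
    view_web: KnowledgeGraph
    tail_alignments: list[AlignmentPair]
    head_alignments: list[AlignmentPair]

    def positive_pairs(self, which: str = "tail") -> set[frozenset[str]]:
        pairs = self.tail_alignments if which == "tail" else self.head_alignments
        return {frozenset((p.left_id, p.right_id)) for p in pairs if p.label == 1}

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_triples(self.truth, out_dir / "truth.tsv")
        save_triples(self.view_emr, out_dir / "view_emr.tsv")
        save_triples(self.view_web, out_dir / "view_web.tsv")
        for name, pairs in (
            ("tail_alignments.tsv", self.tail_alignments),
            ("head_alignments.tsv", self.head_alignments),
        ):
            with (out_dir / name).open("w", encoding="utf-8") as fh:
                fh.write("left_surface\tleft_type\tright_surface\tright_type\tlabel\n")
                for p in pairs:
                    fh.write(
                        f"{p.left_surface}\t{p.etype.value}\t"
                        f"{p.right_surface}\t{p.etype.value}\t{p.label}\n"
                    )


# ---------------------------------------------------------------------------
# Surface corruption


CORRUPTION_OPERATORS = ("substitute", "affix_add", "affix_drop", "synonym")


def corrupt_surface(
    surface: str,
    rng: np.random.Generator,
    lexicon: Mapping[str, tuple[str, ...]] | None = None,
    alphabet: str = DEFAULT_ALPHABET,
    return_op: bool = False,
):
    """Apply exactly one corruption operator to a surface form.

    The operator is drawn uniformly from {single-character substitution from
    the confusion pool, affix add, affix drop, synonym replacement}; an
    inapplicable draw (affix drop on a short string, synonym without a
    lexicon hit) falls back to substitution, so the result is always
    non-empty and differs from the input whenever the alphabet allows.
    """
    if not surface:
        raise ValueError("cannot corrupt an empty surface")
    op = CORRUPTION_OPERATORS[rng.integers(4)]
    if op == "affix_drop" and len(surface) <= 2:
        op = "substitute"
    if op == "synonym" and not (lexicon and surface in lexicon and lexicon[surface]):
        op = "substitute"

    if op == "substitute":
        pos = int(rng.integers(len(surface)))
        pool = [c for c in alphabet if c != surface[pos]]
        if not pool:  # single-letter alphabet: nothing to substitute with
            out = surface
        else:
            out = surface[:pos] + pool[int(rng.integers(len(pool)))] + surface[pos + 1:]
    elif op == "affix_add":
        out = surface + AFFIXES[int(rng.integers(len(AFFIXES)))]
    elif op == "affix_drop":
        out = surface[:-1] if rng.integers(2) else surface[1:]
    else:  # synonym
        syns = tuple(lexicon[surface])
        out = syns[int(rng.integers(len(syns)))]
    return (out, op) if return_op else out


# ---------------------------------------------------------------------------
# Generation


def _random_surface(rng: np.random.Generator, alphabet: str, used: set[str],
                    lo: int = 2, hi: int = 6) -> str:
    while True:
        n = int(rng.integers(lo, hi + 1))
        s = "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=n))
        if s not in used:
            used.add(s)
            return s


def _random_english(rng: np.random.Generator, used: set[str]) -> str:
    n = int(rng.integers(4, 9))
    s = "".join(_ASCII_ALPHABET[int(i)] for i in rng.integers(0, 26, size=n))
    if s in used:
        return _random_english(rng, used)
    used.add(s)
    return s


def expected_relation_proportions(config: GeneratorConfig) -> dict[str, float]:
    """Expected share of each disease-headed relation among truth triples.

    Body-structure links hang off symptoms (their count depends on how many
    distinct symptoms the truth graph ends up using), and the name
    attributes are coverage-driven, so proportions are defined over the
    Poisson-sampled disease-headed relations only.
    """
    means = {l: config.tails_per_relation[l] for l in _DISEASE_HEADED}
    total = sum(means.values())
    return {l: m / total for l, m in means.items()}


def generate(config: GeneratorConfig) -> SyntheticBenchmark:
    """Generate a truth graph, two corrupted source views and alignment labels."""
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()

    # -- vocabulary pools, sized with the graph ------------------------
    pools: dict[EntityType, list[str]] = {}
    for etype, (factor, floor) in _POOL_SIZING.items():
        size = max(floor, round(factor * config.n_diseases))
        pools[etype] = [_random_surface(rng, config.alphabet, used) for _ in range(size)]
    disease_surfaces = [
        _random_surface(rng, config.alphabet, used, lo=3, hi=6)
        for _ in range(config.n_diseases)
    ]
    # body structures attached per distinct symptom
    body_mean = config.tails_per_relation.get("Symptoms_rel_Body structure", 0.0)
    body_of_symptom: dict[str, list[str]] = {}
    for s in pools[EntityType.SYMPTOM]:
        k = int(rng.poisson(body_mean))
        k = min(k, len(pools[EntityType.BODY_STRUCTURE]))
        picks = rng.choice(len(pools[EntityType.BODY_STRUCTURE]), size=k, replace=False)
        body_of_symptom[s] = [pools[EntityType.BODY_STRUCTURE][int(i)] for i in sorted(picks)]

    # -- truth graph ----------------------------------------------------
    truth = KnowledgeGraph()
    truth_triples: list[tuple[str, EntityType, str, str, EntityType]] = []

    def emit(head_surface, head_type, label, tail_surface, tail_type):
        h = truth.add_entity(head_surface, head_type, "truth")
        t = truth.add_entity(tail_surface, tail_type, "truth")
        truth.add_triple(h, RelationType.parse(label), t, ["truth"])
        truth_triples.append((head_surface, head_type, label, tail_surface, tail_type))

    alt_name_of: dict[str, str] = {}      # disease surface -> alternative name
    eng_name_of: dict[str, str] = {}
    for d in disease_surfaces:
        for label in _DISEASE_HEADED:
            rel = RelationType.parse(label)
            mean = config.tails_per_relation[label]
            k = int(rng.poisson(mean))
            if label == "Diseases_rel_Symptom":
                k = max(k, 1)  # every disease presents at least one symptom
            pool = pools[rel.tail_type]
            k = min(k, len(pool))
            picks = rng.choice(len(pool), size=k, replace=False)
            for i in sorted(picks):
                emit(d, EntityType.DISEASE, label, pool[int(i)], rel.tail_type)
        if rng.random() < config.attr_coverage:
            alt = _random_surface(rng, config.alphabet, used, lo=3, hi=6)
            alt_name_of[d] = alt
            emit(d, EntityType.DISEASE, "Diseases_attr_Alternative name",
                 alt, EntityType.ALTERNATIVE_NAME)
        if rng.random() < config.attr_coverage:
            eng = _random_english(rng, used)
            eng_name_of[d] = eng
            emit(d, EntityType.DISEASE, "Diseases_attr_English name",
                 eng, EntityType.ENGLISH_NAME)
    used_symptoms = sorted(
        {ts for (_, _, lab, ts, tt) in truth_triples if tt is EntityType.SYMPTOM}
    )
    for s in used_symptoms:
        for b in body_of_symptom[s]:
            emit(s, EntityType.SYMPTOM, "Symptoms_rel_Body structure",
                 b, EntityType.BODY_STRUCTURE)

    # -- view membership of tail entities -------------------------------
    relational_tails = sorted(
        {
            (ts, tt)
            for (_, _, lab, ts, tt) in truth_triples
            if not RelationType.parse(lab).is_attribute
        }
        | {(s, EntityType.SYMPTOM) for s in used_symptoms}
    )
    in_emr: dict[tuple[str, EntityType], bool] = {}
    in_web: dict[tuple[str, EntityType], bool] = {}
    for key in relational_tails:
        _, etype = key
        if rng.random() < config.overlap:
            in_emr[key] = in_web[key] = True
        elif rng.random() < _EMR_AFFINITY.get(etype, 0.5):
            in_emr[key], in_web[key] = True, False
        else:
            in_emr[key], in_web[key] = False, True
    for d in disease_surfaces:
        in_emr[(d, EntityType.DISEASE)] = in_web[(d, EntityType.DISEASE)] = True
    for (_, _, lab, ts, tt) in truth_triples:
        if RelationType.parse(lab).is_attribute:
            in_emr[(ts, tt)], in_web[(ts, tt)] = False, True

    # -- surface variants for shared entities ----------------------------
    surf_in_view: dict[tuple[str, EntityType, str], str] = {}  # (surface, etype, view)
    for key in sorted(set(in_emr)):
        s, etype = key
        emr_s = web_s = s
        if in_emr[key] and in_web[key] and rng.random() < config.variant_rate:
            corrupted = corrupt_surface(
                s, rng, lexicon=config.synonym_lexicon, alphabet=config.alphabet
            )
            if rng.integers(2):
                emr_s = corrupted
            else:
                web_s = corrupted
        surf_in_view[(s, etype, "emr")] = emr_s
        surf_in_view[(s, etype, "web")] = web_s

    # -- materialize the views -------------------------------------------
    view_emr, view_web = KnowledgeGraph(), KnowledgeGraph()
    for (hs, ht, lab, ts, tt) in truth_triples:
        rel = RelationType.parse(lab)
        for view, kg, present in (
            ("emr", view_emr, in_emr),
            ("web", view_web, in_web),
        ):
            if not (present.get((hs, ht), False) and present.get((ts, tt), False)):
                continue
            h = kg.add_entity(surf_in_view[(hs, ht, view)], ht, view)
            t = kg.add_entity(surf_in_view[(ts, tt, view)], tt, view)
            kg.add_triple(h, rel, t, [view])
    # web records the emr spelling of a corrupted disease as an alternative
    # name when the disease has attribute coverage — the mechanism by which
    # attribute alignment can recover spelling-variant diseases
    for d in alt_name_of:
        emr_s = surf_in_view[(d, EntityType.DISEASE, "emr")]
        web_s = surf_in_view[(d, EntityType.DISEASE, "web")]
        if emr_s != web_s:
            h = view_web.add_entity(web_s, EntityType.DISEASE, "web")
            t = view_web.add_entity(emr_s, EntityType.ALTERNATIVE_NAME, "web")
            view_web.add_triple(
                h, RelationType.parse("Diseases_attr_Alternative name"), t, ["web"]
            )

    # -- alignment labels -------------------------------------------------
    tail_alignments = _make_alignments(
        rng, config, view_emr, view_web, surf_in_view, in_emr, in_web,
        types=(EntityType.SYMPTOM, EntityType.EXAMINATION),
    )
    head_alignments = _make_alignments(
        rng, config, view_emr, view_web, surf_in_view, in_emr, in_web,
        types=(EntityType.DISEASE,),
    )
    return SyntheticBenchmark(
        config, truth, view_emr, view_web, tail_alignments, head_alignments
    )


def _make_alignments(
    rng, config, view_emr, view_web, surf_in_view, in_emr, in_web, types
) -> list[AlignmentPair]:
    positives: list[AlignmentPair] = []
    truth_of_emr: dict[str, str] = {}
    truth_of_web: dict[str, str] = {}
    for (s, etype, view), surf in sorted(surf_in_view.items()):
        if etype not in types:
            continue
        kg = view_emr if view == "emr" else view_web
        present = in_emr if view == "emr" else in_web
        if not present.get((s, etype), False):
            continue
        ent = kg.add_entity(surf, etype, view)  # idempotent lookup
        if view == "emr":
            truth_of_emr[ent.id] = s
        else:
            truth_of_web[ent.id] = s
    for (s, etype, view) in sorted(surf_in_view):
        if etype not in types or view != "emr":
            continue
        if not (in_emr.get((s, etype)) and in_web.get((s, etype))):
            continue
        ls = surf_in_view[(s, etype, "emr")]
        rs = surf_in_view[(s, etype, "web")]
        le = view_emr.add_entity(ls, etype, "emr")
        re = view_web.add_entity(rs, etype, "web")
        positives.append(AlignmentPair(le.id, re.id, ls, rs, etype, 1))

    # negatives: same-type cross-view pairs of distinct truth entities
    n_neg = round(config.neg_ratio * len(positives))
    lefts = sorted(truth_of_emr)
    rights = sorted(truth_of_web)
    negatives: list[AlignmentPair] = []
    seen: set[tuple[str, str]] = {(p.left_id, p.right_id) for p in positives}
    guard = 0
    while len(negatives) < n_neg and lefts and rights and guard < 50 * n_neg + 100:
        guard += 1
        li = lefts[int(rng.integers(len(lefts)))]
        ri = rights[int(rng.integers(len(rights)))]
        if truth_of_emr[li] == truth_of_web[ri] or (li, ri) in seen:
            continue
        le, re = view_emr.entity(li), view_web.entity(ri)
        if le.etype is not re.etype:
            continue
        seen.add((li, ri))
        negatives.append(AlignmentPair(li, ri, le.surface, re.surface, le.etype, 0))
    return positives + negatives


def default_benchmark(seed: int = 42) -> SyntheticBenchmark:
    """The standard evaluation benchmark: 50 diseases, 60% tail overlap,
    30% surface-variant rate, 30% attribute coverage."""
    return generate(GeneratorConfig(seed=seed))
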