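"""End-to-end pipeline: simulate → embed → fuse tails → fuse heads → export.

Each stage writes its outputs under the run directory so the pipeline is
resumable at any stage boundary, and the full configuration is serialized
alongside the outputs for provenance.  With fixed seeds the whole run is
deterministic: rerunning with an identical config reproduces byte-identical
merge files and reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import head_fusion, tail_fusion
from .embeddings import EmbeddingConfig, KGEmbedding, train
from .graph import (
    KnowledgeGraph,
    MergeBuilder,
    MergeMap,
    apply_merge,
    export_neo4j_csv,
    export_ntriples,
    save_triples,
    union_graphs,
)
from .synthetic import GeneratorConfig, SyntheticBenchmark, generate
from .tail_fusion import PairClassifierConfig

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("neo4j", "ntriples")


@dataclass
class PipelineConfig:
    out_dir: str = "kgfuse_run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    tail_classifier: PairClassifierConfig = field(default_factory=PairClassifierConfig)
    head_classifier: PairClassifierConfig = field(
        default_factory=lambda: PairClassifierConfig(model="dtree")
    )
    export_formats: tuple[str, ...] = EXPORT_FORMATS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for f in self.export_formats:
            if f not in EXPORT_FORMATS:
                raise ValueError(f"unknown export format {f!r}")

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["tails_per_relation"] = dict(
            d["generator"]["tails_per_relation"]
        )
        d["export_formats"] = list(self.export_formats)
        gen = d["generator"]
        if gen.get("synonym_lexicon"):
            gen["synonym_lexicon"] = {
                k: list(v) for k, v in gen["synonym_lexicon"].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if gen.get("synonym_lexicon"):
            gen["synonym_lexicon"] = {
                k: tuple(v) for k, v in gen["synonym_lexicon"].items()
            }
        tail = dict(d.pop("tail_classifier", {}))
        head = dict(d.pop("head_classifier", {}))
        for c in (tail, head):
            if "mlp_hidden" in c:
                c["mlp_hidden"] = tuple(c["mlp_hidden"])
        return cls(
            generator=GeneratorConfig(**gen),
            embedding=EmbeddingConfig(**d.pop("embedding", {})),
            tail_classifier=PairClassifierConfig(**tail),
            head_classifier=PairClassifierConfig(**head),
            export_formats=tuple(d.pop("export_formats", EXPORT_FORMATS)),
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, allow_unicode=True),
            encoding="utf-8",
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, out: Path) -> SyntheticBenchmark:
    benchmark = generate(config.generator)
    benchmark.write(out / "benchmark")
    return benchmark


@_stage("embed")
def stage_embed(config: PipelineConfig, out: Path, union: KnowledgeGraph) -> KGEmbedding:
    emb = train(union, config.embedding)
    emb.save(out / "embedding")
    return emb


@_stage("fuse-tail")
def stage_fuse_tails(config, out, benchmark, emb):
    pairs = tail_fusion.labeled_tail_pairs(benchmark, emb)
    clf, heldout = tail_fusion.train_classifier(pairs, config.tail_classifier)
    merges, metrics, matched = tail_fusion.fuse_tails(
        benchmark.view_emr,
        benchmark.view_web,
        clf,
        embedding=emb,
        reference_pairs=benchmark.positive_pairs("tail"),
    )
    scores = {frozenset((l, r)): s for l, r, s in matched}
    tail_fusion.save_merges(merges, scores, out / "merges_tail.tsv")
    (out / "metrics_tail.json").write_text(
        json.dumps(
            {"heldout": heldout.as_dict(), "against_truth": metrics.as_dict()},
            indent=1, sort_keys=True,
        )
    )
    return merges, heldout, metrics


@_stage("fuse-head")
def stage_fuse_heads(config, out, benchmark, emb, tail_merges):
    attr = head_fusion.align_by_attribute(benchmark.view_emr, benchmark.view_web)
    pairs = head_fusion.labeled_head_pairs(benchmark, tail_merges, emb)
    clf, heldout = tail_fusion.train_classifier(pairs, config.head_classifier)
    merges, metrics, matched = head_fusion.fuse_heads(
        benchmark.view_emr,
        benchmark.view_web,
        tail_merges,
        emb,
        clf,
        attr_merges=attr,
        reference_pairs=benchmark.positive_pairs("head"),
    )
    scores = {frozenset((l, r)): s for l, r, s in matched}
    tail_fusion.save_merges(merges, scores, out / "merges_head.tsv")
    (out / "metrics_head.json").write_text(
        json.dumps(
            {"heldout": heldout.as_dict(), "against_truth": metrics.as_dict()},
            indent=1, sort_keys=True,
        )
    )
    return merges, heldout, metrics


def combine_merges(union: KnowledgeGraph, *maps: MergeMap) -> MergeMap:
    """Union-find closure over several stage merge maps."""
    builder = MergeBuilder(dict(union.entities))
    for mm in maps:
        for eid, canon in mm.mapping.items():
            if eid != canon:
                builder.union(eid, canon, mm.provenance.get(eid, "exact"))
    return builder.build()


@_stage("export")
def stage_export(config: PipelineConfig, out: Path, fused: KnowledgeGraph) -> None:
    save_triples(fused, out / "fused.tsv")
    if "neo4j" in config.export_formats:
        export_neo4j_csv(fused, out / "neo4j")
    if "ntriples" in config.export_formats:
        export_ntriples(fused, out / "fused.nt")


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save_yaml(out / "config.yaml")

    benchmark = stage_simulate(config, out)
    union = union_graphs(benchmark.view_emr, benchmark.view_web)
    emb = stage_embed(config, out, union)
    tail_merges, tail_heldout, tail_truth = stage_fuse_tails(config, out, benchmark, emb)
    head_merges, head_heldout, head_truth = stage_fuse_heads(
        config, out, benchmark, emb, tail_merges
    )
    merges = combine_merges(union, tail_merges, head_merges)
    with (out / "merges_all.tsv").open("w", encoding="utf-8") as fh:
        fh.write("entity_id\tcanonical_id\tstage\n")
        for eid in sorted(merges.mapping):
            canon = merges.mapping[eid]
            if eid != canon:
                fh.write(f"{eid}\t{canon}\t{merges.provenance.get(eid, '')}\n")
    fused = apply_merge(union, merges)
    stage_export(config, out, fused)

    report = head_fusion.fusion_report(
        benchmark, merges, tail_metrics=tail_heldout, head_metrics=head_heldout
    )
    report["tail_fusion_vs_truth"] = tail_truth.as_dict()
    report["head_fusion_vs_truth"] = head_truth.as_dict()
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return out
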