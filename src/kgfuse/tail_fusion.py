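"""Tail-entity fusion: classify cross-source pairs, then merge greedily.

Symptoms and examinations extracted from clinical records and from web
sources refer to the same concepts under varying surface forms.  Fusion is
cast as binary classification of cross-source same-type candidate pairs on
three features (semantic similarity, embedding cosine, character Jaccard),
followed by greedy one-to-one matching of pairs scored above a probability
threshold and union-find closure into a :class:`~kgfuse.graph.MergeMap`.

The classifier machinery here (feature standardization, train/test split,
the three model families, greedy matching) is shared with head-entity
fusion, which consumes it with structural features instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import jaccard_chars, semantic_score, tail_features
from .graph import Entity, KnowledgeGraph, MergeBuilder, MergeMap
from .schema import EntityType

DEFAULT_TAIL_TYPES = (EntityType.SYMPTOM, EntityType.EXAMINATION)


@dataclass(frozen=True)
class PairClassifierConfig:
    model: str = "mlp"              # logreg | dtree | mlp
    decision_threshold: float = 0.5
    split_ratio: float = 0.8        # train fraction of the labeled pairs
    seed: int = 0
    mlp_hidden: tuple[int, ...] = (16,)
    mlp_epochs: int = 200

    def __post_init__(self) -> None:
        if self.model not in ("logreg", "dtree", "mlp"):
            raise ValueError(f"unknown classifier model {self.model!r}")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")


@dataclass(frozen=True)
class FusionMetrics:
    precision: float
    recall: float
    f1: float
    n_train: int = 0
    n_test: int = 0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def precision_recall_f1(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


class PairClassifier:
    """A fitted scaler+model pipeline scoring pair feature rows."""

    def __init__(self, pipeline: Pipeline, config: PairClassifierConfig) -> None:
        self.pipeline = pipeline
        self.config = config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(pair refers to the same concept) per row."""
        X = np.asarray(X, dtype=float)
        proba = self.pipeline.predict_proba(X)
        pos_col = list(self.pipeline.classes_).index(1)
        return proba[:, pos_col]


def _make_model(config: PairClassifierConfig):
    if config.model == "logreg":
        return LogisticRegression(max_iter=1000, random_state=config.seed)
    if config.model == "dtree":
        return DecisionTreeClassifier(min_samples_leaf=2, random_state=config.seed)
    return MLPClassifier(
        hidden_layer_sizes=config.mlp_hidden,
        max_iter=config.mlp_epochs,
        random_state=config.seed,
    )


def _as_rows(pairs: Iterable) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for vec, label in pairs:
        X.append(vec.as_row() if hasattr(vec, "as_row") else vec)
        y.append(int(label))
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def train_classifier(
    pairs: Iterable,
    config: PairClassifierConfig,
) -> tuple[PairClassifier, FusionMetrics]:
    """Fit a pair classifier on labeled feature vectors.

    ``pairs`` yields ``(feature_vector, label)`` with label in {0, 1}.
    Features are z-scored on the training split; metrics are measured on
    the held-out fraction.  Deterministic for a fixed seed.
    """
    X, y = _as_rows(pairs)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y,
        train_size=config.split_ratio,
        random_state=config.seed,
        stratify=y,
    )
    pipeline = Pipeline(
        [("scale", StandardScaler()), ("model", _make_model(config))]
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        pipeline.fit(X_tr, y_tr)
    clf = PairClassifier(pipeline, config)
    y_hat = (clf.predict_proba(X_te) >= config.decision_threshold).astype(int)
    p, r, f1 = precision_recall_f1(y_te, y_hat)
    return clf, FusionMetrics(p, r, f1, n_train=len(y_tr), n_test=len(y_te))


# ---------------------------------------------------------------------------
# Candidate generation and matching


def candidate_pairs(
    kg_a: KnowledgeGraph,
    kg_b: KnowledgeGraph,
    types: Sequence[EntityType] = DEFAULT_TAIL_TYPES,
    prefilter: bool = False,
) -> Iterator[tuple[Entity, Entity]]:
    """Cross-source candidate pairs blocked on identical entity type.

    With ``prefilter`` enabled, pairs with zero character Jaccard *and*
    zero default semantic similarity are dropped to bound the quadratic
    blow-up on large vocabularies (off by default).
    """
    for etype in types:
        for ea in kg_a.entities_of_type(etype):
            for eb in kg_b.entities_of_type(etype):
                if prefilter:
                    if jaccard_chars(ea.surface, eb.surface) == 0.0 and \
                       semantic_score(ea.surface, eb.surface) == 0.0:
                        continue
                yield ea, eb


def greedy_one_to_one(
    scored: Iterable[tuple[str, str, float]],
    threshold: float,
) -> list[tuple[str, str, float]]:
    """Greedy one-to-one matching in descending score above ``threshold``.

    Ties are broken by the id pair, so matching is deterministic.  Each
    left and each right id is used at most once.
    """
    ranked = sorted(scored, key=lambda x: (-x[2], x[0], x[1]))
    used_left: set[str] = set()
    used_right: set[str] = set()
    out = []
    for left, right, s in ranked:
        if s < threshold or left in used_left or right in used_right:
            continue
        used_left.add(left)
        used_right.add(right)
        out.append((left, right, s))
    return out


def alignment_metrics(
    predicted: set[frozenset[str]],
    truth: set[frozenset[str]],
) -> FusionMetrics:
    """Precision/recall/F1 of predicted merge pairs against ground truth."""
    tp = len(predicted & truth)
    p = tp / len(predicted) if predicted else 0.0
    r = tp / len(truth) if truth else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return FusionMetrics(p, r, f1)


def _combined_entities(kg_a: KnowledgeGraph, kg_b: KnowledgeGraph) -> dict[str, Entity]:
    ents = dict(kg_a.entities)
    ents.update(kg_b.entities)
    return ents


def fuse_tails(
    kg_a: KnowledgeGraph,
    kg_b: KnowledgeGraph,
    classifier: PairClassifier,
    threshold: float | None = None,
    embedding=None,
    scorer=None,
    types: Sequence[EntityType] = DEFAULT_TAIL_TYPES,
    reference_pairs: set[frozenset[str]] | None = None,
) -> tuple[MergeMap, FusionMetrics | None, list[tuple[str, str, float]]]:
    """Score all candidate tail pairs and merge greedily one-to-one.

    Returns the closed merge map, metrics against ``reference_pairs`` when
    ground truth is supplied (else ``None``), and the matched scored pairs.
    """
    threshold = classifier.config.decision_threshold if threshold is None else threshold
    cands = list(candidate_pairs(kg_a, kg_b, types))
    scored: list[tuple[str, str, float]] = []
    if cands:
        X = np.array(
            [
                tail_features(
                    ea.surface, eb.surface, ea.id, eb.id, embedding, scorer
                ).as_row()
                for ea, eb in cands
            ]
        )
        probs = classifier.predict_proba(X)
        scored = [(ea.id, eb.id, float(p)) for (ea, eb), p in zip(cands, probs)]
    matched = greedy_one_to_one(scored, threshold)
    builder = MergeBuilder(_combined_entities(kg_a, kg_b))
    for left, right, _ in matched:
        builder.union(left, right, "tail_model")
    merges = builder.build()
    metrics = None
    if reference_pairs is not None:
        metrics = alignment_metrics(
            {frozenset((l, r)) for l, r, _ in matched}, reference_pairs
        )
    return merges, metrics, matched


# ---------------------------------------------------------------------------
# Labeled-pair I/O


def load_labeled_pairs(
    path: str | Path,
    kg_a: KnowledgeGraph,
    kg_b: KnowledgeGraph,
    embedding=None,
    scorer=None,
) -> list[tuple]:
    """Load a labeled alignment TSV and featurize each pair.

    Format: ``left_surface  left_type  right_surface  right_type  label``
    with a header row; left surfaces are resolved in ``kg_a``, right in
    ``kg_b``.
    """
    from .graph import entity_id, normalize_surface

    out = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("left_surface"):
            raise ValueError(f"{path}: expected alignment header, got {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ls, lt, rs, rt, label = line.split("\t")
            etype_l, etype_r = EntityType.parse(lt), EntityType.parse(rt)
            ls_n = normalize_surface(ls, etype_l)
            rs_n = normalize_surface(rs, etype_r)
            lid = _find_entity_id(kg_a, ls_n, etype_l)
            rid = _find_entity_id(kg_b, rs_n, etype_r)
            vec = tail_features(ls_n, rs_n, lid, rid, embedding, scorer)
            out.append((vec, int(label)))
    return out


def _find_entity_id(kg: KnowledgeGraph, surface: str, etype: EntityType) -> str:
    for e in kg.entities_of_type(etype):
        if e.surface == surface:
            return e.id
    return f"missing:{etype.value}:{surface}"


def labeled_tail_pairs(benchmark, embedding=None, scorer=None) -> list[tuple]:
    """Featurize a benchmark's labeled tail alignment pairs for training."""
    return [
        (
            tail_features(p.left_surface, p.right_surface, p.left_id, p.right_id,
                          embedding, scorer),
            p.label,
        )
        for p in benchmark.tail_alignments
    ]


def save_merges(merges: MergeMap, scores: dict[frozenset[str], float], path: str | Path) -> None:
    """Write ``entity_id  canonical_id  score  stage`` rows for audit."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("entity_id\tcanonical_id\tscore\tstage\n")
        for eid in sorted(merges.mapping):
            canon = merges.mapping[eid]
            if eid == canon:
                continue
            score = scores.get(frozenset((eid, canon)), float("nan"))
            fh.write(f"{eid}\t{canon}\t{score:.6f}\t{merges.provenance.get(eid, '')}\n")
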