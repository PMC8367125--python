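"""Translational knowledge-graph embeddings: TransE, TransH, TransR.

All three models embed entities and relations in R^dim and score a triple
(h, r, t) by a translation distance f(h, r, t) = ‖proj_r(h) + r − proj_r(t)‖₂
(lower = more plausible), differing only in the projection:

* TransE — identity projection, f = ‖h + r − t‖.
* TransH — projection onto the relation's hyperplane with unit normal w_r:
  proj(x) = x − (wᵀx)w.
* TransR — a full relation-specific linear map M_r: proj(x) = M_r x.

Training minimizes the margin ranking loss
Σ max(0, γ + f(h, r, t) − f(h', r, t')) by minibatch SGD, where each
positive triple is paired with corrupted triples obtained by replacing the
head or the tail (equal probability) with a uniformly random entity of the
same type (type-constrained negative sampling; with a closed schema,
cross-type corruptions would be trivially negative).  Entity vectors are
projected back onto the unit ball after every batch, the standard Trans*
norm constraint.

Everything is plain NumPy and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import KnowledgeGraph
from .schema import EntityType

MODELS = ("transE", "transH", "transR")


@dataclass(frozen=True)
class EmbeddingConfig:
    model: str = "transR"
    dim: int = 50
    margin: float = 1.0          # ranking-loss margin γ
    learning_rate: float = 0.01
    lr_decay: float = 0.05       # inverse-time decay: lr_t = lr / (1 + decay·epoch)
    epochs: int = 500
    neg_per_pos: int = 1
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class KGEmbedding:
    """Trained entity/relation vectors plus per-relation projections.

    ``relation_projections`` holds M_r for TransR (identity for TransE) and
    the unit hyperplane normal w_r for TransH.
    """

    def __init__(
        self,
        config: EmbeddingConfig,
        entity_ids: list[str],
        entity_types: list[str],
        relation_labels: list[str],
        E: np.ndarray,
        R: np.ndarray,
        P: np.ndarray,
        loss_history: list[float] | None = None,
    ) -> None:
        self.config = config
        self.entity_ids = list(entity_ids)
        self.entity_types = list(entity_types)
        self.relation_labels = list(relation_labels)
        self._eidx = {e: i for i, e in enumerate(entity_ids)}
        self._ridx = {r: i for i, r in enumerate(relation_labels)}
        self.E = E  # (n_ent, dim)
        self.R = R  # (n_rel, dim)
        self.P = P  # transR: (n_rel, dim, dim); transH: (n_rel, dim); transE: (n_rel, dim, dim) identity
        self.loss_history = loss_history or []

    # -- lookups ------------------------------------------------------

    def has(self, entity_id: str) -> bool:
        return entity_id in self._eidx

    def vector(self, entity_id: str) -> np.ndarray:
        try:
            return self.E[self._eidx[entity_id]]
        except KeyError:
            raise KeyError(f"entity {entity_id!r} not in embedding vocabulary") from None

    def relation_vector(self, label: str) -> np.ndarray:
        try:
            return self.R[self._ridx[label]]
        except KeyError:
            raise KeyError(f"relation {label!r} not in embedding vocabulary") from None

    def _project(self, x: np.ndarray, r_i: int) -> np.ndarray:
        if self.config.model == "transE":
            return x
        if self.config.model == "transH":
            w = self.P[r_i]
            return x - (x @ w) * w
        return self.P[r_i] @ x  # transR

    # -- scoring ------------------------------------------------------

    def score_triple(self, h: str, r: str, t: str) -> float:
        """Translation distance f(h, r, t); lower means more plausible."""
        r_i = self._ridx.get(r)
        if r_i is None:
            raise KeyError(f"relation {r!r} not in embedding vocabulary")
        hv = self._project(self.vector(h), r_i)
        tv = self._project(self.vector(t), r_i)
        return float(np.linalg.norm(hv + self.R[r_i] - tv))

    def score_tails(self, h: str, r: str, tail_ids: list[str]) -> np.ndarray:
        """Vectorized f(h, r, ·) over candidate tails."""
        r_i = self._ridx[r]
        T = self.E[[self._eidx[t] for t in tail_ids]]
        if self.config.model == "transE":
            Tp = T
        elif self.config.model == "transH":
            w = self.P[r_i]
            Tp = T - np.outer(T @ w, w)
        else:
            Tp = T @ self.P[r_i].T
        hv = self._project(self.vector(h), r_i)
        return np.linalg.norm(hv + self.R[r_i] - Tp, axis=1)

    def cosine(self, a: str, b: str) -> float:
        """Cosine similarity of two entity vectors (in the shared entity space)."""
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValueError("cannot take cosine of a zero vector")
        return float(np.dot(va, vb) / (na * nb))

    # -- persistence --------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with (out_dir / "entities.tsv").open("w", encoding="utf-8") as fh:
            for eid, et, row in zip(self.entity_ids, self.entity_types, self.E):
                fh.write(eid + "\t" + et + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
        with (out_dir / "relations.tsv").open("w", encoding="utf-8") as fh:
            for lab, row in zip(self.relation_labels, self.R):
                fh.write(lab + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
        (out_dir / "projections.bin").write_bytes(
            np.ascontiguousarray(self.P, dtype="<f8").tobytes()
        )
        manifest = {
            "model": self.config.model,
            "dim": self.config.dim,
            "seed": self.config.seed,
            "margin": self.config.margin,
            "learning_rate": self.config.learning_rate,
            "lr_decay": self.config.lr_decay,
            "epochs": self.config.epochs,
            "neg_per_pos": self.config.neg_per_pos,
            "batch_size": self.config.batch_size,
            "projection_shape": list(np.asarray(self.P).shape),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "KGEmbedding":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        config = EmbeddingConfig(
            model=manifest["model"],
            dim=manifest["dim"],
            seed=manifest["seed"],
            margin=manifest["margin"],
            learning_rate=manifest["learning_rate"],
            lr_decay=manifest["lr_decay"],
            epochs=manifest["epochs"],
            neg_per_pos=manifest["neg_per_pos"],
            batch_size=manifest["batch_size"],
        )
        eids, etypes, erows = [], [], []
        for line in (in_dir / "entities.tsv").read_text(encoding="utf-8").splitlines():
            parts = line.split("\t")
            eids.append(parts[0])
            etypes.append(parts[1])
            erows.append([float(x) for x in parts[2:]])
        rlabels, rrows = [], []
        for line in (in_dir / "relations.tsv").read_text(encoding="utf-8").splitlines():
            parts = line.split("\t")
            rlabels.append(parts[0])
            rrows.append([float(x) for x in parts[1:]])
        P = np.frombuffer((in_dir / "projections.bin").read_bytes(), dtype="<f8")
        P = P.reshape(manifest["projection_shape"]).copy()
        return cls(config, eids, etypes, rlabels, np.array(erows), np.array(rrows), P)


# ---------------------------------------------------------------------------
# Training


def _type_pools(kg: KnowledgeGraph, eidx: dict[str, int]) -> dict[str, np.ndarray]:
    pools: dict[str, list[int]] = {}
    for eid, ent in kg.entities.items():
        pools.setdefault(ent.etype.value, []).append(eidx[eid])
    return {k: np.array(sorted(v)) for k, v in pools.items()}


def train(kg: KnowledgeGraph, config: EmbeddingConfig) -> KGEmbedding:
    """Fit a Trans* model on a graph by minibatch SGD over the margin loss.

    Negative sampling is type-constrained; if a slot's type pool offers no
    alternative entity, corruption falls back to the full entity set for
    that slot (with a warning) so that trivially small graphs still train.
    Deterministic for a fixed config.
    """
    if kg.n_triples() == 0:
        raise ValueError("cannot train embeddings on an empty graph")
    rng = np.random.default_rng(config.seed)
    dim = config.dim

    entity_ids = sorted(kg.entities)
    entity_types = [kg.entities[e].etype.value for e in entity_ids]
    eidx = {e: i for i, e in enumerate(entity_ids)}
    triple_list = list(kg.triples())
    relation_labels = sorted({tr.relation.label for tr in triple_list})
    ridx = {r: i for i, r in enumerate(relation_labels)}
    n_ent, n_rel = len(entity_ids), len(relation_labels)

    bound = 6.0 / np.sqrt(dim)
    E = rng.uniform(-bound, bound, size=(n_ent, dim))
    R = rng.uniform(-bound, bound, size=(n_rel, dim))
    R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)
    if config.model == "transR":
        P = np.repeat(np.eye(dim)[None], n_rel, axis=0)
    elif config.model == "transH":
        P = rng.uniform(-bound, bound, size=(n_rel, dim))
        P /= np.maximum(np.linalg.norm(P, axis=1, keepdims=True), 1e-12)
    else:
        P = np.repeat(np.eye(dim)[None], n_rel, axis=0)

    H = np.array([eidx[tr.head_id] for tr in triple_list])
    Rl = np.array([ridx[tr.relation.label] for tr in triple_list])
    T = np.array([eidx[tr.tail_id] for tr in triple_list])
    n_tr = len(triple_list)

    pools = _type_pools(kg, eidx)
    all_pool = np.arange(n_ent)
    # per-relation corruption pools for the head and tail slot
    head_pool: dict[int, np.ndarray] = {}
    tail_pool: dict[int, np.ndarray] = {}
    warned = False
    for lab, i in ridx.items():
        rel = triple_list[int(np.flatnonzero(Rl == i)[0])].relation
        for slot, etype, target in (
            ("head", rel.head_type, head_pool),
            ("tail", rel.tail_type, tail_pool),
        ):
            pool = pools.get(etype.value, np.array([], dtype=int))
            if len(pool) < 2:
                if not warned:
                    warnings.warn(
                        f"relation {lab!r} has <2 entities in its {slot} slot; "
                        "falling back to untyped corruption",
                        stacklevel=2,
                    )
                    warned = True
                pool = all_pool
            target[i] = pool

    # padded per-relation pools so corruption sampling vectorizes
    max_pool = max(max(len(p) for p in head_pool.values()),
                   max(len(p) for p in tail_pool.values()))
    pad_head = np.zeros((n_rel, max_pool), dtype=int)
    pad_tail = np.zeros((n_rel, max_pool), dtype=int)
    len_head = np.zeros(n_rel, dtype=int)
    len_tail = np.zeros(n_rel, dtype=int)
    for i in range(n_rel):
        pad_head[i, : len(head_pool[i])] = head_pool[i]
        len_head[i] = len(head_pool[i])
        pad_tail[i, : len(tail_pool[i])] = tail_pool[i]
        len_tail[i] = len(tail_pool[i])

    margin = config.margin
    loss_history: list[float] = []
    # filtered corruption: never present a true triple as a negative (with 1-N
    # relations a raw uniform draw hits a true tail a few % of the time, which
    # would put an irreducible floor under the ranking loss)
    true_set = set(zip(H.tolist(), Rl.tolist(), T.tolist()))

    def _eval_loss(mh, mr, mt, nh, nt) -> float:
        total = 0.0
        for r_i in np.unique(mr):
            m = mr == r_i
            total += _hinge_loss(
                config.model, E, R, P, int(r_i), mh[m], mt[m], nh[m], nt[m], margin
            )
        return total

    # the monitored loss is evaluated on one fixed corruption per positive,
    # drawn up front, so it is a deterministic function of the parameters
    # (the SGD updates themselves use freshly resampled corruptions)
    mon_ch = rng.random(n_tr) < 0.5
    mon_ci = rng.integers(0, np.where(mon_ch, len_head[Rl], len_tail[Rl]))
    mon_cand = np.where(mon_ch, pad_head[Rl, mon_ci], pad_tail[Rl, mon_ci])
    mon_orig = np.where(mon_ch, H, T)
    mon_lens = np.where(mon_ch, len_head[Rl], len_tail[Rl])
    fix = (mon_cand == mon_orig) & (mon_lens > 1)
    if fix.any():
        ci2 = (mon_ci + 1) % mon_lens
        mon_cand = np.where(
            fix, np.where(mon_ch, pad_head[Rl, ci2], pad_tail[Rl, ci2]), mon_cand
        )
    mon_nh = np.where(mon_ch, mon_cand, H)
    mon_nt = np.where(mon_ch, T, mon_cand)
    for j in range(n_tr):  # filter true triples out of the monitored set too
        if (mon_nh[j], Rl[j], mon_nt[j]) not in true_set:
            continue
        pool = head_pool[Rl[j]] if mon_ch[j] else tail_pool[Rl[j]]
        orig_j = H[j] if mon_ch[j] else T[j]
        for _try in range(10):
            c = int(pool[rng.integers(len(pool))])
            cand_triple = (c, Rl[j], T[j]) if mon_ch[j] else (H[j], Rl[j], c)
            if c != orig_j and cand_triple not in true_set:
                if mon_ch[j]:
                    mon_nh[j] = c
                else:
                    mon_nt[j] = c
                break

    for _epoch in range(config.epochs):
        lr = config.learning_rate / (1.0 + config.lr_decay * _epoch)
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.neg_per_pos > 1:
                idx = np.repeat(idx, config.neg_per_pos)
            bh, br, bt = H[idx], Rl[idx], T[idx]
            # corrupt head or tail with equal probability
            corrupt_head = rng.random(len(idx)) < 0.5
            lens = np.where(corrupt_head, len_head[br], len_tail[br])
            ci = rng.integers(0, lens)
            cand = np.where(
                corrupt_head, pad_head[br, ci], pad_tail[br, ci]
            )
            orig = np.where(corrupt_head, bh, bt)
            clash = (cand == orig) & (lens > 1)
            if clash.any():
                ci2 = (ci + 1) % lens
                cand2 = np.where(corrupt_head, pad_head[br, ci2], pad_tail[br, ci2])
                cand = np.where(clash, cand2, cand)
            nh = np.where(corrupt_head, cand, bh)
            nt = np.where(corrupt_head, bt, cand)
            # resample any negative that is itself a true triple
            for j in range(len(idx)):
                if (nh[j], br[j], nt[j]) not in true_set:
                    continue
                pool = head_pool[br[j]] if corrupt_head[j] else tail_pool[br[j]]
                orig_j = bh[j] if corrupt_head[j] else bt[j]
                for _try in range(10):
                    c = int(pool[rng.integers(len(pool))])
                    cand_triple = (c, br[j], bt[j]) if corrupt_head[j] else (bh[j], br[j], c)
                    if c != orig_j and cand_triple not in true_set:
                        if corrupt_head[j]:
                            nh[j] = c
                        else:
                            nt[j] = c
                        break

            for r_i in np.unique(br):
                m = br == r_i
                _sgd_step(
                    config.model, E, R, P, int(r_i),
                    bh[m], bt[m], nh[m], nt[m], lr, margin,
                )
            # unit-ball norm constraint on entity vectors
            norms = np.linalg.norm(E, axis=1, keepdims=True)
            np.divide(E, norms, out=E, where=norms > 1.0)
            if config.model == "transH":
                P /= np.maximum(np.linalg.norm(P, axis=1, keepdims=True), 1e-12)
        loss_history.append(_eval_loss(H, Rl, T, mon_nh, mon_nt))

    return KGEmbedding(
        config, entity_ids, entity_types, relation_labels, E, R, P, loss_history
    )


def _hinge_loss(
    model: str,
    E: np.ndarray,
    R: np.ndarray,
    P: np.ndarray,
    r_i: int,
    ph: np.ndarray,
    pt: np.ndarray,
    nh: np.ndarray,
    nt: np.ndarray,
    margin: float,
) -> float:
    """Margin ranking loss of a same-relation batch (no parameter updates)."""
    r = R[r_i]

    def proj(X: np.ndarray) -> np.ndarray:
        if model == "transE":
            return X
        if model == "transH":
            w = P[r_i]
            return X - np.outer(X @ w, w)
        return X @ P[r_i].T

    d_pos = np.linalg.norm(proj(E[ph]) + r - proj(E[pt]), axis=1)
    d_neg = np.linalg.norm(proj(E[nh]) + r - proj(E[nt]), axis=1)
    return float(np.maximum(0.0, margin + d_pos - d_neg).sum())


def _sgd_step(
    model: str,
    E: np.ndarray,
    R: np.ndarray,
    P: np.ndarray,
    r_i: int,
    ph: np.ndarray,
    pt: np.ndarray,
    nh: np.ndarray,
    nt: np.ndarray,
    lr: float,
    margin: float,
) -> float:
    """One hinge-loss SGD update for a same-relation sub-batch; returns its loss."""
    r = R[r_i]

    def proj(X: np.ndarray) -> np.ndarray:
        if model == "transE":
            return X
        if model == "transH":
            w = P[r_i]
            return X - np.outer(X @ w, w)
        return X @ P[r_i].T

    Hp, Tp = E[ph], E[pt]
    Hn, Tn = E[nh], E[nt]
    v_pos = proj(Hp) + r - proj(Tp)
    v_neg = proj(Hn) + r - proj(Tn)
    d_pos = np.linalg.norm(v_pos, axis=1)
    d_neg = np.linalg.norm(v_neg, axis=1)
    hinge = margin + d_pos - d_neg
    viol = hinge > 0
    loss = float(hinge[viol].sum())
    if not viol.any():
        return 0.0

    u_pos = v_pos[viol] / np.maximum(d_pos[viol, None], 1e-12)
    u_neg = v_neg[viol] / np.maximum(d_neg[viol, None], 1e-12)
    ph_v, pt_v, nh_v, nt_v = ph[viol], pt[viol], nh[viol], nt[viol]

    # ∂f/∂h = Jᵀu where J is the projection's Jacobian; ∂f/∂t = −Jᵀu; ∂f/∂r = u
    if model == "transE":
        gh_pos, gt_pos = u_pos, -u_pos
        gh_neg, gt_neg = u_neg, -u_neg
    elif model == "transH":
        w = P[r_i]
        gh_pos = u_pos - np.outer(u_pos @ w, w)
        gt_pos = -gh_pos
        gh_neg = u_neg - np.outer(u_neg @ w, w)
        gt_neg = -gh_neg
        z_pos = E[ph_v] - E[pt_v]
        z_neg = E[nh_v] - E[nt_v]
        gw = -(
            z_pos * (u_pos @ w)[:, None] + u_pos * ((z_pos * w).sum(axis=1))[:, None]
        ).sum(axis=0) + (
            z_neg * (u_neg @ w)[:, None] + u_neg * ((z_neg * w).sum(axis=1))[:, None]
        ).sum(axis=0)
        P[r_i] -= lr * gw
    else:  # transR
        M = P[r_i]
        gh_pos, gt_pos = u_pos @ M, -(u_pos @ M)
        gh_neg, gt_neg = u_neg @ M, -(u_neg @ M)
        z_pos = E[ph_v] - E[pt_v]
        z_neg = E[nh_v] - E[nt_v]
        gM = u_pos.T @ z_pos - u_neg.T @ z_neg
        P[r_i] -= lr * gM

    np.add.at(E, ph_v, -lr * gh_pos)
    np.add.at(E, pt_v, -lr * gt_pos)
    np.add.at(E, nh_v, lr * gh_neg)
    np.add.at(E, nt_v, lr * gt_neg)
    R[r_i] -= lr * (u_pos.sum(axis=0) - u_neg.sum(axis=0))
    return loss


# ---------------------------------------------------------------------------
# Evaluation


def hits_at_k(emb: KGEmbedding, test_triples, k: int) -> float:
    """Raw tail-ranking hits@k.

    For each test triple the true tail is ranked among all embedded entities
    of the relation's tail type by ascending translation distance, ties
    broken by entity id.  Returns the fraction of test triples whose true
    tail ranks within the top k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    test_triples = list(test_triples)
    if not test_triples:
        raise ValueError("no test triples supplied")
    by_type: dict[str, list[str]] = {}
    for eid, et in zip(emb.entity_ids, emb.entity_types):
        by_type.setdefault(et, []).append(eid)
    hits = 0
    for tr in test_triples:
        cands = by_type.get(tr.relation.tail_type.value, [])
        if tr.tail_id not in cands:
            raise KeyError(f"test tail {tr.tail_id!r} not in embedding vocabulary")
        scores = emb.score_tails(tr.head_id, tr.relation.label, cands)
        t_pos = cands.index(tr.tail_id)
        st = scores[t_pos]
        rank = 1 + int(
            np.sum(
                (scores < st)
                | ((scores == st) & np.array([c < tr.tail_id for c in cands]))
            )
        )
        if rank <= k:
            hits += 1
    return hits / len(test_triples)
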