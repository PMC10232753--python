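"""Knowledge-graph embedding and triple scoring for link prediction.

The model learns a d-dimensional embedding per entity and per relation and
scores a triple (h, r, t) with one of three architectures:

* ``concat-mlp`` (default): the head and relation embeddings are
  concatenated and pushed through a one-hidden-layer projector; the
  projected vector is matched against the tail embedding,
  ``s = sigmoid(W2 tanh(W1 [e_h; e_r] + b1) + b2) . e_t``.
  This realizes the concatenate-then-predict pattern and makes tail ranking
  cheap: one projector forward, then a matrix-vector product over all
  candidate tails.
* ``distmult``: trilinear product ``s = sum_k h_k r_k t_k`` (closed form,
  used as an oracle/baseline).
* ``transe``: negative translation distance ``s = -||e_h + e_r - e_t||``.

Training is binary cross-entropy against uniformly corrupted heads/tails,
by mini-batch Adagrad with manual gradients (numpy); Adagrad's
per-parameter step scaling makes optimization insensitive to the tiny raw
gradient magnitudes of small random embeddings. Inverse relations
(``<r>__inv``) are added internally so head ranking reduces to tail
ranking on the inverse relation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kg import KnowledgeGraph, TripleRecord

INVERSE_SUFFIX = "__inv"

ARCHITECTURES = ("concat-mlp", "distmult", "transe")


class LookupError_(KeyError):
    """Entity or relation unknown to the model."""


@dataclass
class ScorerConfig:
    architecture: str = "concat-mlp"
    embedding_dim: int = 32
    hidden_width: int = 64
    nonlinearity: str = "tanh"

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}, got {self.architecture!r}")
        if self.embedding_dim <= 0 or self.hidden_width <= 0:
            raise ValueError("embedding_dim and hidden_width must be positive")
        if self.nonlinearity not in ("tanh", "relu"):
            raise ValueError(f"unsupported nonlinearity {self.nonlinearity!r}")


@dataclass
class TrainingConfig:
    epochs: int = 150
    learning_rate: float = 0.1
    negatives_per_positive: int = 5
    batch_size: int = 512
    l2: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        for name in ("epochs", "learning_rate", "negatives_per_positive", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")


@dataclass
class RankedList:
    """Ordered candidate ranking for one query.

    Scores are non-increasing with rank; ranks are 1..n without gaps; ties
    are broken by lexicographic candidate id.
    """

    records: list[tuple[str, float, int]]
    query: dict = field(default_factory=dict)

    def candidate_ids(self) -> list[str]:
        return [r[0] for r in self.records]


class KGEModel:
    """Entity/relation embedding table plus scorer parameters."""

    def __init__(
        self,
        entity_ids: Sequence[str],
        relation_ids: Sequence[str],
        entity_types: Mapping[str, str],
        scorer_config: ScorerConfig,
        rng: np.random.Generator,
    ):
        scorer_config.validate()
        self.config = scorer_config
        self.entity_ids = sorted(entity_ids)
        self.relation_ids = sorted(relation_ids)
        self.entity_index = {e: i for i, e in enumerate(self.entity_ids)}
        self.relation_index = {r: i for i, r in enumerate(self.relation_ids)}
        self.entity_types = dict(entity_types)
        d = scorer_config.embedding_dim
        lim = 1.0 / np.sqrt(d)
        self.E = rng.uniform(-lim, lim, size=(len(self.entity_ids), d))
        self.R = rng.uniform(-lim, lim, size=(len(self.relation_ids), d))
        if scorer_config.architecture == "concat-mlp":
            h = scorer_config.hidden_width
            lim1 = np.sqrt(6.0 / (2 * d + h))
            lim2 = np.sqrt(6.0 / (h + d))
            self.W1 = rng.uniform(-lim1, lim1, size=(h, 2 * d))
            self.b1 = np.zeros(h)
            self.W2 = rng.uniform(-lim2, lim2, size=(d, h))
            self.b2 = np.zeros(d)
        self.loss_history: list[float] = []

    # -- scoring ---------------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.tanh(z) if self.config.nonlinearity == "tanh" else np.maximum(z, 0.0)

    def _act_grad(self, a: np.ndarray, z: np.ndarray) -> np.ndarray:
        return 1.0 - a * a if self.config.nonlinearity == "tanh" else (z > 0).astype(float)

    def project_query(self, h_idx: np.ndarray, r_idx: np.ndarray) -> np.ndarray:
        """concat-mlp query vector p(h, r) such that s = p . e_t."""
        X = np.concatenate([self.E[h_idx], self.R[r_idx]], axis=1)
        A = self._act(X @ self.W1.T + self.b1)
        U = A @ self.W2.T + self.b2
        return 1.0 / (1.0 + np.exp(-U))

    def score_indices(self, h_idx: np.ndarray, r_idx: np.ndarray, t_idx: np.ndarray) -> np.ndarray:
        arch = self.config.architecture
        if arch == "distmult":
            return np.sum(self.E[h_idx] * self.R[r_idx] * self.E[t_idx], axis=-1)
        if arch == "transe":
            diff = self.E[h_idx] + self.R[r_idx] - self.E[t_idx]
            return -np.linalg.norm(diff, axis=-1)
        P = self.project_query(h_idx, r_idx)
        return np.sum(P * self.E[t_idx], axis=-1)

    def _lookup_entity(self, eid: str) -> int:
        try:
            return self.entity_index[eid]
        except KeyError:
            raise LookupError_(f"unknown entity {eid!r}") from None

    def _lookup_relation(self, rel: str) -> int:
        try:
            return self.relation_index[rel]
        except KeyError:
            raise LookupError_(f"unknown relation {rel!r}") from None

    def score_triple(self, head_id: str, relation: str, tail_id: str) -> float:
        h = np.array([self._lookup_entity(head_id)])
        r = np.array([self._lookup_relation(relation)])
        t = np.array([self._lookup_entity(tail_id)])
        return float(self.score_indices(h, r, t)[0])

    def score_tails(self, head_id: str, relation: str, tail_ids: Sequence[str]) -> np.ndarray:
        h = self._lookup_entity(head_id)
        r = self._lookup_relation(relation)
        t_idx = np.array([self._lookup_entity(t) for t in tail_ids], dtype=int)
        if self.config.architecture == "concat-mlp":
            p = self.project_query(np.array([h]), np.array([r]))[0]
            return self.E[t_idx] @ p
        h_arr = np.full(len(t_idx), h)
        r_arr = np.full(len(t_idx), r)
        return self.score_indices(h_arr, r_arr, t_idx)

    # -- persistence -----------------------------------------------------

    FORMAT_TAG = "repurposekit-kge-v1"

    def save(self, path: str | Path) -> None:
        meta = {
            "format": self.FORMAT_TAG,
            "entity_ids": self.entity_ids,
            "relation_ids": self.relation_ids,
            "entity_types": self.entity_types,
            "config": vars(self.config),
        }
        arrays = {"E": self.E, "R": self.R}
        if self.config.architecture == "concat-mlp":
            arrays.update(W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2)
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "KGEModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("format") != cls.FORMAT_TAG:
                raise ValueError(f"unrecognized checkpoint format {meta.get('format')!r}")
            cfg = ScorerConfig(**meta["config"])
            model = cls.__new__(cls)
            model.config = cfg
            model.entity_ids = list(meta["entity_ids"])
            model.relation_ids = list(meta["relation_ids"])
            model.entity_index = {e: i for i, e in enumerate(model.entity_ids)}
            model.relation_index = {r: i for i, r in enumerate(model.relation_ids)}
            model.entity_types = dict(meta["entity_types"])
            model.E = z["E"]
            model.R = z["R"]
            if cfg.architecture == "concat-mlp":
                model.W1, model.b1 = z["W1"], z["b1"]
                model.W2, model.b2 = z["W2"], z["b2"]
            model.loss_history = []
        return model


def _with_inverses(triples: Iterable[TripleRecord]) -> list[tuple[str, str, str]]:
    out = []
    for t in triples:
        out.append((t.head_id, t.relation, t.tail_id))
        out.append((t.tail_id, t.relation + INVERSE_SUFFIX, t.head_id))
    return out


def train(
    train_triples: Sequence[TripleRecord],
    kg: KnowledgeGraph,
    scorer_config: ScorerConfig | None = None,
    training_config: TrainingConfig | None = None,
) -> KGEModel:
    """Fit embeddings and scorer parameters on the training triples.

    Deterministic given ``training_config.seed``. Per-epoch mean losses are
    recorded on ``model.loss_history``. Raises if the loss goes non-finite
    (learning rate too high).
    """
    scorer_config = scorer_config or ScorerConfig()
    training_config = training_config or TrainingConfig()
    scorer_config.validate()
    training_config.validate()
    if not train_triples:
        raise ValueError("train_triples is empty")

    rng = np.random.default_rng(training_config.seed)
    pairs = _with_inverses(train_triples)
    relations = sorted({r for _, r, _ in pairs})
    model = KGEModel(sorted(kg.entities.keys()), relations,
                     {e: rec.entity_type for e, rec in kg.entities.items()},
                     scorer_config, rng)

    H = np.array([model.entity_index[h] for h, _, _ in pairs], dtype=int)
    Rl = np.array([model.relation_index[r] for _, r, _ in pairs], dtype=int)
    T = np.array([model.entity_index[t] for _, _, t in pairs], dtype=int)
    known = set(zip(H.tolist(), Rl.tolist(), T.tolist()))
    n_pos = len(H)
    n_ent = len(model.entity_ids)
    k = training_config.negatives_per_positive
    lr = training_config.learning_rate
    l2 = training_config.l2
    arch = scorer_config.architecture

    accum = {"E": np.zeros_like(model.E), "R": np.zeros_like(model.R)}
    if arch == "concat-mlp":
        accum.update(
            W1=np.zeros_like(model.W1), b1=np.zeros_like(model.b1),
            W2=np.zeros_like(model.W2), b2=np.zeros_like(model.b2),
        )

    for epoch in range(training_config.epochs):
        order = rng.permutation(n_pos)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, n_pos, training_config.batch_size):
            idx = order[start : start + training_config.batch_size]
            bh, br, bt = H[idx], Rl[idx], T[idx]
            B = len(idx)
            # negatives: corrupt head or tail with equal probability,
            # resampling collisions with known true triples
            nh = np.repeat(bh, k)
            nr = np.repeat(br, k)
            nt = np.repeat(bt, k)
            corrupt_head = rng.random(B * k) < 0.5
            repl = rng.integers(0, n_ent, size=B * k)
            nh = np.where(corrupt_head, repl, nh)
            nt = np.where(corrupt_head, nt, repl)
            for _ in range(3):  # a few resampling passes; leftovers are rare
                bad = np.fromiter(
                    ((h, r, t) in known for h, r, t in zip(nh, nr, nt)),
                    dtype=bool, count=B * k,
                )
                if not bad.any():
                    break
                repl = rng.integers(0, n_ent, size=int(bad.sum()))
                heads_bad = corrupt_head & bad
                tails_bad = (~corrupt_head) & bad
                nh[heads_bad] = repl[: int(heads_bad.sum())]
                nt[tails_bad] = repl[int(heads_bad.sum()):]

            ah = np.concatenate([bh, nh])
            ar = np.concatenate([br, nr])
            at = np.concatenate([bt, nt])
            y = np.concatenate([np.ones(B), np.zeros(B * k)])
            loss = _adagrad_step(model, accum, ah, ar, at, y, lr, l2, arch)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; reduce learning_rate"
                )
            epoch_loss += loss * len(y)
            n_seen += len(y)
        model.loss_history.append(epoch_loss / n_seen)
    return model


def _adagrad_update(param: np.ndarray, grad: np.ndarray, acc: np.ndarray, lr: float) -> None:
    acc += grad * grad
    param -= lr * grad / (np.sqrt(acc) + 1e-8)


def _adagrad_step(model: KGEModel, accum: dict, h: np.ndarray, r: np.ndarray,
                  t: np.ndarray, y: np.ndarray, lr: float, l2: float, arch: str) -> float:
    """One mini-batch BCE Adagrad step; returns the mean batch loss."""
    E, R = model.E, model.R
    n = len(y)
    if arch == "concat-mlp":
        X = np.concatenate([E[h], R[r]], axis=1)
        Z = X @ model.W1.T + model.b1
        A = model._act(Z)
        U = A @ model.W2.T + model.b2
        P = 1.0 / (1.0 + np.exp(-U))
        s = np.sum(P * E[t], axis=1)
    elif arch == "distmult":
        s = np.sum(E[h] * R[r] * E[t], axis=1)
    else:  # transe
        diff = E[h] + R[r] - E[t]
        nrm = np.linalg.norm(diff, axis=1)
        s = -nrm

    # numerically stable BCE with logits
    loss = float(np.mean(np.maximum(s, 0) - s * y + np.log1p(np.exp(-np.abs(s)))))
    g = (1.0 / (1.0 + np.exp(-s)) - y) / n  # dL/ds

    dE = np.zeros_like(E)
    dR = np.zeros_like(R)
    if arch == "concat-mlp":
        dP = g[:, None] * E[t]
        np.add.at(dE, t, g[:, None] * P)
        dU = dP * P * (1.0 - P)
        dW2 = dU.T @ A
        db2 = dU.sum(axis=0)
        dA = dU @ model.W2
        dZ = dA * model._act_grad(A, Z)
        dW1 = dZ.T @ X
        db1 = dZ.sum(axis=0)
        dX = dZ @ model.W1
        d = E.shape[1]
        np.add.at(dE, h, dX[:, :d])
        np.add.at(dR, r, dX[:, d:])
        _adagrad_update(model.W2, dW2 + l2 * model.W2, accum["W2"], lr)
        _adagrad_update(model.b2, db2, accum["b2"], lr)
        _adagrad_update(model.W1, dW1 + l2 * model.W1, accum["W1"], lr)
        _adagrad_update(model.b1, db1, accum["b1"], lr)
    elif arch == "distmult":
        np.add.at(dE, h, g[:, None] * R[r] * E[t])
        np.add.at(dR, r, g[:, None] * E[h] * E[t])
        np.add.at(dE, t, g[:, None] * E[h] * R[r])
    else:
        safe = np.maximum(nrm, 1e-12)
        dd = -(g / safe)[:, None] * diff  # ds/ddiff = -diff/||diff||
        np.add.at(dE, h, dd)
        np.add.at(dR, r, dd)
        np.add.at(dE, t, -dd)

    touched_e = np.abs(dE).sum(axis=1, keepdims=True) > 0
    touched_r = np.abs(dR).sum(axis=1, keepdims=True) > 0
    _adagrad_update(model.E, dE + l2 * model.E * touched_e, accum["E"], lr)
    _adagrad_update(model.R, dR + l2 * model.R * touched_r, accum["R"], lr)
    return loss


def rank_tails(
    model: KGEModel,
    head_id: str,
    relation: str,
    candidate_type: str,
    known_triples: Iterable[tuple[str, str, str]] = (),
) -> RankedList:
    """Filtered tail ranking: score every entity of ``candidate_type``.

    Known true triples (h, r, c) other than the query itself are removed
    from the candidate pool (the standard "filtered" protocol). Ties are
    broken by lexicographic candidate id.
    """
    model._lookup_entity(head_id)
    model._lookup_relation(relation)
    candidates = sorted(
        e for e, ty in model.entity_types.items() if ty == candidate_type
    )
    filtered_out = {
        t for (h, r, t) in known_triples if h == head_id and r == relation
    }
    candidates = [c for c in candidates if c not in filtered_out]
    if not candidates:
        raise ValueError(
            f"empty candidate pool for type {candidate_type!r} after filtering"
        )
    scores = model.score_tails(head_id, relation, candidates)
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    records = [(candidates[i], float(scores[i]), rank + 1) for rank, i in enumerate(order)]
    return RankedList(
        records=records,
        query={"head": head_id, "relation": relation, "candidate_type": candidate_type},
    )


def rank_heads(
    model: KGEModel,
    relation: str,
    tail_id: str,
    candidate_type: str,
    known_triples: Iterable[tuple[str, str, str]] = (),
) -> RankedList:
    """Filtered head ranking via the internally trained inverse relation."""
    inv = relation + INVERSE_SUFFIX
    inv_known = [(t, inv, h) for (h, r, t) in known_triples if r == relation]
    rl = rank_tails(model, tail_id, inv, candidate_type, inv_known)
    rl.query = {"tail": tail_id, "relation": relation, "candidate_type": candidate_type}
    return rl


def evaluate_ranking(
    model: KGEModel,
    test_triples: Sequence[TripleRecord],
    known_triples: Iterable[tuple[str, str, str]] = (),
) -> dict:
    """Filtered MRR and Hits@k of the true tails among same-type candidates."""
    known = set(known_triples)
    rr = []
    hits1 = []
    hits10 = []
    for tr in test_triples:
        ttype = model.entity_types[tr.tail_id]
        pool_known = known - {(tr.head_id, tr.relation, tr.tail_id)}
        rl = rank_tails(model, tr.head_id, tr.relation, ttype, pool_known)
        rank = dict((c, k) for c, _s, k in rl.records)[tr.tail_id]
        rr.append(1.0 / rank)
        hits1.append(rank <= 1)
        hits10.append(rank <= 10)
    return {
        "MRR": float(np.mean(rr)),
        "Hits@1": float(np.mean(hits1)),
        "Hits@10": float(np.mean(hits10)),
        "n": len(test_triples),
    }


def random_baseline_mrr(pool_size: int) -> float:
    """Expected MRR of a uniformly random ranking over a pool of size m."""
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    return float(np.mean(1.0 / np.arange(1, pool_size + 1)))
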