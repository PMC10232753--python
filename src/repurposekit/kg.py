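"""Typed biomedical knowledge-graph assembly.

A knowledge graph here is a directed multigraph whose nodes are typed
biomedical entities (drug, gene, disease, phenotype, ...) and whose edges
carry semantic relation labels, e.g. ``(aspirin, target, PTGS2)``. Graphs
are assembled from tab-separated triple tables with columns

    head_id  head_type  relation  tail_id  tail_type  source

merged with optional alias maps, deduplicated, and split into
train/validation/test edge sets for link prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

TRIPLE_COLUMNS = ("head_id", "head_type", "relation", "tail_id", "tail_type", "source")


class SchemaError(ValueError):
    """A triple table is missing a required column."""


class RowError(ValueError):
    """One or more rows of a triple table are malformed."""


class MergeError(ValueError):
    """Alias map or entity typing is inconsistent during merge."""


@dataclass(frozen=True)
class EntityRecord:
    """A typed node: opaque identifier plus a type from the graph vocabulary."""

    entity_id: str
    entity_type: str
    display_name: str | None = None


@dataclass(frozen=True)
class TripleRecord:
    """A directed edge ``(head, relation, tail)`` with a provenance tag."""

    head_id: str
    relation: str
    tail_id: str
    source: str = ""

    def key(self) -> tuple[str, str, str]:
        return (self.head_id, self.relation, self.tail_id)


@dataclass
class KnowledgeGraph:
    """Deduplicated entity/relation/triple store with adjacency indexes.

    Invariants: every triple endpoint resolves to an entity; no duplicate
    (head, relation, tail); per-type and per-relation counts sum to totals.
    """

    entities: dict[str, EntityRecord] = field(default_factory=dict)
    triples: list[TripleRecord] = field(default_factory=list)
    _triple_keys: set[tuple[str, str, str]] = field(default_factory=set, repr=False)
    _by_head: dict[tuple[str, str], list[TripleRecord]] = field(default_factory=dict, repr=False)
    _by_tail: dict[tuple[str, str], list[TripleRecord]] = field(default_factory=dict, repr=False)

    @property
    def relations(self) -> list[str]:
        return sorted({t.relation for t in self.triples})

    @property
    def entity_types(self) -> list[str]:
        return sorted({e.entity_type for e in self.entities.values()})

    def add_entity(self, rec: EntityRecord) -> None:
        prev = self.entities.get(rec.entity_id)
        if prev is not None:
            if prev.entity_type != rec.entity_type:
                raise MergeError(
                    f"conflicting types for entity {rec.entity_id!r}: "
                    f"{prev.entity_type!r} vs {rec.entity_type!r}"
                )
            return
        self.entities[rec.entity_id] = rec

    def add_triple(self, rec: TripleRecord) -> bool:
        """Add a triple if not present; returns True if it was new."""
        for eid in (rec.head_id, rec.tail_id):
            if eid not in self.entities:
                raise MergeError(f"dangling endpoint {eid!r}")
        k = rec.key()
        if k in self._triple_keys:
            return False
        self._triple_keys.add(k)
        self.triples.append(rec)
        self._by_head.setdefault((rec.head_id, rec.relation), []).append(rec)
        self._by_tail.setdefault((rec.tail_id, rec.relation), []).append(rec)
        return True

    def has_triple(self, head_id: str, relation: str, tail_id: str) -> bool:
        return (head_id, relation, tail_id) in self._triple_keys

    def tails_of(self, head_id: str, relation: str) -> list[str]:
        return [t.tail_id for t in self._by_head.get((head_id, relation), [])]

    def heads_of(self, tail_id: str, relation: str) -> list[str]:
        return [t.head_id for t in self._by_tail.get((tail_id, relation), [])]

    def entities_of_type(self, entity_type: str) -> list[str]:
        return sorted(e.entity_id for e in self.entities.values() if e.entity_type == entity_type)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_triples(self) -> int:
        return len(self.triples)


@dataclass
class EdgeSplit:
    """Disjoint train/validation/test triple subsets whose union is the graph.

    Every entity appearing in validation or test also appears in at least one
    training triple (otherwise rank evaluation of that entity is undefined);
    violating triples are reassigned to train and counted in ``reassigned``.
    """

    train: list[TripleRecord]
    validation: list[TripleRecord]
    test: list[TripleRecord]
    seed: int
    reassigned: int = 0


def load_triple_table(
    source: str | Path | TextIO,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[TripleRecord], list[EntityRecord]]:
    """Read a triple TSV into records.

    ``schema`` optionally maps the canonical column names in
    :data:`TRIPLE_COLUMNS` to the file's actual header names. Rows are kept
    as-is (duplicates retained — deduplication happens at merge); entity
    records are deduplicated. Comment lines start with ``#``.
    """
    schema = dict(schema or {})
    close = False
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        lines = [ln.rstrip("\n") for ln in fh]
    finally:
        if close:
            fh.close()

    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise SchemaError("empty triple table (no header)")
    header = rows[0][1].split("\t")
    colmap: dict[str, int] = {}
    for canon in TRIPLE_COLUMNS:
        name = schema.get(canon, canon)
        if name not in header:
            raise SchemaError(f"missing column {name!r} (for {canon!r}); header={header}")
        colmap[canon] = header.index(name)

    triples: list[TripleRecord] = []
    entities: dict[str, EntityRecord] = {}
    errors: list[str] = []
    for lineno, ln in rows[1:]:
        parts = ln.split("\t")
        if len(parts) < len(header):
            errors.append(f"line {lineno}: expected {len(header)} fields, got {len(parts)}")
            continue
        vals = {c: parts[colmap[c]].strip() for c in TRIPLE_COLUMNS}
        if not vals["head_id"] or not vals["tail_id"]:
            errors.append(f"line {lineno}: empty entity id")
            continue
        if not vals["relation"] or not vals["head_type"] or not vals["tail_type"]:
            errors.append(f"line {lineno}: empty relation or type label")
            continue
        triples.append(
            TripleRecord(vals["head_id"], vals["relation"], vals["tail_id"], vals["source"])
        )
        for eid, etype in ((vals["head_id"], vals["head_type"]), (vals["tail_id"], vals["tail_type"])):
            prev = entities.get(eid)
            if prev is None:
                entities[eid] = EntityRecord(eid, etype)
            elif prev.entity_type != etype:
                errors.append(f"line {lineno}: entity {eid!r} typed {etype!r} but earlier {prev.entity_type!r}")
    if errors:
        raise RowError("triple table has malformed rows:\n  " + "\n  ".join(errors))
    return triples, sorted(entities.values(), key=lambda e: e.entity_id)


def standardize_and_merge(
    tables: Sequence[tuple[Sequence[TripleRecord], Sequence[EntityRecord]]],
    id_map: Mapping[str, str] | None = None,
) -> KnowledgeGraph:
    """Rewrite aliases to canonical ids, merge tables, deduplicate triples.

    ``id_map`` maps alias -> canonical id. An alias whose canonical id is
    itself an alias is a cycle/chain and rejected; conflicting entity types
    for one canonical id raise :class:`MergeError`.
    """
    id_map = dict(id_map or {})
    for alias, canon in id_map.items():
        if canon in id_map and id_map[canon] != canon:
            raise MergeError(f"alias chain/cycle: {alias!r} -> {canon!r} -> {id_map[canon]!r}")

    def canon(eid: str) -> str:
        return id_map.get(eid, eid)

    kg = KnowledgeGraph()
    for triples, entities in tables:
        for e in entities:
            kg.add_entity(EntityRecord(canon(e.entity_id), e.entity_type, e.display_name))
    for triples, _entities in tables:
        for t in triples:
            kg.add_triple(TripleRecord(canon(t.head_id), t.relation, canon(t.tail_id), t.source))
    return kg


def graph_summary(kg: KnowledgeGraph) -> dict:
    """Counts per entity type and per relation, plus totals.

    Per-type counts sum to ``n_entities``; per-relation to ``n_triples``.
    """
    by_type: dict[str, int] = {}
    for e in kg.entities.values():
        by_type[e.entity_type] = by_type.get(e.entity_type, 0) + 1
    by_rel: dict[str, int] = {}
    for t in kg.triples:
        by_rel[t.relation] = by_rel.get(t.relation, 0) + 1
    return {
        "n_entities": kg.n_entities,
        "n_triples": kg.n_triples,
        "n_entity_types": len(by_type),
        "n_relations": len(by_rel),
        "entities_by_type": dict(sorted(by_type.items())),
        "triples_by_relation": dict(sorted(by_rel.items())),
    }


def split_edges(
    kg: KnowledgeGraph,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> EdgeSplit:
    """Random train/validation/test split of the graph's triples.

    Enforces that every entity in validation/test occurs in at least one
    training triple: offending triples are moved back to train (counted).
    """
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    triples = sorted(kg.triples, key=lambda t: t.key())
    order = rng.permutation(len(triples))
    n = len(triples)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train = [triples[i] for i in order[:n_train]]
    val = [triples[i] for i in order[n_train : n_train + n_val]]
    test = [triples[i] for i in order[n_train + n_val :]]

    reassigned = 0
    for _ in range(n):  # iterate to fixpoint; each pass can only shrink val/test
        seen = {e for t in train for e in (t.head_id, t.tail_id)}
        moved = False
        for subset in (val, test):
            keep = []
            for t in subset:
                if t.head_id in seen and t.tail_id in seen:
                    keep.append(t)
                else:
                    train.append(t)
                    seen.update((t.head_id, t.tail_id))
                    reassigned += 1
                    moved = True
            subset[:] = keep
        if not moved:
            break
    held_out_requested = (n_val > 0) or (n - n_train - n_val > 0)
    if held_out_requested and not val and not test:
        raise ValueError("graph too small to satisfy entity-coverage constraint for held-out splits")
    return EdgeSplit(train=train, validation=val, test=test, seed=seed, reassigned=reassigned)


def write_triples(kg_or_triples: KnowledgeGraph | Iterable[TripleRecord], path: str | Path,
                  entity_types: Mapping[str, str] | None = None) -> None:
    """Write triples to the TSV dialect read by :func:`load_triple_table`."""
    if isinstance(kg_or_triples, KnowledgeGraph):
        triples = kg_or_triples.triples
        types = {eid: e.entity_type for eid, e in kg_or_triples.entities.items()}
    else:
        triples = list(kg_or_triples)
        if entity_types is None:
            raise ValueError("entity_types required when writing bare triples")
        types = dict(entity_types)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRIPLE_COLUMNS) + "\n")
        for t in triples:
            fh.write(
                f"{t.head_id}\t{types[t.head_id]}\t{t.relation}\t{t.tail_id}\t{types[t.tail_id]}\t{t.source}\n"
            )


def write_summary(summary: dict, path_tsv: str | Path | None = None,
                  path_json: str | Path | None = None) -> None:
    if path_json is not None:
        Path(path_json).write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    if path_tsv is not None:
        lines = ["kind\tlabel\tcount"]
        for k, v in summary["entities_by_type"].items():
            lines.append(f"entity_type\t{k}\t{v}")
        for k, v in summary["triples_by_relation"].items():
            lines.append(f"relation\t{k}\t{v}")
        lines.append(f"total\tentities\t{summary['n_entities']}")
        lines.append(f"total\ttriples\t{summary['n_triples']}")
        Path(path_tsv).write_text("\n".join(lines) + "\n", encoding="utf-8")
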