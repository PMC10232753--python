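"""Synthetic knowledge graphs with planted drug-gene-disease mechanism blocks.

The generator partitions drugs and genes into latent "mechanism" communities
(blocks). A drug targets genes of its own block with probability ``p_in`` and
genes of other blocks with probability ``p_noise``; diseases and phenotypes
attach to blocks through gene-disease and gene-phenotype edges, so the
emitted graph exercises at least four node types and four relations. A
configurable fraction of the planted within-block drug->gene ``target`` edges
is withheld from the emitted graph and recorded as ground truth, giving the
embedding and ranking stages a known set of recoverable links.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg import EntityRecord, KnowledgeGraph, TripleRecord

TARGET_RELATION = "target"


@dataclass
class KGSimConfig:
    """Study-condition knob set for the planted-block knowledge graph."""

    n_drugs: int = 120
    n_genes: int = 240
    n_diseases: int = 36
    n_phenotypes: int = 48
    n_blocks: int = 12
    p_in: float = 0.5          # within-block drug->gene target probability
    p_noise: float = 0.005     # cross-block target probability
    p_gene_disease: float = 0.5
    p_gene_phenotype: float = 0.3
    p_treats: float = 0.3      # drug->disease within-block treatment edge
    holdout_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_in", "p_noise", "p_gene_disease", "p_gene_phenotype",
                     "p_treats", "holdout_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_drugs", "n_genes", "n_diseases", "n_phenotypes", "n_blocks"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.p_in == 0.0 and self.p_noise == 0.0:
            raise ValueError("config implies zero plantable target edges (p_in = p_noise = 0)")


@dataclass
class PlantedTruth:
    """Ground truth of a generated graph: block labels and planted edges."""

    blocks: dict[str, int]
    planted_target_edges: list[tuple[str, str]]      # all planted (drug, gene)
    held_out_edges: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "blocks": self.blocks,
                    "planted_target_edges": [list(e) for e in self.planted_target_edges],
                    "held_out_edges": [list(e) for e in self.held_out_edges],
                },
                indent=1,
            )
            + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            blocks=d["blocks"],
            planted_target_edges=[tuple(e) for e in d["planted_target_edges"]],
            held_out_edges=[tuple(e) for e in d["held_out_edges"]],
        )


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_kg(config: KGSimConfig) -> tuple[KnowledgeGraph, PlantedTruth]:
    """Sample a planted-block knowledge graph; deterministic under the seed.

    Held-out target edges are absent from the returned graph but listed in
    the returned :class:`PlantedTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    drugs = _ids("DRUG:", config.n_drugs)
    genes = _ids("GENE:", config.n_genes)
    diseases = _ids("DIS:", config.n_diseases)
    phenos = _ids("PHE:", config.n_phenotypes)

    blocks: dict[str, int] = {}
    for pool in (drugs, genes, diseases):
        for i, eid in enumerate(pool):
            blocks[eid] = i % config.n_blocks
    # phenotypes attach to blocks too (via their genes)
    for i, eid in enumerate(phenos):
        blocks[eid] = i % config.n_blocks

    kg = KnowledgeGraph()
    for eid in drugs:
        kg.add_entity(EntityRecord(eid, "drug"))
    for eid in genes:
        kg.add_entity(EntityRecord(eid, "gene"))
    for eid in diseases:
        kg.add_entity(EntityRecord(eid, "disease"))
    for eid in phenos:
        kg.add_entity(EntityRecord(eid, "phenotype"))

    # planted drug -> gene target edges (block model)
    planted: list[tuple[str, str]] = []
    u = rng.random((config.n_drugs, config.n_genes))
    for i, d in enumerate(drugs):
        for j, g in enumerate(genes):
            p = config.p_in if blocks[d] == blocks[g] else config.p_noise
            if u[i, j] < p:
                planted.append((d, g))
    if not planted:
        raise ValueError("no target edges realized; raise p_in/p_noise or sizes")

    # hold out a fraction of the *within-block* planted edges
    within = [e for e in planted if blocks[e[0]] == blocks[e[1]]]
    n_hold = int(round(config.holdout_fraction * len(within)))
    hold_idx = set(rng.choice(len(within), size=n_hold, replace=False)) if n_hold else set()
    held_out = [within[i] for i in sorted(hold_idx)]
    held_set = set(held_out)

    for d, g in planted:
        if (d, g) not in held_set:
            kg.add_triple(TripleRecord(d, TARGET_RELATION, g, "synthetic"))

    # gene -> disease / phenotype attachments within block
    for g in genes:
        for dis in diseases:
            if blocks[g] == blocks[dis] and rng.random() < config.p_gene_disease:
                kg.add_triple(TripleRecord(g, "associated_with", dis, "synthetic"))
        for ph in phenos:
            if blocks[g] == blocks[ph] and rng.random() < config.p_gene_phenotype:
                kg.add_triple(TripleRecord(g, "has_phenotype", ph, "synthetic"))
    # drug -> disease treatment edges within block
    for d in drugs:
        for dis in diseases:
            if blocks[d] == blocks[dis] and rng.random() < config.p_treats:
                kg.add_triple(TripleRecord(d, "treats", dis, "synthetic"))

    return kg, PlantedTruth(blocks=blocks, planted_target_edges=planted, held_out_edges=held_out)
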