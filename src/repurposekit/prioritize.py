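"""Target-based drug prioritization against a disease gene set.

Given a trained triple scorer and a set of disease-associated genes, every
drug-type entity is scored against every mapped gene through the drug ->
``target`` -> gene relation, and the per-gene scores are aggregated (mean by
default) into a single ranking. This is the repurposing query: drugs whose
embeddings predict links to the disease genes rise to the top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embedding import INVERSE_SUFFIX, KGEModel
from .kg import KnowledgeGraph

#: Diabetic-cataract-associated gene symbols used as the reference query
#: (literature-curated; 12 distinct symbols).
DM_CATARACT_GENES = (
    "CCDC102A", "CRYAA", "KIAA1671", "PPARD", "AKR1B1", "RPS6KA2",
    "CACNA1C", "VEGFA", "VARS1", "MMP2", "TAC1", "G6PD",
)

AGGREGATIONS = ("mean", "max", "rank-sum")


@dataclass
class GeneSetQuery:
    """A gene-set query resolved against a graph's gene entities."""

    gene_symbols: list[str]
    mapped_ids: list[str]
    unmapped: list[str]
    relation: str = "target"


@dataclass
class DrugRanking:
    """Aggregate drug ranking plus the per-gene score matrix behind it."""

    records: list[tuple[str, float, int]]        # (drug_id, aggregate, rank)
    aggregation: str
    drug_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    score_matrix: np.ndarray | None = None       # drugs x genes


def build_gene_set_query(
    symbols: Sequence[str],
    kg: KnowledgeGraph,
    relation: str = "target",
) -> GeneSetQuery:
    """Resolve gene symbols against the graph; unmapped symbols are reported,
    never silently dropped. Duplicate symbols are removed with a warning."""
    if not symbols:
        raise ValueError("empty gene symbol list")
    seen: list[str] = []
    for s in symbols:
        s = s.strip()
        if not s:
            continue
        if s in seen:
            warnings.warn(f"duplicate gene symbol {s!r} removed", stacklevel=2)
        else:
            seen.append(s)
    gene_ids = set(kg.entities_of_type("gene"))
    mapped = [s for s in seen if s in gene_ids]
    unmapped = [s for s in seen if s not in gene_ids]
    if not mapped:
        raise ValueError(f"none of the {len(seen)} gene symbols map to graph gene entities")
    return GeneSetQuery(gene_symbols=seen, mapped_ids=mapped, unmapped=unmapped, relation=relation)


def prioritize_drugs(
    model: KGEModel,
    kg: KnowledgeGraph,
    query: GeneSetQuery,
    aggregation: str = "mean",
    exclude_known_targeters: bool = False,
) -> DrugRanking:
    """Score every drug against every mapped query gene and aggregate.

    The query direction is (drug, target, gene): for each gene the model
    ranks candidate drugs as heads, realized through the internally trained
    inverse relation. Drugs already linked to query genes are kept in the
    ranking by default (repurposing wants known targeters to surface);
    ``exclude_known_targeters`` drops them instead.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}, got {aggregation!r}")
    drugs = kg.entities_of_type("drug")
    if not drugs:
        raise ValueError("graph contains no drug-type entities")
    if exclude_known_targeters:
        known = {
            h for g in query.mapped_ids for h in kg.heads_of(g, query.relation)
        }
        drugs = [d for d in drugs if d not in known]
        if not drugs:
            raise ValueError("all drugs excluded as known targeters")

    inv = query.relation + INVERSE_SUFFIX
    mat = np.empty((len(drugs), len(query.mapped_ids)))
    for j, gene in enumerate(query.mapped_ids):
        mat[:, j] = model.score_tails(gene, inv, drugs)

    if aggregation == "mean":
        agg = mat.mean(axis=1)
    elif aggregation == "max":
        agg = mat.max(axis=1)
    else:  # rank-sum: lower summed per-gene rank is better; negate so that
        # higher aggregate = better, preserving the ordering contract
        ranks = np.empty_like(mat)
        for j in range(mat.shape[1]):
            order = np.argsort(-mat[:, j], kind="stable")
            ranks[order, j] = np.arange(1, len(drugs) + 1)
        agg = -ranks.sum(axis=1)

    order = sorted(range(len(drugs)), key=lambda i: (-agg[i], drugs[i]))
    records = [(drugs[i], float(agg[i]), rank + 1) for rank, i in enumerate(order)]
    return DrugRanking(
        records=records,
        aggregation=aggregation,
        drug_ids=drugs,
        gene_ids=list(query.mapped_ids),
        score_matrix=mat,
    )


def top_k(ranking: DrugRanking, k: int) -> list[str]:
    """First min(k, n) drug ids in rank order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [r[0] for r in ranking.records[:k]]


def write_ranking(ranking: DrugRanking, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdrug_id\taggregate_score\tn_genes_scored\n")
        n_genes = len(ranking.gene_ids)
        for drug, score, rank in ranking.records:
            fh.write(f"{rank}\t{drug}\t{score:.6g}\t{n_genes}\n")
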