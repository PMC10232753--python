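"""End-to-end orchestration of the repurposing strategy on synthetic data.

Stages run in the strategy's order: build/simulate the knowledge graph,
train the triple scorer, rank drugs against the query gene set, then
emulate the retrospective cohort study (eligibility, propensity matching,
balance diagnostics) and fit windowed Cox models with risk/RRR summaries.
A single run seed fans out to per-stage seeds by fixed offsets so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .embedding import ScorerConfig, TrainingConfig, evaluate_ranking, train
from .kg import KnowledgeGraph, graph_summary, split_edges, write_summary, write_triples
from .matching import (
    CohortSpec,
    balance_table,
    build_cohorts,
    covariate_matrix,
    estimate_propensity,
    greedy_match,
    write_balance,
    write_consort,
)
from .prioritize import build_gene_set_query, prioritize_drugs, write_ranking
from .simulate_ehr import EHRSimConfig, generate_population
from .simulate_kg import KGSimConfig, generate_kg
from .survival import cox_fit, forest_table, rrr_trend, truncate_follow_up, window_risks

KG_SEED_OFFSET = 0
TRAIN_SEED_OFFSET = 1
EHR_SEED_OFFSET = 2


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    kg_sim: KGSimConfig = field(default_factory=KGSimConfig)
    scorer: ScorerConfig = field(default_factory=ScorerConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    ehr_sim: EHRSimConfig = field(default_factory=EHRSimConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    genes: list[str] | None = None       # query symbols; None = block-0 genes
    genes_file: str | None = None
    n_query_genes: int = 12
    aggregation: str = "mean"
    top_k: int = 10
    caliper: float = 0.1
    windows: tuple[float, ...] = (5.0, 10.0, 20.0)
    subgroups: tuple[str, ...] = ("all",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        for fld in dataclasses.fields(cls):
            if fld.name not in raw:
                continue
            v = raw[fld.name]
            sub = {"kg_sim": KGSimConfig, "scorer": ScorerConfig,
                   "training": TrainingConfig, "ehr_sim": EHRSimConfig,
                   "cohort": CohortSpec}.get(fld.name)
            if sub is not None:
                v = sub(**v)
            elif fld.name in ("windows", "subgroups"):
                v = tuple(v)
            kwargs[fld.name] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: RunConfig, check_files: bool = True) -> list[str]:
    """Enumerate every problem with the config (empty list = valid).

    ``check_files=False`` skips filesystem checks; stages then surface
    missing files themselves, named by stage.
    """
    problems: list[str] = []
    for name, sub in (("kg_sim", config.kg_sim), ("scorer", config.scorer),
                      ("training", config.training), ("ehr_sim", config.ehr_sim)):
        try:
            sub.validate()
        except ValueError as exc:
            problems.append(f"{name}: {exc}")
    problems.extend(f"cohort: {p}" for p in config.cohort.validate())
    if any(w <= 0 for w in config.windows):
        problems.append(f"windows: non-positive follow-up window in {config.windows}")
    if config.caliper < 0:
        problems.append("caliper: must be non-negative")
    if config.top_k < 1:
        problems.append("top_k: must be >= 1")
    if config.aggregation not in ("mean", "max", "rank-sum"):
        problems.append(f"aggregation: unknown method {config.aggregation!r}")
    for sg in config.subgroups:
        if sg not in ("all", "female", "male"):
            problems.append(f"subgroups: unknown subgroup {sg!r}")
    if check_files and config.genes_file is not None and not Path(config.genes_file).exists():
        problems.append(f"genes_file: {config.genes_file} does not exist")
    return problems


def _query_symbols(config: RunConfig, kg: KnowledgeGraph, truth) -> list[str]:
    if config.genes_file is not None:
        path = Path(config.genes_file)
        if not path.exists():
            raise FileNotFoundError(f"genes file {path} does not exist")
        return [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if config.genes is not None:
        return list(config.genes)
    # default demo query: genes of the first mechanism block
    block0 = [g for g in kg.entities_of_type("gene") if truth.blocks.get(g) == 0]
    return block0[: config.n_query_genes]


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Outputs: ranking.tsv, consort.tsv, balance.tsv, forest.tsv, rrr.tsv,
    run.log (plus graph_summary.json and truth/eval JSON sidecars).
    Identical config + seed produce byte-identical TSVs.
    """
    problems = validate_config(config, check_files=False)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"repurposekit {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]

    def _log(msg: str) -> None:
        log.append(msg)
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")

    # --- stage 1: knowledge graph -------------------------------------
    stage = "simulate-kg"
    try:
        kg_cfg = dataclasses.replace(config.kg_sim, seed=config.seed + KG_SEED_OFFSET)
        kg, truth = generate_kg(kg_cfg)
        write_triples(kg, out / "triples.tsv")
        truth.to_json(out / "truth.json")
        summ = graph_summary(kg)
        write_summary(summ, out / "graph_summary.tsv", out / "graph_summary.json")
        _log(f"{stage}: {summ['n_entities']} entities, {summ['n_triples']} triples")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 2: embedding training ----------------------------------
    stage = "train"
    try:
        split = split_edges(kg, (0.9, 0.0, 0.1), seed=config.seed)
        train_cfg = dataclasses.replace(config.training, seed=config.seed + TRAIN_SEED_OFFSET)
        model = train(split.train, kg, config.scorer, train_cfg)
        known = {(t.head_id, t.relation, t.tail_id) for t in kg.triples}
        metrics = evaluate_ranking(model, split.test[:200], known)
        (out / "link_eval.json").write_text(json.dumps(metrics, indent=1) + "\n", encoding="utf-8")
        _log(f"{stage}: final loss {model.loss_history[-1]:.4f}, filtered MRR {metrics['MRR']:.3f}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 3: drug ranking ----------------------------------------
    stage = "rank-drugs"
    try:
        symbols = _query_symbols(config, kg, truth)
        query = build_gene_set_query(symbols, kg)
        ranking = prioritize_drugs(model, kg, query, aggregation=config.aggregation)
        write_ranking(ranking, out / "ranking.tsv")
        top = [r[0] for r in ranking.records[: config.top_k]]
        _log(f"{stage}: {len(query.mapped_ids)} mapped genes, top-{config.top_k}: {', '.join(top)}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 4: cohorts + matching ----------------------------------
    stage = "run-cohort"
    try:
        ehr_cfg = dataclasses.replace(config.ehr_sim, seed=config.seed + EHR_SEED_OFFSET)
        patients = generate_population(ehr_cfg).set_index("patient_id")
        exposed, control, consort = build_cohorts(patients, config.cohort)
        write_consort(consort, out / "consort.tsv")
        prop = estimate_propensity(exposed, control)
        matched = greedy_match(prop.scores.loc[exposed.index], prop.scores.loc[control.index],
                               caliper=config.caliper)
        me = exposed.loc[matched.exposed_ids]
        mc = control.loc[matched.control_ids]
        rows = balance_table(me, mc)
        write_balance(rows, out / "balance.tsv")
        pd.DataFrame(matched.pairs, columns=["exposed_id", "control_id", "score_diff"]).to_csv(
            out / "pairs.csv", index=False
        )
        _log(f"{stage}: {len(matched.pairs)} matched pairs "
             f"({matched.n_unmatched_exposed} exposed unmatched)")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 5: survival --------------------------------------------
    stage = "survival"
    try:
        fits = {}
        risk_by_window = []
        for subgroup in config.subgroups:
            sme, smc = me, mc
            if subgroup in ("female", "male"):
                sme = me[me["sex"] == subgroup]
                smc = mc[mc["sex"] == subgroup]
            rec = pd.concat([sme.assign(arm=1), smc.assign(arm=0)])
            for window in config.windows:
                tr = truncate_follow_up(rec, window)
                fit = cox_fit(tr)
                risk = window_risks(rec, window)
                fits[("drugA", "all", window, subgroup)] = (fit, risk)
                if subgroup == "all":
                    risk_by_window.append(risk)
        forest = forest_table(fits)
        forest.to_csv(out / "forest.tsv", sep="\t", index=False, float_format="%.6g")
        trend, label = rrr_trend(risk_by_window)
        trend.insert(0, "group", "all")
        trend.insert(0, "drug", "drugA")
        trend.to_csv(out / "rrr.tsv", sep="\t", index=False, float_format="%.6g")
        _log(f"{stage}: {len(forest)} forest rows, RRR trend {label}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _log("done")
    return out
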