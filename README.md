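# repurposekit

Computational drug repurposing in two stages, as used in knowledge-graph +
EHR corroboration studies (e.g. nominating repurposing candidates against
diabetic-cataract genes and then emulating a retrospective trial of each
candidate on patient records):

1. **Candidate prediction.** A heterogeneous biomedical knowledge graph
   (drugs, genes, diseases, phenotypes linked by typed relations) is
   embedded; a concatenate-and-predict scorer ranks triples
   `(drug, target, gene)`, and every drug is scored against a disease gene
   set to produce a repurposing ranking.
2. **Clinical corroboration.** For a candidate drug, an EHR-style cohort
   study is emulated: exposure and control cohorts under eligibility rules
   (same indication, no prior outcome), 1:1 greedy propensity matching with
   a caliper, standardized-mean-difference (SMD) balance tables, Cox
   proportional-hazards hazard ratios over 5/10/20-year windows, and
   relative-risk-reduction (RRR) trends.

Because the real inputs of such studies (licensed interaction databases,
proprietary EHR platforms) are not redistributable, the package ships first-class
synthetic generators: a planted-block knowledge graph with known held-out
true edges, and a patient simulator with confounding-by-indication
exposure and a configurable true hazard ratio. Every stage is validated
against these known truths.

## The models

**Triple scoring.** Each entity and relation gets an embedding
`e ∈ R^d`. The default scorer projects the concatenated head/relation
embeddings through one hidden layer and matches the result against the
tail embedding:

    s(h, r, t) = σ(W₂ tanh(W₁ [e_h; e_r] + b₁) + b₂) · e_t

trained with binary cross-entropy against uniformly corrupted heads/tails
(DistMult `Σₖ hₖrₖtₖ` and TransE `−‖e_h+e_r−e_t‖` are included as
closed-form baselines/oracles). Ranking uses the filtered protocol: known
true triples are removed from candidate pools. A gene-set query scores
every drug against every query gene via the `target` relation and
aggregates (mean by default).

**Cohort emulation.** Propensity scores are maximum-likelihood logistic
regressions of exposure on the Table-1-style covariate list; matching is
greedy nearest-neighbor, 1:1, without replacement, within a caliper of
0.1 on the score scale. Balance uses the pooled-variance SMD,

    SMD_cont = |m₁−m₀| / √((s₁²+s₀²)/2),   SMD_bin = |p₁−p₀| / √((p₁(1−p₁)+p₀(1−p₀))/2)

with SMD > 0.1 flagging imbalance. Hazard ratios come from an in-package
Newton–Raphson Cox partial-likelihood engine (Breslow default, Efron
available), `HR = exp(β̂)` with Wald 95% CI; window risks are plain
proportions and `RRR = 1 − risk_exposed/risk_control`.

## Worked example

```bash
python examples/01_rank_drugs.py
```

```
graph: 444 entities, 1838 triples, 245 held-out target edges
training loss 0.527 -> 0.080
filtered MRR on held-out edges: 0.284 (random baseline 0.025) — higher means
the planted drug-gene structure was recovered

top 10 drugs for the block-0 gene set (block-0 drugs are the truth):
   1. DRUG:036  score 2.103  block 0
   2. DRUG:012  score 2.076  block 0
   ...
  10. DRUG:108  score 1.278  block 0
```

All ten top-ranked drugs belong to the mechanism block whose genes were
queried: the scorer recovered the planted drug–gene structure from the
training edges alone (MRR 0.284 is ~11× the random-ranking expectation).

```bash
python examples/03_survival_windows.py
```

```
true HR 0.71; 2666 matched pairs

   5y: HR 0.87 (95% CI 0.79-0.96)  risks 26.5% vs 29.9%  RRR 11.4%
  10y: HR 0.86 (95% CI 0.80-0.93)  risks 45.0% vs 50.0%  RRR 10.0%
  20y: HR 0.85 (95% CI 0.80-0.91)  risks 68.2% vs 73.7%  RRR 7.5%
```

The matched estimate moves most of the way from the confounded crude
association back toward the simulated truth (see `docs/methods.md` on the
residual gap from incomplete balance and hazard-ratio non-collapsibility).

Other examples: `02_matched_cohort.py` (CONSORT counts and before/after
SMD balance), `04_end_to_end.py` (the full pipeline writing
`ranking.tsv`, `consort.tsv`, `balance.tsv`, `forest.tsv`, `rrr.tsv`,
`run.log`). The same stages are available as a CLI:
`repurposekit run-all --seed 1 --out results/demo`.

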