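# Methods

## Overview

The package implements a two-stage drug-repurposing analysis: (1) link
prediction on a typed biomedical knowledge graph to rank drugs against a
disease gene set, and (2) an emulated retrospective cohort study of a
candidate drug on patient-level records — propensity matching, balance
diagnostics, windowed Cox hazard ratios, and relative-risk-reduction
trends. Both stages are exercised end to end on synthetic inputs whose
ground truth is known, so every estimator can be checked against the
quantity it is supposed to recover.

## Knowledge graph and triple scorer

A graph is a deduplicated set of directed triples `(head, relation,
tail)` over typed entities. Entity-type and relation vocabularies are
configuration, not constants: real graphs of this kind mix drug, gene,
disease, phenotype, tissue, pathway and ontology-term nodes under several
semantic relations, and nothing in the algorithms depends on which
vocabulary is used. Merging rewrites aliases to canonical identifiers and
treats conflicting entity types as errors rather than silent overwrites,
since a type flip usually signals an upstream provenance problem.

Edge splits for evaluation enforce that every entity in a held-out triple
also occurs in training (rank evaluation of a never-seen entity is
undefined); violating triples are reassigned to the training set and the
count is reported.

The scorer learns one d-dimensional embedding per entity and relation
(default d = 32, initialized uniformly in ±1/√d). The default
architecture concatenates the head and relation embeddings, projects them
through one hidden layer (width 64, tanh), squashes with a logistic
sigmoid, and takes the inner product with the tail embedding. This
realizes the concatenate-then-predict pattern while keeping tail ranking
cheap: one projector forward pass, then a single matrix–vector product
over all candidate tails. DistMult and TransE are included because they
have closed forms that an independent oracle can recompute exactly, which
pins down the scoring plumbing.

Training minimizes binary cross-entropy of true triples against
corruptions: for each positive, five corruptions sample a uniformly
random replacement head or tail (equal probability), resampling
collisions with known true triples. Inverse relations (`r__inv`) are
added to the training stream so that head ranking reduces to tail ranking
on the inverse relation. The optimizer is mini-batch Adagrad (rate 0.1,
batch 512, 150 epochs, L2 1e-6). Plain fixed-rate gradient descent was
the first choice but stalls here: with small random embeddings the raw
gradient magnitudes are orders of magnitude below the parameter scale,
and a fixed rate that moves them also destabilizes the MLP weights.
Adagrad's per-parameter normalization removes that sensitivity while
keeping the run deterministic under the seed. A non-finite epoch loss
aborts training with a diagnostic rather than continuing silently.

Ranking is filtered (known true triples leave the candidate pool) and
type-restricted; ties break lexicographically by entity id so results are
reproducible. Gene-set prioritization scores every drug against every
mapped query gene via the target relation and aggregates with the mean by
default (max and rank-sum are available for sensitivity analysis). Drugs
already known to target query genes are kept in the ranking —
repurposing wants known targeters to surface — with a flag to drop them.

## Planted-block graph generator

Entities are partitioned round-robin into latent mechanism blocks; a drug
targets genes of its own block with probability `p_in` and others with
`p_noise`, and diseases/phenotypes attach to blocks through gene–disease
and gene–phenotype edges so the graph exercises four node types and four
relations. A fraction of the within-block target edges (default 20%) is
withheld from the emitted graph and recorded as truth.

Defaults: 120 drugs, 240 genes, 36 diseases, 48 phenotypes, 12 blocks,
`p_in` = 0.5, `p_noise` = 0.005. These were set by working out the
information ceiling of the design before measuring anything else: under a
block model the best any scorer can do on a held-out edge is to rank the
true gene uniformly among its block's unobserved genes, so the expected
ceiling is roughly `H_k/k` with k ≈ (1−p_in·(1−holdout))·(genes per
block). Twenty genes per block at `p_in` = 0.5 puts that ceiling near
0.26, comfortably above five times the uniform-random expectation over a
240-gene pool (0.126), which is the learnability margin the generator is
supposed to guarantee. Larger, sparser blocks (e.g. 30-gene blocks at
`p_in` = 0.3) push the ceiling *below* that margin no matter how good the
model is — a property of the design, not of any estimator.

## Patient simulator

One row per patient: age (normal, clipped to 18–100), sex, ethnicity,
race, six binary comorbidity/medication flags, an indication flag, a
diabetes-group label, an exposure label (study drug / same-class control
drug / untreated), a prior-outcome flag, and an outcome time with an
event indicator. Default covariate margins are copied from the published
aspirin-cohort characteristics table so demo output looks like the real
population; they are display defaults, not estimates.

Exposure among indication patients follows a logistic model on the
covariates (intercept −1.8; positive weights on standardized age,
hypertension, dry-eye, and diabetes-drug use). The intercept is set so
the control-class pool is larger than the exposed pool, as in real
prescription data; an earlier draft with a higher intercept made the
exposed arm the majority, and greedy matching then exhausts the control
pool and cannot balance anything.

Event times are inverse-transform draws from
`h(t) = h0(t)·exp(β_true·exposed + γᵀx)` with an exponential baseline
(default rate 0.04/year; Weibull optional), administratively censored at
20 years. The default true hazard ratio is 0.71 — the magnitude of a
representative protective effect in this literature — and the hazard
coefficients γ overlap the exposure coefficients, which is exactly the
confounding-by-indication structure matching is meant to neutralize.
Prior-outcome patients (5%) are generated so the exclusion rule is
exercised rather than vacuous.

What the simulator does not emulate: longitudinal coded encounters,
medication adherence/dosage, informative censoring, and unmeasured
confounding. Passing tests therefore show that the estimators recover
what this generative model encodes, not that any real-data conclusion is
correct.

## Matching and balance

Eligibility follows the emulated-trial rules: exposure arm = indication +
study drug + no prior outcome; control arm = indication + same-class
drug, never the study drug, no prior outcome; per-filter counts are
logged CONSORT-style. Propensity scores come from maximum-likelihood
logistic regression (Newton/IRLS, tolerance 1e-10) on the covariate list;
perfect separation raises an error naming the problem rather than
returning degenerate scores.

Greedy 1:1 nearest-neighbor matching processes exposed patients in
descending propensity order (ties by id — no RNG anywhere in matching)
and gives each the nearest unmatched control within the caliper, without
replacement. The caliper phrase "0.1 standardized mean difference" in
this study family is ambiguous; the default reads it as a width of 0.1 on
the propensity-score scale, with `caliper_scale="logit-sd"` implementing
the common alternative (0.1 × SD of the logit of the score). Both
dialects are tested; neither is asserted as the original authors'
intent.

Balance uses the pooled-variance SMD formulas given in the README;
both are validated against the published table's printed values on the
rows where the printed inputs are precise enough to determine the printed
SMD. The age-before-matching row is the known exception: the printed
summaries (63.6 ± 12.2 vs 60.4 ± 13.6) recompute to 0.248 while the table
prints 0.24 — the printed inputs are too coarsely rounded to pin down the
third digit, so that row is documented rather than asserted.

## Cox engine

The partial likelihood is maximized by Newton–Raphson with step-halving
(relative tolerance 1e-9, ≤ 50 iterations), covariates centered for
conditioning; standard errors come from the inverse observed information
and the CI multiplier is fixed at 1.959964. Breslow tie handling is the
default with Efron available; the two coincide on distinct event times.
An arm with zero events makes the likelihood monotone, so that case is
rejected up front with a named error. The engine is cross-checked three
ways: brute-force grid maximization of the directly enumerated partial
likelihood on tiny fixtures, the independent lifelines implementation
(Efron), and simulations with known truth (bias of the mean estimate
< 0.03 at n = 10,000 over 50 seeds; Wald 95% CI coverage within
[90%, 98%] over 200 replicates at n = 500).

Post-matching fits are unadjusted (arm indicator only), the convention
for matched designs on aggregate EHR platforms; an adjusted fit is one
keyword away. Matched-pair correlation is ignored — a known limitation;
robust pairwise variance estimators are out of scope. Window risks are
plain proportions of the arm at index (no person-time or competing-risk
adjustment), and RRR = 1 − risk ratio; an RRR trend over windows is
classified waning/strengthening/flat by the sign of the last-minus-first
difference.

Two effects keep the matched marginal estimate above the conditional
simulation truth even when matching works: residual imbalance (a 0.1
raw-scale caliper rarely binds, so every exposed patient matches, well or
badly) and non-collapsibility of the hazard ratio (with strong covariate
effects and common events, the marginal HR is attenuated toward 1
relative to the conditional HR even under perfect balance). The
matching-effectiveness checks are therefore comparative — the matched
estimate must beat the crude one seed after seed — rather than demanding
exact recovery of the conditional coefficient.

## Determinism and problem sizes

Every stochastic stage takes a seed; the pipeline fans one run seed out
to per-stage seeds by fixed offsets, so stages are independently
reproducible and a rerun with the same configuration is byte-identical in
its TSV outputs. Simulation-based checks use n = 10,000 patients (50
seeds) for bias, n = 500 (200 replicates) for coverage, and the default
graph (444 entities) over 3 seeds for link prediction — sizes at which
the binomial/SE tolerances quoted above are meaningful while a full run
of the suite stays in the minutes range.
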