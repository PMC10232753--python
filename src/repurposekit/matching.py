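"""Cohort construction, propensity-score matching, and covariate balance.

Implements the retrospective-cohort design: the exposure arm is patients
with the study drug's indication who received the drug and had no outcome
before the index date; the control arm received another drug of the same
class, never the study drug, again with no prior outcome. Arms are then
1:1 propensity-matched (greedy nearest neighbor, caliper, without
replacement) and balance is reported as standardized mean differences
(SMD), flagged when SMD > 0.1 — the conventional imbalance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .simulate_ehr import BINARY_COVARIATES, CONTROL_LABEL, EXPOSED_LABEL

IMBALANCE_THRESHOLD = 0.1

#: Covariates matched on by default: demographics plus cataract comorbidity
#: flags and diabetes-drug use (the published covariate list's shape).
DEFAULT_COVARIATES = (
    "age", "female", "hispanic", "black", "white", "asian",
) + BINARY_COVARIATES


class CohortError(ValueError):
    """An eligibility filter left an empty arm."""


class SeparationError(ValueError):
    """Propensity model is not identifiable (perfect separation)."""


@dataclass
class CohortSpec:
    """Eligibility rules for one drug's emulated trial."""

    exposure_label: str = EXPOSED_LABEL
    control_label: str = CONTROL_LABEL
    require_indication: bool = True
    exclude_prior_outcome: bool = True
    follow_up_windows: tuple[float, ...] = (5.0, 10.0, 20.0)
    subgroup: str = "all"            # all | female | male

    def validate(self) -> list[str]:
        problems = []
        if self.exposure_label == self.control_label:
            problems.append("exposure drug listed inside its own control class")
        if any(w <= 0 for w in self.follow_up_windows):
            problems.append(f"non-positive follow-up window in {self.follow_up_windows}")
        if self.subgroup not in ("all", "female", "male"):
            problems.append(f"unknown subgroup {self.subgroup!r}")
        return problems


@dataclass
class PropensityModel:
    coefficients: pd.Series        # indexed by covariate name
    intercept: float
    scores: pd.Series              # per-patient P(exposed | x), index = patient rows
    converged: bool


@dataclass
class MatchedCohort:
    """1:1 matched pairs (without replacement) within the caliper."""

    pairs: list[tuple[str, str, float]]   # (exposed id, control id, |score diff|)
    caliper: float
    n_unmatched_exposed: int
    n_unmatched_control: int

    @property
    def exposed_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [p[1] for p in self.pairs]


@dataclass
class BalanceRow:
    covariate: str
    exposed_summary: str
    control_summary: str
    smd: float
    imbalanced: bool


def covariate_matrix(patients: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Numeric design matrix: age as-is; sex/ethnicity/race expanded to
    indicator columns; comorbidity flags passed through."""
    out = pd.DataFrame(index=patients.index)
    for cov in covariates:
        if cov == "age":
            out["age"] = patients["age"].astype(float)
        elif cov == "female":
            out["female"] = (patients["sex"] == "female").astype(int)
        elif cov == "hispanic":
            out["hispanic"] = (patients["ethnicity"] == "hispanic").astype(int)
        elif cov in ("black", "white", "asian", "other"):
            out[cov] = (patients["race"] == cov).astype(int)
        else:
            out[cov] = patients[cov].astype(int)
    return out


def build_cohorts(
    patients: pd.DataFrame, spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, int]]]:
    """Apply the eligibility rules; returns (exposed, control, consort log).

    The consort log records the cohort size after each filter, in order,
    for a CONSORT-style flow report. A patient exposed to both the study
    drug and a control-class drug belongs to the exposure arm only (the
    control arm requires *never* taking the study drug); prior-outcome
    patients are excluded from both arms.
    """
    df = patients
    consort: list[tuple[str, int]] = [("all_patients", len(df))]
    if spec.require_indication:
        df = df[df["indication"] == 1]
        consort.append(("with_indication", len(df)))
    if spec.subgroup in ("female", "male"):
        df = df[df["sex"] == spec.subgroup]
        consort.append((f"subgroup_{spec.subgroup}", len(df)))
    exposed = df[df["exposure"] == spec.exposure_label]
    control = df[df["exposure"] == spec.control_label]
    consort.append(("exposed_drug", len(exposed)))
    consort.append(("control_class_drug", len(control)))
    if spec.exclude_prior_outcome:
        exposed = exposed[exposed["prior_outcome"] == 0]
        control = control[control["prior_outcome"] == 0]
        consort.append(("exposed_no_prior_outcome", len(exposed)))
        consort.append(("control_no_prior_outcome", len(control)))
    if len(exposed) == 0:
        raise CohortError("exposure arm empty after eligibility filters")
    if len(control) == 0:
        raise CohortError("control arm empty after eligibility filters")
    return exposed.copy(), control.copy(), consort


def smd_binary(p1: float, p0: float) -> float:
    """Standardized mean difference of a binary covariate from prevalences.

    |p1 - p0| / sqrt((p1(1-p1) + p0(1-p0)) / 2); defined as 0 when both
    arms are degenerate at the same value.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
        raise ValueError(f"prevalences must be in [0,1], got {p1}, {p0}")
    pooled_var = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
    if pooled_var == 0.0:
        if p1 == p0:
            return 0.0
        raise ValueError("zero pooled variance with unequal prevalences")
    return abs(p1 - p0) / np.sqrt(pooled_var)


def smd_continuous(m1: float, s1: float, m0: float, s0: float) -> float:
    """Standardized mean difference of a continuous covariate:
    |m1 - m0| / sqrt((s1^2 + s0^2)/2)."""
    if s1 < 0 or s0 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt((s1 * s1 + s0 * s0) / 2.0)
    if pooled == 0.0:
        if m1 == m0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: SMD undefined")
    return abs(m1 - m0) / pooled


def estimate_propensity(
    exposed: pd.DataFrame,
    control: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> PropensityModel:
    """Maximum-likelihood logistic regression of arm membership on the
    covariates (Newton/IRLS); scores strictly in (0,1)."""
    if len(exposed) == 0 or len(control) == 0:
        raise CohortError("both arms must be nonempty to fit a propensity model")
    X = pd.concat(
        [covariate_matrix(exposed, covariates), covariate_matrix(control, covariates)]
    )
    y = np.concatenate([np.ones(len(exposed)), np.zeros(len(control))])
    degenerate = [c for c in X.columns if X[c].nunique() <= 1]
    Xf = X.drop(columns=degenerate)
    Xc = sm.add_constant(Xf, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(method="newton", tol=1e-10, maxiter=100, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"propensity model not identifiable: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("propensity model did not converge")
    scores = pd.Series(np.asarray(res.predict(Xc)), index=X.index)
    eps = np.finfo(float).tiny
    scores = scores.clip(eps, 1 - eps)
    if scores.min() <= 0 or scores.max() >= 1:
        raise SeparationError("fitted scores hit 0/1: separation")
    coefs = pd.Series(res.params, index=Xc.columns)
    for c in degenerate:
        coefs[c] = 0.0
    return PropensityModel(
        coefficients=coefs.drop(index="const"),
        intercept=float(coefs["const"]),
        scores=scores,
        converged=True,
    )


def greedy_match(
    exposed_scores: pd.Series,
    control_scores: pd.Series,
    caliper: float = 0.1,
    caliper_scale: str = "raw",
) -> MatchedCohort:
    """1:1 greedy nearest-neighbor matching without replacement.

    Exposed patients are processed in descending propensity order (ties by
    id, so the procedure is deterministic and RNG-free); each takes the
    nearest unmatched control whose score differs by at most the caliper.
    ``caliper_scale='raw'`` applies the caliper to raw score differences;
    ``'logit-sd'`` uses ``caliper x SD(logit(score))`` pooled over arms —
    the common alternative reading.
    """
    if caliper < 0:
        raise ValueError("caliper must be non-negative")
    if caliper_scale not in ("raw", "logit-sd"):
        raise ValueError(f"unknown caliper_scale {caliper_scale!r}")
    width = caliper
    if caliper_scale == "logit-sd":
        allscores = np.concatenate([exposed_scores.to_numpy(), control_scores.to_numpy()])
        logit = np.log(allscores / (1 - allscores))
        width = caliper * float(np.std(logit, ddof=1))
        # width on the logit scale; match on logit-transformed scores
        exposed_scores = np.log(exposed_scores / (1 - exposed_scores))
        control_scores = np.log(control_scores / (1 - control_scores))

    import bisect

    exp_order = sorted(exposed_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    pool = sorted(control_scores.items(), key=lambda kv: (kv[1], kv[0]))
    pool_scores = [s for _i, s in pool]
    pairs: list[tuple[str, str, float]] = []
    for eid, es in exp_order:
        if not pool:
            break
        j = bisect.bisect_left(pool_scores, es)
        best = None
        # nearest of the two neighbors; ties go to the lower-score control
        for cand in (j - 1, j):
            if 0 <= cand < len(pool):
                d = abs(pool_scores[cand] - es)
                if d <= width and (best is None or d < best[1]):
                    best = (cand, d)
        if best is not None:
            cand, d = best
            cid, _cs = pool.pop(cand)
            pool_scores.pop(cand)
            pairs.append((str(eid), str(cid), float(d)))
    return MatchedCohort(
        pairs=pairs,
        caliper=width,
        n_unmatched_exposed=len(exp_order) - len(pairs),
        n_unmatched_control=len(control_scores) - len(pairs),
    )


def balance_table(
    exposed: pd.DataFrame,
    control: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> list[BalanceRow]:
    """Per-covariate SMD balance rows in the published table's shape."""
    if len(exposed) == 0 or len(control) == 0:
        raise CohortError("balance table needs nonempty arms")
    Xe = covariate_matrix(exposed, covariates)
    Xc = covariate_matrix(control, covariates)
    rows: list[BalanceRow] = []
    for cov in Xe.columns:
        ve, vc = Xe[cov].to_numpy(float), Xc[cov].to_numpy(float)
        binary = set(np.unique(np.concatenate([ve, vc]))) <= {0.0, 1.0}
        if binary:
            p1, p0 = ve.mean(), vc.mean()
            smd = smd_binary(p1, p0)
            es, cs = f"{100*p1:.1f}%", f"{100*p0:.1f}%"
        else:
            m1, s1 = ve.mean(), ve.std(ddof=1)
            m0, s0 = vc.mean(), vc.std(ddof=1)
            smd = smd_continuous(m1, s1, m0, s0)
            es, cs = f"{m1:.1f} ± {s1:.1f}", f"{m0:.1f} ± {s0:.1f}"
        rows.append(BalanceRow(cov, es, cs, float(smd), bool(smd > IMBALANCE_THRESHOLD)))
    return rows


def write_balance(rows: Sequence[BalanceRow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("covariate\texposed\tcontrol\tsmd\timbalanced\n")
        for r in rows:
            fh.write(f"{r.covariate}\t{r.exposed_summary}\t{r.control_summary}\t{r.smd:.4f}\t{r.imbalanced}\n")


def write_consort(consort: Sequence[tuple[str, int]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("step\tn\n")
        for step, n in consort:
            fh.write(f"{step}\t{n}\n")
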