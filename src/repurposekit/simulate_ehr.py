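"""Synthetic EHR-style patient tables with confounded exposure and
proportional-hazards outcomes.

The generator emulates a retrospective-cohort population: demographics and
comorbidity flags drawn from configurable margins (defaults copied from the
published aspirin/T1DM cohort characteristics, as realistic-looking demo
margins — not estimates of anything), an indication flag, a drug exposure
assigned by a logistic model *on the same covariates that enter the hazard*
(confounding by indication), and an event time drawn from

    h(t) = h0(t) * exp(beta_true * exposed + gamma' x)

with an exponential (default) or Weibull baseline, administratively censored
at a horizon. A known fraction of patients carry the outcome before the
index date so the downstream exclusion rule is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table1 import ASPIRIN_T1DM_BEFORE

EXPOSED_LABEL = "drugA"
CONTROL_LABEL = "control_class"
NONE_LABEL = "none"

#: binary covariates carried by every simulated patient
BINARY_COVARIATES = (
    "hypertension", "tobacco_use", "glaucoma", "dry_eye",
    "macular_degeneration", "dm_drug_use",
)

_M = ASPIRIN_T1DM_BEFORE["exposed"]

_DEFAULT_PREVALENCES = {k: _M.prevalences[k] for k in BINARY_COVARIATES}


@dataclass
class EHRSimConfig:
    """Study conditions for the synthetic population.

    ``exposure_coefs`` is the logit of receiving the study drug (among
    indication patients) as a function of covariates; ``hazard_coefs`` are
    the covariate log-hazard coefficients gamma. Age enters both models
    standardized ((age - mean)/sd). Overlapping non-zero entries in the two
    maps produce confounding by indication, which matching must remove.
    """

    n: int = 10_000
    age_mean: float = _M.age.mean
    age_sd: float = _M.age.sd
    prevalences: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    p_female: float = _M.prevalences["female"]
    p_hispanic: float = _M.prevalences["hispanic"]
    race_probs: dict[str, float] = field(
        default_factory=lambda: {"white": 0.601, "black": 0.254, "asian": 0.015, "other": 0.130}
    )
    diabetes_probs: dict[str, float] = field(
        default_factory=lambda: {"T1DM": 0.2, "T2DM": 0.6, "hyperglycemia": 0.2}
    )
    p_indication: float = 0.8
    exposure_intercept: float = -1.8
    exposure_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age_std": 0.5, "hypertension": 0.7, "dry_eye": 0.6, "dm_drug_use": 0.5,
        }
    )
    p_control_drug: float = 0.7    # indication patients not on the study drug
    beta_true: float = float(np.log(0.71))
    hazard_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age_std": 0.4, "hypertension": 0.3, "dry_eye": 0.3, "dm_drug_use": 0.25,
        }
    )
    baseline: str = "exponential"     # or "weibull"
    baseline_rate: float = 0.04       # events per year (exponential)
    weibull_shape: float = 1.0
    weibull_scale: float = 25.0       # years
    horizon_years: float = 20.0
    dropout_max_years: float | None = None   # uniform(0, max) dropout if set
    p_prior_outcome: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if self.baseline == "exponential" and self.baseline_rate <= 0:
            raise ValueError("degenerate config: baseline_rate must be > 0")
        if self.baseline == "weibull" and (self.weibull_shape <= 0 or self.weibull_scale <= 0):
            raise ValueError("degenerate config: Weibull shape/scale must be > 0")
        for name, p in {
            "p_female": self.p_female, "p_hispanic": self.p_hispanic,
            "p_indication": self.p_indication, "p_control_drug": self.p_control_drug,
            "p_prior_outcome": self.p_prior_outcome, **self.prevalences,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0,1]")


def _covariate_frame(cfg: EHRSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n
    df = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(n)]})
    df["age"] = rng.normal(cfg.age_mean, cfg.age_sd, size=n).clip(18, 100)
    df["sex"] = np.where(rng.random(n) < cfg.p_female, "female", "male")
    df["ethnicity"] = np.where(rng.random(n) < cfg.p_hispanic, "hispanic", "non_hispanic")
    races = sorted(cfg.race_probs)
    rp = np.array([cfg.race_probs[r] for r in races], dtype=float)
    df["race"] = rng.choice(races, size=n, p=rp / rp.sum())
    groups = sorted(cfg.diabetes_probs)
    gp = np.array([cfg.diabetes_probs[g] for g in groups], dtype=float)
    df["diabetes_group"] = rng.choice(groups, size=n, p=gp / gp.sum())
    for cov in BINARY_COVARIATES:
        df[cov] = (rng.random(n) < cfg.prevalences[cov]).astype(int)
    df["indication"] = (rng.random(n) < cfg.p_indication).astype(int)
    return df


def _linear_predictor(df: pd.DataFrame, coefs: dict[str, float], cfg: EHRSimConfig) -> np.ndarray:
    eta = np.zeros(len(df))
    age_std = (df["age"].to_numpy() - cfg.age_mean) / cfg.age_sd
    for name, c in coefs.items():
        if name == "age_std":
            eta += c * age_std
        elif name == "female":
            eta += c * (df["sex"] == "female").to_numpy()
        else:
            eta += c * df[name].to_numpy()
    return eta


def generate_population(config: EHRSimConfig) -> pd.DataFrame:
    """Sample a patient table; deterministic under ``config.seed``.

    Columns: demographics, comorbidity flags, ``indication``,
    ``diabetes_group``, ``exposure`` (drugA / control_class / none),
    ``prior_outcome``, ``time`` (years from index), ``event``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    df = _covariate_frame(config, rng)
    n = config.n

    # exposure: logistic in the covariates among indication patients
    eta = config.exposure_intercept + _linear_predictor(df, config.exposure_coefs, config)
    p_drug = 1.0 / (1.0 + np.exp(-eta))
    u = rng.random(n)
    gets_drug = (df["indication"] == 1) & (u < p_drug)
    u2 = rng.random(n)
    gets_control = (df["indication"] == 1) & ~gets_drug & (u2 < config.p_control_drug)
    df["exposure"] = np.select(
        [gets_drug, gets_control], [EXPOSED_LABEL, CONTROL_LABEL], default=NONE_LABEL
    )

    df["prior_outcome"] = (rng.random(n) < config.p_prior_outcome).astype(int)

    # event time: inverse-transform under the proportional-hazards model
    hr = np.exp(
        config.beta_true * (df["exposure"] == EXPOSED_LABEL).to_numpy()
        + _linear_predictor(df, config.hazard_coefs, config)
    )
    u3 = rng.random(n)
    if config.baseline == "exponential":
        t_event = -np.log(u3) / (config.baseline_rate * hr)
    else:
        # S(t) = exp(-(t/scale)^shape * hr)  =>  t = scale * (-ln U / hr)^(1/shape)
        t_event = config.weibull_scale * (-np.log(u3) / hr) ** (1.0 / config.weibull_shape)

    censor = np.full(n, config.horizon_years)
    if config.dropout_max_years is not None:
        censor = np.minimum(censor, rng.uniform(0, config.dropout_max_years, size=n))
    df["event"] = (t_event <= censor).astype(int)
    df["time"] = np.minimum(t_event, censor)
    df.loc[df["time"] <= 0, "time"] = 1e-6
    return df


def emulate_table1_margins(config: EHRSimConfig) -> pd.DataFrame:
    """Analytic covariate margins implied by the config, for side-by-side
    comparison with realized margins of a generated table."""
    rows = [("age_mean", config.age_mean), ("age_sd", config.age_sd),
            ("female", config.p_female), ("hispanic", config.p_hispanic)]
    rows += [(r, p) for r, p in sorted(config.race_probs.items())]
    rows += [(c, config.prevalences[c]) for c in BINARY_COVARIATES]
    return pd.DataFrame(rows, columns=["covariate", "expected"])


def realized_margins(df: pd.DataFrame) -> pd.DataFrame:
    rows = [("age_mean", df["age"].mean()), ("age_sd", df["age"].std()),
            ("female", (df["sex"] == "female").mean()),
            ("hispanic", (df["ethnicity"] == "hispanic").mean())]
    rows += [(r, (df["race"] == r).mean()) for r in sorted(df["race"].unique())]
    rows += [(c, df[c].mean()) for c in BINARY_COVARIATES]
    return pd.DataFrame(rows, columns=["covariate", "realized"])
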