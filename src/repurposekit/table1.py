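"""Published cohort-characteristics reference table (aspirin, T1DM group).

Printed summary statistics of the exposure (aspirin) and control
(non-aspirin) cohorts before and after propensity matching, as reported for
the type-1-diabetes cataract population. These printed margins serve two
purposes here: they are the worked inputs for the standardized-mean-
difference arithmetic, and they provide realistic default covariate margins
for the synthetic EHR generator.

Prevalences are stored as proportions (the source prints percentages);
age is mean +/- SD in years.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ContinuousSummary:
    mean: float
    sd: float


@dataclass(frozen=True)
class CohortMargins:
    """One arm's printed summaries: age plus binary-covariate prevalences."""

    n: int
    age: ContinuousSummary
    prevalences: dict[str, float]


ASPIRIN_T1DM_BEFORE = {
    "exposed": CohortMargins(
        n=14376,
        age=ContinuousSummary(63.6, 12.2),
        prevalences={
            "female": 0.531,
            "male": 0.468,
            "hispanic": 0.116,
            "non_hispanic": 0.663,
            "black": 0.254,
            "white": 0.601,
            "asian": 0.015,
            "hypertension": 0.903,
            "tobacco_use": 0.048,
            "glaucoma": 0.267,
            "dry_eye": 0.175,
            "macular_degeneration": 0.171,
            "dm_drug_use": 0.804,
        },
    ),
    "control": CohortMargins(
        n=24180,
        age=ContinuousSummary(60.4, 13.6),
        prevalences={
            "female": 0.554,
            "male": 0.445,
            "hispanic": 0.119,
            "non_hispanic": 0.539,
            "black": 0.193,
            "white": 0.571,
            "asian": 0.014,
            "hypertension": 0.761,
            "tobacco_use": 0.039,
            "glaucoma": 0.117,
            "dry_eye": 0.059,
            "macular_degeneration": 0.055,
            "dm_drug_use": 0.596,
        },
    ),
}

ASPIRIN_T1DM_AFTER = {
    "exposed": CohortMargins(
        n=9608,
        age=ContinuousSummary(62.5, 12.2),
        prevalences={
            "female": 0.529,
            "male": 0.471,
            "hispanic": 0.121,
            "non_hispanic": 0.635,
            "black": 0.235,
            "white": 0.604,
            "asian": 0.015,
            "hypertension": 0.885,
            "tobacco_use": 0.048,
            "glaucoma": 0.194,
            "dry_eye": 0.107,
            "macular_degeneration": 0.101,
            "dm_drug_use": 0.771,
        },
    ),
    "control": CohortMargins(
        n=9608,
        age=ContinuousSummary(62.3, 12.4),
        prevalences={
            "female": 0.527,
            "male": 0.472,
            "hispanic": 0.121,
            "non_hispanic": 0.646,
            "black": 0.241,
            "white": 0.617,
            "asian": 0.013,
            "hypertension": 0.891,
            "tobacco_use": 0.045,
            "glaucoma": 0.192,
            "dry_eye": 0.104,
            "macular_degeneration": 0.092,
            "dm_drug_use": 0.773,
        },
    ),
}

#: Printed SMD values alongside the summaries, for cross-checking the
#: pooled-variance formulas (values as printed, at printed precision).
PRINTED_SMD_BEFORE = {
    "age": 0.24,
    "female": 0.04,
    "male": 0.04,
    "hispanic": 0.008,
    "non_hispanic": 0.25,
    "black": 0.14,
    "white": 0.06,
    "asian": 0.001,
    "hypertension": 0.39,
    "tobacco_use": 0.04,
    "glaucoma": 0.38,
    "dry_eye": 0.36,
    "macular_degeneration": 0.36,
    "dm_drug_use": 0.46,
}

PRINTED_SMD_AFTER = {
    "age": 0.02,
    "female": 0.004,
    "male": 0.004,
    "hispanic": 0.005,
    "non_hispanic": 0.02,
    "black": 0.01,
    "white": 0.02,
    "asian": 0.01,
    "hypertension": 0.01,
    "tobacco_use": 0.01,
    "glaucoma": 0.006,
    "dry_eye": 0.01,
    "macular_degeneration": 0.02,
    "dm_drug_use": 0.008,
}
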