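import numpy as np
import pandas as pd
import pytest

import repurposekit as rk
from repurposekit.kg import TripleRecord


SMALL_KG_CONFIG = dict(
    n_drugs=40, n_genes=80, n_diseases=12, n_phenotypes=16,
    n_blocks=4, p_in=0.5, p_noise=0.01, holdout_fraction=0.2, seed=7,
)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-block graph with its ground truth."""
    return rk.generate_kg(rk.KGSimConfig(**SMALL_KG_CONFIG))


@pytest.fixture(scope="session")
def trained_small(small_planted):
    """A concat-mlp model trained briefly on the small planted graph."""
    kg, truth = small_planted
    model = rk.train(
        kg.triples, kg, rk.ScorerConfig(),
        rk.TrainingConfig(epochs=60, seed=7),
    )
    return kg, truth, model


@pytest.fixture(scope="session")
def null_population():
    """Unconfounded population with a known true hazard ratio of 0.71."""
    cfg = rk.EHRSimConfig(
        n=10_000, seed=5, hazard_coefs={}, exposure_coefs={}, exposure_intercept=0.0
    )
    return rk.generate_population(cfg)


@pytest.fixture(scope="session")
def confounded_population():
    """Default (confounded) population at n=10,000."""
    return rk.generate_population(rk.EHRSimConfig(n=10_000, seed=11))


def arm_frame(population: pd.DataFrame) -> pd.DataFrame:
    """Exposed/control survival frame with a 0/1 arm column."""
    df = population[population["exposure"].isin(["drugA", "control_class"])].copy()
    df["arm"] = (df["exposure"] == "drugA").astype(int)
    return df


def held_out_triples(truth) -> list[TripleRecord]:
    return [TripleRecord(d, "target", g) for d, g in truth.held_out_edges]
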