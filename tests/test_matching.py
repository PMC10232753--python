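"""Cohort eligibility, SMD arithmetic, propensity fitting, greedy matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import repurposekit as rk
from repurposekit.matching import CohortError, SeparationError
from repurposekit.table1 import ASPIRIN_T1DM_AFTER, PRINTED_SMD_AFTER


# ---------------------------------------------------------------- SMD ----

def test_smd_binary_published_values():
    assert round(rk.smd_binary(0.903, 0.761), 2) == 0.39   # hypertension, before
    assert round(rk.smd_binary(0.048, 0.039), 2) == 0.04   # tobacco use, before


def test_smd_binary_trivial_cases():
    assert rk.smd_binary(0.5, 0.5) == 0.0
    assert rk.smd_binary(0.0, 0.0) == 0.0
    assert rk.smd_binary(1.0, 1.0) == 0.0


def test_smd_continuous_published_value():
    assert round(rk.smd_continuous(62.5, 12.2, 62.3, 12.4), 2) == 0.02  # age, after


def test_smd_continuous_unit_case():
    assert rk.smd_continuous(1.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)
    assert rk.smd_continuous(3.0, 2.0, 3.0, 2.0) == 0.0


def test_smd_continuous_zero_sd_unequal_means_errors():
    with pytest.raises(ValueError, match="undefined"):
        rk.smd_continuous(1.0, 0.0, 2.0, 0.0)


@given(p1=st.floats(0, 1), p0=st.floats(0, 1))
@settings(deadline=None, max_examples=50)
def test_smd_binary_symmetric_nonnegative(p1, p0):
    if p1 == p0 and p1 in (0.0, 1.0):
        return
    if (p1 in (0, 1)) and (p0 in (0, 1)) and p1 != p0:
        return  # zero pooled variance, undefined by contract
    assert rk.smd_binary(p1, p0) == pytest.approx(rk.smd_binary(p0, p1))
    assert rk.smd_binary(p1, p0) >= 0.0


@given(m1=st.floats(-50, 50), m0=st.floats(-50, 50),
       s=st.floats(0.1, 20), scale=st.floats(0.01, 100))
@settings(deadline=None, max_examples=50)
def test_smd_continuous_scale_invariant(m1, m0, s, scale):
    a = rk.smd_continuous(m1, s, m0, s)
    b = rk.smd_continuous(m1 * scale, s * scale, m0 * scale, s * scale)
    assert a == pytest.approx(b, rel=1e-9)


# ------------------------------------------------------------ cohorts ----

def tiny_patients() -> pd.DataFrame:
    rows = [
        # pid, indication, exposure, prior_outcome
        ("p1", 1, "drugA", 0),
        ("p2", 1, "control_class", 0),
        ("p3", 1, "drugA", 1),            # prior outcome: excluded
        ("p4", 1, "control_class", 1),    # prior outcome: excluded
        ("p5", 0, "none", 0),             # no indication
        ("p6", 1, "none", 0),             # indication but untreated
        ("p7", 1, "drugA", 0),
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "indication", "exposure", "prior_outcome"])
    df["sex"] = "female"
    return df.set_index("patient_id")


def test_eligibility_rules_and_consort_counts():
    exposed, control, consort = rk.build_cohorts(tiny_patients(), rk.CohortSpec())
    assert sorted(exposed.index) == ["p1", "p7"]
    assert sorted(control.index) == ["p2"]
    log = dict(consort)
    assert log["all_patients"] == 7
    assert log["with_indication"] == 6
    assert log["exposed_drug"] == 3
    assert log["control_class_drug"] == 2
    assert log["exposed_no_prior_outcome"] == 2
    assert log["control_no_prior_outcome"] == 1


def test_prior_outcome_excluded_from_both_arms():
    exposed, control, _ = rk.build_cohorts(tiny_patients(), rk.CohortSpec())
    assert "p3" not in exposed.index and "p4" not in control.index


def test_empty_arm_raises_named_error():
    df = tiny_patients()
    df = df[df["exposure"] != "control_class"]
    with pytest.raises(CohortError, match="control"):
        rk.build_cohorts(df, rk.CohortSpec())


def test_consort_counts_match_generator_bookkeeping(confounded_population):
    df = confounded_population.set_index("patient_id")
    _, _, consort = rk.build_cohorts(df, rk.CohortSpec())
    log = dict(consort)
    ind = df[df["indication"] == 1]
    assert log["with_indication"] == len(ind)
    assert log["exposed_drug"] == (ind["exposure"] == "drugA").sum()
    expected_kept = ((ind["exposure"] == "drugA") & (ind["prior_outcome"] == 0)).sum()
    assert log["exposed_no_prior_outcome"] == expected_kept


# ---------------------------------------------------------- propensity ----

def two_by_two_frame(n11, n10, n01, n00) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arms with a single binary covariate x: counts (exposed x=1, exposed
    x=0, control x=1, control x=0)."""
    def frame(n1, n0, tag):
        df = pd.DataFrame({
            "age": 50.0,
            "sex": "female",
            "ethnicity": "non_hispanic",
            "race": "white",
            "hypertension": [1] * n1 + [0] * n0,
        })
        df.index = [f"{tag}{i}" for i in range(len(df))]
        return df

    return frame(n11, n10, "e"), frame(n01, n00, "c")


def test_propensity_single_binary_covariate_matches_log_odds_ratio():
    e, c = two_by_two_frame(30, 10, 15, 25)
    model = rk.estimate_propensity(e, c, covariates=["hypertension"])
    want = np.log((30 * 25) / (10 * 15))
    assert model.coefficients["hypertension"] == pytest.approx(want, abs=1e-6)
    assert ((model.scores > 0) & (model.scores < 1)).all()


def test_propensity_null_covariate_near_zero():
    rng = np.random.default_rng(0)
    n = 4000
    def frame(tag):
        df = pd.DataFrame({
            "age": 50.0, "sex": "female", "ethnicity": "non_hispanic", "race": "white",
            "hypertension": rng.integers(0, 2, n),
        })
        df.index = [f"{tag}{i}" for i in range(n)]
        return df
    model = rk.estimate_propensity(frame("e"), frame("c"), covariates=["hypertension"])
    se = np.sqrt(4 / n * 2)  # rough SE bound for a balanced 2x2 logit
    assert abs(model.coefficients["hypertension"]) < 3 * se


def test_propensity_invariant_to_row_order():
    e, c = two_by_two_frame(30, 10, 15, 25)
    m1 = rk.estimate_propensity(e, c, covariates=["hypertension"])
    m2 = rk.estimate_propensity(e.iloc[::-1], c.iloc[::-1], covariates=["hypertension"])
    assert m1.coefficients["hypertension"] == pytest.approx(m2.coefficients["hypertension"])
    s1, s2 = m1.scores.sort_index(), m2.scores.sort_index()
    assert (s1.index == s2.index).all()
    np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)


def test_perfect_separation_raises():
    e, c = two_by_two_frame(40, 0, 0, 40)
    with pytest.raises(SeparationError):
        rk.estimate_propensity(e, c, covariates=["hypertension"])


# ------------------------------------------------------------ matching ----

def test_caliper_zero_only_exact_ties():
    es = pd.Series({"e1": 0.5, "e2": 0.41})
    cs = pd.Series({"c1": 0.5, "c2": 0.4})
    m = rk.greedy_match(es, cs, caliper=0.0)
    assert m.pairs == [("e1", "c1", 0.0)]
    assert m.n_unmatched_exposed == 1 and m.n_unmatched_control == 1


def test_greedy_order_hand_trace():
    """Highest-propensity exposed is processed first and takes the only
    control; the second exposed is left unmatched."""
    es = pd.Series({"eHigh": 0.50, "eLow": 0.40})
    cs = pd.Series({"cOnly": 0.45})
    m = rk.greedy_match(es, cs, caliper=0.1)
    assert m.pairs == [("eHigh", "cOnly", pytest.approx(0.05))]
    assert m.n_unmatched_exposed == 1


def test_matched_pairs_within_caliper_and_one_to_one(confounded_population):
    df = confounded_population.set_index("patient_id")
    exposed, control, _ = rk.build_cohorts(df, rk.CohortSpec())
    prop = rk.estimate_propensity(exposed, control)
    m = rk.greedy_match(prop.scores.loc[exposed.index], prop.scores.loc[control.index], 0.1)
    assert all(d <= m.caliper for _, _, d in m.pairs)
    assert len(set(m.exposed_ids)) == len(m.pairs)     # 1:1, no reuse
    assert len(set(m.control_ids)) == len(m.pairs)     # without replacement
    assert set(m.exposed_ids) <= set(exposed.index)
    assert set(m.control_ids) <= set(control.index)


def test_logit_sd_caliper_dialect_runs():
    rng = np.random.default_rng(1)
    es = pd.Series(rng.uniform(0.2, 0.8, 50), index=[f"e{i}" for i in range(50)])
    cs = pd.Series(rng.uniform(0.2, 0.8, 80), index=[f"c{i}" for i in range(80)])
    m = rk.greedy_match(es, cs, caliper=0.1, caliper_scale="logit-sd")
    assert all(d <= m.caliper for _, _, d in m.pairs)
    assert len(m.pairs) > 0


# ------------------------------------------------------------- balance ----

def test_identical_arms_all_smd_zero():
    e, _ = two_by_two_frame(30, 10, 1, 1)
    rows = rk.balance_table(e, e.copy(), covariates=["age", "female", "hypertension"])
    assert all(r.smd == 0.0 for r in rows)
    assert not any(r.imbalanced for r in rows)


def test_published_after_matching_rows_balanced():
    """Recomputing every after-matching SMD from the printed summaries
    stays under the 0.1 imbalance threshold."""
    e = ASPIRIN_T1DM_AFTER["exposed"]
    c = ASPIRIN_T1DM_AFTER["control"]
    smds = {"age": rk.smd_continuous(e.age.mean, e.age.sd, c.age.mean, c.age.sd)}
    for cov in e.prevalences:
        smds[cov] = rk.smd_binary(e.prevalences[cov], c.prevalences[cov])
    for cov, smd in smds.items():
        assert smd < 0.1, cov
        assert cov in PRINTED_SMD_AFTER


def test_matching_reduces_flagged_covariates(confounded_population):
    df = confounded_population.set_index("patient_id")
    exposed, control, _ = rk.build_cohorts(df, rk.CohortSpec())
    before = sum(r.imbalanced for r in rk.balance_table(exposed, control))
    prop = rk.estimate_propensity(exposed, control)
    m = rk.greedy_match(prop.scores.loc[exposed.index], prop.scores.loc[control.index], 0.1)
    after = sum(r.imbalanced for r in rk.balance_table(exposed.loc[m.exposed_ids],
                                                       control.loc[m.control_ids]))
    assert after <= before
    assert before > 0  # the confounded generator plants real imbalance
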