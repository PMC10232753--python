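"""Windowed Cox hazard ratios and the relative-risk-reduction trend.

On a matched synthetic cohort with true hazard ratio 0.71, fits the Cox
model over 5/10/20-year follow-up windows and prints the hazard ratio
with its 95% CI, the per-arm window risks, and the RRR trend
classification. The matched estimate should sit near the simulated truth.
"""

import numpy as np
import pandas as pd

import repurposekit as rk

patients = rk.generate_population(rk.EHRSimConfig(n=10_000, seed=11)).set_index("patient_id")
exposed, control, _ = rk.build_cohorts(patients, rk.CohortSpec())
prop = rk.estimate_propensity(exposed, control)
m = rk.greedy_match(prop.scores.loc[exposed.index], prop.scores.loc[control.index], 0.1)
rec = pd.concat([exposed.loc[m.exposed_ids].assign(arm=1),
                 control.loc[m.control_ids].assign(arm=0)])

print(f"true HR {np.exp(rk.EHRSimConfig().beta_true):.2f}; "
      f"{len(m.pairs)} matched pairs\n")
summaries = []
for window in (5.0, 10.0, 20.0):
    fit = rk.cox_fit(rk.truncate_follow_up(rec, window))
    risk = rk.window_risks(rec, window)
    summaries.append(risk)
    lo, hi = fit.ci95
    print(f"{window:4.0f}y: HR {fit.hr:.2f} (95% CI {lo:.2f}-{hi:.2f})  "
          f"risks {risk.risk_exposed:.1%} vs {risk.risk_control:.1%}  RRR {risk.rrr:.1%}")

trend, label = rk.rrr_trend(summaries)
print(f"\nRRR trend over windows: {label} "
      f"(a constant-hazard-ratio effect shows slowly drifting RRR)")
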