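"""Trajectory groups to incident disease: person-years, rates, Cox models.

Excludes prevalent cases at baseline, accumulates person-time, computes
incidence per 1,000 person-years with exact Poisson intervals, and fits
the three staged Cox models (age/sex; + lifestyle and medications;
+ wGRS quartiles) for the uncontrolled-vs-controlled contrast.
"""

import numpy as np
import pandas as pd

from mrtraj import (SimulationConfig, build_wgrs, generate_cohort,
                    table2_report)

cfg = SimulationConfig(n_subjects=4000, missing_rate=0.0, seed=31,
                       traj_group_shares=(0.8, 0.2))
panel = generate_cohort(cfg)
vm = panel.variant_meta
wgrs = build_wgrs(panel, vm[vm.affects_sbp][
    ["snp_id", "effect_allele", "true_beta_sbp"]]
    .rename(columns={"true_beta_sbp": "beta"}))

# use the generating class labels as the grouping (the trajectory stage
# recovers them; see example 04)
unc = panel.meta["uncontrolled_group"]["sbp"]
assignments = pd.DataFrame({
    "subject_id": panel.subject_ids,
    "label": np.where(panel.true_labels == unc, "uncontrolled",
                      "controlled")})

rep = table2_report(panel, assignments, wgrs, outcome="t2d",
                    grouping_phenotype="sbp")
print("exclusions:", rep.exclusion_report)
print("\nincidence by SBP trajectory group (per 1,000 person-years):")
print(rep.incidence_rows.to_string(index=False))
print("\nCox models, uncontrolled vs controlled:")
print(rep.cox_rows.to_string(index=False,
                             float_format=lambda v: f"{v:.3f}"))
print(f"\nplanted T2D hazard ratio for the uncontrolled class: "
      f"{np.exp(cfg.event_model.log_hr['t2d']['uncontrolled']):.2f}")
# The uncontrolled group's rate exceeds the controlled group's, and each
# model's HR confidence interval should bracket the planted 1.25 once the
# confounding covariates (age, BMI, sex) are adjusted for.
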