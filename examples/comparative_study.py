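"""A small seeded comparative study with inter-animal variability.

Cohorts of six animals per marker estimate the same true water flux;
group means are compared against the classic-marker group with Welch's
t-test after a Shapiro-Wilk normality check, mirroring how such animal
experiments are reported (mean +/- SD, p-values per comparison).
"""

import gutperm as gp
import gutperm.io as gio

config = gio.default_study_config()  # seed 0, 6 animals/group, CVs on
tables = gp.run_marker_comparison(config)

summary = tables.estimates.groupby("marker")["jwater_est_uL_per_cm_per_h"].agg(
    ["mean", "std", "count"]
)
print("estimated Jwater by marker (true value: "
      f"{config.perfusion_design.true_jwater_uL_per_cm_per_h} uL/cm/h):")
print(summary.round(1).to_string())
print()
print("comparisons vs the classic marker:")
cols = ["group_b", "mean_b", "sd_b", "t_p", "significant_0.05"]
print(tables.comparisons[cols].round(4).to_string(index=False))
print()
print("With self-absorbing classic marker vs PEGylated markers the group")
print("means separate in the biased direction; significance at n = 6 varies")
print("with the seeded inter-animal spread, as in real cohorts.")
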