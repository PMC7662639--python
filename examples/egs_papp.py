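"""Everted-gut-sac apparent permeability with sampling-replacement correction.

A 120-min sac experiment with 0.4-mL receiver samples replaced by blank
every 15 min.  The cumulative-amount reconstruction Q = Cn*V + s*sum(Ci)
restores what earlier aliquots carried away; Papp follows from the OLS
flux, and W is the cumulative absorption percentage of the donor amount.
"""

import gutperm as gp

geometry = gp.default_geometry("jejunum")
design = gp.EGSDesign()  # 10-mL donor, 2-mL sac, 0.4 mL / 15 min, 120 min
solute = gp.SoluteSpec(name="PR-like", role="marker",
                       permeability_cm_per_s=5e-6, initial_concentration_uM=56.0)
noise = gp.NoiseModel(assay_cv=0.0, animal_cv_jwater=0.0,
                      animal_cv_permeability=0.0, seed=0)

run = gp.simulate_egs_run(geometry, design, solute, noise)
result = gp.apparent_permeability(
    run.observations, reference_volume_mL=design.donor_volume_mL
)

print("cumulative amounts Q (nmol):",
      ", ".join(f"{q:.3f}" for q in result.cumulative_amounts_nmol))
print("flux dQ/dt   : %.4f nmol/min (r2 = %.6f)"
      % (result.flux_nmol_per_min, result.r_squared))
print("true Papp    : %.2e cm/s" % solute.permeability_cm_per_s)
print("est. Papp    : %.2e cm/s" % result.papp_cm_per_s)
print("W            : %.2f%% of the donor amount in 120 min"
      % result.cumulative_fraction_percent)
print()
print("Q equals the true transferred amount to machine precision; the")
print("small Papp deficit reflects donor depletion over the run.")
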