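"""Simulate one recirculation-perfusion run and recover its parameters.

A noise-free run with an ideal (non-absorbed) volume marker and an
atenolol-like drug: the estimation chain reconstructs the perfusate
volumes from the marker, corrects the drug concentrations for water
absorption, fits the first-order disappearance rate and converts it to an
effective permeability.
"""

import gutperm as gp

geometry = gp.default_geometry("jejunum")
design = gp.PerfusionDesign()  # 20 mL, 0.4-mL samples every 10 min for 60 min
marker = gp.SoluteSpec(name="ideal-marker", role="marker",
                       permeability_cm_per_s=0.0, initial_concentration_uM=56.0)
drug = gp.SoluteSpec(name="atenolol-like", role="drug",
                     permeability_cm_per_s=2.5e-5, initial_concentration_uM=100.0)
noise = gp.NoiseModel(assay_cv=0.0, animal_cv_jwater=0.0,
                      animal_cv_permeability=0.0, seed=0)

run = gp.simulate_perfusion_run(geometry, design, marker, drug, noise)
result = gp.analyze_perfusion(run.observations)

print("true Jwater   :", run.truth.jwater_uL_per_cm_per_h, "uL/cm/h")
print("est. Jwater   : %.3f uL/cm/h (r2 = %.6f)"
      % (result.jwater_uL_per_cm_per_h, result.water_flux.r_squared))
print("true Peff     : %.3e cm/s" % drug.permeability_cm_per_s)
print("est. Peff     : %.3e cm/s (ka = %.5f /min, r2 = %.6f)"
      % (result.peff_cm_per_s, result.ka_fit.ka_per_min, result.ka_fit.r_squared))
print()
print("Jwater is exact; the small Peff overshoot is the sampling artifact:")
print("each replaced 0.4-mL aliquot removes ~2% of the drug, which the")
print("volume correction cannot restore (see docs/methods.md).")
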