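"""Marker self-absorption biases Jwater and Peff downward.

The same experiment is simulated with three markers of decreasing
permeability (a classic phenol-red-like marker and two PEGylated-marker
surrogates).  The marker's own absorption inflates the reconstructed
volumes, so the water flux — and with it the drug permeability — is
underestimated; the less permeable the marker, the closer both estimates
sit to the truth.
"""

import gutperm as gp

geometry = gp.default_geometry("jejunum")
design = gp.PerfusionDesign()
drug = gp.SoluteSpec(name="atenolol-like", role="drug",
                     permeability_cm_per_s=2.5e-5, initial_concentration_uM=100.0)
noise = gp.NoiseModel(assay_cv=0.0, animal_cv_jwater=0.0,
                      animal_cv_permeability=0.0, seed=0)

print(f"true Jwater = {design.true_jwater_uL_per_cm_per_h} uL/cm/h\n")
print(f"{'marker':<16}{'Papp (cm/s)':>12}{'est. Jwater':>14}{'est. Peff':>14}")
for name, papp in (("PR-like", 5e-6), ("PEG4k-PR-like", 8e-7),
                   ("PEG5k-PR-like", 3e-7), ("ideal", 0.0)):
    marker = gp.SoluteSpec(name=name, role="marker",
                           permeability_cm_per_s=papp,
                           initial_concentration_uM=56.0)
    run = gp.simulate_perfusion_run(geometry, design, marker, drug, noise)
    result = gp.analyze_perfusion(run.observations)
    print(f"{name:<16}{papp:>12.1e}{result.jwater_uL_per_cm_per_h:>14.3f}"
          f"{result.peff_cm_per_s:>14.3e}")
print()
print("Both estimates increase monotonically as the marker becomes less")
print("permeable: the least-absorbed marker gives the least-biased result.")
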