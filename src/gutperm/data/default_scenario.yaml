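# Default simulated-study scenario.
#
# Every number below is a simulation INPUT (a ground-truth condition the
# synthetic cohorts are generated from), not a package output.  Permeability
# scenario values follow reported experimental ranges: the classic
# phenol-red-like marker carries an in-vitro Papp near 5e-6 cm/s, roughly
# 8-15x the PEGylated markers (3-8e-7 cm/s); drug effective permeabilities
# use the least-biased reported per-segment estimates for an
# atenolol-like (BCS III), ketoprofen-like (BCS II) and metoprolol-like
# (BCS I boundary) compound.  Segment trend for markers: jejunum > duodenum
# > ileum > colon.

segments:
  - {segment_name: jejunum, radius_cm: 0.18, length_cm: 10.0}
  - {segment_name: ileum, radius_cm: 0.18, length_cm: 10.0}
  - {segment_name: colon, radius_cm: 0.18, length_cm: 10.0}

markers:
  - name: PR-like            # classic phenol-red-style marker, measurably absorbed
    role: marker
    concentration_uM: 56.0
    permeability_cm_per_s:
      duodenum: 4.0e-6
      jejunum: 5.0e-6
      ileum: 3.0e-6
      colon: 2.0e-6
      whole_small_intestine: 4.0e-6
  - name: PEG4k-PR-like      # PEGylated marker, upper end of the low-Papp range
    role: marker
    concentration_uM: 56.0
    permeability_cm_per_s:
      duodenum: 6.0e-7
      jejunum: 8.0e-7
      ileum: 5.0e-7
      colon: 3.0e-7
      whole_small_intestine: 6.0e-7
  - name: PEG5k-PR-like      # heavier PEGylation, lowest permeability
    role: marker
    concentration_uM: 56.0
    permeability_cm_per_s:
      duodenum: 2.5e-7
      jejunum: 3.0e-7
      ileum: 2.0e-7
      colon: 1.5e-7
      whole_small_intestine: 2.5e-7

drugs:
  - name: atenolol-like      # BCS III, paracellular, low permeability
    role: drug
    concentration_uM: 100.0
    permeability_cm_per_s:
      duodenum: 2.5e-5
      jejunum: 2.6e-5
      ileum: 2.3e-5
      colon: 3.3e-5
      whole_small_intestine: 2.5e-5
  - name: ketoprofen-like    # BCS II
    role: drug
    concentration_uM: 100.0
    permeability_cm_per_s:
      duodenum: 1.0e-4
      jejunum: 1.1e-4
      ileum: 1.11e-4
      colon: 1.29e-4
      whole_small_intestine: 1.1e-4
  - name: metoprolol-like    # BCS I high-permeability boundary reference
    role: drug
    concentration_uM: 100.0
    permeability_cm_per_s:
      duodenum: 1.0e-4
      jejunum: 1.07e-4
      ileum: 9.4e-5
      colon: 1.02e-4
      whole_small_intestine: 1.0e-4

perfusion_design:
  nominal_volume_mL: 20.0        # recirculating perfusate V'
  sample_volume_mL: 0.4
  sampling_interval_min: 10.0
  n_samples: 6                   # every 10 min for 60 min
  replacement_policy: marker_stock
  true_jwater_uL_per_cm_per_h: 200.0   # ground-truth net water absorption
  stabilization_min: 10.0
  marker_in_t0_addition: true

egs_design:
  donor_volume_mL: 10.0
  sac_volume_mL: 2.0
  sample_volume_mL: 0.4
  sampling_interval_min: 15.0
  n_samples: 8                   # 120 min total

n_animals_per_group: 6

noise:
  assay_cv: 0.05                 # multiplicative assay error per concentration
  animal_cv_jwater: 0.4          # lognormal inter-animal spread of Jwater
  animal_cv_permeability: 0.3
  seed: 0

analysis:
  variant: recursive             # marker-amount-conserving volume recursion
  fit_window: null               # null = all drug time points
  welch: true
  holm: false

reference_marker: PR-like
reference_drug: metoprolol-like
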