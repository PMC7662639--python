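# Methods

## Scope

`gutperm` does two things: (1) it implements the marker-based
water-flux-correction and permeability-estimation chain used with rat
in-situ recirculation perfusion and everted-gut-sac (EGS) experiments, and
(2) it simulates those experiments by exact mass balance with known ground
truth, so that the estimators' bias — in particular the bias caused by the
volume marker's own absorption — can be measured by parameter recovery
rather than asserted.  Real animal-derived numbers are used only as
*scenario inputs* (plausible permeabilities, water fluxes, dispersions);
the package makes no claim to reproduce any specific animal experiment.

## Forward model

### Recirculation perfusion

The perfusate circuit (donor chamber + pump tubing + gut lumen, nominally
20 mL) is treated as a single well-mixed compartment.  The 5 mL/min pump
flow is fast relative to the sampling interval, so transport delay around
the loop is neglected; samples are drawn from the donor chamber exactly as
in the bench protocol.

Three state variables evolve between sampling events:

* **Volume.**  Net water absorption is constant within a run (zero-order):
  dV/dt = −q with q = J_water·L, J_water in µL/cm/h and L the segment
  length in cm.  This matches the estimator's model of a single volume-loss
  slope.
* **Marker amount M.**  The marker is lost by membrane flux from the
  well-mixed circuit: dM/dt = −P_app·S·M/V with S = 2πRL.  The closed form
  between events is M(t) = M_k·(V(t)/V_k)^(P_app·S/q), computed through a
  `log1p` exponent so it degenerates smoothly to the exponential branch
  M(t) = M_k·exp(−P_app·S·(t−t_k)/V_k) as q → 0 (the two branches agree to
  < 1e−8 at q = 1e−12).
* **Drug amount D.**  The drug is parameterized directly by its
  *operational* effective permeability — the estimand of the recirculation
  method — and disappears at the constant first-order rate
  k_a = 2·P_eff/R, i.e. exactly the relation P_eff = k_a·R/2 that the
  estimator inverts.  This is a deliberate modeling choice: the method
  defines P_eff through the cylindrical-lumen relation, so the simulator's
  "true P_eff" is the quantity an ideal, artifact-free application of the
  method would return.  Coupling the drug to the circuit volume instead
  (as the marker is) would make the recovered value depend on the
  circuit-to-lumen volume ratio and leave no consistent ground truth for
  recovery studies.  The marker, by contrast, is kept volume-coupled
  because its loss *rate relative to the circuit* is what generates the
  correction bias under study, and its scenario values come from in-vitro
  P_app measurements.

Events: the circuit starts with V′ mL of marker solution at C′ and
stabilizes for 10 min (water flux and marker absorption already act, which
is why C′₀ ≥ C′ and V₀ ≤ V′).  At t = 0 a sample (s = 0.4 mL) is
withdrawn, and an equal aliquot is added that carries marker at C′
(configurable via `marker_in_t0_addition`; the volume-reconstruction
recursion assumes it) plus a concentrated drug load bringing the circuit
to the nominal C₀.  Each subsequent sample measures both analytes and is
replaced according to the replacement policy (default: marker stock, no
drug; alternatives: marker+drug stock, blank, none).  No replacement
follows the final sample.  Withdrawal removes both solutes at their
current concentrations.  If water absorption would exhaust the perfusate
before sampling completes, the simulator raises an explicit error naming
the exhaustion time.

Every noise-free run closes its per-solute amount ledger
(initial + added − withdrawn − absorbed − remaining = 0) and its volume
balance to < 1e−9 relative error; this is asserted property-based across
the design space.

### Everted gut sac

Solute transfers from the donor chamber (default 10 mL) into the sac
(V = 2 mL of blank buffer) at rate P_app·A·(C_donor − C_receiver), with
closed-form two-compartment propagation between events.  Two flags bracket
the usual idealizations: `sink_assumption` drops the receiver term from
the gradient, `constant_donor` freezes the donor.  Every 15 min a 0.4-mL
receiver aliquot is withdrawn and replaced with blank buffer; 8 samples
give a 120-min run.  The 10-mL donor default puts the 120-min cumulative
transfer of a classic-marker permeability (5e−6 cm/s) at ~3.8% of the
donor amount and PEGylated-marker permeabilities (3–8e−7 cm/s) at
0.2–0.7%, the ranges reported for these marker classes.

### Noise and inter-animal variability

Measured concentrations get multiplicative Gaussian error,
C_obs = C·(1+ε) with ε ~ N(0, cv) truncated (clipped) at −3 SD so
observations stay positive; default assay CV 5%.  Per-animal water flux
and permeabilities are drawn from mean-preserving lognormals
(σ² = ln(1+CV²), µ = ln(mean) − σ²/2); defaults CV 0.4 for J_water
(matching the ~40–47% dispersions reported for marker-corrected water
fluxes in such cohorts) and 0.3 for permeabilities.  Concentrations and
fluxes are positive quantities, hence the multiplicative/lognormal forms.
Each animal's stream is spawned deterministically from the base seed:
identical seeds reproduce byte-identical tables.

What the generator does **not** emulate: segmental pH and mucus effects,
carrier-mediated or concentration-dependent marker transport (the classic
marker's colon concentration dependence is documented experimentally),
drug–marker interaction, assay carryover, or any blood-side kinetics.
Passing recovery tests therefore demonstrates correctness of the
estimation algebra and the direction/structure of the marker bias under
these dynamics — not that real tissue behaves this simply.

## Estimators

### Perfusion chain

V₀ = C′V′/C′₀ (Eq.-of-dilution of the known initial marker amount).  The
volume recursion has two variants:

* **recursive** (default): V_t = ((V_{t−1} − s)·C′_{t−1} + s·C′)/C′_t.
  This conserves the assumed marker amount across *all* prior
  withdrawals/replacements; it equals an explicit step-by-step
  marker-amount ledger by construction (property-tested), and with an
  ideal marker it reproduces the simulator's true volumes exactly.
* **literal**: V_t = ((V₀ − s)·C′_{t−1} + s·C′)/C′_t, which reuses V₀ at
  every step.  The two coincide at t = 1 and diverge from t = 2 on; the
  literal form double-counts earlier withdrawals and is retained only for
  comparison with the printed formula it mirrors.

Corrected concentrations C_t = C_e·V_t/V₀ reference every drug amount to
the initial volume, cancelling the concentration rise from water loss.
k_a comes from unweighted log-linear OLS of ln C_t vs t (nonpositive
points are excluded with a logged warning; ≥ 3 usable points required);
P_eff = k_a·R/2 after converting k_a to s⁻¹.  J_water is the OLS slope of
(V₀ − V_t) vs t anchored at (0, 0), divided by L and converted to µL/cm/h.
The endpoint alternative (V₀ − V_n)/t_n/L is reported alongside because it
depends entirely on the final sample; the regression estimator uses every
point and is the package's primary output.  The fit window is configurable
(default: all drug time points) since bench protocols differ on which
interval they fit.

### EGS chain

Q_n = C_n·V + s·Σ_{i<n} C_i exactly restores the cumulative transferred
amount under sampling-with-blank-replacement — on noise-free simulated
runs the identity holds to machine precision, and this is the package's
strongest internal consistency check.  P_app = (dQ/dt)/(A·C₀)/60 in cm/s
with dQ/dt by OLS.  A = 2πRL (smooth cylinder; an area multiplier is
available since "effective surface area" is not uniquely defined).  W is
reported against the donor-chamber amount by default — an "absorption
percentage" semantically references what was available to absorb — with a
literal mode using the sac volume V as denominator, since the printed
formula of the classical method uses V.

### Statistics

Groups are summarized as mean ± sample SD (n−1).  Normality is checked
per group with Shapiro–Wilk; two groups are compared with the t-test,
Welch by default (the pooled-variance Student form is an option) — when a
protocol says only "t-test", the variant robust to unequal variances is
the safer default.  Zero-variance-in-both-arms comparisons are flagged
not evaluable instead of raising.  No multiple-testing correction is
applied by default, matching per-comparison reporting conventions in this
literature; a Holm adjustment is available.  The wrapper's type-I error
is Monte-Carlo calibrated in the tests (1000 null replicates at n = 6).

## Numerical and design choices

* Units are fixed internally (µM, mL, min, cm/s, µL/cm/h); all
  conversions live in `gutperm.units`.
* Closed forms, not ODE solvers, propagate between events; the piecewise
  trajectory is cross-checked against an independent fixed-step RK4
  integration (0.01-min steps) to < 1e−6 relative error over a grid of
  water fluxes and marker permeabilities.
* Default geometry: R = 0.18 cm, L = 10 cm per segment (40 cm for the
  whole small intestine).  Protocols report the measured length but not a
  radius; 0.18 cm is a conventional rat small-intestine figure.  R enters
  P_eff linearly, so its absolute value scales results without affecting
  any recovery or bias conclusion.
* Default true J_water = 200 µL/cm/h, chosen near the estimate obtained
  with the least-absorbed marker class (which the bias analysis shows is
  closest to truth).
* V₀ sanity bound: a reconstructed V₀ > 1.5·V′ fails loudly
  (configurable), since it implies an implausible marker series.
* CSV output carries 12 significant digits so disk round-trips perturb
  downstream fits by < 1e−9.

## The residual sampling artifact

With 0.4-mL samples from a ~20-mL circuit, each replaced aliquot removes
~2% of the *drug* amount that the replacement (marker stock) does not
return.  The volume reconstruction cannot see this loss, so the fitted
k_a is inflated by ln(V/(V−s))/Δt ≈ 0.0020 min⁻¹ regardless of the drug.
For fast drugs this is small (≈ +3% on a metoprolol-like k_a of
0.067 min⁻¹); for an atenolol-like drug (k_a ≈ 0.017 min⁻¹) it is ≈ +12%.
The acceptance tests assert that this deviation equals the analytically
predicted withdrawal bias exactly, rather than hiding it in a widened
tolerance; with 1-µL samples the whole chain recovers truth to < 0.1%.
This artifact is *marker-independent* (it offsets all marker groups
equally), so marker-bias comparisons are made against the ideal-marker
estimate under the same design, isolating the marker's contribution.
Modeling the withdrawal correction into the estimator would be
straightforward but is deliberately out of scope: the package implements
the method as practiced.

## Known limitations

* Disappearance kinetics only; no blood-side appearance data.
* Constant-within-run water flux; no secretion/absorption switching.
* Single-compartment circuit (no pump-loop transport delay).
* The drug's constant-k_a parameterization means cross-checks of the
  *drug* trajectory against volume-coupled kinetics are by construction
  out of scope (the marker trajectory carries that physics).
* Scenario permeabilities are segment-level constants; no within-segment
  heterogeneity.
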