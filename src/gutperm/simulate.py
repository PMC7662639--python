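"""Forward simulation of perfusion and everted-gut-sac experiments.

Both experiments are simulated by exact mass balance: between sampling
events the state follows closed-form solutions of the compartmental ODEs,
and each sampling is a discrete withdrawal/replacement event.  Every run
carries its ground truth (realized water flux and permeabilities, the
noise-free state trajectory, and a per-solute amount ledger), so estimator
bias can be measured by parameter recovery.

Recirculation perfusion
-----------------------
The recirculating circuit is treated as one well-mixed compartment.  Water
is absorbed at the constant rate q = Jwater * L (zero-order volume loss),
so dV/dt = -q.  The marker is lost through the gut wall by membrane flux
from the circuit, dM/dt = -Papp * S * M / V with S = 2*pi*R*L, whose closed
form between events is

    M(t) = M_k * (V(t)/V_k)^(Papp*S/q),   V(t) = V_k - q*(t - t_k),

degenerating to M(t) = M_k * exp(-Papp*S*(t-t_k)/V_k) when q = 0.  The
model drug is parameterized directly by its operational effective
permeability — the estimand of the recirculation method — and disappears
with the constant first-order rate ka = 2*Peff/R implied by the
cylindrical-lumen relation Peff = ka*R/2.

Everted gut sac
---------------
Solute transfers from the donor chamber into the sac at rate
Papp*A*(C_donor - C_receiver), with flags to neglect the receiver term
(sink assumption) and/or hold the donor constant.  Receiver aliquots are
replaced with blank buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
import pandas as pd

from .egs import EGSTimeSeries
from .models import EGSDesign, NoiseModel, PerfusionDesign, SegmentGeometry, SoluteSpec
from .perfusion import PerfusionTimeSeries
from . import units


class PerfusateExhaustedError(RuntimeError):
    """Water absorption used up the perfusate before sampling finished."""

    def __init__(self, time_min: float) -> None:
        self.time_min = time_min
        super().__init__(
            f"perfusate exhausted at t = {time_min:.2f} min; "
            "water absorption left too little volume to sample"
        )


@dataclass(frozen=True)
class SoluteBalance:
    """Amount ledger (nmol) for one solute over a noise-free run."""

    initial_nmol: float
    added_nmol: float
    withdrawn_nmol: float
    absorbed_nmol: float
    remaining_nmol: float

    @property
    def relative_error(self) -> float:
        scale = max(abs(self.initial_nmol) + abs(self.added_nmol), 1e-30)
        gap = (
            self.initial_nmol
            + self.added_nmol
            - self.withdrawn_nmol
            - self.absorbed_nmol
            - self.remaining_nmol
        )
        return abs(gap) / scale


@dataclass(frozen=True)
class RunTruth:
    """Hidden ground truth carried by a simulated run."""

    jwater_uL_per_cm_per_h: float
    permeabilities_cm_per_s: dict[str, float]
    #: noise-free state at each sampling time, just before withdrawal.
    trajectory: pd.DataFrame
    balances: dict[str, SoluteBalance]
    volume_balance_rel_error: float
    #: EGS only: true cumulative transferred amount at each sampling time.
    cumulative_transferred_nmol: np.ndarray | None = None

    def mass_balance_error(self) -> float:
        errors = [b.relative_error for b in self.balances.values()]
        return max(errors + [self.volume_balance_rel_error])


@dataclass(frozen=True)
class SimulatedRun:
    run_id: str
    experiment_type: Literal["perfusion", "egs"]
    observations: Union[PerfusionTimeSeries, EGSTimeSeries]
    truth: RunTruth


def _observe(rng: np.random.Generator, true_value: float, cv: float) -> float:
    """Multiplicative Gaussian assay error, truncated at -3 SD."""
    if cv == 0.0:
        return true_value
    eps = max(rng.normal(0.0, cv), -3.0 * cv)
    return true_value * (1.0 + eps)


def _marker_decay_factor(clearance: float, q: float, volume: float, dt: float) -> float:
    """Amount ratio M(t+dt)/M(t) for membrane flux under a shrinking volume.

    Uses the exponent (clearance/q) * ln(V2/V1); via log1p the q -> 0 limit
    goes over smoothly to exp(-clearance*dt/V).
    """
    if clearance == 0.0 or dt == 0.0:
        return 1.0
    if q == 0.0:
        return math.exp(-clearance * dt / volume)
    return math.exp(clearance * math.log1p(-q * dt / volume) / q)


def simulate_perfusion_run(
    geometry: SegmentGeometry,
    design: PerfusionDesign,
    marker: SoluteSpec,
    drug: SoluteSpec,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    run_id: str = "perfusion-000",
) -> SimulatedRun:
    """Simulate one recirculation-perfusion run.

    Protocol: the circuit starts with ``nominal_volume_mL`` of marker
    solution at the nominal marker concentration and stabilizes for
    ``stabilization_min`` (water flux and marker absorption already act).
    At t=0 a marker sample is withdrawn and an equal aliquot is added that
    carries marker stock (if ``marker_in_t0_addition``) plus the drug load
    bringing the circuit to the nominal drug concentration.  Samples at
    each interval measure both analytes and are replaced according to
    ``replacement_policy`` (no replacement after the final sample).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    q = units.jwater_to_volume_rate(
        design.true_jwater_uL_per_cm_per_h, geometry.length_cm
    )
    surface = geometry.surface_area_cm2
    clearance = units.permeability_to_clearance(marker.permeability_cm_per_s, surface)
    ka_drug = units.peff_to_ka_per_min(drug.permeability_cm_per_s, geometry.radius_cm)
    s = design.sample_volume_mL
    c_marker_stock = marker.initial_concentration_uM
    c_drug_nominal = drug.initial_concentration_uM

    volume = design.nominal_volume_mL
    m_amt = c_marker_stock * volume
    d_amt = 0.0
    ledger = {
        marker.name: {"initial": m_amt, "added": 0.0, "withdrawn": 0.0, "absorbed": 0.0},
        drug.name: {"initial": 0.0, "added": 0.0, "withdrawn": 0.0, "absorbed": 0.0},
    }
    vol_added = 0.0
    vol_withdrawn = 0.0
    elapsed = 0.0

    def propagate(dt: float, t_start: float) -> None:
        nonlocal volume, m_amt, d_amt, elapsed
        if dt == 0.0:
            return
        v_next = volume - q * dt
        if v_next <= 0.0:
            raise PerfusateExhaustedError(t_start + volume / q)
        m_next = m_amt * _marker_decay_factor(clearance, q, volume, dt)
        d_next = d_amt * math.exp(-ka_drug * dt)
        ledger[marker.name]["absorbed"] += m_amt - m_next
        ledger[drug.name]["absorbed"] += d_amt - d_next
        volume, m_amt, d_amt = v_next, m_next, d_next
        elapsed += dt

    propagate(design.stabilization_min, -design.stabilization_min)

    n = design.n_samples
    times = [i * design.sampling_interval_min for i in range(n + 1)]
    marker_obs: list[float] = []
    drug_obs: list[float] = []
    traj_rows: list[tuple[float, float, float, float]] = []

    for k, t_k in enumerate(times):
        if k > 0:
            propagate(design.sampling_interval_min, times[k - 1])
        traj_rows.append((t_k, volume, m_amt, d_amt))
        if s > 0.0 and volume <= s and k < n:
            raise PerfusateExhaustedError(t_k)
        c_m = m_amt / volume
        c_d = d_amt / volume
        marker_obs.append(_observe(rng, c_m, noise.assay_cv))
        if k > 0:
            drug_obs.append(_observe(rng, c_d, noise.assay_cv))
        # withdrawal: the aliquot carries both analytes at their current
        # (noise-free) concentrations
        m_amt -= s * c_m
        d_amt -= s * c_d
        volume -= s
        ledger[marker.name]["withdrawn"] += s * c_m
        ledger[drug.name]["withdrawn"] += s * c_d
        vol_withdrawn += s
        # replacement
        if k == 0:
            volume += s
            vol_added += s
            if design.marker_in_t0_addition:
                m_amt += s * c_marker_stock
                ledger[marker.name]["added"] += s * c_marker_stock
            # concentrated drug load dissolved in the aliquot brings the
            # circuit to the nominal drug concentration
            spike = c_drug_nominal * volume - d_amt
            d_amt += spike
            ledger[drug.name]["added"] += spike
        elif k < n:
            policy = design.replacement_policy
            if policy in ("marker_stock", "marker_and_drug_stock"):
                volume += s
                vol_added += s
                m_amt += s * c_marker_stock
                ledger[marker.name]["added"] += s * c_marker_stock
                if policy == "marker_and_drug_stock":
                    d_amt += s * c_drug_nominal
                    ledger[drug.name]["added"] += s * c_drug_nominal
            elif policy == "blank":
                volume += s
                vol_added += s
            # "none": nothing returned

    balances = {
        name: SoluteBalance(
            initial_nmol=entry["initial"],
            added_nmol=entry["added"],
            withdrawn_nmol=entry["withdrawn"],
            absorbed_nmol=entry["absorbed"],
            remaining_nmol=(m_amt if name == marker.name else d_amt),
        )
        for name, entry in ledger.items()
    }
    vol_gap = (
        design.nominal_volume_mL
        + vol_added
        - vol_withdrawn
        - q * elapsed
        - volume
    )
    truth = RunTruth(
        jwater_uL_per_cm_per_h=design.true_jwater_uL_per_cm_per_h,
        permeabilities_cm_per_s={
            marker.name: marker.permeability_cm_per_s,
            drug.name: drug.permeability_cm_per_s,
        },
        trajectory=pd.DataFrame(
            traj_rows,
            columns=["time_min", "volume_mL", "marker_amount_nmol", "drug_amount_nmol"],
        ),
        balances=balances,
        volume_balance_rel_error=abs(vol_gap) / design.nominal_volume_mL,
    )
    observations = PerfusionTimeSeries(
        times_min=np.asarray(times, dtype=float),
        marker_concentrations_uM=np.asarray(marker_obs, dtype=float),
        drug_concentrations_uM=np.asarray(drug_obs, dtype=float),
        nominal_marker_concentration_uM=c_marker_stock,
        nominal_volume_mL=design.nominal_volume_mL,
        nominal_drug_concentration_uM=c_drug_nominal,
        sample_volume_mL=s,
        geometry=geometry,
    )
    return SimulatedRun(
        run_id=run_id,
        experiment_type="perfusion",
        observations=observations,
        truth=truth,
    )


def _egs_interval_transfer(
    a_donor: float,
    a_receiver: float,
    v_donor: float,
    v_receiver: float,
    clearance: float,
    dt: float,
    sink: bool,
    constant_donor: bool,
) -> tuple[float, float, float]:
    """Closed-form update over one interval.

    Returns (new donor amount, new receiver amount, transferred amount).
    """
    if clearance == 0.0 or dt == 0.0:
        return a_donor, a_receiver, 0.0
    if sink:
        if constant_donor:
            transfer = clearance * (a_donor / v_donor) * dt
            return a_donor, a_receiver + transfer, transfer
        a_d_next = a_donor * math.exp(-clearance * dt / v_donor)
        transfer = a_donor - a_d_next
        return a_d_next, a_receiver + transfer, transfer
    if constant_donor:
        c_d = a_donor / v_donor
        a_eq = c_d * v_receiver
        a_r_next = a_eq + (a_receiver - a_eq) * math.exp(-clearance * dt / v_receiver)
        transfer = a_r_next - a_receiver
        return a_donor, a_r_next, transfer
    total = a_donor + a_receiver
    a_eq = total * v_receiver / (v_donor + v_receiver)
    rate = clearance * (1.0 / v_donor + 1.0 / v_receiver)
    a_r_next = a_eq + (a_receiver - a_eq) * math.exp(-rate * dt)
    transfer = a_r_next - a_receiver
    return total - a_r_next, a_r_next, transfer


def simulate_egs_run(
    geometry: SegmentGeometry,
    design: EGSDesign,
    solute: SoluteSpec,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    run_id: str = "egs-000",
) -> SimulatedRun:
    """Simulate one everted-gut-sac run with periodic blank replacement."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    clearance = units.permeability_to_clearance(
        solute.permeability_cm_per_s, geometry.surface_area_cm2
    )
    v_d, v_r, s = design.donor_volume_mL, design.sac_volume_mL, design.sample_volume_mL
    a_d = solute.initial_concentration_uM * v_d
    a_r = 0.0
    withdrawn = 0.0
    transferred = 0.0

    times: list[float] = []
    obs: list[float] = []
    cum_transfer: list[float] = []
    traj_rows: list[tuple[float, float, float]] = []

    for k in range(1, design.n_samples + 1):
        a_d, a_r, step = _egs_interval_transfer(
            a_d, a_r, v_d, v_r, clearance, design.sampling_interval_min,
            design.sink_assumption, design.constant_donor,
        )
        transferred += step
        t_k = k * design.sampling_interval_min
        times.append(t_k)
        traj_rows.append((t_k, a_d, a_r))
        cum_transfer.append(transferred)
        c_r = a_r / v_r
        obs.append(_observe(rng, c_r, noise.assay_cv))
        if k < design.n_samples:
            a_r -= s * c_r
            withdrawn += s * c_r
            # blank replacement restores the sac volume, adds no solute

    donor_initial = solute.initial_concentration_uM * v_d
    balances = {
        solute.name: SoluteBalance(
            initial_nmol=donor_initial,
            added_nmol=0.0,
            withdrawn_nmol=withdrawn,
            absorbed_nmol=0.0 if not design.constant_donor else -(transferred),
            remaining_nmol=a_d + a_r,
        )
    }
    # with a constant donor the transferred amount is created rather than
    # depleted; book it as a (negative) absorption so the ledger still closes
    truth = RunTruth(
        jwater_uL_per_cm_per_h=0.0,
        permeabilities_cm_per_s={solute.name: solute.permeability_cm_per_s},
        trajectory=pd.DataFrame(
            traj_rows, columns=["time_min", "donor_amount_nmol", "receiver_amount_nmol"]
        ),
        balances=balances,
        volume_balance_rel_error=0.0,
        cumulative_transferred_nmol=np.asarray(cum_transfer, dtype=float),
    )
    observations = EGSTimeSeries(
        times_min=np.asarray(times, dtype=float),
        receiver_concentrations_uM=np.asarray(obs, dtype=float),
        sac_volume_mL=v_r,
        sample_volume_mL=s,
        donor_concentration_uM=solute.initial_concentration_uM,
        geometry=geometry,
    )
    return SimulatedRun(
        run_id=run_id, experiment_type="egs", observations=observations, truth=truth
    )


@dataclass(frozen=True)
class PerfusionScenario:
    """Everything needed to simulate one perfusion cohort."""

    geometry: SegmentGeometry
    design: PerfusionDesign
    marker: SoluteSpec
    drug: SoluteSpec


@dataclass(frozen=True)
class EGSScenario:
    geometry: SegmentGeometry
    design: EGSDesign
    solute: SoluteSpec


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-preserving lognormal draw; degenerate cases return the mean."""
    if cv == 0.0 or mean <= 0.0:
        return mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def generate_cohort(
    scenario: Union[PerfusionScenario, EGSScenario],
    n_animals: int,
    noise: NoiseModel,
    run_id_prefix: str | None = None,
) -> list[SimulatedRun]:
    """Simulate a cohort of animals with lognormal inter-animal variability.

    Each animal gets its own deterministic random stream spawned from the
    base seed, so the cohort is reproducible and runs are independent.
    Per-animal water flux and permeabilities are drawn lognormally around
    the scenario means with the configured CVs.
    """
    if n_animals < 2:
        raise ValueError("a cohort needs at least 2 animals")
    is_perfusion = isinstance(scenario, PerfusionScenario)
    if run_id_prefix is None:
        run_id_prefix = "perfusion" if is_perfusion else "egs"
    children = np.random.SeedSequence(noise.seed).spawn(n_animals)
    runs: list[SimulatedRun] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        run_id = f"{run_id_prefix}-{i:03d}"
        if is_perfusion:
            jw = _lognormal_around(
                rng, scenario.design.true_jwater_uL_per_cm_per_h, noise.animal_cv_jwater
            )
            p_marker = _lognormal_around(
                rng, scenario.marker.permeability_cm_per_s, noise.animal_cv_permeability
            )
            p_drug = _lognormal_around(
                rng, scenario.drug.permeability_cm_per_s, noise.animal_cv_permeability
            )
            design = scenario.design.model_copy(
                update={"true_jwater_uL_per_cm_per_h": jw}
            )
            marker = scenario.marker.model_copy(
                update={"permeability_cm_per_s": p_marker}
            )
            drug = scenario.drug.model_copy(update={"permeability_cm_per_s": p_drug})
            runs.append(
                simulate_perfusion_run(
                    scenario.geometry, design, marker, drug, noise, rng=rng,
                    run_id=run_id,
                )
            )
        else:
            p = _lognormal_around(
                rng, scenario.solute.permeability_cm_per_s, noise.animal_cv_permeability
            )
            solute = scenario.solute.model_copy(update={"permeability_cm_per_s": p})
            runs.append(
                simulate_egs_run(
                    scenario.geometry, scenario.design, solute, noise, rng=rng,
                    run_id=run_id,
                )
            )
    return runs
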