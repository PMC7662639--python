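"""Independent numeric oracles used by the tests.

These deliberately avoid the package's closed forms: the perfusion
trajectory is integrated with a classical fixed-step fourth-order
Runge-Kutta scheme, and the marker-volume reconstruction is checked against
a step-by-step amount ledger.
"""

from __future__ import annotations

import math

import numpy as np


def rk4_perfusion_trajectory(
    geometry,
    design,
    marker,
    drug,
    step_min: float = 0.01,
):
    """Integrate the perfusion ODEs with RK4 and replay the event schedule.

    Returns (times, volumes, marker_concentrations, drug_concentrations)
    at the sampling instants, just before each withdrawal — the same
    quantities the simulator observes noise-free.
    """
    q = design.true_jwater_uL_per_cm_per_h * geometry.length_cm / 1000.0 / 60.0
    surface = 2.0 * math.pi * geometry.radius_cm * geometry.length_cm
    clearance = marker.permeability_cm_per_s * surface * 60.0  # mL/min
    ka = 2.0 * drug.permeability_cm_per_s / geometry.radius_cm * 60.0  # 1/min

    def deriv(state):
        v, m, d = state
        return np.array([-q, -clearance * m / v, -ka * d])

    def integrate(state, duration):
        n_steps = max(1, round(duration / step_min))
        h = duration / n_steps
        for _ in range(n_steps):
            k1 = deriv(state)
            k2 = deriv(state + h / 2 * k1)
            k3 = deriv(state + h / 2 * k2)
            k4 = deriv(state + h * k3)
            state = state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        return state

    s = design.sample_volume_mL
    c_marker = marker.initial_concentration_uM
    c_drug = drug.initial_concentration_uM
    state = np.array([design.nominal_volume_mL, c_marker * design.nominal_volume_mL, 0.0])
    if design.stabilization_min > 0:
        state = integrate(state, design.stabilization_min)

    times, volumes, c_m_list, c_d_list = [], [], [], []
    for k in range(design.n_samples + 1):
        if k > 0:
            state = integrate(state, design.sampling_interval_min)
        v, m, d = state
        times.append(k * design.sampling_interval_min)
        volumes.append(v)
        c_m_list.append(m / v)
        c_d_list.append(d / v)
        # withdrawal
        m -= s * m / v
        d -= s * d / v
        v -= s
        # replacement
        if k == 0:
            v += s
            if design.marker_in_t0_addition:
                m += s * c_marker
            d = c_drug * v
        elif k < design.n_samples:
            policy = design.replacement_policy
            if policy in ("marker_stock", "marker_and_drug_stock"):
                v += s
                m += s * c_marker
                if policy == "marker_and_drug_stock":
                    d += s * c_drug
            elif policy == "blank":
                v += s
        state = np.array([v, m, d])
    return (
        np.array(times),
        np.array(volumes),
        np.array(c_m_list),
        np.array(c_d_list),
    )


def marker_amount_ledger_volumes(
    marker_concentrations, nominal_marker_uM, nominal_volume_mL, sample_volume_mL,
    replacement_uM,
):
    """Volumes at each sampling implied by tracking the assumed marker amount.

    amount_0 = C' * V'; each event withdraws s at the measured concentration
    and returns s at the replacement concentration; the volume before event
    t is the running amount divided by the measured concentration.
    """
    s = sample_volume_mL
    amount = nominal_marker_uM * nominal_volume_mL
    volumes = []
    for t, c_t in enumerate(marker_concentrations):
        v_t = amount / c_t
        volumes.append(v_t)
        amount = amount - s * c_t + s * replacement_uM
    return np.array(volumes)  # index 0 is V0
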