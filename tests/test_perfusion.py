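"""Perfusion estimation chain: volume reconstruction, corrected
concentrations, ka fit, Peff, water flux, and parameter recovery against
the simulator's ground truth."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gutperm as gp
from gutperm.perfusion import PerfusionTimeSeries

from _oracles import marker_amount_ledger_volumes


def make_series(marker, drug, s=0.4, c_prime=56.0, v_prime=20.0, c0=100.0,
                interval=10.0, geometry=None):
    marker = np.asarray(marker, dtype=float)
    drug = np.asarray(drug, dtype=float)
    times = np.arange(len(marker)) * interval
    return PerfusionTimeSeries(
        times_min=times,
        marker_concentrations_uM=marker,
        drug_concentrations_uM=drug,
        nominal_marker_concentration_uM=c_prime,
        nominal_volume_mL=v_prime,
        nominal_drug_concentration_uM=c0,
        sample_volume_mL=s,
        geometry=geometry or gp.default_geometry("jejunum"),
    )


class TestInitialVolume:
    def test_identity_when_concentration_unchanged(self):
        series = make_series([56.0, 57.0, 58.0], [90.0, 80.0])
        assert gp.initial_volume(series) == pytest.approx(20.0)

    def test_hand_arithmetic(self):
        """V0 = 56 * 20 / 58.8 = 19.0476 mL."""
        series = make_series([58.8, 58.8, 61.6], [90.0, 80.0])
        assert gp.initial_volume(series) == pytest.approx(1120.0 / 58.8, rel=1e-12)


class TestVolumeTrace:
    def test_constant_marker_gives_nominal_volume_both_variants(self):
        series = make_series([56.0] * 4, [90.0, 85.0, 80.0])
        for variant in ("literal", "recursive"):
            trace = gp.volume_trace(series, variant=variant)
            np.testing.assert_allclose(trace.volumes_mL, 20.0, rtol=1e-12)
            assert trace.v0_mL == pytest.approx(20.0)

    def test_hand_ledger_values(self):
        """Frozen from the step-by-step marker-amount ledger with s = 0.4,
        C' = 56, V' = 20 and measured 58.8, 58.8, 61.6 uM:
        recursive V2 = 18.145455 mL; literal V2 = 18.163636 mL."""
        series = make_series([58.8, 58.8, 61.6], [90.0, 80.0])
        recursive = gp.volume_trace(series, variant="recursive")
        literal = gp.volume_trace(series, variant="literal")
        assert recursive.volumes_mL[1] == pytest.approx(18.145454545454545, rel=1e-9)
        assert literal.volumes_mL[1] == pytest.approx(18.163636363636364, rel=1e-9)
        # both variants coincide at the first sample
        assert recursive.volumes_mL[0] == pytest.approx(literal.volumes_mL[0], rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        concentrations=st.lists(st.floats(30.0, 80.0), min_size=3, max_size=8),
        s=st.floats(0.0, 0.5),
    )
    def test_recursive_variant_matches_amount_ledger(self, concentrations, s):
        """The recursive reconstruction conserves the assumed marker amount
        across all withdrawals/replacements: it must equal the independent
        step-by-step ledger at every sample."""
        n_drug = len(concentrations) - 1
        series = make_series(concentrations, [50.0] * n_drug, s=s)
        trace = gp.volume_trace(series, variant="recursive", max_v0_ratio=10.0)
        ledger = marker_amount_ledger_volumes(
            np.asarray(concentrations), 56.0, 20.0, s, replacement_uM=56.0
        )
        assert trace.v0_mL == pytest.approx(ledger[0], rel=1e-9)
        np.testing.assert_allclose(trace.volumes_mL, ledger[1:], rtol=1e-9)

    def test_noise_free_run_recovers_true_volumes(self, jejunum, marker_spec, drug_spec, quiet_noise):
        """With an ideal (non-absorbed) marker the recursive trace equals the
        simulator's true volumes at every sampling instant."""
        design = gp.PerfusionDesign(true_jwater_uL_per_cm_per_h=150.0)
        run = gp.simulate_perfusion_run(
            jejunum, design, marker_spec(papp=0.0), drug_spec(), quiet_noise
        )
        trace = gp.volume_trace(run.observations, variant="recursive")
        true_volumes = run.truth.trajectory["volume_mL"].to_numpy()
        assert trace.v0_mL == pytest.approx(true_volumes[0], rel=1e-9)
        np.testing.assert_allclose(trace.volumes_mL, true_volumes[1:], rtol=1e-9)

    def test_implausible_marker_series_rejected(self):
        # marker far below nominal implies V0 >> V', beyond the sanity bound
        series = make_series([20.0, 21.0, 22.0], [90.0, 80.0])
        with pytest.raises(ValueError, match="V0"):
            gp.volume_trace(series)


class TestCorrectedConcentrations:
    def test_identity_when_volume_constant(self):
        series = make_series([56.0] * 3, [90.0, 80.0])
        trace = gp.volume_trace(series)
        np.testing.assert_allclose(
            gp.corrected_concentrations(series, trace), [90.0, 80.0], rtol=1e-12
        )

    def test_hand_arithmetic(self):
        """C_e = 90, Vt = 18, V0 = 20 -> Ct = 81."""
        trace = gp.VolumeTrace(v0_mL=20.0, volumes_mL=np.array([18.0]), variant="recursive")
        series = make_series([56.0, 60.0], [90.0])
        np.testing.assert_allclose(
            gp.corrected_concentrations(series, trace), [81.0], rtol=1e-12
        )

    def test_water_absorption_cancelled_for_inert_drug(self, jejunum, marker_spec, drug_spec, quiet_noise):
        """Zero drug permeability + water absorption + idealized sampling:
        the corrected concentration is exactly flat (the concentration rise
        from volume loss is cancelled by the correction)."""
        design = gp.PerfusionDesign(
            true_jwater_uL_per_cm_per_h=200.0, sample_volume_mL=0.0
        )
        run = gp.simulate_perfusion_run(
            jejunum, design, marker_spec(papp=0.0), drug_spec(peff=0.0), quiet_noise
        )
        trace = gp.volume_trace(run.observations)
        corrected = gp.corrected_concentrations(run.observations, trace)
        np.testing.assert_allclose(corrected, corrected[0], rtol=1e-6)


class TestKaFit:
    def test_exact_exponential(self):
        t = np.arange(10.0, 70.0, 10.0)
        c = 100.0 * np.exp(-0.01 * t)
        fit = gp.fit_ka(t, c)
        assert fit.ka_per_min == pytest.approx(0.01, rel=1e-12)
        assert fit.c0_fit_uM == pytest.approx(100.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_concentration_gives_zero_rate(self):
        fit = gp.fit_ka([10, 20, 30, 40], [50.0] * 4)
        assert fit.ka_per_min == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_points_excluded_with_warning(self, caplog):
        t = [10, 20, 30, 40, 50]
        c = [90.0, 80.0, 0.0, 60.0, 50.0]
        with caplog.at_level(logging.WARNING, logger="gutperm.perfusion"):
            fit = gp.fit_ka(t, c)
        assert fit.n_points_used == 4
        assert any("nonpositive" in rec.message for rec in caplog.records)

    def test_too_few_points_fails(self):
        with pytest.raises(ValueError):
            gp.fit_ka([10, 20, 30], [1.0, 0.0, -1.0])

    def test_noisy_cohort_median_recovery(self, jejunum, marker_spec, drug_spec):
        """Assay CV 5%, n = 6 runs, fixed seed: the median recovered ka is
        within 5% of the truth for the high-permeability reference drug."""
        noise = gp.NoiseModel(
            assay_cv=0.05, animal_cv_jwater=0.0, animal_cv_permeability=0.0, seed=11
        )
        scenario = gp.PerfusionScenario(
            geometry=jejunum, design=gp.PerfusionDesign(),
            marker=marker_spec(papp=0.0), drug=drug_spec(peff=1.0e-4),
        )
        runs = gp.generate_cohort(scenario, 6, noise)
        kas = [gp.analyze_perfusion(r.observations).ka_fit.ka_per_min for r in runs]
        true_ka = 2.0 * 1.0e-4 / jejunum.radius_cm * 60.0
        assert np.median(kas) == pytest.approx(true_ka, rel=0.05)


class TestPeffAndWaterFlux:
    def test_peff_arithmetic_identity(self):
        geometry = gp.SegmentGeometry(segment_name="jejunum", radius_cm=0.2, length_cm=10.0)
        fit = gp.KaFit(ka_per_min=0.06, c0_fit_uM=100.0, r_squared=1.0, n_points_used=6)
        # ka = 1e-3 /s, R = 0.2 cm -> Peff = 1e-4 cm/s
        assert gp.peff_from_ka(fit, geometry) == pytest.approx(1.0e-4, rel=1e-12)
        zero = gp.KaFit(ka_per_min=0.0, c0_fit_uM=100.0, r_squared=1.0, n_points_used=6)
        assert gp.peff_from_ka(zero, geometry) == 0.0

    def test_water_flux_hand_conversion(self):
        """V0 - Vt = 0.025*t mL with L = 10 cm is 150 uL/cm/h."""
        geometry = gp.default_geometry("jejunum")
        t = np.arange(10.0, 70.0, 10.0)
        trace = gp.VolumeTrace(v0_mL=20.0, volumes_mL=20.0 - 0.025 * t, variant="recursive")
        est = gp.water_flux(trace, t, geometry)
        assert est.jwater_uL_per_cm_per_h == pytest.approx(150.0, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0)
        assert est.endpoint_jwater_uL_per_cm_per_h == pytest.approx(150.0, rel=1e-12)

    def test_constant_volume_gives_zero_flux(self):
        geometry = gp.default_geometry("jejunum")
        t = np.array([10.0, 20.0, 30.0])
        trace = gp.VolumeTrace(v0_mL=20.0, volumes_mL=np.full(3, 20.0), variant="recursive")
        assert gp.water_flux(trace, t, geometry).jwater_uL_per_cm_per_h == pytest.approx(0.0, abs=1e-12)


class TestFullChainRecovery:
    def test_idealized_recovery(self, jejunum, marker_spec, drug_spec, quiet_noise):
        """Sample volume -> 0 and noise -> 0: both Peff and Jwater recover
        the simulated truth to < 0.1%."""
        design = gp.PerfusionDesign(sample_volume_mL=0.001)
        run = gp.simulate_perfusion_run(
            jejunum, design, marker_spec(papp=0.0), drug_spec(peff=2.5e-5), quiet_noise
        )
        result = gp.analyze_perfusion(run.observations)
        assert result.peff_cm_per_s == pytest.approx(2.5e-5, rel=1e-3)
        assert result.jwater_uL_per_cm_per_h == pytest.approx(
            run.truth.jwater_uL_per_cm_per_h, rel=1e-3
        )

    def test_jwater_bias_monotone_in_marker_permeability(self, jejunum, marker_spec, drug_spec, quiet_noise):
        """Marker self-absorption biases Jwater downward, strictly more for
        more permeable markers."""
        design = gp.PerfusionDesign()
        estimates = []
        for papp in (1e-7, 5e-7, 1e-6, 5e-6):
            run = gp.simulate_perfusion_run(
                jejunum, design, marker_spec(papp=papp), drug_spec(), quiet_noise
            )
            estimates.append(gp.analyze_perfusion(run.observations).jwater_uL_per_cm_per_h)
        truth = design.true_jwater_uL_per_cm_per_h
        assert all(e < truth for e in estimates)
        assert all(a > b for a, b in zip(estimates, estimates[1:]))

    def test_peff_bias_asymmetry(self, jejunum, marker_spec, drug_spec, quiet_noise):
        """The marker-induced relative Peff underestimation is larger for a
        low-permeability (atenolol-like) drug than for a high-permeability
        (metoprolol-like) drug."""
        design = gp.PerfusionDesign()

        def rel_under(peff):
            biased = gp.simulate_perfusion_run(
                jejunum, design, marker_spec(papp=5e-6), drug_spec(peff=peff), quiet_noise
            )
            ideal = gp.simulate_perfusion_run(
                jejunum, design, marker_spec(papp=0.0), drug_spec(peff=peff), quiet_noise
            )
            p_biased = gp.analyze_perfusion(biased.observations).peff_cm_per_s
            p_ideal = gp.analyze_perfusion(ideal.observations).peff_cm_per_s
            return (p_ideal - p_biased) / p_ideal

        assert rel_under(2.5e-5) > rel_under(1.0e-4) > 0.0

    def test_literal_and_recursive_agree_without_water_flux(self, jejunum, marker_spec, drug_spec, quiet_noise):
        design = gp.PerfusionDesign(true_jwater_uL_per_cm_per_h=0.0)
        run = gp.simulate_perfusion_run(
            jejunum, design, marker_spec(papp=0.0), drug_spec(), quiet_noise
        )
        lit = gp.volume_trace(run.observations, variant="literal")
        rec = gp.volume_trace(run.observations, variant="recursive")
        np.testing.assert_allclose(lit.volumes_mL, rec.volumes_mL, rtol=1e-9)
        np.testing.assert_allclose(rec.volumes_mL, 20.0, rtol=1e-9)

    def test_result_internal_consistency(self, jejunum, marker_spec, drug_spec, quiet_noise):
        """Peff = ka*R/2 holds inside every result to machine precision."""
        run = gp.simulate_perfusion_run(
            jejunum, gp.PerfusionDesign(), marker_spec(papp=1e-6), drug_spec(), quiet_noise
        )
        result = gp.analyze_perfusion(run.observations)
        expected = result.ka_fit.ka_per_min / 60.0 * jejunum.radius_cm / 2.0
        assert result.peff_cm_per_s == pytest.approx(expected, rel=1e-15)


class TestSeriesValidation:
    def test_marker_must_be_longer_than_drug(self):
        with pytest.raises(ValueError, match="drug series"):
            make_series([56.0, 57.0], [90.0, 80.0])

    def test_nonpositive_marker_rejected(self):
        with pytest.raises(ValueError, match="marker concentration"):
            make_series([56.0, 0.0, 57.0], [90.0, 80.0])

    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            PerfusionTimeSeries(
                times_min=np.array([10.0, 20.0, 30.0]),
                marker_concentrations_uM=np.array([56.0, 57.0, 58.0]),
                drug_concentrations_uM=np.array([90.0, 80.0]),
                nominal_marker_concentration_uM=56.0,
                nominal_volume_mL=20.0,
                nominal_drug_concentration_uM=100.0,
                sample_volume_mL=0.4,
                geometry=gp.default_geometry("jejunum"),
            )
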