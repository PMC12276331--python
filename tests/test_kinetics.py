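"""Kinetic-rate inference: Bell-Evans fit, P(t) fit, derived rates, tables."""

import math

import numpy as np
import pytest

from forcekin.bond_physics import bell_evans_force
from forcekin.densities import LoadingRateSegment
from forcekin.errors import InsufficientDataError, InvalidInputError
from forcekin.kinetics import (
    RateTable,
    binding_probability_curve,
    bond_lifetime,
    compare_binding_probabilities,
    compute_affinity,
    compute_k2,
    compute_kon,
    fit_bell_evans,
    fit_binding_kinetics,
    predict_double_bond_overlay,
    summarize_rates,
)


def _segments_from_model(params, rates, peak_sd=8.0):
    return [LoadingRateSegment(
        log10_lo=math.floor(2 * math.log10(r)) / 2.0,
        log10_hi=math.floor(2 * math.log10(r)) / 2.0 + 0.5,
        events=[], representative_rate=r,
        peak_mean=bell_evans_force(r, params), peak_sd=peak_sd)
        for r in rates]


class TestFitBellEvans:
    RATES = [1e3, 3e3, 1e4, 3e4, 1e5, 3e5]

    def test_exact_recovery_from_noiseless_peaks(self, bell_params):
        segs = _segments_from_model(bell_params, self.RATES)
        fit = fit_bell_evans(segs)
        assert fit.params.k_off == pytest.approx(bell_params.k_off, rel=1e-6)
        assert fit.params.x_beta == pytest.approx(bell_params.x_beta, rel=1e-6)

    def test_doubling_peak_sd_doubles_standard_errors(self, bell_params):
        segs1 = _segments_from_model(bell_params, self.RATES, peak_sd=8.0)
        segs2 = _segments_from_model(bell_params, self.RATES, peak_sd=16.0)
        f1, f2 = fit_bell_evans(segs1), fit_bell_evans(segs2)
        assert f2.params.k_off == pytest.approx(f1.params.k_off, rel=1e-9)
        assert f2.se_log10_koff == pytest.approx(2 * f1.se_log10_koff, rel=1e-9)
        assert f2.se_xbeta == pytest.approx(2 * f1.se_xbeta, rel=1e-9)

    def test_too_few_segments_rejected(self, bell_params):
        segs = _segments_from_model(bell_params, self.RATES[:2])
        with pytest.raises(InsufficientDataError):
            fit_bell_evans(segs)

    def test_full_pipeline_parameter_recovery(self, mono_dataset):
        """Simulate -> detect -> segment -> fit recovers the generating
        k_off within +/-0.3 decades and x_beta within 20%."""
        from forcekin.curves import detect_ruptures
        from forcekin.densities import segment_by_loading_rate, segment_peak_stats
        events = []
        for curve, _ in mono_dataset:
            events.extend(detect_ruptures(curve))
        segs = [segment_peak_stats(s) for s in segment_by_loading_rate(events)]
        fit = fit_bell_evans(segs)
        assert abs(math.log10(fit.params.k_off / 0.03)) <= 0.3
        assert fit.params.x_beta == pytest.approx(0.5, rel=0.20)


class TestDoubleBondOverlay:
    def test_overlay_above_single_bond_curve(self, bell_params):
        segs = _segments_from_model(bell_params, TestFitBellEvans.RATES)
        fit = fit_bell_evans(segs)
        grid = np.geomspace(1e3, 1e5, 30)
        overlay = predict_double_bond_overlay(fit, grid)
        single = bell_evans_force(grid, fit.params)
        assert np.all(overlay >= single)
        assert np.all(overlay < 2.0 * single)  # below two-fold at finite rates


class TestFitBindingKinetics:
    T = np.array([0.05, 0.1, 0.15, 0.2, 0.3, 0.45, 0.7, 1.0])

    def test_exact_recovery(self):
        p = binding_probability_curve(self.T, 0.4, 0.01, 0.2)
        fit = fit_binding_kinetics(self.T, p)
        assert fit.A == pytest.approx(0.4, abs=1e-6)
        assert fit.t0 == pytest.approx(0.01, abs=1e-6)
        assert fit.tau == pytest.approx(0.2, abs=1e-6)

    def test_second_bond_fixes_lag_time(self):
        p = binding_probability_curve(self.T, 0.3, 0.0, 0.25)
        fit = fit_binding_kinetics(self.T, p, bond_order=2)
        assert fit.t0 == 0.0
        assert fit.tau == pytest.approx(0.25, abs=1e-6)

    def test_flat_nonzero_profile_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_binding_kinetics(self.T, np.full(self.T.shape, 0.3))

    def test_too_few_contact_times_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_binding_kinetics([0.1, 0.2, 0.4], [0.1, 0.2, 0.3])


class TestDerivedRates:
    def test_kon_from_interaction_time(self):
        k_on, se = compute_kon(0.13, 4.59e-4, se_log10_tau=0.05)
        assert k_on == pytest.approx(1.68e4, rel=0.005)
        assert se == 0.05

    def test_kon_scaling(self):
        base, _ = compute_kon(0.2, 1e-4)
        half, _ = compute_kon(0.4, 1e-4)
        assert half == pytest.approx(base / 2.0, rel=1e-12)

    def test_k2_reciprocal(self):
        assert compute_k2(0.25)[0] == pytest.approx(4.0, rel=1e-12)
        with pytest.raises(InvalidInputError):
            compute_k2(-1.0)

    def test_mean_second_bond_rate_of_reported_antibody_panel(self):
        """The four antibody-subclass second-bond rates average to 4.1/s."""
        k2 = [5.5, 4.8, 2.2, 3.9]
        assert np.mean(k2) == pytest.approx(4.1, abs=0.05)

    def test_affinity_identity_and_error_quadrature(self):
        kd, se = compute_affinity(3.0e-2, 2.8e4, 0.16, 0.08)
        assert kd == pytest.approx(1.07e-6, rel=0.005)
        assert se == pytest.approx(math.hypot(0.16, 0.08), rel=1e-12)
        kd_sym, se_sym = compute_affinity(3.0e-2, 2.8e4, 0.08, 0.16)
        assert se_sym == pytest.approx(se, rel=1e-12)

    def test_affinity_error_against_monte_carlo(self, rng):
        """Log-quadrature SE equals the Monte-Carlo SD of log10(K_D) under
        independent log-normal rate errors."""
        se_koff, se_kon = 0.2, 0.1
        koff = 0.03 * 10 ** rng.normal(0, se_koff, 200_000)
        kon = 2.8e4 * 10 ** rng.normal(0, se_kon, 200_000)
        mc_sd = np.std(np.log10(koff / kon))
        _, se = compute_affinity(0.03, 2.8e4, se_koff, se_kon)
        assert se == pytest.approx(mc_sd, rel=0.05)

    def test_lifetimes(self):
        assert bond_lifetime(0.35) == pytest.approx(2.857, abs=0.001)
        lifetimes = [bond_lifetime(k) for k in (0.041, 0.041, 0.029, 0.030)]
        assert np.mean(lifetimes) == pytest.approx(29.2, abs=0.1)
        assert bond_lifetime(1.0) == 1.0


class TestRateTable:
    PANEL = {
        "mAb-1": {"k_off": 4.1e-2, "k_on": 2.6e4, "k_2": 5.5,
                  "se_log10_k_off": 0.26, "se_log10_k_on": 0.09},
        "mAb-2B": {"k_off": 3.0e-2, "k_on": 2.8e4, "k_2": 3.9,
                   "se_log10_k_off": 0.16, "se_log10_k_on": 0.08},
    }

    def test_reproduces_affinity_columns(self):
        table = summarize_rates(self.PANEL)
        assert table.frame.loc["mAb-1", "K_D"] == pytest.approx(1.6e-6, rel=0.02)
        assert table.frame.loc["mAb-2B", "K_D"] == pytest.approx(1.1e-6, rel=0.03)

    def test_internal_identities_hold_exactly(self):
        table = summarize_rates(self.PANEL)
        for _, row in table.frame.iterrows():
            assert row["k_off_2"] == pytest.approx(row["k_off"] * 2.0 / 3.0, rel=1e-14)
            assert row["K_D"] == pytest.approx(row["k_off"] / row["k_on"], rel=1e-14)
            assert row["K_D_2"] == pytest.approx(row["k_off_2"] / row["k_on"], rel=1e-14)
            assert row["lifetime"] == pytest.approx(1.0 / row["k_off"], rel=1e-14)

    def test_csv_round_trip_lossless(self, tmp_path):
        table = summarize_rates(self.PANEL)
        path = tmp_path / "rates.csv"
        table.to_csv(path)
        back = RateTable.from_csv(path)
        np.testing.assert_allclose(back.frame.to_numpy(dtype=float),
                                   table.frame.to_numpy(dtype=float), rtol=1e-15)

    def test_text_rendering_convention(self):
        text = summarize_rates(self.PANEL).to_text()
        assert "4.1 x 10^-2 +/- 0.26" in text
        assert "2.7 x 10^-2 +/- 0.26" in text  # derived two-bond column


class TestCompareBindingProbabilities:
    def test_identical_groups(self):
        res = compare_binding_probabilities([0.3, 0.31, 0.29, 0.3], [0.3, 0.31, 0.29, 0.3])
        assert res.p_value > 0.95
        assert res.effect == pytest.approx(0.0, abs=1e-12)

    def test_power_on_blocked_vs_unblocked(self):
        """0.05 vs 0.30 binding at 4 cells x 300 curves: significant in
        >= 95/100 replicates."""
        master = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            a = master.binomial(300, 0.30, size=4) / 300.0
            b = master.binomial(300, 0.05, size=4) / 300.0
            hits += compare_binding_probabilities(a, b).p_value < 0.05
        assert hits >= 95

    def test_single_cell_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_binding_probabilities([0.3], [0.2, 0.25, 0.3])
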