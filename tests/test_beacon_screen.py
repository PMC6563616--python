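"""Beacon kinetics, plate QC, hit calling and dose-response fitting."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tdgtool.beacon_screen import (
    KineticParams,
    TimeCourse,
    WellSpec,
    activity_endpoint,
    activity_slope,
    analyze_plate,
    beacon_kinetics,
    call_hits,
    default_layout_384,
    fit_4pl,
    percent_inhibition,
    simulate_plate,
    traces_from_tsv,
    traces_to_tsv,
    z_prime,
)


def _noiseless(**kw) -> KineticParams:
    return KineticParams(noise_sd=0.0, **kw)


def _trace(times, rfu, role="compound"):
    return TimeCourse("p", "A01", role, np.asarray(times, float),
                      np.asarray(rfu, float))


class TestBeaconKinetics:
    def test_no_glycosylase_means_background_plus_drift(self):
        p = _noiseless(kg=0.0)
        t = np.array([0.0, 100.0, 7200.0])
        assert beacon_kinetics(p, t) == pytest.approx(p.F_bg + p.drift * t)

    def test_mass_conservation_at_long_times(self):
        p = _noiseless(drift=0.0, kg=1e-2, kap=1e-2)
        assert beacon_kinetics(p, 1e7) == pytest.approx(
            p.F_bg + p.F_scale * p.S0, rel=1e-9)

    def test_continuous_at_equal_rates(self):
        t = np.linspace(0, 7200, 50)
        equal = beacon_kinetics(_noiseless(kg=5e-4, kap=5e-4), t)
        near = beacon_kinetics(_noiseless(kg=5e-4, kap=5e-4 * (1 + 1e-9)), t)
        assert np.max(np.abs(equal - near)) < 1e-6

    def test_matches_numerical_ode(self, rng):
        for _ in range(20):
            p = _noiseless(
                kg=float(10 ** rng.uniform(-5, -2)),
                kap=float(10 ** rng.uniform(-5, -2)),
                drift=float(rng.uniform(0, 1e-2)),
            )
            t = np.linspace(0, 7200, 60)
            sol = solve_ivp(
                lambda ti, y: [-p.kg * y[0], p.kg * y[0] - p.kap * y[1]],
                (0, 7200), [p.S0, 0.0], t_eval=t, rtol=1e-11, atol=1e-12,
            )
            numeric = p.F_bg + p.drift * t + p.F_scale * (p.S0 - sol.y[0] - sol.y[1])
            closed = beacon_kinetics(p, t)
            assert np.max(np.abs(numeric - closed)) <= 1e-6 * p.F_scale * p.S0

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(kg=-1e-4)


class TestActivityMetrics:
    def test_flat_trace_zero_endpoint(self):
        tr = _trace([0, 10, 20], [7, 7, 7])
        assert activity_endpoint(tr, 0, 20) == 0.0

    def test_linear_trace_endpoint(self):
        t = np.arange(0, 11.0)
        tr = _trace(t, 5 * t)
        assert activity_endpoint(tr, 0, 10) == pytest.approx(50.0)

    def test_endpoint_interpolates_between_samples(self):
        tr = _trace([0, 10], [0, 100])
        assert activity_endpoint(tr, 2.5, 7.5) == pytest.approx(50.0)

    def test_endpoint_beyond_trace_rejected(self):
        tr = _trace([0, 10], [0, 1])
        with pytest.raises(ValueError, match="outside trace span"):
            activity_endpoint(tr, 0, 11)

    def test_endpoint_matches_closed_form_on_noiseless_sim(self):
        p = _noiseless()
        t = np.arange(0.0, 7201.0, 0.5)
        tr = _trace(t, np.asarray(beacon_kinetics(p, t)))
        expected = float(beacon_kinetics(p, 7200.0) - beacon_kinetics(p, 0.0))
        assert activity_endpoint(tr, 0, 7200) == pytest.approx(expected, abs=1e-9)

    def test_slope_of_linear_trace(self):
        t = np.arange(0, 30.0)
        assert activity_slope(_trace(t, 3 * t + 7), (0, 29)) == pytest.approx(3.0)

    def test_slope_of_constant_trace_is_zero(self):
        t = np.arange(0, 30.0)
        assert activity_slope(_trace(t, np.full_like(t, 2.0)), (0, 29)) == (
            pytest.approx(0.0, abs=1e-12))

    def test_slope_needs_three_points(self):
        tr = _trace([0, 1, 2, 3], [0, 1, 2, 3])
        with pytest.raises(ValueError, match=">= 3"):
            activity_slope(tr, (0, 1))

    def test_early_slope_tracks_numerical_derivative(self):
        p = _noiseless(drift=0.0)
        t = np.arange(0.0, 301.0, 0.5)
        f = np.asarray(beacon_kinetics(p, t))
        slope = activity_slope(_trace(t, f), (0.0, 300.0))
        numeric = np.gradient(f, t).mean()
        assert slope == pytest.approx(numeric, rel=0.02)


class TestZPrime:
    def test_zero_sds_give_perfect_assay(self):
        qc = z_prime([100.0, 100.0], [10.0, 10.0])
        assert qc.z_prime == 1.0

    def test_hand_value(self):
        # sd 5 both groups, means 100 vs 10: 1 - 3*10/90
        pos = [95.0, 105.0]  # mean 100, sample sd ~7.07 -- use exact sd 5
        pos = [100 - 5, 100 + 5]
        # sample sd of two points a, b is |a-b|/sqrt(2); construct sd exactly 5
        d = 5 / np.sqrt(2)
        qc = z_prime([100 - d, 100 + d], [10 - d, 10 + d])
        assert qc.sd_pos == pytest.approx(5.0)
        assert qc.z_prime == pytest.approx(1 - 30 / 90)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError, match="separation undefined"):
            z_prime([5.0, 5.0], [5.0, 5.0])

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            pos = rng.normal(100, 5, 8)
            neg = rng.normal(10, 5, 8)
            assert z_prime(pos, neg).z_prime <= 1.0

    def test_monotone_non_increasing_in_noise(self):
        """Mean Z' over seeded plates never improves as noise grows."""
        means = []
        for noise in (1.0, 2.0, 5.0, 10.0, 20.0):
            zs = []
            for seed in range(50):
                p = KineticParams(noise_sd=noise)
                layout = [WellSpec(f"P{i}", "pos_control") for i in range(8)] + [
                    WellSpec(f"N{i}", "neg_control") for i in range(8)
                ]
                traces = simulate_plate(layout, p, seed=seed,
                                        times=np.array([0.0, 3600.0, 7200.0]))
                qc, _ = analyze_plate(traces)
                zs.append(qc.z_prime)
            means.append(np.mean(zs))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestInhibitionAndHits:
    QC = z_prime([100.0, 100.1, 99.9], [10.0, 10.1, 9.9])

    def test_pos_control_activity_is_zero_inhibition(self):
        assert percent_inhibition(self.QC.mean_pos, self.QC) == pytest.approx(0.0)

    def test_neg_control_activity_is_full_inhibition(self):
        assert percent_inhibition(self.QC.mean_neg, self.QC) == pytest.approx(100.0)

    def test_midpoint_arithmetic(self):
        assert percent_inhibition(55.0, self.QC) == pytest.approx(50.0, abs=0.1)

    def test_threshold_calling(self):
        hits = call_hits({"a": 60.0, "b": 40.0}, threshold=50.0)
        assert [(h.compound_id, h.is_hit) for h in hits] == [("a", True), ("b", False)]

    def test_zero_threshold_calls_everything(self):
        hits = call_hits({"a": -5.0, "b": 0.0}, threshold=0.0)
        assert all(h.is_hit for h in hits if h.pct_inhibition >= 0)

    def test_dataframe_collapses_replicates_by_median(self):
        import pandas as pd

        df = pd.DataFrame({"compound_id": ["a", "a", "a"],
                           "pct_inhibition": [10.0, 60.0, 80.0]})
        (hit,) = call_hits(df, threshold=50.0)
        assert hit.pct_inhibition == 60.0 and hit.is_hit

    def test_planted_inhibitors_recovered_on_simulated_plate(self):
        planted = {17, 150, 288}
        compounds = [
            ("C%03d" % i, 1e-5, 1e-7 if i in planted else float("inf"))
            for i in range(300)
        ]
        traces = simulate_plate(default_layout_384(compounds), KineticParams(),
                                seed=123)
        qc, inhibition = analyze_plate(traces)
        hits = {h.compound_id for h in call_hits(inhibition, 50.0) if h.is_hit}
        expected = {"C%03d" % i for i in planted}
        assert expected <= hits
        assert len(hits - expected) <= 1


class TestFit4PL:
    @staticmethod
    def _curve(conc, bottom, top, hill, ic50):
        return bottom + (top - bottom) / (1 + (conc / ic50) ** hill)

    def test_noiseless_self_consistency(self):
        conc = 1e-7 * 3.0 ** np.arange(10)
        resp = self._curve(conc, 0.0, 100.0, 1.0, 1e-5)
        fit = fit_4pl(conc, resp)
        assert fit.converged
        assert fit.ic50 == pytest.approx(1e-5, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)

    def test_recovery_under_multiplicative_noise(self):
        fitted = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            conc = 100e-6 / 3.0 ** np.arange(10)
            resp = self._curve(conc, 0.0, 100.0, 1.0, 10e-6)
            resp = resp * (1 + 0.05 * rng.standard_normal(10))
            fit = fit_4pl(conc, resp)
            fitted.append(fit.ic50)
        median = float(np.median(fitted))
        assert 0.75 * 10e-6 <= median <= 1.25 * 10e-6

    def test_flat_response_reports_non_convergence(self):
        conc = 1e-7 * 3.0 ** np.arange(6)
        fit = fit_4pl(conc, np.full(6, 42.0), noise_floor=1.0)
        assert not fit.converged and fit.reason == "flat_response"

    def test_rising_response_flags_hill_sign(self):
        conc = 1e-7 * 3.0 ** np.arange(8)
        resp = self._curve(conc, 100.0, 0.0, 1.0, 1e-5)  # increases with dose
        fit = fit_4pl(conc, resp)
        assert not fit.converged and fit.reason == "nonpositive_hill"

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            fit_4pl([1e-6, 2e-6, 4e-6, 8e-6], [1, 2, 3, 4])

    def test_ic50_recovers_ki_from_kinetic_simulation(self):
        """Endpoint inhibition measured in the low-conversion regime follows
        a 4PL in compound concentration with IC50 ~ Ki."""
        ki = 5e-6
        p = KineticParams(kg=2e-5, noise_sd=0.0)  # low conversion over 2 h
        conc = 100e-6 / 3.0 ** np.arange(10)
        layout = [WellSpec(f"W{i}", "compound", f"c{i}", float(c), ki)
                  for i, c in enumerate(conc)]
        traces = simulate_plate(layout, p, seed=0)
        resp = [activity_endpoint(tr, 0.0, 7200.0) for tr in traces]
        fit = fit_4pl(conc, resp)
        assert fit.converged
        assert fit.ic50 == pytest.approx(ki, rel=0.25)


class TestPlateSimulation:
    def test_neg_controls_flat_up_to_drift_and_noise(self):
        p = KineticParams(noise_sd=0.0)
        (tr,) = simulate_plate([WellSpec("A1", "neg_control")], p, seed=0)
        expected = p.F_bg + p.drift * tr.times
        assert tr.rfu == pytest.approx(expected)

    def test_ki_equal_conc_halves_excision_rate(self):
        p = KineticParams(kg=2e-5, noise_sd=0.0, drift=0.0)  # linear regime
        specs = [WellSpec("P", "pos_control"),
                 WellSpec("C", "compound", "c", 1e-5, 1e-5)]
        pos, cmpd = simulate_plate(specs, p, seed=0)
        a_pos = activity_endpoint(pos, 0, 7200)
        a_cmp = activity_endpoint(cmpd, 0, 7200)
        assert a_cmp / a_pos == pytest.approx(0.5, rel=0.05)

    def test_fluorescence_conservation_bound(self):
        p = KineticParams()
        traces = simulate_plate([WellSpec("P", "pos_control")] * 20, p, seed=1)
        for tr in traces:
            bound = p.F_bg + p.drift * tr.times + p.F_scale * p.S0 + 5 * p.noise_sd
            assert np.all(tr.rfu <= bound)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate([WellSpec("A1", "blank")], KineticParams(), seed=0)

    def test_default_plate_passes_qc(self):
        traces = simulate_plate(default_layout_384([]), KineticParams(), seed=5)
        qc, _ = analyze_plate(traces)
        assert qc.z_prime >= 0.5

    def test_tsv_round_trip(self, tmp_path):
        compounds = [("c1", 1e-5, 1e-6)]
        traces = simulate_plate(default_layout_384(compounds, n_controls=2),
                                KineticParams(), seed=3)
        path = tmp_path / "plate.tsv"
        traces_to_tsv(traces, path)
        back = traces_from_tsv(path)
        assert len(back) == len(traces)
        orig = {t.well: t for t in traces}
        for tr in back:
            assert tr.rfu == pytest.approx(orig[tr.well].rfu)
            assert tr.role == orig[tr.well].role
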