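"""Treatments, classification, Securin reporting, mutant screen."""

import numpy as np
import pandas as pd
import pytest

from sacsim import (AssayError, ConfigurationError, SolverSettings,
                    Thresholds, TimeCourse, Treatment, apply_treatment,
                    build_full_network, classify, nocodazole_to_kattach,
                    run_mutant_screen, securin_report, simulate)


class TestApplyTreatment:
    def test_mad2_depletion_scales_both_pools(self, ref_params):
        p = apply_treatment(ref_params, Treatment(
            kind="depletion", target="Mad2", magnitude=0.05))
        assert p.OMad2 == pytest.approx(0.05 * ref_params.OMad2)
        assert p.CMad2 == pytest.approx(0.05 * ref_params.CMad2)
        assert p.Cdc20 == ref_params.Cdc20

    def test_tenfold_overexpression(self, ref_params):
        p = apply_treatment(ref_params, Treatment(
            kind="overexpression", target="Cdc20", magnitude=10))
        assert p.Cdc20 == pytest.approx(10 * ref_params.Cdc20)

    def test_none_is_identity(self, ref_params):
        assert apply_treatment(ref_params, Treatment()) is ref_params

    def test_unknown_target_rejected(self, ref_params):
        with pytest.raises(ConfigurationError):
            apply_treatment(ref_params, Treatment(
                kind="depletion", target="Separase", magnitude=0.5))

    def test_nocodazole_touches_only_kattach(self, ref_params):
        p = apply_treatment(ref_params, Treatment(kind="nocodazole",
                                                  dose=10.0))
        assert p.k_attach == pytest.approx(ref_params.k_attach / 2.0)
        assert p.OMad2 == ref_params.OMad2


class TestNocodazoleMap:
    def test_zero_dose_identity(self):
        assert nocodazole_to_kattach(0.0, 0.0058) == 0.0058

    def test_half_effect_at_c50(self):
        assert nocodazole_to_kattach(10.0, 0.0058, c50=10.0) == \
            pytest.approx(0.0058 / 2)

    def test_monotone_over_dose_range(self):
        vals = [nocodazole_to_kattach(d, 0.0058) for d in
                np.linspace(1, 100, 25)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_stepwise_table_mode(self):
        table = {0.0: 1.0, 10.0: 0.4, 50.0: 0.1}
        assert nocodazole_to_kattach(5, 1.0, table=table) == 1.0
        assert nocodazole_to_kattach(10, 1.0, table=table) == 0.4
        assert nocodazole_to_kattach(99, 1.0, table=table) == \
            pytest.approx(0.1)


def _run(params, t_end=6000.0):
    return simulate(build_full_network(params),
                    SolverSettings(t_end=t_end, n_out=1200))


class TestClassify:
    def test_wild_type_full_inhibition_proper_exit(self, ref_params,
                                                   wt_timecourse):
        cl = classify(wt_timecourse, min(ref_params.APC, ref_params.Cdc20))
        assert (cl.inhibition, cl.exit) == ("FI", "PE")

    def test_mad2_depletion_fails_checkpoint(self, ref_params):
        p = apply_treatment(ref_params, Treatment(
            kind="depletion", target="Mad2", magnitude=0.05))
        cl = classify(_run(p), min(p.APC, p.Cdc20))
        assert (cl.inhibition, cl.exit) == ("NI", "IE")
        assert cl.reactivation_delay == 0.0   # premature activation

    def test_cdc20_depletion_delays_exit(self, ref_params):
        p = apply_treatment(ref_params, Treatment(
            kind="depletion", target="Cdc20", magnitude=0.05))
        cl = classify(_run(p), min(p.APC, p.Cdc20))
        assert (cl.inhibition, cl.exit) == ("FI", "DE")

    def test_pure_function_of_inputs(self, ref_params, wt_timecourse):
        apct = min(ref_params.APC, ref_params.Cdc20)
        a = classify(wt_timecourse, apct)
        b = classify(wt_timecourse, apct)
        assert a == b

    def test_short_trajectory_rejected(self, ref_params):
        tc = _run(ref_params, t_end=300.0)  # ends before last attachment
        with pytest.raises(AssayError):
            classify(tc, ref_params.APC)

    def test_thresholds_recorded(self, ref_params, wt_timecourse):
        th = Thresholds(theta_fi=0.2)
        cl = classify(wt_timecourse, ref_params.APC, th)
        assert cl.thresholds_used is th


class TestSecurinReport:
    def test_constant_securin_has_zero_rate(self):
        times = np.linspace(0, 100, 200)
        values = np.column_stack([np.full(200, 0.3)])
        tc = TimeCourse(times=times, values=values, species=["Securin"],
                        attachment_events=[], t_last_attach=50.0)
        norm, rate, _ = securin_report(tc)
        assert np.allclose(norm, 1.0)
        assert np.allclose(rate, 0.0, atol=1e-12)

    def test_exponential_decay_rate_recovered(self):
        """-dS/dt of S0*exp(-r t) is r*S(t); the smoothed estimate must
        match the analytic derivative away from the window edges."""
        r, s0 = 3e-3, 0.5
        times = np.linspace(0, 2000, 600)
        s = s0 * np.exp(-r * times)
        tc = TimeCourse(times=times, values=s[:, None], species=["Securin"],
                        attachment_events=[], t_last_attach=900.0)
        _, rate, _ = securin_report(tc)
        inner = slice(30, -30)
        np.testing.assert_allclose(rate[inner], r * s[inner], rtol=1e-3)

    def test_zero_initial_securin_rejected(self):
        tc = TimeCourse(times=np.linspace(0, 10, 50),
                        values=np.zeros((50, 1)), species=["Securin"],
                        attachment_events=[], t_last_attach=5.0)
        with pytest.raises(AssayError):
            securin_report(tc)

    def test_wild_type_rate_peaks_inside_mitosis(self, wt_timecourse):
        _, rate, onset = securin_report(wt_timecourse)
        assert 0 < onset < wt_timecourse.times[-1]
        assert onset > 0.0  # degradation accelerates after attachment starts


@pytest.fixture(scope="module")
def screen(ref_params):
    return run_mutant_screen(ref_params)


class TestScreen:
    def test_ten_rows_with_wild_type_first(self, screen):
        assert len(screen) == 10
        assert screen.iloc[0]["mutation"] == "Wild-Type"
        assert screen.iloc[0]["classification"] == "(FI) - (PE)"

    def test_every_row_classified(self, screen):
        assert set(screen["inhibition"]) <= {"FI", "WI", "NI"}
        assert set(screen["exit"]) <= {"PE", "DE", "IE"}

    def test_securin_monotone_under_all_screen_treatments(self, ref_params):
        for t in [Treatment(),
                  Treatment(kind="depletion", target="Mad2",
                            magnitude=0.4),
                  Treatment(kind="nocodazole", dose=30.0)]:
            p = apply_treatment(ref_params, t)
            tc = _run(p, t_end=4000.0)
            assert np.all(np.diff(tc["Securin"]) <= 1e-10)

    def test_sirna_exits_before_wild_type(self, ref_params, wt_timecourse):
        _, _, onset_wt = securin_report(wt_timecourse)
        p = apply_treatment(ref_params, Treatment(kind="siRNA_Mad2",
                                                  magnitude=0.05))
        _, _, onset_si = securin_report(_run(p))
        assert onset_si < onset_wt
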