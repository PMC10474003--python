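"""Steady states, invasion rates, feedback terms, and the interior solver."""

import numpy as np
import pytest

from timeco import (
    all_equilibria,
    ati_reinvasion_rate,
    closed_form_equilibria,
    feedback_terms,
    invasion_growth_rate,
    solve_tpa,
    steady_states_to_frame,
    tp_feasibility,
)
from timeco.equilibria import EquilibriumError

from _oracles import feasible_quadratic_tpa, quadratic_tpa_roots
from conftest import random_parameters


def by_label(states, label):
    return [s for s in states if s.label == label]


class TestInvasionRates:
    def test_tumor_into_ati_only_threshold(self, killing_sweep):
        # with unit growth rate and capacity the tumor invasion rate of the
        # cancer-free state vanishes exactly at alpha_TA = 1
        p = killing_sweep.replace(alpha_TA=1.0)
        assert invasion_growth_rate(p, (0, 0, p.K_A), "T") == 0.0

    def test_tumor_into_ati_only_value(self, basin_ref):
        assert invasion_growth_rate(basin_ref, (0, 0, 1.0), "T") == pytest.approx(-0.5)

    def test_matches_feedback_terms(self, basin_ref):
        assert feedback_terms(basin_ref).omega_T_to_A == pytest.approx(
            invasion_growth_rate(basin_ref, (0, 0, 1.0), "T"), abs=1e-14
        )

    def test_invader_already_present_rejected(self, basin_ref):
        with pytest.raises(EquilibriumError):
            invasion_growth_rate(basin_ref, (1.0, 0, 0), "T")

    def test_pti_invasion_diverges_with_conversion_influx(self, basin_ref):
        # at a state with A, T > 0 the conversion influx omega*A*T makes the
        # per-capita PTI growth rate diverge
        p = basin_ref.replace(omega=0.5)
        assert invasion_growth_rate(p, (1.0, 0, 1.0), "P") == np.inf

    def test_ati_invasion_of_tp_vanishes_at_transcritical(self, fold_sweep):
        p = fold_sweep.replace(omega=0.8325)
        assert abs(ati_reinvasion_rate(p)) < 1e-12


class TestFeedbackTerms:
    def test_tp_self_feedback(self, basin_ref):
        assert feedback_terms(basin_ref).gamma_TT_TP == pytest.approx(0.8575, abs=1e-14)

    def test_tp_self_feedback_violated(self, runaway_ref):
        # alpha_PT = 1.5 puts the tumor-PTI loop past tumor self-limitation
        assert feedback_terms(runaway_ref).gamma_TT_TP == pytest.approx(-0.425, abs=1e-14)

    def test_coexistence_self_feedback(self, killing_sweep):
        p = killing_sweep.replace(alpha_TA=0.5)
        assert feedback_terms(p).gamma_TT_TPA == pytest.approx(0.845, abs=1e-14)

    def test_tp_feasibility_margin(self, basin_ref, runaway_ref):
        ok, margin = tp_feasibility(basin_ref)
        assert ok and margin == pytest.approx(0.8575)
        ok, margin = tp_feasibility(runaway_ref)
        assert not ok and margin == pytest.approx(-0.425)

    def test_no_pti_growth_always_feasible(self, basin_ref):
        ok, _ = tp_feasibility(basin_ref.replace(alpha_TP=0.0))
        assert ok


class TestAtiReinvasion:
    def test_value_without_conversion(self, basin_ref):
        assert ati_reinvasion_rate(basin_ref) == pytest.approx(0.970845, abs=1e-6)

    def test_monotone_decreasing_in_omega(self, basin_ref):
        values = [ati_reinvasion_rate(basin_ref.replace(omega=w)) for w in (0, 1, 2)]
        assert values[0] > values[1] > values[2]
        assert values[2] < 0

    def test_infeasible_tp_rejected(self, runaway_ref):
        with pytest.raises(EquilibriumError):
            ati_reinvasion_rate(runaway_ref)


class TestClosedForms:
    def test_tumor_only_state(self, basin_ref):
        (t_state,) = by_label(closed_form_equilibria(basin_ref), "T")
        np.testing.assert_allclose(t_state.densities, [1.0, 0.0, 0.0])
        assert t_state.feasible

    def test_tp_state(self, basin_ref):
        (tp,) = by_label(closed_form_equilibria(basin_ref), "TP")
        np.testing.assert_allclose(
            tp.densities, [1.166180, 0.174927, 0.0], rtol=0, atol=1e-6
        )
        assert tp.residual < 1e-10

    def test_coexistence_without_conversion(self, killing_sweep):
        p = killing_sweep.replace(alpha_TA=0.5)
        (tpa,) = by_label(closed_form_equilibria(p), "TPA")
        np.testing.assert_allclose(
            tpa.densities, [0.591716, 0.088757, 0.985207], rtol=0, atol=1e-6
        )
        assert tpa.residual < 1e-10

    def test_tp_omitted_with_warning_when_infeasible(self, runaway_ref):
        with pytest.warns(UserWarning, match="unbounded-growth"):
            states = closed_form_equilibria(runaway_ref)
        assert not by_label(states, "TP")

    def test_no_ta_state_with_conversion(self, basin_ref):
        states = all_equilibria(
            basin_ref.replace(omega=0.3), include_infeasible=True
        )
        assert not by_label(states, "TA")

    def test_residuals_below_tolerance(self, basin_ref, rng):
        for _ in range(20):
            p = random_parameters(rng)
            for s in closed_form_equilibria(p):
                assert s.residual < 1e-10


class TestSolveTpa:
    def test_matches_closed_form_without_conversion(self, killing_sweep):
        p = killing_sweep.replace(alpha_TA=0.5)
        (closed,) = by_label(closed_form_equilibria(p), "TPA")
        (numeric,) = solve_tpa(p)
        np.testing.assert_allclose(
            numeric.densities, closed.densities, atol=1e-8, rtol=0
        )

    def test_bistable_window_has_two_roots(self, fold_sweep):
        # between the fold and the transcritical point the coexistence
        # branch is a stable/unstable pair
        from timeco import classify_stability

        p = fold_sweep.replace(omega=0.72)  # midway between ~0.611 and 0.8325
        roots = solve_tpa(p)
        assert len(roots) == 2
        verdicts = sorted(
            classify_stability(p, s).verdict for s in roots
        )
        assert verdicts == ["stable", "unstable"]

    def test_no_roots_below_fold(self, fold_sweep):
        with pytest.warns(UserWarning):
            roots = solve_tpa(fold_sweep.replace(omega=0.3))
        assert roots == []

    def test_matches_quadratic_oracle_on_random_draws(self, rng):
        for _ in range(30):
            p = random_parameters(rng)
            expected = feasible_quadratic_tpa(p)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = solve_tpa(p)
            assert len(got) == len(expected)
            for s in got:
                d = min(
                    np.max(np.abs(s.densities - np.asarray(e)))
                    for e in expected
                )
                assert d < 1e-7

    def test_infeasible_branch_exposed_on_request(self, fold_sweep):
        # beyond the pitchfork the fold survives only with negative ATI density
        p = fold_sweep.replace(alpha_TA=20.0, omega=0.8)
        feasible = solve_tpa(p)
        everything = solve_tpa(p, include_infeasible=True)
        assert len(feasible) == 0 and len(everything) == 2
        assert all(s.A < 0 for s in everything)


class TestExport:
    def test_frame_round_trips_labels_and_densities(self, basin_ref):
        states = all_equilibria(basin_ref)
        frame = steady_states_to_frame(states)
        assert set(frame.columns) >= {"label", "T", "P", "A", "feasible", "residual"}
        assert len(frame) == len(states)
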