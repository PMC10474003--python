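"""Sweeps, branch continuity, and codimension-one bifurcation location."""

import warnings

import numpy as np
import pytest

from timeco import (
    ati_reinvasion_rate,
    locate_pitchfork_alpha_ta,
    locate_saddle_node,
    phase_diagram,
    solve_tpa,
    sweep_omega,
    transcritical_omega,
)
from timeco.equilibria import EquilibriumError


class TestTranscritical:
    def test_value_and_alpha_ta_independence(self, fold_sweep):
        for alpha in (1.0, 2.0, 20.0):
            w = transcritical_omega(fold_sweep.replace(alpha_TA=alpha))
            assert w == pytest.approx(0.8325, abs=1e-14)

    def test_none_when_expression_negative(self, fold_sweep):
        assert transcritical_omega(fold_sweep.replace(alpha_AP=10.0)) is None

    def test_infeasible_tp_rejected(self, runaway_ref):
        with pytest.raises(EquilibriumError):
            transcritical_omega(runaway_ref)

    def test_coincides_with_ati_reinvasion_root(self, fold_sweep):
        from scipy.optimize import brentq

        w_tc = transcritical_omega(fold_sweep)
        root = brentq(
            lambda w: ati_reinvasion_rate(fold_sweep.replace(omega=w)), 0.1, 2.0,
            xtol=1e-14,
        )
        assert abs(root - w_tc) < 1e-12


class TestSaddleNode:
    def test_fold_location(self, fold_sweep):
        # frozen from the exact quadratic reduction of the interior system
        w = locate_saddle_node(fold_sweep, (1e-3, 0.8))
        assert w == pytest.approx(0.6109250, abs=1e-5)

    def test_root_counts_jump_across_fold(self, fold_sweep):
        w = locate_saddle_node(fold_sweep, (1e-3, 0.8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            below = solve_tpa(fold_sweep.replace(omega=w - 1e-4))
            above = solve_tpa(fold_sweep.replace(omega=w + 1e-4))
        assert (len(below), len(above)) == (0, 2)

    def test_none_when_branch_emerges_continuously(self, killing_sweep):
        # at the invasion threshold the coexistence branch grows out of the
        # cancer-free state: no fold
        p = killing_sweep.replace(alpha_TA=1.0)
        with pytest.warns(UserWarning, match="no fold"):
            assert locate_saddle_node(p, (1e-3, 0.8)) is None

    def test_infeasible_fold_decreases_beyond_pitchfork(self, fold_sweep):
        w12 = locate_saddle_node(
            fold_sweep.replace(alpha_TA=12.0), (0.5, 0.83), feasible_only=False
        )
        w20 = locate_saddle_node(
            fold_sweep.replace(alpha_TA=20.0), (0.5, 0.83), feasible_only=False
        )
        assert w12 is not None and w20 is not None
        assert w20 < w12 < 0.8325


class TestPitchfork:
    def test_location(self, fold_sweep):
        alpha = locate_pitchfork_alpha_ta(fold_sweep, (5.0, 15.0))
        assert alpha == pytest.approx(9.05, abs=0.01)

    def test_bracket_miss_returns_none(self, fold_sweep):
        with pytest.warns(UserWarning, match="does not straddle"):
            assert locate_pitchfork_alpha_ta(fold_sweep, (12.0, 15.0)) is None

    def test_fold_meets_transcritical_at_pitchfork(self, fold_sweep):
        # defining property: at the located alpha_TA the fold sits at the
        # transcritical omega (counting roots of either sign)
        alpha = locate_pitchfork_alpha_ta(fold_sweep, (5.0, 15.0))
        w_sn = locate_saddle_node(
            fold_sweep.replace(alpha_TA=alpha), (0.8, 0.84), feasible_only=False
        )
        assert w_sn is not None
        assert abs(w_sn - 0.8325) < 1e-4

    def test_coarse_fold_existence_cross_check(self, fold_sweep):
        # a feasible fold exists below the transcritical point just below
        # the pitchfork and disappears just above it
        alpha = locate_pitchfork_alpha_ta(fold_sweep, (5.0, 15.0))

        def has_fold(a):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = locate_saddle_node(
                    fold_sweep.replace(alpha_TA=a), (1e-3, 0.83249), xtol=1e-7
                )
            return w is not None

        assert has_fold(alpha - 0.5) and not has_fold(alpha + 0.5)


class TestSweep:
    def test_empty_grid_rejected(self, fold_sweep):
        with pytest.raises(ValueError):
            sweep_omega(fold_sweep, [])

    def test_detects_transcritical_and_fold(self, fold_sweep):
        d = sweep_omega(fold_sweep, np.linspace(0.3, 1.2, 46))
        kinds = {p.kind: p.value for p in d.detected_points}
        assert kinds["transcritical"] == pytest.approx(0.8325, abs=1e-9)
        assert kinds["saddle_node"] == pytest.approx(0.61093, abs=1e-4)

    def test_tp_leading_eigenvalue_vanishes_at_transcritical(self, fold_sweep):
        from timeco import classify_stability, closed_form_equilibria

        d = sweep_omega(fold_sweep, np.linspace(0.7, 1.0, 16))
        (tc,) = [p for p in d.detected_points if p.kind == "transcritical"]
        p = fold_sweep.replace(omega=tc.value)
        (tp,) = [s for s in closed_form_equilibria(p) if s.label == "TP"]
        lead = max(classify_stability(p, tp).eigenvalues.real)
        assert abs(lead) < 1e-6

    def test_stable_sets_in_each_regime(self, fold_sweep):
        d = sweep_omega(fold_sweep, np.linspace(0.3, 1.2, 46))
        assert d.stable_labels_at(0.4) == {"A"}  # below the fold
        assert d.stable_labels_at(0.72) == {"A", "TPA"}  # bistable window
        assert d.stable_labels_at(1.1) == {"A", "TP"}  # past transcritical

    def test_no_stable_tumor_free_state_when_tumor_invades(self, killing_sweep):
        p = killing_sweep.replace(alpha_TA=0.5)
        d = sweep_omega(p, np.linspace(0.0, 2.0, 21))
        for w in d.grid:
            for label in d.stable_labels_at(w):
                (s,) = [
                    b.state for b in d.at(w) if b.state.label == label and b.stable
                ]
                assert s.T > 1e-9

    def test_branch_continuity(self, fold_sweep):
        d = sweep_omega(fold_sweep, np.linspace(0.3, 1.2, 46))
        frame = d.to_frame()
        step = np.diff(d.grid).max()
        for _, branch in frame.groupby("branch_id"):
            xyz = branch[["T", "P", "A"]].to_numpy()
            if len(xyz) > 1:
                jumps = np.abs(np.diff(xyz, axis=0)).max(axis=1)
                assert jumps.max() < max(10 * step, 0.25)


class TestPhaseDiagram:
    def test_regimes_at_reference_points(self, basin_ref):
        grid = phase_diagram(basin_ref, (1.49, 1.51), (0.0, 2.0), resolution=3)
        # (alpha_TA=1.5, omega=0): cancer-free only; (1.5, 2): A/TP bistable
        assert grid.labels[1, 0] == "A_only_stable"
        assert grid.labels[1, 2] == "A_TP_bistable"

    def test_boundaries_consistent_with_located_points(self, basin_ref):
        w_tc = transcritical_omega(basin_ref)
        w_sn = locate_saddle_node(basin_ref, (1e-3, 0.8))
        omegas = np.linspace(0.0, 1.0, 11)
        grid = phase_diagram(basin_ref, (1.5, 1.5), (0.0, 1.0), resolution=11)
        labels = grid.labels[0]
        for w, lab in zip(omegas, labels):
            if w < w_sn - 0.05:
                assert lab == "A_only_stable"
            elif w_sn + 0.05 < w < w_tc - 0.05:
                assert lab == "A_TPA_bistable"
            elif w > w_tc + 0.05:
                assert lab == "A_TP_bistable"
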