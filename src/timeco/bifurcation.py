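"""Parameter sweeps, branch tracking, and codimension-one bifurcations.

Three bifurcations organize the dynamics as the conversion rate ``omega``
(and the ATI killing rate ``alpha_TA``) vary:

* a **saddle-node** on the coexistence (TPA) branch: below a critical
  ``omega`` there is no steady state with positive tumor density, above it
  a stable/unstable pair exists — the tumor needs a minimal conversion
  rate to persist;
* a **transcritical** point where the stable TPA branch collides with the
  TP state and they exchange stability; its location has the closed form
  ``omega_TC = Gamma_{T->T;TP} * r_A/r_T + alpha_AT - alpha_AP*alpha_PT/d_P``
  (the equality case of the TP stability condition), independent of
  ``alpha_TA``;
* a **pitchfork** at the ``alpha_TA`` where the fold collides with the
  transcritical point; beyond it the fold survives only on an infeasible
  (negative-A) branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import (
    FEASIBILITY_TOL,
    EquilibriumError,
    SteadyState,
    all_equilibria,
    feedback_terms,
    solve_tpa,
    tp_feasibility,
)
from .model import BASELINE_VARIANT, ModelParameters, ModelVariant
from .stability import StabilityVerdict, classify_stability

__all__ = [
    "BifurcationDiagram",
    "DetectedPoint",
    "sweep_omega",
    "transcritical_omega",
    "locate_saddle_node",
    "locate_pitchfork_alpha_ta",
    "phase_diagram",
    "RegimeGrid",
]


@dataclass(frozen=True)
class DetectedPoint:
    """A detected codimension-one bifurcation."""

    kind: str  # {"saddle_node", "transcritical", "pitchfork"}
    parameter: str
    value: float
    description: str = ""


@dataclass
class BranchSample:
    """One steady state on one branch at one grid value."""

    parameter_value: float
    branch_id: int
    state: SteadyState
    verdict: StabilityVerdict

    @property
    def stable(self) -> bool:
        return self.verdict.is_stable


@dataclass
class BifurcationDiagram:
    """Swept branches with stability and detected bifurcation points."""

    swept_parameter: str
    grid: np.ndarray
    samples: list[BranchSample]
    detected_points: list[DetectedPoint] = field(default_factory=list)

    def at(self, value: float) -> list[BranchSample]:
        """Samples at the grid value closest to ``value``."""
        v = self.grid[np.argmin(np.abs(self.grid - value))]
        return [s for s in self.samples if s.parameter_value == v]

    def stable_labels_at(self, value: float) -> set[str]:
        return {s.state.label for s in self.at(value) if s.stable}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                self.swept_parameter: s.parameter_value,
                "branch_id": s.branch_id,
                "label": s.state.label,
                "T": s.state.T,
                "P": s.state.P,
                "A": s.state.A,
                "feasible": s.state.feasible,
                "stable": s.stable,
                "verdict": s.verdict.verdict,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)

    def detected_to_records(self) -> list[dict]:
        return [
            {
                "kind": d.kind,
                "parameter": d.parameter,
                "value": d.value,
                "description": d.description,
            }
            for d in self.detected_points
        ]


def transcritical_omega(params: ModelParameters) -> float | None:
    """The conversion rate at which the TPA branch collides with TP.

    Equality case of the TP stability condition,
    ``Gamma_{T->T;TP} * r_A/r_T + alpha_AT - alpha_AP*alpha_PT/d_P``;
    independent of ``alpha_TA``.  Returns ``None`` when the expression is
    non-positive (TP then never stabilizes by increasing conversion).
    Requires the TP state to be feasible.
    """
    feasible, _ = tp_feasibility(params)
    if not feasible:
        raise EquilibriumError("TP state infeasible: transcritical point undefined")
    p = params
    rates = feedback_terms(p)
    value = (
        rates.gamma_TT_TP * p.r_A / p.r_T
        + p.alpha_AT
        - p.alpha_AP * p.alpha_PT / p.d_P
    )
    return value if value > 0 else None


def _classify_fast(params, state, variant, resolve_marginal):
    """Linear classification; marginal states resolved numerically only on
    request (the sweep resolves them, regime grids use the validated
    sign-of-invasion-rate shortcut for the A state)."""
    if resolve_marginal:
        return classify_stability(params, state, variant)
    from .model import evaluate_jacobian
    import numpy.linalg as la

    eig = la.eigvals(evaluate_jacobian(params, state.densities, variant))
    re = eig.real
    if np.all(re < -1e-8):
        return StabilityVerdict(eig, "stable", "linear")
    if np.any(re > 1e-8):
        return StabilityVerdict(eig, "unstable", "linear")
    # marginal; for the A state of the baseline model, stability is
    # equivalent to a negative tumor invasion rate (validated property)
    if variant.is_baseline and state.label == "A":
        om = feedback_terms(params).omega_T_to_A
        verdict = (
            "marginal_numerically_stable" if om < 0 else "marginal_numerically_unstable"
        )
        return StabilityVerdict(eig, verdict, "linear_plus_numeric")
    return classify_stability(params, state, variant)


def sweep_omega(
    params: ModelParameters,
    omega_grid,
    variant: ModelVariant = BASELINE_VARIANT,
    *,
    include_infeasible: bool = False,
    resolve_marginal: bool = False,
) -> BifurcationDiagram:
    """All steady states and verdicts at each conversion rate in the grid.

    Branches are matched between consecutive grid points by nearest
    neighbor in the full three-dimensional state space (the per-density
    projections of a diagram can cross without the branches intersecting),
    with label continuity as tie-break.  Detects the transcritical point
    (stability swap of the TP branch, refined by bisection on its leading
    eigenvalue) and saddle-node points (changes in the feasible
    coexistence-root count) for the baseline variant.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.size == 0:
        raise ValueError("omega grid is empty")
    if np.any(np.diff(omega_grid) <= 0):
        raise ValueError("omega grid must be strictly increasing")

    samples: list[BranchSample] = []
    prev: list[BranchSample] = []
    next_branch_id = 0
    tpa_feasible_count: list[int] = []
    tp_leading: list[float] = []

    for w in omega_grid:
        p = params.replace(omega=w)
        states = all_equilibria(p, variant, include_infeasible=include_infeasible)
        verdicts = [
            _classify_fast(p, s, variant, resolve_marginal) for s in states
        ]
        # nearest-neighbor continuation in (T, P, A)
        current: list[BranchSample] = []
        unmatched_prev = list(prev)
        for s, v in zip(states, verdicts):
            best, best_d = None, np.inf
            for q in unmatched_prev:
                d = float(np.max(np.abs(s.densities - q.state.densities)))
                if q.state.label == s.label:
                    d *= 0.5  # label continuity as tie-break
                if d < best_d:
                    best, best_d = q, d
            if best is not None and best_d < _step_bound(params, omega_grid):
                bid = best.branch_id
                unmatched_prev.remove(best)
            else:
                bid = next_branch_id
                next_branch_id += 1
            current.append(BranchSample(w, bid, s, v))
        samples.extend(current)
        prev = current
        tpa_feasible_count.append(
            sum(
                1
                for s in states
                if s.label == "TPA" and np.all(s.densities > FEASIBILITY_TOL)
            )
        )
        tp_lead = [
            max(bs.verdict.eigenvalues.real)
            for bs in current
            if bs.state.label == "TP"
        ]
        tp_leading.append(tp_lead[0] if tp_lead else np.nan)

    detected: list[DetectedPoint] = []
    if variant.is_baseline:
        detected.extend(
            _detect_transcritical(params, omega_grid, np.array(tp_leading))
        )
        detected.extend(
            _detect_saddle_nodes(params, omega_grid, tpa_feasible_count)
        )
    return BifurcationDiagram("omega", omega_grid, samples, detected)


def _step_bound(params: ModelParameters, grid: np.ndarray) -> float:
    """Continuation match threshold: generous multiple of the grid step
    relative to the density scale (branches move O(step) per grid point
    away from bifurcations)."""
    scale = max(params.K_T, params.K_A, 1.0)
    step = np.median(np.diff(grid)) if grid.size > 1 else 1.0
    return max(10.0 * step, 0.25 * scale)


def _detect_transcritical(params, grid, tp_leading):
    out = []
    valid = ~np.isnan(tp_leading)
    for i in range(len(grid) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        a, b = tp_leading[i], tp_leading[i + 1]
        if a == 0 or b == 0 or np.sign(a) == np.sign(b):
            continue
        from scipy.optimize import brentq

        def lead(w):
            p = params.replace(omega=w)
            rates = feedback_terms(p)
            if rates.omega_A_to_TP is None:
                return np.nan
            return rates.omega_A_to_TP  # leading TP eigenvalue = ATI reinvasion rate

        try:
            w_tc = brentq(lead, grid[i], grid[i + 1], xtol=1e-12)
        except ValueError:
            w_tc = 0.5 * (grid[i] + grid[i + 1])
        out.append(
            DetectedPoint(
                "transcritical",
                "omega",
                float(w_tc),
                "TP/TPA collision with stability swap",
            )
        )
    return out


def _detect_saddle_nodes(params, grid, counts):
    out = []
    for i in range(len(grid) - 1):
        lo_n, hi_n = counts[i], counts[i + 1]
        if {lo_n, hi_n} == {0, 2}:
            w = locate_saddle_node(params, (grid[i], grid[i + 1]))
            if w is not None:
                out.append(
                    DetectedPoint(
                        "saddle_node",
                        "omega",
                        float(w),
                        "feasible coexistence pair created/destroyed",
                    )
                )
    return out


def _tpa_count(params: ModelParameters, omega: float, feasible_only: bool) -> int:
    p = params.replace(omega=omega)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # a 10x10 start grid is ample for counting (at most two roots exist)
        states = solve_tpa(p, include_infeasible=not feasible_only, n_per_axis=10)
    return len(states)


def locate_saddle_node(
    params: ModelParameters,
    omega_bracket,
    *,
    feasible_only: bool = True,
    xtol: float = 1e-6,
) -> float | None:
    """Fold of the coexistence branch, by bisection on the root count.

    The number of coexistence roots jumps between 0 and 2 across the fold;
    bisection refines the jump to ``|d omega| < xtol``.  With
    ``feasible_only=False`` roots with negative ATI density count too,
    which is needed beyond the pitchfork where the fold survives only on
    the infeasible branch.  Returns ``None`` (with a diagnostic warning)
    when both bracket ends see the same count.
    """
    lo, hi = float(omega_bracket[0]), float(omega_bracket[1])
    n_lo = _tpa_count(params, lo, feasible_only)
    n_hi = _tpa_count(params, hi, feasible_only)
    if (n_lo == 0) == (n_hi == 0):
        warnings.warn(
            f"no fold in bracket: {n_lo} roots at omega={lo}, {n_hi} at omega={hi}",
            stacklevel=2,
        )
        return None
    # orient so that `a` has 0 roots
    a, b = (lo, hi) if n_lo == 0 else (hi, lo)
    while abs(b - a) > xtol:
        m = 0.5 * (a + b)
        if _tpa_count(params, m, feasible_only) == 0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def locate_pitchfork_alpha_ta(
    params: ModelParameters,
    alpha_bracket,
    *,
    xtol: float = 1e-3,
) -> float | None:
    """The ATI killing rate at which the fold meets the transcritical point.

    Below the pitchfork the feasible coexistence pair folds at some
    ``omega_SN < omega_TC``; at the pitchfork the fold reaches the
    transcritical point and the two coincide.  At that degeneracy the TP
    point is a *double* root of the reduced interior system at
    ``omega_TC``, so the pitchfork is located by root-finding the reduced
    Jacobian determinant at the TP point (evaluated at ``omega_TC``) over
    ``alpha_TA`` — a smooth sign change, robust where direct fold counting
    degenerates because the colliding pair is separated by less than the
    root-finder can resolve.  Returns ``None`` (with a diagnostic) when
    the bracket does not straddle a sign change.
    """
    from scipy.optimize import brentq

    w_tc = transcritical_omega(params)
    if w_tc is None:
        raise EquilibriumError("no transcritical point: pitchfork undefined")

    from .equilibria import feedback_terms as _ft, interior_reduced_system

    def det_at_tp(alpha: float) -> float:
        p = params.replace(alpha_TA=alpha, omega=w_tc)
        rates = _ft(p)
        T_tp = p.r_T / rates.gamma_TT_TP
        P_tp = p.alpha_PT / p.d_P * T_tp
        reduced, _ = interior_reduced_system(p)
        x0 = np.array([T_tp, P_tp])
        h = 1e-7 * max(1.0, T_tp)
        J = np.empty((2, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            J[:, j] = (reduced(x0 + e) - reduced(x0 - e)) / (2 * h)
        return float(np.linalg.det(J))

    lo, hi = float(alpha_bracket[0]), float(alpha_bracket[1])
    f_lo, f_hi = det_at_tp(lo), det_at_tp(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        warnings.warn(
            f"bracket [{lo}, {hi}] does not straddle the pitchfork "
            f"(determinant signs {np.sign(f_lo)}, {np.sign(f_hi)})",
            stacklevel=2,
        )
        return None
    return float(brentq(det_at_tp, lo, hi, xtol=min(xtol, 1e-6)))


# ---------------------------------------------------------------------------
# two-parameter regime map
# ---------------------------------------------------------------------------

REGIME_LABELS = (
    "A_only_stable",
    "TPA_stable",
    "A_TPA_bistable",
    "A_TP_bistable",
    "no_T_zero_stable",
)


@dataclass
class RegimeGrid:
    """Stable-state regime per (alpha_TA, omega) grid point."""

    alpha_ta_values: np.ndarray
    omega_values: np.ndarray
    labels: np.ndarray  # shape (n_alpha, n_omega), dtype object

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.alpha_ta_values):
            for j, w in enumerate(self.omega_values):
                rows.append(
                    {"alpha_TA": a, "omega": w, "regime": self.labels[i, j]}
                )
        return pd.DataFrame(rows)


def _regime_label(stable: set[str]) -> str:
    a = "A" in stable
    if a and "TP" in stable:
        return "A_TP_bistable"
    if a and "TPA" in stable:
        return "A_TPA_bistable"
    if a:
        return "A_only_stable"
    if "TPA" in stable:
        return "TPA_stable"
    return "no_T_zero_stable"


def phase_diagram(
    params: ModelParameters,
    alpha_ta_range,
    omega_range,
    resolution: int = 25,
) -> RegimeGrid:
    """Regime map over (alpha_TA, omega) from the stable-state set.

    At each grid point the baseline equilibria are computed and classified
    (the A state via the validated invasion-rate criterion, the rest
    linearly); the point is labeled by which of {A, TP, TPA} are stable.
    """
    alphas = np.linspace(alpha_ta_range[0], alpha_ta_range[1], resolution)
    omegas = np.linspace(omega_range[0], omega_range[1], resolution)
    labels = np.empty((alphas.size, omegas.size), dtype=object)
    for i, a in enumerate(alphas):
        for j, w in enumerate(omegas):
            p = params.replace(alpha_TA=a, omega=w)
            stable = set()
            for s in all_equilibria(p):
                v = _classify_fast(p, s, BASELINE_VARIANT, resolve_marginal=False)
                if v.is_stable and s.feasible:
                    stable.add(s.label)
            labels[i, j] = _regime_label(stable)
    return RegimeGrid(alphas, omegas, labels)
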