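"""Steady states of the model: closed forms, numeric interior solver, and the
invasion / feedback rates that organize them.

Steady states are classified by which cell types have positive density:

* ``TRIVIAL`` — extinction, ``(0, 0, 0)``;
* ``T`` — tumor-only, ``(K_T, 0, 0)``;
* ``A`` — ATI-only (cancer-free), ``(0, 0, K_A)``;
* ``TA`` — tumor-ATI coexistence (exists only without conversion, since
  ``dP/dt = omega*A*T > 0`` whenever ``omega, A, T > 0``);
* ``TP`` — tumor-PTI coexistence (cancer state with the local anti-tumor
  response extinguished);
* ``TPA`` — three-way coexistence ("stalemate"); the only class that can
  have more than one member, and the only one without a general closed form
  when ``omega > 0``.

Two families of derived quantities compress the closed forms:

* invasion growth rates ``Omega_{X->S}`` — the per-capita growth rate of an
  infinitesimal density of type ``X`` introduced at steady state ``S``;
* net negative feedbacks ``Gamma_{X->Y;S}`` — aggregate feedback
  coefficients, e.g. ``Gamma_{T->T;TP} = r_T/K_T - alpha_TP*alpha_PT/d_P``,
  whose positivity is exactly the feasibility condition for the TP state
  (violated, the tumor-PTI positive feedback loop overwhelms tumor
  self-limitation and unbounded growth is possible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (
    BASELINE_VARIANT,
    ModelParameters,
    ModelVariant,
    evaluate_jacobian,
    evaluate_rhs,
)

__all__ = [
    "SteadyState",
    "DerivedRates",
    "invasion_growth_rate",
    "feedback_terms",
    "closed_form_equilibria",
    "solve_tpa",
    "find_equilibria",
    "all_equilibria",
    "tp_feasibility",
    "ati_reinvasion_rate",
    "steady_states_to_frame",
]

#: residual bound (max-norm of the vector field) for any reported state
RESIDUAL_TOL = 1e-10
#: strict-positivity tolerance separating interior from boundary densities
FEASIBILITY_TOL = 1e-9
#: distinct roots are merged when within this max-norm distance
DEDUP_TOL = 1e-7
#: fixed seed for any randomized multistart jitter
MULTISTART_SEED = 20230901

LABELS = ("TRIVIAL", "T", "A", "TA", "TP", "TPA")


class EquilibriumError(ValueError):
    """Domain error for equilibrium computations (e.g. infeasible TP state)."""


@dataclass(frozen=True)
class SteadyState:
    """A steady state with its class label and bookkeeping.

    ``feasible`` means all densities are non-negative (strictly positive
    interior components are classified with tolerance ``FEASIBILITY_TOL``).
    ``residual`` is the max-norm of the vector field at the state.
    """

    densities: np.ndarray
    label: str
    feasible: bool
    residual: float
    provenance: str  # {"closed_form", "numeric"}

    def __post_init__(self):
        object.__setattr__(
            self, "densities", np.asarray(self.densities, dtype=float)
        )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def T(self) -> float:
        return float(self.densities[0])

    @property
    def P(self) -> float:
        return float(self.densities[1])

    @property
    def A(self) -> float:
        return float(self.densities[2])


def classify_label(densities, tol: float = FEASIBILITY_TOL) -> str:
    """Label from the sign pattern of the densities (|x| <= tol counts as 0)."""
    T, P, A = densities
    t, p, a = (abs(T) > tol, abs(P) > tol, abs(A) > tol)
    if not (t or p or a):
        return "TRIVIAL"
    if t and p and a:
        return "TPA"
    if t and p:
        return "TP"
    if t and a:
        return "TA"
    if t:
        return "T"
    if a:
        return "A"
    return "TPA"  # P-only sign patterns do not occur; fall through defensively


def _make_state(
    params: ModelParameters,
    densities,
    provenance: str,
    variant: ModelVariant = BASELINE_VARIANT,
) -> SteadyState:
    densities = np.asarray(densities, dtype=float)
    residual = float(
        np.max(np.abs(evaluate_rhs(params, densities, variant)))
    )
    feasible = bool(np.all(densities >= -FEASIBILITY_TOL))
    return SteadyState(
        densities=densities,
        label=classify_label(densities),
        feasible=feasible,
        residual=residual,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# invasion growth rates and feedback terms
# ---------------------------------------------------------------------------

_INVADER_INDEX = {"T": 0, "P": 1, "A": 2}


def invasion_growth_rate(
    params: ModelParameters,
    resident: SteadyState | np.ndarray,
    invader: str,
    variant: ModelVariant = BASELINE_VARIANT,
) -> float:
    """Per-capita growth rate of an infinitesimal invader at a resident state.

    Defined as ``lim_{dN->0+} (1/dN) dN/dt`` with an infinitesimal density
    ``dN`` of the invader added to the resident steady state.  When the
    invader's equation has a source term that is already positive at zero
    invader density (e.g. the conversion influx ``omega*A*T`` for P), the
    per-capita rate diverges and ``+inf`` is returned: invasion always
    succeeds.  Otherwise the limit is the diagonal Jacobian entry.
    """
    dens = resident.densities if isinstance(resident, SteadyState) else np.asarray(
        resident, dtype=float
    )
    try:
        j = _INVADER_INDEX[invader]
    except KeyError:
        raise EquilibriumError(f"invader must be one of 'T','P','A', got {invader!r}")
    if dens[j] > FEASIBILITY_TOL:
        raise EquilibriumError(
            f"invader {invader} already present at density {dens[j]}"
        )
    f0 = evaluate_rhs(params, dens, variant)[j]
    if abs(f0) > RESIDUAL_TOL:
        # source-driven influx (or outflux) independent of invader density
        return float(np.inf if f0 > 0 else -np.inf)
    return float(evaluate_jacobian(params, dens, variant)[j, j])


@dataclass(frozen=True)
class DerivedRates:
    """Invasion rates Omega and net negative feedbacks Gamma (baseline model).

    ``omega_A_to_TP`` is ``None`` when the TP state is infeasible.
    """

    omega_T_to_A: float
    omega_A_to_T: float
    omega_A_to_TP: float | None
    gamma_TT_TP: float
    gamma_TT_TPA: float
    gamma_TA_TPA: float
    gamma_AA_TA: float


def feedback_terms(params: ModelParameters) -> DerivedRates:
    """All Omega/Gamma terms appearing in the closed-form steady states.

    * ``Omega_{T->A} = r_T - alpha_TA*K_A`` — tumor invading the cancer-free
      state.
    * ``Omega_{A->T} = r_A + (alpha_AT - omega)*K_T`` — ATI invading the
      tumor-only state.
    * ``Gamma_{T->T;TP} = r_T/K_T - alpha_TP*alpha_PT/d_P`` — net tumor
      self-limitation at TP; its positivity is the TP feasibility condition.
    * ``Gamma_{T->T;TPA}`` — net tumor self-limitation at the omega=0
      coexistence state, including the indirect channels through A and P.
    * ``Gamma_{T->A;TPA} = alpha_AP*alpha_PT/d_P - alpha_AT`` — net negative
      effect of tumor density on the ATI density at coexistence.
    * ``Gamma_{A->A;TA} = r_A/K_A + alpha_AT*alpha_TA*K_T/r_T`` — net ATI
      self-limitation at the (omega=0) tumor-ATI state.
    """
    p = params
    sA = p.r_A / p.K_A  # ATI self-limitation coefficient
    gamma_TT_TP = p.r_T / p.K_T - p.alpha_TP * p.alpha_PT / p.d_P
    gamma_TT_TPA = (
        p.r_T / p.K_T
        + p.alpha_TA * p.alpha_AT / sA
        - p.alpha_TA * p.alpha_AP * p.alpha_PT / (sA * p.d_P)
        - p.alpha_TP * p.alpha_PT / p.d_P
    )
    gamma_TA_TPA = p.alpha_AP * p.alpha_PT / p.d_P - p.alpha_AT
    gamma_AA_TA = sA + p.alpha_AT * p.alpha_TA * p.K_T / p.r_T

    omega_A_to_TP = None
    if gamma_TT_TP > 0:
        T_tp = p.r_T / gamma_TT_TP
        P_tp = p.alpha_PT / p.d_P * T_tp
        omega_A_to_TP = p.r_A + (p.alpha_AT - p.omega) * T_tp - p.alpha_AP * P_tp

    return DerivedRates(
        omega_T_to_A=p.r_T - p.alpha_TA * p.K_A,
        omega_A_to_T=p.r_A + (p.alpha_AT - p.omega) * p.K_T,
        omega_A_to_TP=omega_A_to_TP,
        gamma_TT_TP=gamma_TT_TP,
        gamma_TT_TPA=gamma_TT_TPA,
        gamma_TA_TPA=gamma_TA_TPA,
        gamma_AA_TA=gamma_AA_TA,
    )


def tp_feasibility(params: ModelParameters) -> tuple[bool, float]:
    """Whether the TP state is feasible, and the margin ``Gamma_{T->T;TP}``.

    Feasibility requires ``r_T/K_T > alpha_TP*alpha_PT/d_P``: direct tumor
    self-limitation must exceed the tumor->PTI->tumor positive feedback.
    When violated, unbounded tumor growth is possible.
    """
    margin = feedback_terms(params).gamma_TT_TP
    return margin > 0, margin


def ati_reinvasion_rate(params: ModelParameters) -> float:
    """Growth rate of a small ATI density introduced at the TP state.

    ``r_A + (alpha_AT - omega)*T_TP - alpha_AP*P_TP``; a non-positive value
    signals possible bistability between the cancer-free (A) and cancer (TP)
    states.  Strictly decreasing in omega since ``T_TP > 0``.
    """
    rates = feedback_terms(params)
    if rates.omega_A_to_TP is None:
        raise EquilibriumError(
            "TP state is infeasible (Gamma_{T->T;TP} <= 0); "
            "ATI reinvasion rate undefined"
        )
    return rates.omega_A_to_TP


# ---------------------------------------------------------------------------
# closed-form steady states (baseline model)
# ---------------------------------------------------------------------------

def closed_form_equilibria(params: ModelParameters) -> list[SteadyState]:
    """All steady states of the baseline model with a closed form.

    Always returns TRIVIAL, T, and A.  TA and the coexistence (TPA) closed
    form exist only at ``omega = 0``.  TP is returned when feasible
    (``Gamma_{T->T;TP} > 0``); otherwise it is omitted with a warning, since
    the system is then in the unbounded-growth regime.  For ``omega > 0``
    the coexistence states have no general closed form — use
    :func:`solve_tpa`.
    """
    p = params
    rates = feedback_terms(p)
    out = [
        _make_state(p, (0.0, 0.0, 0.0), "closed_form"),
        _make_state(p, (p.K_T, 0.0, 0.0), "closed_form"),
        _make_state(p, (0.0, 0.0, p.K_A), "closed_form"),
    ]

    if p.omega == 0:
        # TA: A = Omega_{A->T} / Gamma_{A->A;TA}, T from the tumor nullcline
        A_ta = rates.omega_A_to_T / rates.gamma_AA_TA
        T_ta = p.K_T * (1.0 - (p.alpha_TA / p.r_T) * A_ta)
        out.append(_make_state(p, (T_ta, 0.0, A_ta), "closed_form"))

    if rates.gamma_TT_TP > 0:
        T_tp = p.r_T / rates.gamma_TT_TP
        P_tp = p.alpha_PT / p.d_P * T_tp
        out.append(_make_state(p, (T_tp, P_tp, 0.0), "closed_form"))
    else:
        warnings.warn(
            "TP state omitted: Gamma_{T->T;TP} <= 0 (unbounded-growth regime)",
            stacklevel=2,
        )

    if p.omega == 0 and rates.gamma_TT_TPA != 0:
        sA = p.r_A / p.K_A
        T_i = rates.omega_T_to_A / rates.gamma_TT_TPA
        P_i = p.alpha_PT / p.d_P * T_i
        A_i = p.K_A - rates.gamma_TA_TPA / sA * T_i
        out.append(_make_state(p, (T_i, P_i, A_i), "closed_form"))

    return out


# ---------------------------------------------------------------------------
# numeric interior (TPA) solver
# ---------------------------------------------------------------------------

def interior_reduced_system(params: ModelParameters):
    """Reduce the baseline interior equilibrium problem to two variables.

    On the interior tumor nullcline (``dT/dt = 0`` divided by ``T``) the
    ATI density is ``A(T, P) = (r_T - (r_T/K_T) T + alpha_TP P)/alpha_TA``.
    Substituting it into the P equation and the interior ATI nullcline
    (``dA/dt`` divided by ``A``) leaves a polynomial system in ``(T, P)``
    whose roots (with ``T, P != 0``) are the coexistence states.

    Returns ``(reduced, A_of)``: the residual function of ``(T, P)`` and
    the eliminated ATI density.  Requires ``alpha_TA > 0``.
    """
    p = params
    if p.alpha_TA <= 0:
        raise EquilibriumError("alpha_TA must be positive to eliminate A")

    def A_of(T, P):
        return (p.r_T - (p.r_T / p.K_T) * T + p.alpha_TP * P) / p.alpha_TA

    def reduced(x):
        T, P = x
        A = A_of(T, P)
        fP = P * (-p.d_P * P + p.alpha_PT * T) + p.omega * A * T
        fA = (
            p.r_A
            - (p.r_A / p.K_A) * A
            + (p.alpha_AT - p.omega) * T
            - p.alpha_AP * P
        )
        return np.array([fP, fA])

    return reduced, A_of


def _multistart_grid(upper: float, n_per_axis: int = 20) -> np.ndarray:
    """Hybrid log/linear 1-D grid of starting values in (0, upper]."""
    n_log = n_per_axis // 2
    n_lin = n_per_axis - n_log
    logs = np.geomspace(upper * 1e-4, upper * 0.5, n_log)
    lins = np.linspace(upper / n_lin, upper, n_lin)
    return np.concatenate([logs, lins])


def _refine_root(params, x, variant=BASELINE_VARIANT) -> np.ndarray:
    """Snap near-boundary components to zero and Newton-polish the rest.

    Residual-based convergence leaves position error up to ~sqrt(tol) in
    directions where the vector field is quadratically flat (e.g. the PTI
    direction at the cancer-free state), so components numerically
    indistinguishable from an exact boundary zero are snapped — accepted
    only when the residual stays within tolerance — and the remaining
    coordinates are polished by Newton on the corresponding subsystem.
    """
    x = np.asarray(x, dtype=float).copy()
    x[np.abs(x) < FEASIBILITY_TOL] = 0.0

    def res(y):
        return float(np.max(np.abs(evaluate_rhs(params, y, variant))))

    def polish(y):
        y = y.copy()
        nz = np.flatnonzero(y != 0.0)
        for _ in range(8):
            r = evaluate_rhs(params, y, variant)
            if np.max(np.abs(r)) < 1e-14 or nz.size == 0:
                break
            J = evaluate_jacobian(params, y, variant)[np.ix_(nz, nz)]
            try:
                dx = np.linalg.solve(J, r[nz])
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(dx)) or np.max(np.abs(dx)) > 0.1 * (
                1.0 + np.max(np.abs(y))
            ):
                break
            z = y.copy()
            z[nz] -= dx
            if res(z) >= res(y):
                break
            y = z
        return y

    # candidate boundary snaps, most-snapped first: small components can
    # only balance each other (e.g. the conversion influx omega*A*T at the
    # cancer-free state), so a boundary root is preferred whenever the
    # polished snapped candidate still satisfies the residual bound
    candidates = []
    small = (np.abs(x) > 0.0) & (np.abs(x) < 1e-6)
    if np.any(small):
        y = x.copy()
        y[small] = 0.0
        candidates.append(y)
        for i in np.flatnonzero(small):
            y = x.copy()
            y[i] = 0.0
            candidates.append(y)
    candidates.append(x)
    for c in candidates:
        c = polish(c)
        if res(c) < RESIDUAL_TOL:
            return c
    return polish(x)


def _dedup(roots: list[np.ndarray], tol: float = DEDUP_TOL) -> list[np.ndarray]:
    kept: list[np.ndarray] = []
    for r in roots:
        if not any(np.max(np.abs(r - k)) < tol for k in kept):
            kept.append(r)
    return kept


def solve_tpa(
    params: ModelParameters,
    *,
    include_infeasible: bool = False,
    n_per_axis: int = 20,
) -> list[SteadyState]:
    """Isolated interior (coexistence) roots of the baseline vector field.

    Eliminates ``A`` via the tumor nullcline (interior branch of
    ``dT/dt = 0``), reduces the remaining two equations to a system in
    ``(T, P)``, and solves it by dense multistart root-finding over a
    20x20 hybrid log/linear grid with deduplication.  Every root is
    verified against the full vector field (max-norm residual below
    ``RESIDUAL_TOL``).

    By default only feasible roots (``T, P, A > 0``) are returned; with
    ``include_infeasible=True`` roots with ``T, P > 0`` but ``A <= 0`` are
    kept as well (branches of this kind appear beyond the pitchfork, where
    the fold survives only on an infeasible branch).

    Failure to converge from every start yields an empty list and a
    warning, not an exception.
    """
    p = params
    if p.alpha_TA <= 0:
        return _solve_tpa_3d(p, include_infeasible=include_infeasible)

    reduced_raw, A_of = interior_reduced_system(p)

    def reduced(x):
        if not np.all(np.isfinite(x)):  # root-finder probe left the domain
            return np.full(2, 1e12)
        return reduced_raw(x)

    upper = 3.0 * max(p.K_T, 1.0)
    grid = _multistart_grid(upper, n_per_axis)
    roots: list[np.ndarray] = []
    any_converged = False
    for T0 in grid:
        for P0 in grid:
            sol = optimize.root(reduced, [T0, P0], method="hybr", options={"xtol": 1e-12})
            if not sol.success:
                continue
            any_converged = True
            T, P = sol.x
            if T <= FEASIBILITY_TOL or P <= FEASIBILITY_TOL:
                continue
            full = _refine_root(p, np.array([T, P, A_of(T, P)]))
            if full[0] <= FEASIBILITY_TOL or full[1] <= FEASIBILITY_TOL:
                continue
            if np.max(np.abs(evaluate_rhs(p, full))) < RESIDUAL_TOL:
                roots.append(full)
    if not any_converged:
        warnings.warn("solve_tpa: no multistart converged", stacklevel=2)
        return []

    states = [
        _make_state(p, r, "numeric") for r in _dedup(roots)
    ]
    if not include_infeasible:
        states = [s for s in states if np.all(s.densities > FEASIBILITY_TOL)]
    return states


def _solve_tpa_3d(
    params: ModelParameters, *, include_infeasible: bool
) -> list[SteadyState]:
    """Fallback interior solver when A cannot be eliminated (alpha_TA = 0)."""
    out = []
    for s in find_equilibria(params, BASELINE_VARIANT):
        if s.T <= FEASIBILITY_TOL or s.P <= FEASIBILITY_TOL:
            continue
        if s.A > FEASIBILITY_TOL or include_infeasible:
            out.append(s)
    return out


def find_equilibria(
    params: ModelParameters,
    variant: ModelVariant = BASELINE_VARIANT,
    *,
    n_per_axis: int = 6,
    upper: float | None = None,
) -> list[SteadyState]:
    """Generic multistart equilibrium finder for any model variant.

    Root-finds the full three-dimensional vector field from a grid of
    starting points (including zeros on each axis, so boundary states are
    reachable), deduplicates, and keeps residual-verified roots.  States
    with negative components are retained but flagged infeasible; tiny
    negative numerical residue (within ``FEASIBILITY_TOL``) is clamped to
    zero at this reporting boundary.
    """
    p = params
    if upper is not None:
        uppers = (float(upper),) * 3
    else:
        # per-axis search scales: the tumor scale includes r_T over the net
        # TP self-feedback (the TP-state tumor density when that margin is
        # small), and the PTI scale follows P ~ (alpha_PT/d_P) T
        u_t = max(p.K_T, 1.0)
        margin = p.r_T / p.K_T - p.alpha_TP * p.alpha_PT / p.d_P
        if margin > 0:
            u_t = max(u_t, p.r_T / margin)
        u_p = max(1.0, p.K_A, u_t * p.alpha_PT / p.d_P)
        u_a = max(p.K_A, 1.0)
        uppers = (3.0 * u_t, 3.0 * u_p, 3.0 * u_a)
    axes = [
        np.concatenate([[0.0], _multistart_grid(u, n_per_axis - 1)])
        for u in uppers
    ]

    def f(x):
        if not np.all(np.isfinite(x)):  # root-finder probe left the domain
            return np.full(3, 1e12)
        return evaluate_rhs(p, x, variant)

    roots: list[np.ndarray] = []

    def add_candidate(x):
        x = _refine_root(p, x, variant)
        if np.max(np.abs(f(x))) < RESIDUAL_TOL:
            roots.append(x)

    for T0 in axes[0]:
        for P0 in axes[1]:
            for A0 in axes[2]:
                sol = optimize.root(f, [T0, P0, A0], method="hybr", options={"xtol": 1e-12})
                if sol.success:
                    add_candidate(sol.x)

    # dedicated sweeps of the boundary subsystems: roots on the axes and
    # coordinate planes are found far more reliably in their own dimension
    # (the full residual check below discards them for variants where the
    # subspace is not invariant, e.g. A = 0 with constant ATI recruitment)
    for i in range(3):
        for s0 in _multistart_grid(uppers[i], 8):

            def g1(v, i=i):
                x = np.zeros(3)
                x[i] = v[0]
                return [f(x)[i]]

            sol = optimize.root(g1, [s0], method="hybr", options={"xtol": 1e-12})
            if sol.success:
                x = np.zeros(3)
                x[i] = sol.x[0]
                add_candidate(x)
    for i, j in ((0, 1), (0, 2)):
        for s0 in _multistart_grid(uppers[i], 8):
            for s1 in _multistart_grid(uppers[j], 8):

                def g2(v, i=i, j=j):
                    x = np.zeros(3)
                    x[i], x[j] = v
                    fx = f(x)
                    return [fx[i], fx[j]]

                sol = optimize.root(
                    g2, [s0, s1], method="hybr", options={"xtol": 1e-12}
                )
                if sol.success:
                    x = np.zeros(3)
                    x[i], x[j] = sol.x
                    add_candidate(x)
    return [
        _make_state(p, r, "numeric", variant) for r in _dedup(roots)
    ]


def all_equilibria(
    params: ModelParameters,
    variant: ModelVariant = BASELINE_VARIANT,
    *,
    include_infeasible: bool = False,
) -> list[SteadyState]:
    """All steady states: closed forms plus numeric coexistence roots.

    For the baseline variant this merges :func:`closed_form_equilibria`
    with :func:`solve_tpa` (deduplicating the omega=0 overlap); for the
    other variants it falls back to the generic numeric finder.
    """
    if variant.is_baseline:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            states = closed_form_equilibria(params)
            tpa = solve_tpa(params, include_infeasible=include_infeasible)
        seen = [s.densities for s in states]
        for s in tpa:
            if not any(np.max(np.abs(s.densities - d)) < DEDUP_TOL for d in seen):
                states.append(s)
    else:
        states = find_equilibria(params, variant)
    if not include_infeasible:
        states = [s for s in states if s.feasible]
    return states


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def steady_states_to_frame(
    states: list[SteadyState],
    verdicts=None,
) -> pd.DataFrame:
    """Tabulate steady states (one row each), optionally with stability."""
    rows = []
    for i, s in enumerate(states):
        row = {
            "label": s.label,
            "T": s.T,
            "P": s.P,
            "A": s.A,
            "feasible": s.feasible,
            "residual": s.residual,
            "provenance": s.provenance,
        }
        if verdicts is not None:
            v = verdicts[i]
            row["verdict"] = v.verdict
            for k, ev in enumerate(np.sort_complex(v.eigenvalues)):
                row[f"eig{k}_re"] = ev.real
                row[f"eig{k}_im"] = ev.imag
        rows.append(row)
    return pd.DataFrame(rows)
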