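"""Independent oracles used by the tests.

These deliberately avoid the package's own solvers: the coexistence roots
come from an exact algebraic reduction to a scalar quadratic, and the
Jacobian check uses central finite differences of the vector field.
"""

from __future__ import annotations

import numpy as np

from timeco.model import evaluate_rhs


def quadratic_tpa_roots(p):
    """Interior equilibria of the baseline model by exact reduction.

    Eliminating A with the interior tumor nullcline and substituting the
    (linear-in-T) P relation from the interior ATI nullcline turns the P
    equation into a scalar quadratic in T, so the coexistence states can
    be enumerated in closed form.  Requires ``alpha_TA > 0``.  Returns a
    list of (T, P, A) triples, any sign.
    """
    sA = p.r_A / p.K_A
    cP = p.alpha_TP + p.alpha_TA * p.alpha_AP / sA
    # P = c0 + c1*T from equating the two expressions for A
    c0 = (p.alpha_TA * p.K_A - p.r_T) / cP
    c1 = (p.r_T / p.K_T + p.alpha_TA * (p.alpha_AT - p.omega) / sA) / cP
    # A = A0 + A1*T on that line
    A0 = p.K_A - p.alpha_AP / sA * c0
    A1 = (p.alpha_AT - p.omega) / sA - p.alpha_AP / sA * c1
    # P-equation: -d_P P^2 + alpha_PT T P + omega A T = 0
    a2 = -p.d_P * c1**2 + p.alpha_PT * c1 + p.omega * A1
    a1 = -2 * p.d_P * c0 * c1 + p.alpha_PT * c0 + p.omega * A0
    a0 = -p.d_P * c0**2
    if abs(a2) > 1e-14:
        roots = np.roots([a2, a1, a0])
    elif abs(a1) > 1e-14:
        roots = np.array([-a0 / a1])
    else:
        return []
    out = []
    for T in roots:
        if abs(T.imag) > 1e-10:
            continue
        T = T.real
        P = c0 + c1 * T
        A = A0 + A1 * T
        out.append((T, P, A))
    return out


def feasible_quadratic_tpa(p, tol=1e-9):
    return [
        r for r in quadratic_tpa_roots(p) if min(r) > tol and max(np.abs(
            evaluate_rhs(p, r))) < 1e-9
    ]


def fd_jacobian(params, state, variant, h=1e-6):
    """Central finite-difference Jacobian of the vector field."""
    state = np.asarray(state, dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h * max(1.0, abs(state[j]))
        fp = evaluate_rhs(params, state + e, variant)
        fm = evaluate_rhs(params, state - e, variant)
        J[:, j] = (fp - fm) / (2 * e[j])
    return J
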