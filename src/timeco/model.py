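"""Core model definition: parameters, structural variants, vector field, Jacobian.

The model is a generalized Lotka-Volterra system for three interacting cell
densities in the tumor-immune microenvironment:

* ``T`` — tumor cells,
* ``P`` — pro-tumor immune (PTI) cells, e.g. M2-polarized macrophages,
* ``A`` — anti-tumor immune (ATI) cells, e.g. M1-polarized macrophages.

The distinguishing ingredient is tumor-catalyzed immune cell conversion: ATI
cells switch to the PTI phenotype at rate ``omega * A * T``, moving density
from the ``A`` equation into the ``P`` equation.  The baseline equations are

.. math::

    dT/dt &= T (r_T - (r_T/K_T) T + \\alpha_{TP} P - \\alpha_{TA} A) \\\\
    dP/dt &= P (-d_P P + \\alpha_{PT} T) + \\omega A T \\\\
    dA/dt &= A (r_A - (r_A/K_A) A + \\alpha_{AT} T - \\alpha_{AP} P)
             - \\omega A T

All parameters are non-negative; ``alpha_XY`` is the per-capita effect of
type ``Y`` on the growth of type ``X``.  Three binary structural switches
(:class:`ModelVariant`) span eight model variants that probe robustness of
the qualitative dynamics to the modeling assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from itertools import product
from typing import Iterator

import numpy as np

__all__ = [
    "ModelParameters",
    "ModelVariant",
    "BASELINE_VARIANT",
    "all_variants",
    "evaluate_rhs",
    "evaluate_jacobian",
]

#: Parameter names that must be strictly positive (they appear in
#: denominators of the closed-form steady states).
_STRICTLY_POSITIVE = ("r_T", "K_T", "d_P", "r_A", "K_A")


class ParameterError(ValueError):
    """Raised for invalid (negative, non-finite, or degenerate) parameters."""


@dataclass(frozen=True)
class ModelParameters:
    """The eleven non-negative rates and capacities of the model.

    Attributes
    ----------
    r_T, r_A
        Intrinsic growth rates of tumor and ATI cells (1/time).
    K_T, K_A
        Carrying capacities of tumor and ATI cells (density units); the
        quadratic self-limitation coefficients are written ``r_T/K_T`` and
        ``r_A/K_A``.  In the {source} ATI variant ``r_A/K_A`` acts purely
        as a linear decay coefficient.
    d_P
        PTI self-limitation / death coefficient.
    alpha_TP, alpha_TA, alpha_PT, alpha_AT, alpha_AP
        Pairwise interaction coefficients; ``alpha_XY`` is the effect of
        type ``Y`` on the net growth rate of type ``X``.
    omega
        Rate at which tumor cells convert ATI cells into PTI cells
        (the ``omega * A * T`` term).
    """

    r_T: float = 1.0
    K_T: float = 1.0
    d_P: float = 1.0
    r_A: float = 1.0
    K_A: float = 1.0
    alpha_TP: float = 0.0
    alpha_TA: float = 0.0
    alpha_PT: float = 0.0
    alpha_AT: float = 0.0
    alpha_AP: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ParameterError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise ParameterError(f"parameter {f.name} must be >= 0, got {v}")
            object.__setattr__(self, f.name, float(v))
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ParameterError(f"parameter {name} must be > 0")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given parameters replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class ModelVariant:
    """Three binary structural switches spanning the eight model variants.

    ``pti_self_limitation``
        ``"quadratic"``: PTI self-limitation enters as ``-d_P P**2``;
        ``"linear"``: as ``-d_P P``.
    ``pti_tumor_growth``
        ``"on"``: tumor cells stimulate PTI growth via ``alpha_PT T P``;
        ``"off"``: that term is absent (``alpha_PT`` effectively zero).
    ``ati_dynamics``
        ``"logistic"``: ATI birth/self-limitation is ``r_A A - (r_A/K_A) A**2``;
        ``"source"``: constant recruitment with linear death,
        ``r_A - (r_A/K_A) A``.  The interaction and conversion terms keep
        their multiplicative-in-``A`` form in both cases.
    """

    pti_self_limitation: str = "quadratic"
    pti_tumor_growth: str = "on"
    ati_dynamics: str = "logistic"

    _CHOICES = {
        "pti_self_limitation": ("quadratic", "linear"),
        "pti_tumor_growth": ("on", "off"),
        "ati_dynamics": ("logistic", "source"),
    }

    def __post_init__(self) -> None:
        for name, choices in self._CHOICES.items():
            if getattr(self, name) not in choices:
                raise ValueError(
                    f"{name} must be one of {choices}, got {getattr(self, name)!r}"
                )

    @property
    def is_baseline(self) -> bool:
        return self == BASELINE_VARIANT

    def tag(self) -> str:
        """Short identifier, e.g. ``'quadratic-on-logistic'``."""
        return f"{self.pti_self_limitation}-{self.pti_tumor_growth}-{self.ati_dynamics}"


BASELINE_VARIANT = ModelVariant()


def all_variants() -> Iterator[ModelVariant]:
    """Iterate over all eight structural variants, baseline first."""
    for sl, tg, ad in product(
        ("quadratic", "linear"), ("on", "off"), ("logistic", "source")
    ):
        yield ModelVariant(sl, tg, ad)


def _check_state(state) -> np.ndarray:
    s = np.asarray(state, dtype=float)
    if s.shape != (3,):
        raise ValueError(f"state must have shape (3,), got {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError(f"state must be finite, got {s}")
    return s


def evaluate_rhs(
    params: ModelParameters,
    state,
    variant: ModelVariant = BASELINE_VARIANT,
) -> np.ndarray:
    """Time derivatives ``(dT/dt, dP/dt, dA/dt)`` for the selected variant.

    Negative state components are permitted (root-finding probes may leave
    the feasible orthant); the state must be finite.
    """
    T, P, A = _check_state(state)
    p = params

    dT = T * (p.r_T - (p.r_T / p.K_T) * T + p.alpha_TP * P - p.alpha_TA * A)

    if variant.pti_self_limitation == "quadratic":
        dP = -p.d_P * P * P
    else:
        dP = -p.d_P * P
    if variant.pti_tumor_growth == "on":
        dP += p.alpha_PT * T * P
    dP += p.omega * A * T

    interact_A = A * (p.alpha_AT * T - p.alpha_AP * P) - p.omega * A * T
    if variant.ati_dynamics == "logistic":
        dA = A * (p.r_A - (p.r_A / p.K_A) * A) + interact_A
    else:
        dA = p.r_A - (p.r_A / p.K_A) * A + interact_A

    return np.array([dT, dP, dA])


def evaluate_jacobian(
    params: ModelParameters,
    state,
    variant: ModelVariant = BASELINE_VARIANT,
) -> np.ndarray:
    """3x3 matrix of partial derivatives of :func:`evaluate_rhs`."""
    T, P, A = _check_state(state)
    p = params

    J = np.empty((3, 3))
    J[0, 0] = p.r_T - 2 * (p.r_T / p.K_T) * T + p.alpha_TP * P - p.alpha_TA * A
    J[0, 1] = p.alpha_TP * T
    J[0, 2] = -p.alpha_TA * T

    if variant.pti_self_limitation == "quadratic":
        dP_dP = -2 * p.d_P * P
    else:
        dP_dP = -p.d_P
    dP_dT = p.omega * A
    if variant.pti_tumor_growth == "on":
        dP_dP += p.alpha_PT * T
        dP_dT += p.alpha_PT * P
    J[1, 0] = dP_dT
    J[1, 1] = dP_dP
    J[1, 2] = p.omega * T

    J[2, 0] = (p.alpha_AT - p.omega) * A
    J[2, 1] = -p.alpha_AP * A
    dA_dA = (p.alpha_AT - p.omega) * T - p.alpha_AP * P
    if variant.ati_dynamics == "logistic":
        dA_dA += p.r_A - 2 * (p.r_A / p.K_A) * A
    else:
        dA_dA += -(p.r_A / p.K_A)
    J[2, 2] = dA_dA

    return J
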