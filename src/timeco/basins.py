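"""Basins of attraction: labeling initial-condition grids by attractor.

When the tumor cannot invade the cancer-free state (``Omega_{T->A} < 0``)
but the conversion rate is past the fold, the cancer-free (A) state
coexists with a cancer attractor (TP or TPA) and the system shows a strong
Allee effect: a threshold initial tumor density separates trajectories
that are cleared from those that establish a tumor.  Grids of initial
conditions, labeled by the steady state they asymptotically approach,
quantify how the cancer-free basin shrinks as conversion accelerates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .equilibria import SteadyState, all_equilibria
from .model import BASELINE_VARIANT, ModelParameters, ModelVariant
from .stability import SimulationError, classify_stability, simulate

__all__ = [
    "BasinGrid",
    "label_attractor",
    "compute_basins",
    "basin_fractions",
    "cancer_free_fraction",
    "estimate_boundary",
]

#: terminal states are matched to an equilibrium within this max-norm radius
MATCH_TOL = 1e-4
#: labels for trajectories that do not settle on a known equilibrium
DIVERGED, UNRESOLVED = "diverged", "unresolved"
#: steady-state labels aggregated as the "cancer" outcome
CANCER_LABELS = ("T", "TP", "TPA")
CANCER_FREE_LABEL = "A"


def default_grid(params: ModelParameters, n: int = 15) -> tuple[np.ndarray, ...]:
    """Default n^3 grid over [0, 1.2*max(K_T, K_A)] per axis."""
    hi = 1.2 * max(params.K_T, params.K_A)
    axis = np.linspace(0.0, hi, n)
    return axis, axis.copy(), axis.copy()


@dataclass
class BasinGrid:
    """A labeled grid of initial conditions.

    ``labels`` has shape ``(len(t_axis), len(p_axis), len(a_axis))`` and
    holds steady-state labels of the matched attractor or the explicit
    non-convergence categories ``"diverged"`` / ``"unresolved"``.
    """

    t_axis: np.ndarray
    p_axis: np.ndarray
    a_axis: np.ndarray
    labels: np.ndarray
    attractors: list[SteadyState]
    params: ModelParameters
    variant: ModelVariant = BASELINE_VARIANT

    @property
    def size(self) -> int:
        return int(self.labels.size)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, t0), (j, p0), (k, a0) in product(
            enumerate(self.t_axis), enumerate(self.p_axis), enumerate(self.a_axis)
        ):
            rows.append(
                {"T0": t0, "P0": p0, "A0": a0, "label": self.labels[i, j, k]}
            )
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "variant": self.variant.tag(),
            "grid": {
                "T": self.t_axis.tolist(),
                "P": self.p_axis.tolist(),
                "A": self.a_axis.tolist(),
            },
            "attractors": [
                {
                    "label": s.label,
                    "densities": s.densities.tolist(),
                    "feasible": s.feasible,
                }
                for s in self.attractors
            ],
        }


def _known_equilibria(params, variant):
    """Feasible equilibria used for terminal-state matching, stable first."""
    eqs = all_equilibria(params, variant)
    verdicts = []
    for s in eqs:
        try:
            verdicts.append(classify_stability(params, s, variant))
        except ValueError:
            verdicts.append(None)
    stable = [
        s for s, v in zip(eqs, verdicts) if v is not None and v.is_stable
    ]
    others = [s for s, v in zip(eqs, verdicts) if v is None or not v.is_stable]
    return stable + others, stable


def label_attractor(
    params: ModelParameters,
    init,
    variant: ModelVariant = BASELINE_VARIANT,
    *,
    equilibria: list[SteadyState] | None = None,
    horizon: float = 1e5,
) -> str:
    """Attractor label for one initial condition.

    Integrates to convergence and matches the terminal state to the
    nearest known equilibrium within ``MATCH_TOL`` max-norm (stable
    attractors take precedence; unstable equilibria such as the extinction
    state can still be reached from invariant boundary sets and are
    matched so that e.g. the origin labels itself).  Trajectories that
    exceed the divergence cutoff label ``"diverged"``; integration failure
    or no match labels ``"unresolved"``.
    """
    if equilibria is None:
        equilibria, _ = _known_equilibria(params, variant)
    try:
        traj = simulate(params, init, horizon=horizon, variant=variant)
    except SimulationError:
        return UNRESOLVED
    if traj.terminal_flag == "diverged":
        return DIVERGED
    final = traj.final_state
    for s in equilibria:
        if np.max(np.abs(final - s.densities)) < MATCH_TOL:
            return s.label
    return UNRESOLVED


def compute_basins(
    params: ModelParameters,
    grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    variant: ModelVariant = BASELINE_VARIANT,
    *,
    horizon: float = 1e5,
) -> BasinGrid:
    """Label every grid point by the attractor it reaches (deterministic)."""
    if grid is None:
        grid = default_grid(params)
    t_axis, p_axis, a_axis = (np.asarray(g, dtype=float) for g in grid)
    if min(t_axis.min(), p_axis.min(), a_axis.min()) < 0:
        raise ValueError("grid bounds must be non-negative")
    equilibria, stable = _known_equilibria(params, variant)
    labels = np.empty((t_axis.size, p_axis.size, a_axis.size), dtype=object)
    for (i, t0), (j, p0), (k, a0) in product(
        enumerate(t_axis), enumerate(p_axis), enumerate(a_axis)
    ):
        labels[i, j, k] = label_attractor(
            params,
            (t0, p0, a0),
            variant,
            equilibria=equilibria,
            horizon=horizon,
        )
    return BasinGrid(t_axis, p_axis, a_axis, labels, stable, params, variant)


def basin_fractions(grid: BasinGrid) -> dict[str, float]:
    """Fraction of grid points per label; fractions sum to one."""
    labels, counts = np.unique(grid.labels.astype(str), return_counts=True)
    return {str(l): float(c) / grid.size for l, c in zip(labels, counts)}


def cancer_free_fraction(grid: BasinGrid) -> float:
    """Fraction of the grid attracted to the cancer-free (A) state."""
    return basin_fractions(grid).get(CANCER_FREE_LABEL, 0.0)


def estimate_boundary(grid: BasinGrid):
    """Fit a smooth classifier to the cancer-free / cancer dichotomy.

    Uses a support vector machine with a degree-3 polynomial kernel, the
    standard smooth-surface estimator for basin interfaces in this model.
    Visualization-only: the fitted surface never feeds a quantitative
    result.  Returns ``(classifier, training_accuracy)``.

    Raises ``ValueError`` when fewer than two of the dichotomy's classes
    are present on the grid.
    """
    from sklearn.svm import SVC

    frame = grid.to_frame()
    mask_cancer = frame["label"].isin(CANCER_LABELS)
    mask_free = frame["label"] == CANCER_FREE_LABEL
    frame = frame[mask_cancer | mask_free]
    y = np.where(frame["label"] == CANCER_FREE_LABEL, 0, 1)
    if np.unique(y).size < 2:
        raise ValueError(
            "boundary estimation needs both cancer-free and cancer labels"
        )
    X = frame[["T0", "P0", "A0"]].to_numpy()
    clf = SVC(kernel="poly", degree=3, C=10.0)
    clf.fit(X, y)
    accuracy = float(clf.score(X, y))
    return clf, accuracy
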