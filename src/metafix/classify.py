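"""Amplifier/suppressor classification against the well-mixed baseline.

A structure is compared with the well-mixed population of the same total
size over a grid of fitness values straddling ``r = 1``.  The sign pattern
of ``phi_structure(r) - phi_wm(r, N)`` outside a tolerance band yields one of
six regime labels:

- ``amplifier``: above well-mixed for advantageous mutants, below for
  deleterious ones (selection is strengthened);
- ``suppressor``: the reverse (selection is weakened);
- ``enhancer`` / ``reducer``: above / below well-mixed on *both* sides of
  neutrality;
- ``isothermal-equivalent``: indistinguishable from well-mixed everywhere;
- ``piecewise``: any mixed pattern; the sign-change locations are reported,
  covering what is informally called a transient amplifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import bipartite as bp
from .exact_chain import fixation_exact
from .low_migration import fixation_lowmig
from .simulate import SimConfig, estimate_fixation
from .structures import PatchGraph, meta_star
from .wellmixed import fixation_wm

__all__ = ["RegimeLabel", "default_r_grid", "classify_regime", "classify_structure", "difference_curve"]

LABELS = (
    "amplifier",
    "suppressor",
    "piecewise",
    "reducer",
    "enhancer",
    "isothermal-equivalent",
)

#: guard band around r = 1 where the sign of the difference is unresolvable
NEUTRAL_GUARD = 1e-3


def default_r_grid(r_min: float = 0.25, r_max: float = 4.0, n: int = 41) -> np.ndarray:
    """Log-spaced fitness grid excluding the neutral guard band around 1."""
    grid = np.geomspace(r_min, r_max, n)
    return grid[np.abs(grid - 1.0) > NEUTRAL_GUARD]


@dataclass(frozen=True)
class RegimeLabel:
    """Classification of a structure relative to the well-mixed baseline."""

    label: str
    r_grid: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)
    tolerance: float
    sign_changes: tuple = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def classify_regime(
    phi_fn: Callable[[float], float],
    N: int,
    r_grid=None,
    tolerance: float = 1e-12,
) -> RegimeLabel:
    """Classify ``phi_fn`` against ``fixation_wm(., N)`` over an r-grid.

    The grid must contain points on both sides of ``r = 1``.  A label other
    than ``piecewise`` requires its sign pattern to hold strictly (outside
    ``tolerance``) at *every* grid point on the relevant side; a grid tied
    to zero everywhere is isothermal-equivalent.
    """
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    below = r_grid < 1.0
    above = r_grid > 1.0
    if not (below.any() and above.any()):
        raise ValueError("r grid must contain points on both sides of r = 1")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    diffs = np.array([phi_fn(r) - fixation_wm(r, N) for r in r_grid])
    pos = diffs > tolerance
    neg = diffs < -tolerance
    tied = ~(pos | neg)
    if tied.all():
        label = "isothermal-equivalent"
    elif pos[above].all() and neg[below].all():
        label = "amplifier"
    elif neg[above].all() and pos[below].all():
        label = "suppressor"
    elif neg.all():
        label = "reducer"
    elif pos.all():
        label = "enhancer"
    else:
        label = "piecewise"
    sign = np.where(pos, 1, np.where(neg, -1, 0))
    resolved = sign[sign != 0]
    r_resolved = r_grid[sign != 0]
    changes = tuple(
        float(np.sqrt(r_resolved[k] * r_resolved[k + 1]))
        for k in range(len(resolved) - 1)
        if resolved[k] * resolved[k + 1] < 0
    )
    return RegimeLabel(
        label=label, r_grid=r_grid, diffs=diffs, tolerance=tolerance, sign_changes=changes
    )


def _phi_function(g: PatchGraph, method: str, lam: float | None, convention: str):
    """Map a (structure, method, lambda) triple to a callable r -> phi."""
    if method == "lowmig":
        return lambda r: fixation_lowmig(g, r).phi
    if method == "exact":
        if lam is None:
            raise ValueError("method 'exact' requires a migration probability")
        return lambda r: fixation_exact(g, lam, r, convention=convention).phi
    if method == "bipartite":
        if lam is not None and lam != 1.0:
            raise ValueError("the bipartite closed form applies only at lambda = 1")
        if g.M == 2:
            N1, N2 = (int(n) for n in g.sizes)
            return lambda r: bp.fixation_bipartite(N1, N2, r).phi_avg
        if g.to_dict()["edges"] == meta_star(g.M, int(g.sizes[1]), int(g.sizes[0])).to_dict()["edges"] and len(set(g.sizes)) == 1:
            M, N = g.M, g.N
            return lambda r: bp.metastar_high_migration(M, N, r)
        raise ValueError("bipartite closed form needs a two-patch or equal-size star structure")
    raise ValueError(f"unknown method {method!r}")


def classify_structure(
    g: PatchGraph,
    method: str,
    lam: float | None = None,
    r_grid=None,
    tolerance: float = 1e-12,
    convention: str = "union",
) -> RegimeLabel:
    """Classify a structure using one of the analytical/exact routes."""
    return classify_regime(_phi_function(g, method, lam, convention), g.N, r_grid, tolerance)


def difference_curve(
    g: PatchGraph,
    method: str,
    lam: float | None = None,
    r_grid=None,
    convention: str = "union",
    sim_cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """Tidy table of ``phi``, ``phi_wm`` and their difference over an r-grid.

    ``method`` is one of ``exact``, ``lowmig``, ``bipartite`` or ``simulate``
    (the last requires ``sim_cfg``); the output reproduces the
    structure-minus-well-mixed difference curves used to diagnose regimes.
    """
    r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    rows = []
    if method == "simulate":
        if sim_cfg is None:
            raise ValueError("method 'simulate' requires sim_cfg")
        if lam is None:
            raise ValueError("method 'simulate' requires a migration probability")
        for r in r_grid:
            est = estimate_fixation(g, lam, float(r), sim_cfg, convention)
            rows.append((float(r), est.phi_hat, est.se))
        df = pd.DataFrame(rows, columns=["r", "phi", "se"])
    else:
        fn = _phi_function(g, method, lam, convention)
        for r in r_grid:
            rows.append((float(r), fn(float(r))))
        df = pd.DataFrame(rows, columns=["r", "phi"])
    df["phi_wm"] = [fixation_wm(float(r), g.N) for r in df["r"]]
    df["diff"] = df["phi"] - df["phi_wm"]
    return df
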