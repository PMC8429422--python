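"""Monte Carlo simulation of the individual-level Birth-death meta-population.

The simulator realises the exact process the analytical routes approximate:
per event one parent is drawn from the whole meta-population proportional to
fitness, and its offspring replaces an individual drawn by the structure's
replacement weights.  Replicates end at global fixation, global extinction,
or an event cap (censored; reported separately and excluded from the
estimate, never folded into either outcome).

Replicates are simulated in fixed-size batches that advance in lockstep on
vectorised state arrays; each batch owns a child RNG stream spawned from the
seed, so a batch's trajectories do not depend on how many batches follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structures import PatchGraph, landing_matrix

__all__ = ["SimConfig", "SimEstimate", "simulate_once", "estimate_fixation"]

_BATCH = 8192


@dataclass(frozen=True)
class SimConfig:
    """Replication plan for :func:`estimate_fixation`."""

    replicates: int
    seed: int
    max_events: int = 10_000_000
    init: object = "uniform"  # "uniform", patch index, or mutant-count vector

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")


@dataclass(frozen=True)
class SimEstimate:
    """Binomial fixation estimate with censoring accounting."""

    phi_hat: float
    se: float
    n_fixed: int
    n_extinct: int
    n_censored: int

    @property
    def replicates(self) -> int:
        return self.n_fixed + self.n_extinct + self.n_censored


def _initial_counts(g: PatchGraph, init, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, M) initial mutant-count array for ``n`` replicates."""
    m = np.zeros((n, g.M), dtype=np.int64)
    if init in ("uniform", "uniform-individual", None):
        probs = g.size_array / g.N
        patch = rng.choice(g.M, size=n, p=probs)
        m[np.arange(n), patch] = 1
    elif isinstance(init, int):
        if not 0 <= init < g.M:
            raise ValueError(f"patch index {init} out of range")
        m[:, init] = 1
    else:
        vec = np.asarray(init, dtype=np.int64)
        if vec.shape != (g.M,) or np.any(vec < 0) or np.any(vec > g.size_array):
            raise ValueError(f"invalid initial state {init!r}")
        m[:] = vec
    return m


def _run_batch(
    g: PatchGraph,
    lam: float,
    r: float,
    n: int,
    rng: np.random.Generator,
    init,
    max_events: int,
    convention: str,
) -> tuple[int, int, int]:
    """Advance ``n`` replicates to absorption; returns (fixed, extinct, censored)."""
    sizes = g.size_array
    N = g.N
    M = g.M
    D = landing_matrix(g, lam, convention)
    D_cum = np.cumsum(D, axis=1)
    m = _initial_counts(g, init, n, rng)
    mut = m.sum(axis=1)
    fixed = int(np.count_nonzero(mut == N))
    extinct = int(np.count_nonzero(mut == 0))
    alive = (mut != 0) & (mut != N)
    m = m[alive]
    mut = mut[alive]
    events = 0
    while m.shape[0] and events < max_events:
        events += 1
        A = m.shape[0]
        F = (r - 1.0) * mut + N
        # parent: categorical over 2M cells [mutant in patch j | wild in patch j]
        w = np.concatenate([r * m, sizes[None, :] - m], axis=1) / F[:, None]
        u = rng.random((A, 1))
        cell = (u < np.cumsum(w, axis=1)).argmax(axis=1)
        parent_mut = cell < M
        src = np.where(parent_mut, cell, cell - M)
        # landing patch of the offspring
        dest = (rng.random((A, 1)) < D_cum[src]).argmax(axis=1)
        md = m[np.arange(A), dest]
        target_mut = rng.random(A) * sizes[dest] < md
        delta = np.where(parent_mut & ~target_mut, 1, 0) + np.where(
            ~parent_mut & target_mut, -1, 0
        )
        m[np.arange(A), dest] += delta
        mut += delta
        done = (mut == 0) | (mut == N)
        if np.any(done):
            fixed += int(np.count_nonzero(mut == N))
            extinct += int(np.count_nonzero(mut[done] == 0))
            keep = ~done
            m = m[keep]
            mut = mut[keep]
    censored = int(m.shape[0])
    return fixed, extinct, censored


def simulate_once(
    g: PatchGraph,
    lam: float,
    r: float,
    rng: np.random.Generator,
    init="uniform",
    max_events: int = 10_000_000,
    convention: str = "union",
) -> tuple[str, int]:
    """Run a single replicate; returns (outcome, events).

    Outcome is ``"fixed"``, ``"extinct"`` or ``"censored"``.  The trajectory
    is a deterministic function of the generator's stream.
    """
    sizes = g.size_array
    N = g.N
    M = g.M
    D_cum = np.cumsum(landing_matrix(g, lam, convention), axis=1)
    m = _initial_counts(g, init, 1, rng)[0]
    mut = int(m.sum())
    events = 0
    while 0 < mut < N and events < max_events:
        events += 1
        F = (r - 1.0) * mut + N
        w = np.concatenate([r * m, sizes - m]) / F
        cell = int((rng.random() < np.cumsum(w)).argmax())
        parent_mut = cell < M
        src = cell if parent_mut else cell - M
        dest = int((rng.random() < D_cum[src]).argmax())
        target_mut = rng.random() * sizes[dest] < m[dest]
        if parent_mut and not target_mut:
            m[dest] += 1
            mut += 1
        elif (not parent_mut) and target_mut:
            m[dest] -= 1
            mut -= 1
    if mut == N:
        return "fixed", events
    if mut == 0:
        return "extinct", events
    return "censored", events


def estimate_fixation(
    g: PatchGraph,
    lam: float,
    r: float,
    cfg: SimConfig,
    convention: str = "union",
) -> SimEstimate:
    """Monte Carlo fixation-probability estimate over independent replicates.

    ``phi_hat = n_fixed / (n_fixed + n_extinct)`` with the binomial standard
    error; censored replicates (event cap hit) are excluded and trigger a
    warning.  The same configuration always yields the identical estimate.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n_batches = (cfg.replicates + _BATCH - 1) // _BATCH
    children = ss.spawn(n_batches)
    fixed = extinct = censored = 0
    remaining = cfg.replicates
    for child in children:
        n = min(_BATCH, remaining)
        remaining -= n
        f, e, c = _run_batch(
            g, lam, r, n, np.random.default_rng(child), cfg.init, cfg.max_events, convention
        )
        fixed += f
        extinct += e
        censored += c
    if censored:
        warnings.warn(
            f"{censored} replicates hit the event cap and were censored", stacklevel=2
        )
    done = fixed + extinct
    phi = fixed / done if done else float("nan")
    se = float(np.sqrt(phi * (1.0 - phi) / done)) if done else float("nan")
    return SimEstimate(
        phi_hat=phi, se=se, n_fixed=fixed, n_extinct=extinct, n_censored=censored
    )
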