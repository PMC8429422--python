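"""Exact fixation probabilities via the full meta-population Markov chain.

The state of the Birth-death meta-population process is the vector of
per-patch mutant counts ``m`` with ``0 <= m_j <= N_j``; the chain has
``prod_j (N_j + 1)`` states.  For migration probability ``lambda > 0`` the
only absorbing states are all-wild-type (extinction) and all-mutant
(fixation), and the fixation probability from any start solves the linear
absorption system of the transition matrix.  This route is exact for every
``lambda`` and is the numerical anchor for the low-migration and
high-migration closed forms.

States are indexed by mixed-radix encoding in patch document order (patch 0
most significant).  The absorption system is solved on the embedded jump
chain (self-transitions removed row-wise), which leaves the solution
unchanged and improves conditioning.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .results import FixationResult
from .structures import PatchGraph, landing_matrix

__all__ = [
    "state_index",
    "state_unindex",
    "step_distribution",
    "transition_matrix",
    "fixation_exact",
]

DEFAULT_STATE_CEILING = 2_000_000


class CapacityError(RuntimeError):
    """State space exceeds the configured ceiling; use the simulator instead."""


def _radices(g: PatchGraph) -> np.ndarray:
    return g.size_array + 1


def _strides(g: PatchGraph) -> np.ndarray:
    rad = _radices(g)
    return np.concatenate([np.cumprod(rad[::-1])[::-1][1:], [1]]).astype(np.int64)


def state_index(m: Sequence[int], g: PatchGraph) -> int:
    """Mixed-radix index of a per-patch mutant-count vector."""
    m = np.asarray(m, dtype=np.int64)
    if m.shape != (g.M,):
        raise ValueError(f"state must have length M={g.M}")
    if np.any(m < 0) or np.any(m > g.size_array):
        raise ValueError(f"state {m.tolist()} outside 0..N_j bounds")
    return int(np.dot(m, _strides(g)))


def state_unindex(k: int, g: PatchGraph) -> tuple[int, ...]:
    """Inverse of :func:`state_index`."""
    rad = _radices(g)
    if not 0 <= k < int(np.prod(rad)):
        raise ValueError(f"state index {k} out of range")
    out = []
    for j in range(g.M):
        stride = int(np.prod(rad[j + 1 :]))
        out.append(int(k // stride) % int(rad[j]))
    return tuple(out)


def _all_states(g: PatchGraph) -> np.ndarray:
    """(K, M) array of every mutant-count vector in index order."""
    rad = _radices(g)
    K = int(np.prod(rad))
    idx = np.arange(K, dtype=np.int64)
    S = np.empty((K, g.M), dtype=np.int64)
    strides = _strides(g)
    for j in range(g.M):
        S[:, j] = (idx // strides[j]) % rad[j]
    return S


def step_distribution(
    m: Sequence[int],
    g: PatchGraph,
    lam: float,
    r: float,
    convention: str = "union",
) -> dict[tuple[int, ...], float]:
    """Distribution over successor states after one Birth-death event.

    A parent is drawn globally proportional to fitness (a patch-``i`` mutant
    with probability ``r m_i / F`` and a patch-``i`` wild-type with
    probability ``(N_i - m_i) / F``, where ``F = r sum m + sum (N - m)``);
    its offspring replaces an individual drawn by the structure's replacement
    weights.  Successors differ from ``m`` in at most one coordinate by
    ``+-1``; the self-transition (offspring replaces an individual of the
    parent's own type) carries the remaining mass.
    """
    m = tuple(int(x) for x in m)
    state_index(m, g)  # validates
    sizes = g.size_array
    mut = int(sum(m))
    F = r * mut + (g.N - mut)
    D = landing_matrix(g, lam, convention)
    dist: dict[tuple[int, ...], float] = {}
    moved = 0.0
    for i in range(g.M):
        p_mut_parent = r * m[i] / F
        p_wt_parent = (sizes[i] - m[i]) / F
        for j in range(g.M):
            if D[i, j] == 0.0:
                continue
            # mutant offspring replaces a wild-type in j -> m_j + 1
            if m[j] < sizes[j] and p_mut_parent > 0:
                p = p_mut_parent * D[i, j] * (sizes[j] - m[j]) / sizes[j]
                succ = m[:j] + (m[j] + 1,) + m[j + 1 :]
                dist[succ] = dist.get(succ, 0.0) + p
                moved += p
            # wild-type offspring replaces a mutant in j -> m_j - 1
            if m[j] > 0 and p_wt_parent > 0:
                p = p_wt_parent * D[i, j] * m[j] / sizes[j]
                succ = m[:j] + (m[j] - 1,) + m[j + 1 :]
                dist[succ] = dist.get(succ, 0.0) + p
                moved += p
    dist[m] = dist.get(m, 0.0) + (1.0 - moved)
    return dist


def transition_matrix(
    g: PatchGraph, lam: float, r: float, convention: str = "union", dtype=np.float64
) -> sp.csr_matrix:
    """Full ``(K, K)`` one-event transition matrix (self-transitions included)."""
    S = _all_states(g)
    K = S.shape[0]
    sizes = g.size_array
    strides = _strides(g)
    mut = S.sum(axis=1)
    F = dtype(r) * mut + (g.N - mut)
    D = landing_matrix(g, lam, convention, dtype=dtype)
    rows, cols, vals = [], [], []
    idx = np.arange(K, dtype=np.int64)
    for i in range(g.M):
        p_mut = dtype(r) * S[:, i] / F
        p_wt = (sizes[i] - S[:, i]) / F
        for j in range(g.M):
            if D[i, j] == 0.0:
                continue
            up_ok = S[:, j] < sizes[j]
            p_up = p_mut * D[i, j] * (sizes[j] - S[:, j]) / sizes[j]
            rows.append(idx[up_ok])
            cols.append(idx[up_ok] + strides[j])
            vals.append(p_up[up_ok])
            dn_ok = S[:, j] > 0
            p_dn = p_wt * D[i, j] * S[:, j] / sizes[j]
            rows.append(idx[dn_ok])
            cols.append(idx[dn_ok] - strides[j])
            vals.append(p_dn[dn_ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    P = sp.coo_matrix((vals, (rows, cols)), shape=(K, K)).tocsr()
    P.sum_duplicates()
    diag = 1.0 - np.asarray(P.sum(axis=1)).ravel()
    P = P + sp.diags(diag)
    return P.tocsr()


def _resolve_init(init, g: PatchGraph) -> np.ndarray:
    """Weights over states for the requested initial condition."""
    K = int(np.prod(_radices(g)))
    w = np.zeros(K)
    if init in ("uniform", "uniform-individual", None):
        # a uniformly random wild-type individual turns into a mutant
        for j in range(g.M):
            m = [0] * g.M
            m[j] = 1
            w[state_index(m, g)] = g.sizes[j] / g.N
    elif isinstance(init, int):
        if not 0 <= init < g.M:
            raise ValueError(f"patch index {init} out of range")
        m = [0] * g.M
        m[init] = 1
        w[state_index(m, g)] = 1.0
    else:
        w[state_index(init, g)] = 1.0
    return w


def fixation_exact(
    g: PatchGraph,
    lam: float,
    r: float,
    init="uniform",
    convention: str = "union",
    state_ceiling: int = DEFAULT_STATE_CEILING,
    return_vector: bool = False,
    rtol: float = 1e-12,
):
    """Exact fixation probability by solving the absorption linear system.

    Parameters
    ----------
    init
        ``"uniform"`` (a uniformly random individual mutates: single-mutant
        starts weighted by ``N_j / N``), a patch index (single mutant in that
        patch), or an explicit mutant-count vector.
    return_vector
        Also return the full per-state absorption-probability vector.

    Notes
    -----
    For ``lambda = 0`` and ``M >= 2`` every mixed homogeneous configuration is
    absorbing and a single mutant can never reach global fixation; the result
    is 0 and a warning is issued.
    """
    K = int(np.prod(_radices(g)))
    if K > state_ceiling:
        raise CapacityError(
            f"{K} states exceed ceiling {state_ceiling}; use the Monte Carlo simulator"
        )
    params = {"r": r, "lambda": lam, "structure": g.digest(), "convention": convention}
    if lam == 0.0 and g.M >= 2:
        warnings.warn(
            "lambda=0 with M>=2: patches are isolated and global fixation from a "
            "single mutant is impossible; returning phi=0",
            stacklevel=2,
        )
        res = FixationResult(phi=0.0, method="exact", params=params)
        if return_vector:
            return res, None
        return res

    ext, fix = 0, K - 1
    transient = np.ones(K, dtype=bool)
    transient[[ext, fix]] = False
    tidx = np.flatnonzero(transient)

    def absorption_system(dtype):
        """(A, rhs) of the embedded jump chain (self-transitions stripped
        row-wise, rows renormalised), which conditions the solve better."""
        P = transition_matrix(g, lam, r, convention, dtype=dtype)
        Pt = P[tidx]
        Q = Pt[:, tidx].tocsr()
        diag = Q.diagonal()
        Q.setdiag(0.0)
        Q.eliminate_zeros()
        b = np.asarray(Pt[:, fix].todense()).ravel()
        scale = dtype(1.0) - diag
        if np.any(scale <= 0):
            raise RuntimeError("found an absorbing state among transients")
        A = sp.eye(len(tidx), dtype=dtype, format="csr") - Q.multiply(
            (dtype(1.0) / scale)[:, None]
        ).tocsr()
        return A, b / scale

    A, rhs = absorption_system(np.float64)
    if len(tidx) <= 100_000:
        lu = spla.splu(A.tocsc())
        x = lu.solve(rhs)
        # conditioning degrades like 1/lambda as migration becomes rare;
        # refine against the system rebuilt in extended precision, using the
        # double-precision factorisation as the preconditioner
        A_hi, rhs_hi = absorption_system(np.longdouble)
        for _ in range(4):
            res = rhs_hi - A_hi @ x.astype(np.longdouble)
            err = float(np.abs(res).max())
            if err < 1e-18:
                break
            x = x + lu.solve(np.asarray(res, dtype=np.float64))
        x = np.asarray(x, dtype=np.float64)
    else:
        x, info = spla.gmres(A, rhs, rtol=rtol, maxiter=10_000)
        if info != 0:
            raise RuntimeError(f"iterative solver did not converge (info={info})")
    full = np.zeros(K)
    full[fix] = 1.0
    full[tidx] = x
    w = _resolve_init(init, g)
    phi = float(np.dot(w, full))
    phi = min(max(phi, 0.0), 1.0)
    res = FixationResult(phi=phi, method="exact", params={**params, "rtol": rtol})
    if return_vector:
        return res, full
    return res
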