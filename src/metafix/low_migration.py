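"""Low-migration (time-scale-separated) fixation probabilities.

When the migration probability ``lambda`` is small enough that the time
between migration events (of order ``1/lambda``) greatly exceeds the
within-patch absorption time, the meta-population is effectively always in a
homogeneous configuration: each patch is entirely mutant or entirely
wild-type.  The dynamics then coarse-grains to a Markov chain on the ``2^M``
binary patch configurations with transition probabilities that factor as

    (global selection weight of the migrating patch)
    x (migration kernel lambda / deg)
    x (within-patch fixation probability phi_wm of the immigrant).

Because ``lambda`` is a common factor of every coarse transition, it cancels
from the absorption probabilities: the low-migration fixation probability is
independent of ``lambda``.

The module provides the general ``2^M`` solver plus closed forms for the two
structures with analytic solutions: the two-patch meta-population and the
meta-star (hub with ``M - 1`` leaves, all patch sizes equal), along with
their weak-selection expansions.  The coarse chain uses the patch-uniform
migration kernel ``lambda / deg(j)``; for every structure with a closed form
the neighbours of a patch have equal sizes, so the kernel coincides with the
union-uniform convention of the exact process.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .results import FixationResult
from .structures import PatchGraph
from .wellmixed import fixation_wm

__all__ = [
    "coarse_transitions",
    "fixation_lowmig",
    "fixation_two_patch",
    "metastar_amplification_gap",
    "two_patch_origin_probs",
    "two_patch_weak",
    "StarEvent",
    "metastar_transition",
    "fixation_metastar",
]

MAX_COARSE_PATCHES = 22


def coarse_transitions(
    g: PatchGraph, lam: float, r: float, c
) -> dict[tuple[int, ...], float]:
    """One-migration-event flip probabilities from a homogeneous configuration.

    ``c`` is a binary vector over patches (1 = homogeneous mutant).  A
    wild-type patch ``k`` flips to mutant when a mutant patch ``j`` adjacent
    to it is selected for birth (global selection weight
    ``r N_j / (r * mutant mass + wild mass)``), sends its offspring to ``k``
    (kernel ``lambda / deg(j)``), and the immigrant fixes locally
    (``phi_wm(r, N_k)``); mutant patches flip to wild-type by the mirrored
    ``1/r`` route.  All-mutant and all-wild-type configurations are absorbing
    and return an empty mapping.
    """
    c = tuple(int(x) for x in c)
    if len(c) != g.M or any(x not in (0, 1) for x in c):
        raise ValueError(f"configuration must be binary of length M={g.M}")
    sizes = g.size_array
    mut_mass = int(sum(n for n, x in zip(sizes, c) if x))
    if mut_mass in (0, g.N):
        return {}
    F = r * mut_mass + (g.N - mut_mass)
    out: dict[tuple[int, ...], float] = {}
    for j in range(g.M):
        deg_j = g.degree(j)
        for k in g.neighbors(j):
            if c[j] == 1 and c[k] == 0:
                p = (r * sizes[j] / F) * (lam / deg_j) * fixation_wm(r, int(sizes[k]))
                succ = c[:k] + (1,) + c[k + 1 :]
            elif c[j] == 0 and c[k] == 1:
                p = (sizes[j] / F) * (lam / deg_j) * fixation_wm(1.0 / r, int(sizes[k]))
                succ = c[:k] + (0,) + c[k + 1 :]
            else:
                continue
            out[succ] = out.get(succ, 0.0) + p
    return out


def fixation_lowmig(g: PatchGraph, r: float, lam: float = 1e-3) -> FixationResult:
    """Low-migration fixation probability via the ``2^M`` coarse chain.

    Two-phase logic: a single mutant arising in patch ``j`` (probability
    ``N_j / N``) first fixes locally with probability ``phi_wm(r, N_j)``,
    then the homogeneous-mutant patch spreads through the coarse chain with
    absorption probability ``A(e_j)``.  ``lam`` only scales the coarse
    transitions and cancels from ``A``; it is accepted for interface symmetry.
    """
    if g.M > MAX_COARSE_PATCHES:
        raise RuntimeError(
            f"coarse chain needs 2^{g.M} states; M <= {MAX_COARSE_PATCHES} supported"
        )
    params = {"r": r, "lambda": lam, "structure": g.digest()}
    if g.M == 1:
        return FixationResult(
            phi=fixation_wm(r, int(g.sizes[0])), method="lowmig", params=params
        )
    K = 1 << g.M
    # bit j of the integer code is patch j's occupancy
    def code(c):
        return sum(1 << j for j, x in enumerate(c) if x)

    rows, cols, vals = [], [], []
    rhs = np.zeros(K)
    full = code((1,) * g.M)
    for s in range(K):
        c = tuple((s >> j) & 1 for j in range(g.M))
        trans = coarse_transitions(g, 1.0, r, c)  # lambda cancels; use 1
        if not trans:
            continue
        tot = sum(trans.values())
        for succ, p in trans.items():
            t = code(succ)
            if t == full:
                rhs[s] += p / tot
            elif t != 0:
                rows.append(s)
                cols.append(t)
                vals.append(p / tot)
    transient = [s for s in range(K) if s not in (0, full)]
    pos = {s: q for q, s in enumerate(transient)}
    T = len(transient)
    A = sp.lil_matrix((T, T))
    bb = np.zeros(T)
    for s in transient:
        A[pos[s], pos[s]] = 1.0
        bb[pos[s]] = rhs[s]
    for rr, cc, vv in zip(rows, cols, vals):
        A[pos[rr], pos[cc]] -= vv
    x = spla.spsolve(A.tocsc(), bb)
    absorb = np.zeros(K)
    absorb[full] = 1.0
    for s in transient:
        absorb[s] = x[pos[s]]
    phi = 0.0
    for j in range(g.M):
        phi += (
            g.sizes[j]
            / g.N
            * fixation_wm(r, int(g.sizes[j]))
            * absorb[1 << j]
        )
    return FixationResult(phi=float(phi), method="lowmig", params=params)


# -- two-patch closed forms ----------------------------------------------

def two_patch_origin_probs(N1: int, N2: int, r: float) -> tuple[float, float]:
    """Fixation probabilities of a mutant arising in patch 1 and in patch 2.

    Per-origin products of the local fixation probability and the patch-level
    invasion odds, valid in the low-migration regime.
    """
    p1r = fixation_wm(r, N1)
    p2r = fixation_wm(r, N2)
    p1i = fixation_wm(1.0 / r, N1)
    p2i = fixation_wm(1.0 / r, N2)
    from_1 = p1r * p2r / (p2r + (N2 / N1) * (1.0 / r) * p1i)
    from_2 = p2r * p1r / (p1r + (N1 / N2) * (1.0 / r) * p2i)
    return from_1, from_2


def fixation_two_patch(N1: int, N2: int, r: float) -> float:
    """Average low-migration fixation probability of a two-patch meta-population.

    Size-weighted average of the per-origin probabilities; equals
    ``1 / (N1 + N2)`` at neutrality and reduces to ``phi_wm(r, 2 N1)`` for
    equal patch sizes (the isothermal case).
    """
    from_1, from_2 = two_patch_origin_probs(N1, N2, r)
    return (N1 * from_1 + N2 * from_2) / (N1 + N2)


def two_patch_weak(N1: int, N2: int, r: float) -> float:
    """Weak-selection expansion of :func:`fixation_two_patch` around ``r = 1``.

    ``1/(N1+N2) + (1/2) (1 - 1/(N1+N2) - (N1-N2)^2 N1 N2 / (N1^2+N2^2)^2)(r-1)``.
    The gap to the well-mixed expansion is
    ``- N1 N2 (N1-N2)^2 / (2 (N1^2+N2^2)^2) * (r-1)``: the two-patch structure
    with unequal sizes is a suppressor of selection under weak selection.
    """
    N = N1 + N2
    slope = 0.5 * (1.0 - 1.0 / N - (N1 - N2) ** 2 * N1 * N2 / (N1**2 + N2**2) ** 2)
    return 1.0 / N + slope * (r - 1.0)


# -- meta-star closed forms ----------------------------------------------

class StarEvent(str, Enum):
    """Coarse meta-star transitions; the center is mutant (filled) or wild (open)."""

    LEAF_GAIN = "leaf_gain"      # center mutant reproduces into a wild leaf
    CENTER_GAIN = "center_gain"  # a mutant leaf reproduces into the wild center
    LEAF_LOSS = "leaf_loss"      # wild center reproduces into a mutant leaf
    CENTER_LOSS = "center_loss"  # a wild leaf reproduces into the mutant center


def metastar_transition(
    j: int, center_mutant: bool, M: int, N1: int, lam: float, r: float, event: StarEvent
) -> float:
    """Coarse transition probability of the equal-size meta-star.

    ``j`` counts homogeneous-mutant leaves (0..M-2 relevant interior).  Events
    incompatible with the center state raise; events with no eligible patch
    (e.g. leaf gain at ``j = M - 1``) return 0.
    """
    event = StarEvent(event)
    if not 0 <= j <= M - 1:
        raise ValueError(f"leaf count j must lie in 0..{M - 1}, got {j}")
    phi_r = fixation_wm(r, N1)
    phi_inv = fixation_wm(1.0 / r, N1)
    if event is StarEvent.LEAF_GAIN:
        if not center_mutant:
            raise ValueError("leaf gain requires a mutant center")
        return r / ((j + 1) * r + M - 1 - j) * (M - 1 - j) / (M - 1) * lam * phi_r
    if event is StarEvent.CENTER_GAIN:
        if center_mutant:
            raise ValueError("center gain requires a wild-type center")
        return j * r / (j * r + M - j) * lam * phi_r
    if event is StarEvent.LEAF_LOSS:
        if center_mutant:
            raise ValueError("leaf loss requires a wild-type center")
        return 1.0 / (j * r + M - j) * j / (M - 1) * lam * phi_inv
    # CENTER_LOSS
    if not center_mutant:
        raise ValueError("center loss requires a mutant center")
    return (M - 1 - j) / ((j + 1) * r + M - 1 - j) * lam * phi_inv


def _star_exit_probs(M: int, N1: int, r: float) -> tuple[float, float]:
    """(T_open, T_filled): probabilities that leaving the current center state
    proceeds by a leaf flip rather than a center flip.  Both are independent
    of the number of mutant leaves for the equal-size meta-star."""
    phi_r = fixation_wm(r, N1)
    phi_inv = fixation_wm(1.0 / r, N1)
    t_open = (phi_inv / r) / (phi_inv / r + (M - 1) * phi_r)
    t_filled = (r * phi_r) / (r * phi_r + (M - 1) * phi_inv)
    return t_open, t_filled


def fixation_metastar(M: int, N1: int, r: float) -> float:
    """Low-migration fixation probability of the equal-size meta-star.

    Closed form from the coarse chain on (number of mutant leaves, center
    state).  Writing ``T_open`` / ``T_filled`` for the leaf-flip exit
    probabilities of the two center states and ``Gamma`` for their ratio,

        phi_center = T_filled / (1 + (1 - T_filled) sum_{j=1}^{M-2} Gamma^j)
        phi_leaf   = (1 - T_open) / T_filled * phi_center

    and the meta-population fixation probability is the local fixation
    probability times the size-weighted patch-level average.
    """
    if M < 2:
        raise ValueError("meta-star needs M >= 2 patches")
    t_open, t_filled = _star_exit_probs(M, N1, r)
    gamma = t_open / t_filled
    geo = sum(gamma**j for j in range(1, M - 1))
    phi_center = t_filled / (1.0 + (1.0 - t_filled) * geo)
    phi_leaf = (1.0 - t_open) / t_filled * phi_center
    phi_patch = (M - 1) / M * phi_leaf + 1.0 / M * phi_center
    return fixation_wm(r, N1) * phi_patch


def metastar_amplification_gap(M: int, N1: int, r: float, dps: int = 200) -> float:
    """High-precision ``phi_star(r) - phi_wm(r, M*N1)`` for the meta-star.

    For large meta-populations the amplification gap decays below double
    precision (both probabilities approach ``1 - 1/r`` for advantageous
    mutants), so the closed form and the well-mixed reference are evaluated
    with ``mpmath`` at ``dps`` decimal digits and only the difference is
    rounded back to a float.  Used to scan the amplifier sign pattern over
    wide ``(M, N1)`` ranges.
    """
    import mpmath

    if M < 2:
        raise ValueError("meta-star needs M >= 2 patches")
    with mpmath.workdps(dps):
        rr = mpmath.mpf(r)

        def phi(x, n):
            if x == 1:
                return mpmath.mpf(1) / n
            return (1 - 1 / x) / (1 - x ** (-n))

        phi_r = phi(rr, N1)
        phi_inv = phi(1 / rr, N1)
        t_open = (phi_inv / rr) / (phi_inv / rr + (M - 1) * phi_r)
        t_filled = (rr * phi_r) / (rr * phi_r + (M - 1) * phi_inv)
        gamma = t_open / t_filled
        geo = sum(gamma**j for j in range(1, M - 1))
        phi_center = t_filled / (1 + (1 - t_filled) * geo)
        phi_leaf = (1 - t_open) / t_filled * phi_center
        phi_patch = mpmath.mpf(M - 1) / M * phi_leaf + mpmath.mpf(1) / M * phi_center
        gap = phi_r * phi_patch - phi(rr, M * N1)
        return float(gap)
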