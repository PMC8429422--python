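"""Closed-form fixation probabilities for a single well-mixed Moran population.

In a well-mixed population of constant size ``N`` under Birth-death (Bd)
updating, one individual is chosen per time step proportional to fitness to
reproduce, and its offspring replaces a uniformly chosen individual.  A mutant
of relative fitness ``r`` (wild-type fitness 1) founds a lineage that either
fixes or goes extinct.  The fixation probability from ``i`` mutants has the
classical birth-death-chain closed form; this module evaluates it stably and
is the reference quantity ``phi_wm`` against which structured meta-populations
are compared throughout the package.
"""

from __future__ import annotations

import math

__all__ = ["moran_transition_probs", "fixation_wm", "fixation_wm_weak"]


def _check_r(r: float) -> None:
    if not (r > 0) or math.isinf(r) or math.isnan(r):
        raise ValueError(f"relative fitness r must be a positive finite real, got {r!r}")


def _check_N_i(N: int, i: int) -> None:
    if int(N) != N or N < 1:
        raise ValueError(f"population size N must be a positive integer, got {N!r}")
    if int(i) != i or not 0 <= i <= N:
        raise ValueError(f"mutant count i must satisfy 0 <= i <= N={N}, got {i!r}")


def moran_transition_probs(i: int, N: int, r: float) -> tuple[float, float]:
    """One-step transition probabilities of the Moran Bd chain on mutant count.

    Parameters
    ----------
    i
        Current number of mutants, ``0 <= i <= N``.
    N
        Population size.
    r
        Relative fitness of the mutant (wild-type fitness is 1).

    Returns
    -------
    (T_plus, T_minus)
        Probability that the mutant count increases to ``i + 1`` and that it
        decreases to ``i - 1``.  Both vanish at the absorbing boundaries
        ``i = 0`` and ``i = N``.  Their ratio is ``T_minus / T_plus = 1 / r``
        for every interior ``i``.
    """
    _check_r(r)
    _check_N_i(N, i)
    if i == 0 or i == N:
        return 0.0, 0.0
    total_fitness = (N - i) + r * i
    t_plus = (r * i) / total_fitness * (N - i) / N
    t_minus = (N - i) / total_fitness * i / N
    return t_plus, t_minus


def fixation_wm(r: float, N: int, i: int = 1) -> float:
    """Fixation probability of ``i`` mutants in a well-mixed Bd Moran population.

    Because the ratio of backward to forward transition probabilities is the
    constant ``1/r``, the absorption probability is a ratio of geometric sums,

        phi_i = (1 - r**-i) / (1 - r**-N)      for r != 1,
        phi_i = i / N                          for r = 1.

    For a single mutant (``i = 1``) this is the textbook
    ``(1 - 1/r) / (1 - 1/r**N)``.

    The expression is evaluated with ``expm1`` in log space so that it neither
    cancels catastrophically near ``r = 1`` nor overflows when ``N*|log r|``
    is large; for ``|r - 1| < 1e-12`` the neutral branch ``i / N`` is used.
    """
    _check_r(r)
    _check_N_i(N, i)
    if i == 0:
        return 0.0
    if i == N:
        return 1.0
    if abs(r - 1.0) < 1e-12:
        return i / N
    log_r = math.log(r)
    a = -i * log_r
    b = -N * log_r
    # a and b share sign; overflow is only possible for r < 1 (a, b > 0).
    if b > 700.0:
        if a > 700.0:
            return math.exp(a - b)
        return math.expm1(a) * math.exp(-b)
    return math.expm1(a) / math.expm1(b)


def fixation_wm_weak(r: float, N: int, sign: int = +1) -> float:
    """First-order weak-selection expansion of :func:`fixation_wm` at ``r = 1``.

    Returns ``1/N + sign * (N - 1) / (2N) * (r - 1)``, the linearisation of
    the single-mutant fixation probability ``phi_wm(r**sign)`` for
    ``|r - 1| << 1``.  ``sign=+1`` expands the mutant's fixation probability,
    ``sign=-1`` the wild-type counterpart ``phi_wm(1/r)``.
    """
    _check_r(r)
    _check_N_i(N, 1)
    if sign not in (+1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign!r}")
    return 1.0 / N + sign * (N - 1) / (2.0 * N) * (r - 1.0)
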