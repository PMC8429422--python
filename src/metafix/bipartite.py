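"""High-migration (lambda = 1) closed forms via the martingale approach.

At maximal migration every offspring is placed outside its natal patch, so a
two-patch meta-population becomes a complete bipartite graph K_{N1,N2} of
individuals, and the meta-star becomes K_{(M-1)N/M, N/M} (all leaves versus
the hub).  For complete bipartite graphs under Birth-death updating the
product statistic ``h1**a * h2**b`` (``a``, ``b`` mutant counts in the two
parts) is a martingale of the process, with

    h1 = (N2/N1 + 1/r) / (N2/N1 + r),
    h2 = (N1/N2 + 1/r) / (N1/N2 + r),

which yields closed-form fixation probabilities from either part.  Any
complete bipartite graph with unequal parts is an amplifier of selection;
equal parts are isothermal.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .wellmixed import _check_r  # shared domain validation

__all__ = [
    "BipartiteFixation",
    "martingale_weights",
    "fixation_bipartite",
    "metastar_high_migration",
    "weak_selection_gap",
]

_NEUTRAL_BAND = 1e-8


class BipartiteFixation(NamedTuple):
    phi1: float   # single mutant arising in part 1
    phi2: float   # single mutant arising in part 2
    phi_avg: float  # size-weighted average


def martingale_weights(N1: int, N2: int, r: float) -> tuple[float, float]:
    """Conserved-product bases (h1, h2) of the complete bipartite martingale."""
    _check_r(r)
    a = N2 / N1
    b = N1 / N2
    return (a + 1.0 / r) / (a + r), (b + 1.0 / r) / (b + r)


def fixation_bipartite(N1: int, N2: int, r: float) -> BipartiteFixation:
    """Fixation probabilities on the complete bipartite graph K_{N1,N2}.

    ``phi_part = (h_part - 1) / (h1**N1 * h2**N2 - 1)``; the denominator is
    evaluated with ``expm1`` of ``N1 log h1 + N2 log h2`` to avoid both
    overflow and the 0/0 cancellation near neutrality, where the analytic
    limits ``phi1 = N1/(N1^2+N2^2)``, ``phi2 = N2/(N1^2+N2^2)`` are used.
    """
    _check_r(r)
    if N1 < 1 or N2 < 1:
        raise ValueError("part sizes must be >= 1")
    if abs(r - 1.0) < _NEUTRAL_BAND:
        s = N1 * N1 + N2 * N2
        phi1 = N1 / s
        phi2 = N2 / s
    else:
        a = N2 / N1
        b = N1 / N2
        # h - 1 = (1/r - r) / (ratio + r), computed without cancellation
        num = (1.0 / r) - r
        h1m1 = num / (a + r)
        h2m1 = num / (b + r)
        log_h1 = math.log1p(h1m1)
        log_h2 = math.log1p(h2m1)
        denom = math.expm1(N1 * log_h1 + N2 * log_h2)
        phi1 = h1m1 / denom
        phi2 = h2m1 / denom
    phi_avg = (N1 * phi1 + N2 * phi2) / (N1 + N2)
    return BipartiteFixation(phi1=phi1, phi2=phi2, phi_avg=phi_avg)


def metastar_high_migration(M: int, N: int, r: float) -> float:
    """Meta-star fixation probability at lambda = 1 via the bipartite mapping.

    The star of ``M`` equal patches of size ``N/M`` maps to the complete
    bipartite graph with the ``M - 1`` leaf patches as one part
    (``(M-1)N/M`` individuals) and the hub as the other (``N/M``).
    """
    if M < 2:
        raise ValueError("meta-star needs M >= 2 patches")
    if N % M != 0:
        raise ValueError(f"total size N={N} must be divisible by M={M}")
    leaf_part = (M - 1) * N // M
    hub_part = N // M
    return fixation_bipartite(leaf_part, hub_part, r).phi_avg


def weak_selection_gap(N1: int, N2: int, r: float) -> float:
    """First-order gap between the bipartite and well-mixed fixation probabilities.

    ``(1/2) (N1-N2)^2/(N1+N2)^2 * (N1(N1-1) + N2(N2-1))/(N1^2+N2^2) * (r-1)``;
    positive for ``r > 1`` and negative for ``r < 1`` whenever ``N1 != N2``
    and ``N1 + N2 > 2`` — unequal complete bipartite graphs amplify selection.
    """
    _check_r(r)
    coef = (
        0.5
        * (N1 - N2) ** 2
        / (N1 + N2) ** 2
        * (N1 * (N1 - 1) + N2 * (N2 - 1))
        / (N1**2 + N2**2)
    )
    return coef * (r - 1.0)
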