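import numpy as np
import pytest

import metafix as mf


@pytest.fixture(scope="session")
def two_patch_37() -> mf.PatchGraph:
    """Two patches of sizes 3 and 7 (the canonical unequal two-patch case)."""
    return mf.two_patch(3, 7)


@pytest.fixture(scope="session")
def meta_star_45() -> mf.PatchGraph:
    """Meta-star with M=4 patches (hub + 3 leaves), all of size 5."""
    return mf.meta_star(4, 5)


@pytest.fixture(scope="session")
def cycle3() -> mf.PatchGraph:
    """3-cycle of size-3 patches: regular and equal-size, hence isothermal."""
    return mf.cycle(3, 3)


def brute_force_moran(r: float, N: int, i: int = 1) -> float:
    """Independent oracle: absorption probability of the (N+1)-state
    birth-death chain assembled from the one-step transition probabilities."""
    A = np.zeros((N + 1, N + 1))
    b = np.zeros(N + 1)
    A[0, 0] = 1.0
    A[N, N] = 1.0
    b[N] = 1.0
    for k in range(1, N):
        tp, tm = mf.moran_transition_probs(k, N, r)
        A[k, k - 1] = -tm
        A[k, k] = tp + tm
        A[k, k + 1] = -tp
    return float(np.linalg.solve(A, b)[i])


def brute_force_coarse(g: mf.PatchGraph, r: float) -> float:
    """Independent oracle for the low-migration fixation probability:
    dense absorption solve over all 2^M homogeneous configurations using the
    coarse flip probabilities, then the two-phase weighting."""
    M = g.M
    K = 1 << M
    A = np.eye(K)
    b = np.zeros(K)
    full = K - 1
    b[full] = 1.0
    for s in range(1, full):
        c = tuple((s >> j) & 1 for j in range(M))
        trans = mf.coarse_transitions(g, 1e-5, r, c)
        tot = sum(trans.values())
        for succ, p in trans.items():
            t = sum(1 << j for j, x in enumerate(succ) if x)
            A[s, t] -= p / tot
    absorb = np.linalg.solve(A, b)
    phi = 0.0
    for j in range(M):
        phi += g.sizes[j] / g.N * mf.fixation_wm(r, int(g.sizes[j])) * absorb[1 << j]
    return float(phi)
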