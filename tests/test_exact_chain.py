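"""Exact full-state Markov-chain solver: operator structure and fixation values."""

import itertools

import numpy as np
import pytest

import metafix as mf
from metafix.exact_chain import CapacityError, transition_matrix


def test_state_index_bijection(two_patch_37):
    assert mf.state_index((0, 0), two_patch_37) == 0
    assert mf.state_index((3, 7), two_patch_37) == 31
    for m in itertools.product(range(4), range(8)):
        assert mf.state_unindex(mf.state_index(m, two_patch_37), two_patch_37) == m
    with pytest.raises(ValueError):
        mf.state_index((4, 0), two_patch_37)
    with pytest.raises(ValueError):
        mf.state_unindex(32, two_patch_37)


def test_step_distribution_absorbing(two_patch_37):
    assert mf.step_distribution((0, 0), two_patch_37, 0.1, 2.0) == {(0, 0): 1.0}
    assert mf.step_distribution((3, 7), two_patch_37, 0.1, 2.0) == {(3, 7): 1.0}


def test_step_distribution_single_patch_reduction():
    g = mf.PatchGraph.from_lists([3], [])
    d = mf.step_distribution((1,), g, 0.5, 2.0)
    tp, tm = mf.moran_transition_probs(1, 3, 2.0)
    assert d[(2,)] == pytest.approx(tp)
    assert d[(0,)] == pytest.approx(tm)
    assert d[(1,)] == pytest.approx(1 - tp - tm)


def test_step_distribution_migration_example(two_patch_37):
    """From a full mutant patch 1: a mutant parent (prob 6/13) migrates
    (prob 0.1) and necessarily replaces a wild-type, so (3,0)->(3,1) carries
    probability (6/13) * 0.1."""
    d = mf.step_distribution((3, 0), two_patch_37, 0.1, 2.0)
    assert d[(3, 1)] == pytest.approx(6 / 13 * 0.1, abs=1e-15)
    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)


def test_step_support_is_one_coordinate_plus_minus_one(meta_star_45):
    rng = np.random.default_rng(0)
    for _ in range(10):
        m = tuple(int(rng.integers(0, n + 1)) for n in meta_star_45.sizes)
        for succ, p in mf.step_distribution(m, meta_star_45, 0.4, 1.3).items():
            delta = np.subtract(succ, m)
            assert np.abs(delta).sum() <= 1
            assert p >= 0


@pytest.mark.parametrize("lam", [0.05, 0.5, 1.0])
def test_transition_rows_sum_to_one(lam, two_patch_37):
    P = transition_matrix(two_patch_37, lam, 1.7)
    assert np.allclose(np.asarray(P.sum(axis=1)).ravel(), 1.0, atol=1e-12)
    # exactly two absorbing states for lam > 0
    diag = P.diagonal()
    assert set(np.flatnonzero(diag == 1.0)) == {0, 31}


def test_single_patch_matches_wellmixed():
    g = mf.PatchGraph.from_lists([10], [])
    res = mf.fixation_exact(g, 0.5, 2.0)
    assert res.phi == pytest.approx(mf.fixation_wm(2.0, 10), abs=1e-12)


@pytest.mark.parametrize("lam", [0.01, 0.3, 1.0])
def test_neutral_uniform_start_is_one_over_N(lam, two_patch_37):
    res = mf.fixation_exact(two_patch_37, lam, 1.0)
    assert res.phi == pytest.approx(0.1, abs=1e-10)


def test_isothermal_cycle_matches_wellmixed(cycle3):
    res = mf.fixation_exact(cycle3, 0.4, 2.0)
    assert res.phi == pytest.approx(mf.fixation_wm(2.0, 9), abs=1e-10)


def test_zero_migration_multi_patch_cannot_fix(two_patch_37):
    with pytest.warns(UserWarning, match="lambda=0"):
        res = mf.fixation_exact(two_patch_37, 0.0, 2.0)
    assert res.phi == 0.0


def test_patch_and_explicit_state_inits(two_patch_37):
    res0 = mf.fixation_exact(two_patch_37, 0.1, 1.5, init=0)
    res1 = mf.fixation_exact(two_patch_37, 0.1, 1.5, init=1)
    vec_init = mf.fixation_exact(two_patch_37, 0.1, 1.5, init=(1, 0))
    assert res0.phi == pytest.approx(vec_init.phi, abs=1e-14)
    uniform = mf.fixation_exact(two_patch_37, 0.1, 1.5).phi
    assert uniform == pytest.approx(0.3 * res0.phi + 0.7 * res1.phi, abs=1e-12)


def test_monotone_in_fitness(two_patch_37):
    phis = [mf.fixation_exact(two_patch_37, 0.2, r).phi for r in (0.5, 0.9, 1.0, 1.3, 2.0)]
    assert all(a < b for a, b in zip(phis, phis[1:]))


def test_full_vector_boundaries(two_patch_37):
    res, vec = mf.fixation_exact(two_patch_37, 0.3, 1.5, return_vector=True)
    assert vec[0] == 0.0 and vec[31] == 1.0
    assert np.all((vec >= 0) & (vec <= 1))
    # absorption vector is harmonic: x = P x on transient states
    P = transition_matrix(two_patch_37, 0.3, 1.5)
    assert np.allclose(P @ vec, vec, atol=1e-10)


def test_state_ceiling():
    g = mf.two_patch(2000, 2000)
    with pytest.raises(CapacityError):
        mf.fixation_exact(g, 0.1, 1.5, state_ceiling=1000)
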