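"""Low-migration coarse chain and the two-patch / meta-star closed forms."""

import numpy as np
import pytest

import metafix as mf
from metafix.low_migration import metastar_amplification_gap
from conftest import brute_force_coarse

R_GRID = np.geomspace(0.25, 4.0, 9)


def test_coarse_absorbing_configs_have_no_successors(two_patch_37):
    assert mf.coarse_transitions(two_patch_37, 0.01, 2.0, (1, 1)) == {}
    assert mf.coarse_transitions(two_patch_37, 0.01, 2.0, (0, 0)) == {}


def test_coarse_two_patch_flip_probabilities(two_patch_37):
    """From (mutant, wild): patch 2 flips up with weight
    (3r/(3r+7)) lam phi_wm(r,7); patch 1 flips down with the 1/r mirror."""
    r, lam = 2.0, 0.01
    trans = mf.coarse_transitions(two_patch_37, lam, r, (1, 0))
    up = (3 * r / (3 * r + 7)) * lam * mf.fixation_wm(r, 7)
    down = (7 / (3 * r + 7)) * lam * mf.fixation_wm(1 / r, 3)
    assert trans[(1, 1)] == pytest.approx(up, rel=1e-14)
    assert trans[(0, 0)] == pytest.approx(down, rel=1e-14)


@pytest.mark.parametrize("r", [0.5, 1.5])
def test_metastar_transition_matches_coarse_chain(meta_star_45, r):
    """The four printed meta-star transitions equal the general coarse
    transitions on the star patch graph, for every leaf count."""
    M, N1, lam = 4, 5, 0.01
    for j in range(0, M - 1):
        # center mutant, j mutant leaves
        c = (1,) + (1,) * j + (0,) * (M - 1 - j)
        trans = mf.coarse_transitions(meta_star_45, lam, r, c)
        gain = sum(p for s, p in trans.items() if sum(s) == j + 2)
        loss = sum(p for s, p in trans.items() if sum(s) == j)
        assert gain == pytest.approx(
            mf.metastar_transition(j, True, M, N1, lam, r, mf.StarEvent.LEAF_GAIN), abs=1e-16
        )
        assert loss == pytest.approx(
            mf.metastar_transition(j, True, M, N1, lam, r, mf.StarEvent.CENTER_LOSS), abs=1e-16
        )
        # center wild, j mutant leaves
        c = (0,) + (1,) * j + (0,) * (M - 1 - j)
        trans = mf.coarse_transitions(meta_star_45, lam, r, c)
        gain = sum(p for s, p in trans.items() if s[0] == 1)
        loss = sum(p for s, p in trans.items() if s[0] == 0 and sum(s) == j - 1)
        assert gain == pytest.approx(
            mf.metastar_transition(j, False, M, N1, lam, r, mf.StarEvent.CENTER_GAIN), abs=1e-16
        )
        assert loss == pytest.approx(
            mf.metastar_transition(j, False, M, N1, lam, r, mf.StarEvent.LEAF_LOSS), abs=1e-16
        )


def test_metastar_transition_boundary_zeros():
    assert mf.metastar_transition(3, True, 4, 5, 0.01, 2.0, mf.StarEvent.LEAF_GAIN) == 0.0
    assert mf.metastar_transition(0, False, 4, 5, 0.01, 2.0, mf.StarEvent.LEAF_LOSS) == 0.0
    with pytest.raises(ValueError):
        mf.metastar_transition(1, False, 4, 5, 0.01, 2.0, mf.StarEvent.LEAF_GAIN)


def test_lowmig_single_patch():
    g = mf.PatchGraph.from_lists([9], [])
    assert mf.fixation_lowmig(g, 2.0).phi == pytest.approx(mf.fixation_wm(2.0, 9))


@pytest.mark.parametrize("r", R_GRID)
def test_two_patch_closed_form_vs_coarse_oracle(r, two_patch_37):
    """Closed form equals the independent 4-state coarse absorption solve."""
    oracle = brute_force_coarse(two_patch_37, float(r))
    assert mf.fixation_two_patch(3, 7, float(r)) == pytest.approx(oracle, abs=1e-12)
    assert mf.fixation_lowmig(two_patch_37, float(r)).phi == pytest.approx(oracle, abs=1e-12)


@pytest.mark.parametrize("r", R_GRID)
def test_metastar_closed_form_vs_coarse_oracle(r, meta_star_45):
    oracle = brute_force_coarse(meta_star_45, float(r))
    assert mf.fixation_metastar(4, 5, float(r)) == pytest.approx(oracle, abs=1e-12)
    assert mf.fixation_lowmig(meta_star_45, float(r)).phi == pytest.approx(oracle, abs=1e-12)


def test_two_patch_neutral_and_equal_size_identities():
    assert mf.fixation_two_patch(3, 7, 1.0) == pytest.approx(0.1, abs=1e-14)
    for N1 in range(1, 51):
        for r in (0.5, 2.0):
            assert mf.fixation_two_patch(N1, N1, r) == pytest.approx(
                mf.fixation_wm(r, 2 * N1), abs=1e-14
            )


def test_metastar_neutral_limit():
    for M, N1 in ((2, 4), (4, 5), (6, 3)):
        target = 1 / (M * N1)
        for r in (1 - 1e-9, 1 + 1e-9):
            assert mf.fixation_metastar(M, N1, r) == pytest.approx(target, abs=1e-8)


def test_lambda_cancels_from_coarse_fixation(two_patch_37, meta_star_45):
    for g in (two_patch_37, meta_star_45):
        a = mf.fixation_lowmig(g, 1.7, lam=1e-8).phi
        b = mf.fixation_lowmig(g, 1.7, lam=1e-3).phi
        assert a == pytest.approx(b, abs=1e-15)


def test_weak_expansion_slope_matches_closed_form():
    h = 1e-4
    num = (mf.fixation_two_patch(3, 7, 1 + h) - mf.fixation_two_patch(3, 7, 1 - h)) / (2 * h)
    ana = (mf.two_patch_weak(3, 7, 1 + h) - mf.two_patch_weak(3, 7, 1 - h)) / (2 * h)
    assert num == pytest.approx(ana, abs=1e-6)
    # equal sizes reduce to the single-population expansion with zero gap
    assert mf.two_patch_weak(5, 5, 1.2) == pytest.approx(mf.fixation_wm_weak(1.2, 10), abs=1e-15)


def test_two_patch_suppressor_pattern(two_patch_37):
    for r in R_GRID:
        d = mf.fixation_two_patch(3, 7, float(r)) - mf.fixation_wm(float(r), 10)
        if r > 1:
            assert d < 0
        elif r < 1:
            assert d > 0


def test_metastar_amplifier_pattern():
    for r in R_GRID:
        d = mf.fixation_metastar(4, 5, float(r)) - mf.fixation_wm(float(r), 20)
        if r > 1:
            assert d > 0
        elif r < 1:
            assert d < 0


def test_metastar_amplifier_scan_high_precision():
    """Amplifier sign pattern over M in {3,4,5}, N1 in {1,2,5,10,100}; the
    gap underflows double precision for N1=100, hence the mpmath route."""
    for M in (3, 4, 5):
        for N1 in (1, 2, 5, 10, 100):
            for r in (0.25, 0.5, 2.0, 4.0):
                gap = metastar_amplification_gap(M, N1, r)
                assert (gap > 0) == (r > 1)


@pytest.mark.parametrize(
    "g_name, closed",
    [
        ("two_patch_37", lambda r: mf.fixation_two_patch(3, 7, r)),
        ("meta_star_45", lambda r: mf.fixation_metastar(4, 5, r)),
    ],
)
def test_agreement_with_exact_chain_at_tiny_migration(g_name, closed, request):
    g = request.getfixturevalue(g_name)
    for r in (0.5, 1.5, 3.0):
        exact = mf.fixation_exact(g, 1e-6, r).phi
        assert closed(r) == pytest.approx(exact, abs=1e-3)


def test_strong_selection_limits():
    # equal halves: taking over the first patch makes global fixation certain
    assert mf.fixation_two_patch(25, 25, 8.0) == pytest.approx(mf.fixation_wm(8.0, 25), rel=0.05)
    # dominant large patch drives fixation of the whole meta-population
    assert mf.fixation_two_patch(50, 2, 8.0) == pytest.approx(mf.fixation_wm(8.0, 52), rel=0.05)
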