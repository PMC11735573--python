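"""Gamete-frequency model: tabulated rows, parameter geometry, symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetraseg.gamete import (
    DEFAULT_DR_CAP,
    MeiosisParams2,
    MeiosisParams3,
    gamete_freq_2p,
    gamete_freq_3p,
    hypergeometric_gamete,
    map_3p_to_2p,
    offspring_freq,
    possible_offspring_genotypes,
    xi_bounds,
)

unit = st.floats(0.0, 1.0, allow_nan=False)
dr = st.floats(0.0, DEFAULT_DR_CAP, allow_nan=False)


@pytest.mark.parametrize(
    "ell, alpha, xi, expected",
    [
        (0, 0.1, 0.9, (1, 0, 0)),
        (4, 0.1, 0.2, (0, 0, 1)),
        (1, 1 / 6, 0.5, (13 / 24, 10 / 24, 1 / 24)),
        (2, 0.0, 1.0, (0, 1, 0)),
        (2, 1 / 6, 1 / 3, (2 / 9, 5 / 9, 2 / 9)),
        (2, 0.0, 1 / 3, (1 / 6, 4 / 6, 1 / 6)),
        (2, 0.0, 0.0, (1 / 4, 2 / 4, 1 / 4)),
    ],
)
def test_two_parameter_rows(ell, alpha, xi, expected):
    np.testing.assert_allclose(gamete_freq_2p(ell, alpha, xi), expected,
                               atol=1e-15)


@pytest.mark.parametrize(
    "ell, tau, beta, gamma, expected",
    [
        (4, 0.3, 0.1, 0.5, (0, 0, 1)),
        (2, 1.0, 0.0, 0.5, (1 / 6, 4 / 6, 1 / 6)),
        (2, 0.0, 0.0, 1.0, (0, 1, 0)),
    ],
)
def test_three_parameter_rows(ell, tau, beta, gamma, expected):
    np.testing.assert_allclose(gamete_freq_3p(ell, tau, beta, gamma), expected,
                               atol=1e-15)


def test_duplex_identifiability_collapse():
    """Double reduction 1/6 with random pairing is indistinguishable from no
    double reduction with xi = 1/9."""
    a = gamete_freq_2p(2, 1 / 6, 1 / 3)
    b = gamete_freq_2p(2, 0.0, 1 / 9)
    np.testing.assert_allclose(a, b, atol=1e-12)


@given(ell=st.integers(0, 4), alpha=dr, xi=unit)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_gamete_dist_sums_to_one_and_flip_symmetry(ell, alpha, xi):
    p = gamete_freq_2p(ell, alpha, xi)
    assert abs(p.sum() - 1.0) < 1e-12
    assert np.all(p >= 0)
    np.testing.assert_allclose(p[::-1], gamete_freq_2p(4 - ell, alpha, xi),
                               atol=1e-12)


@given(tau=unit, beta=dr, gamma=unit, ell=st.integers(0, 4))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_three_param_rows_sum_to_one(tau, beta, gamma, ell):
    p = gamete_freq_3p(ell, tau, beta, gamma)
    assert abs(p.sum() - 1.0) < 1e-12


def test_parameterization_identity_on_grid():
    """The reduced two-parameter model reproduces the three-parameter gamete
    frequencies exactly across a dense (tau, beta, gamma) grid."""
    grid = np.linspace(0.0, 1.0, 10)
    worst = 0.0
    for tau in grid:
        for beta in grid * DEFAULT_DR_CAP:
            for gamma in grid:
                mapped = map_3p_to_2p(MeiosisParams3(tau, beta, gamma, gamma))
                for ell in range(5):
                    p3 = gamete_freq_3p(ell, tau, beta, gamma)
                    p2 = gamete_freq_2p(ell, mapped.alpha, mapped.xi1)
                    worst = max(worst, np.abs(p3 - p2).max())
    assert worst < 1e-12


@pytest.mark.parametrize(
    "tau, beta, gamma, expected_alpha, expected_xi",
    [(1.0, 0.05, 0.7, 0.05, 1 / 3), (0.0, 0.1, 0.8, 0.0, 0.8)],
)
def test_map_special_cases(tau, beta, gamma, expected_alpha, expected_xi):
    m = map_3p_to_2p(MeiosisParams3(tau, beta, gamma, gamma))
    assert m.alpha == pytest.approx(expected_alpha, abs=1e-12)
    assert m.xi1 == pytest.approx(expected_xi, abs=1e-12)


def test_offspring_convolution():
    np.testing.assert_allclose(
        offspring_freq([1, 0, 0], [1, 0, 0]), [1, 0, 0, 0, 0], atol=1e-15)
    np.testing.assert_allclose(
        offspring_freq([0.5, 0.5, 0], [1, 0, 0]), [0.5, 0.5, 0, 0, 0],
        atol=1e-15)
    q = offspring_freq(gamete_freq_2p(1, 1 / 6, 0.0), [1, 0, 0])
    assert q[0] / q[2] == pytest.approx(13.0)
    assert q[1] / q[2] == pytest.approx(10.0)


@given(p1=st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
       p2=st.lists(st.floats(0.01, 1), min_size=3, max_size=3))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_offspring_freq_symmetric(p1, p2):
    p1 = np.array(p1) / np.sum(p1)
    p2 = np.array(p2) / np.sum(p2)
    np.testing.assert_allclose(offspring_freq(p1, p2), offspring_freq(p2, p1),
                               atol=1e-12)


def test_offspring_allele_flip_symmetry():
    for ell1, ell2 in [(1, 0), (2, 1), (2, 2), (3, 4)]:
        q = offspring_freq(gamete_freq_2p(ell1, 0.1, 0.4),
                           gamete_freq_2p(ell2, 0.1, 0.4))
        qf = offspring_freq(gamete_freq_2p(4 - ell1, 0.1, 0.4),
                            gamete_freq_2p(4 - ell2, 0.1, 0.4))
        np.testing.assert_allclose(q, qf[::-1], atol=1e-12)


@pytest.mark.parametrize("ell, expected", [
    (0, (1, 0, 0)), (1, (0.5, 0.5, 0)), (2, (1 / 6, 4 / 6, 1 / 6)),
])
def test_hypergeometric_gamete(ell, expected):
    np.testing.assert_allclose(hypergeometric_gamete(ell), expected,
                               atol=1e-12)


def test_hypergeometric_matches_two_param_at_tetrasomic():
    for ell in range(5):
        np.testing.assert_allclose(
            gamete_freq_2p(ell, 0.0, 1 / 3), hypergeometric_gamete(ell),
            atol=1e-12)


def test_hypergeometric_rejects_odd_ploidy():
    with pytest.raises(ValueError):
        hypergeometric_gamete(1, ploidy=3)


@pytest.mark.parametrize("alpha, cap, expected", [
    (0.0, 1 / 6, (0.0, 1.0)),
    (1 / 6, 1 / 6, (1 / 3, 1 / 3)),
    (1 / 12, 1 / 6, (5 / 33, 1 - 10 / 33)),
])
def test_xi_bounds(alpha, cap, expected):
    lo, hi = xi_bounds(alpha, cap)
    assert lo == pytest.approx(expected[0], abs=1e-12)
    assert hi == pytest.approx(expected[1], abs=1e-12)
    assert lo <= hi + 1e-12


def test_xi_bounds_zero_cap_rejects_positive_alpha():
    with pytest.raises(ValueError):
        xi_bounds(0.05, 0.0)
    assert xi_bounds(0.0, 0.0) == (0.0, 1.0)


def test_params2_validates_joint_bound():
    with pytest.raises(ValueError):
        MeiosisParams2(alpha=1 / 6, xi1=0.9, xi2=1 / 3)


@pytest.mark.parametrize("ells, expected", [
    ((0, 0), {0}), ((1, 0), {0, 1, 2}), ((1, 4), {2, 3, 4}),
    ((2, 2), {0, 1, 2, 3, 4}), ((4, 4), {4}), ((0, 4), {2}),
])
def test_possible_offspring_genotypes(ells, expected):
    assert possible_offspring_genotypes(*ells) == frozenset(expected)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        gamete_freq_2p(5, 0.0, 0.5)
    with pytest.raises(ValueError):
        gamete_freq_2p(1, 0.5, 0.5)  # alpha above the cap
    with pytest.raises(ValueError):
        gamete_freq_3p(2, 1.2, 0.0, 0.5)
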