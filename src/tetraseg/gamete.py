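"""Gamete and offspring genotype frequencies for tetraploid meiosis.

A tetraploid parent with allele dosage ``ell`` in {0,...,4} transmits a
gamete carrying 0, 1, or 2 copies of the alternative allele.  Two meiotic
processes move the gamete frequencies away from the classical hypergeometric
values: *double reduction* (co-migration of sister-chromatid segments into
the same gamete during multivalent meiosis) and *preferential pairing*
(homologues preferring particular bivalent partners, the hallmark of
segmental allopolyploidy).  This module implements

* a three-parameter model in terms of the quadrivalent-formation probability
  ``tau``, the double-reduction probability given a quadrivalent ``beta``,
  and the probability ``gamma`` of an AA:aa bivalent pairing;
* the equivalent two-parameter model in terms of the double reduction rate
  ``alpha = beta * tau`` and a preferential pairing parameter ``xi``
  (``xi = 1/3`` is tetrasomic/random pairing; ``xi`` of 0 or 1 is fully
  disomic);
* the convolution of two parental gamete distributions into the length-5
  offspring genotype distribution; and
* the geometry of the parameter space: the joint bound linking ``alpha``
  and ``xi``, and the set of offspring genotypes reachable under the model.

Probabilities are returned as plain ``numpy`` arrays that sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

#: Maximum double-reduction rate under complete equational segregation.
DEFAULT_DR_CAP = 1.0 / 6.0

#: Tolerance below which a negative probability produced by floating-point
#: cancellation is clipped to zero; larger deficits raise.
_CLIP_TOL = 1e-10

__all__ = [
    "DEFAULT_DR_CAP",
    "MeiosisParams2",
    "MeiosisParams3",
    "gamete_freq_2p",
    "gamete_freq_3p",
    "map_3p_to_2p",
    "offspring_freq",
    "hypergeometric_gamete",
    "xi_bounds",
    "possible_offspring_genotypes",
]


def _validate_dosage(ell: int, ploidy: int = 4) -> int:
    ell = int(ell)
    if not 0 <= ell <= ploidy:
        raise ValueError(f"parent dosage must be in 0..{ploidy}, got {ell}")
    return ell


def _validate_unit(value: float, name: str, hi: float = 1.0) -> float:
    value = float(value)
    if not 0.0 <= value <= hi + 1e-12:
        raise ValueError(f"{name} must be in [0, {hi}], got {value}")
    return min(value, hi)


def _clip_simplex(p: np.ndarray) -> np.ndarray:
    """Clip tiny negative entries and renormalize; reject real deficits."""
    p = np.asarray(p, dtype=float)
    neg = p[p < 0]
    if neg.size:
        if neg.sum() < -_CLIP_TOL:
            raise ValueError(f"invalid probability vector {p}")
        p = np.clip(p, 0.0, None)
    s = p.sum()
    if abs(s - 1.0) > 1e-8:
        raise ValueError(f"probability vector does not sum to 1: {p}")
    return p / s


@dataclass(frozen=True)
class MeiosisParams3:
    """Quadrivalent/bivalent meiosis parameters (three-parameter model).

    tau      : probability of quadrivalent formation.
    beta     : probability of double reduction given a quadrivalent.
    gamma1/2 : per-parent probability of AA:aa bivalent pairing.
    """

    tau: float
    beta: float
    gamma1: float
    gamma2: float
    dr_cap: float = DEFAULT_DR_CAP

    def __post_init__(self):
        _validate_unit(self.tau, "tau")
        _validate_unit(self.beta, "beta", hi=self.dr_cap)
        _validate_unit(self.gamma1, "gamma1")
        _validate_unit(self.gamma2, "gamma2")


@dataclass(frozen=True)
class MeiosisParams2:
    """Reduced meiosis parameters: double reduction rate and pairing.

    alpha  : double reduction rate, in [0, dr_cap].
    xi1/2  : per-parent preferential pairing parameter; must respect the
             joint bound with alpha (see :func:`xi_bounds`).
    """

    alpha: float
    xi1: float
    xi2: float
    dr_cap: float = DEFAULT_DR_CAP

    def __post_init__(self):
        _validate_unit(self.alpha, "alpha", hi=self.dr_cap)
        lo, hi = xi_bounds(self.alpha, self.dr_cap)
        for name, xi in (("xi1", self.xi1), ("xi2", self.xi2)):
            _validate_unit(xi, name)
            if not lo - 1e-9 <= xi <= hi + 1e-9:
                raise ValueError(
                    f"{name}={xi} violates the pairing bound "
                    f"[{lo}, {hi}] at alpha={self.alpha}"
                )


def gamete_freq_2p(
    ell: int, alpha: float, xi: float, dr_cap: float = DEFAULT_DR_CAP
) -> np.ndarray:
    """Gamete dosage distribution under the two-parameter model.

    ``xi`` only enters for a duplex parent (``ell == 2``); it is accepted
    and ignored otherwise, mirroring the structure of the model.
    """
    ell = _validate_dosage(ell)
    alpha = _validate_unit(alpha, "alpha", hi=dr_cap)
    xi = _validate_unit(xi, "xi")
    if ell == 0:
        p = np.array([1.0, 0.0, 0.0])
    elif ell == 1:
        p = np.array([0.5 + alpha / 4, 0.5 - alpha / 2, alpha / 4])
    elif ell == 2:
        outer = alpha / 2 + (1 - alpha) * (1 - xi) / 4
        p = np.array([outer, (1 - alpha) * (1 + xi) / 2, outer])
    elif ell == 3:
        p = np.array([alpha / 4, 0.5 - alpha / 2, 0.5 + alpha / 4])
    else:
        p = np.array([0.0, 0.0, 1.0])
    return _clip_simplex(p)


def gamete_freq_3p(
    ell: int, tau: float, beta: float, gamma: float, dr_cap: float = DEFAULT_DR_CAP
) -> np.ndarray:
    """Gamete dosage distribution under the three-parameter model."""
    ell = _validate_dosage(ell)
    tau = _validate_unit(tau, "tau")
    beta = _validate_unit(beta, "beta", hi=dr_cap)
    gamma = _validate_unit(gamma, "gamma")
    bt = beta * tau
    if ell == 0:
        p = np.array([1.0, 0.0, 0.0])
    elif ell == 1:
        p = np.array([0.5 + bt / 4, 0.5 - bt / 2, bt / 4])
    elif ell == 2:
        outer = bt / 3 + tau / 6 + (1 - tau) * (1 - gamma) / 4
        mid = -2 * bt / 3 + 2 * tau / 3 + (1 - tau) * (1 + gamma) / 2
        p = np.array([outer, mid, outer])
    elif ell == 3:
        p = np.array([bt / 4, 0.5 - bt / 2, 0.5 + bt / 4])
    else:
        p = np.array([0.0, 0.0, 1.0])
    return _clip_simplex(p)


def map_3p_to_2p(params: MeiosisParams3) -> MeiosisParams2:
    """Reduce (tau, beta, gamma1, gamma2) to (alpha, xi1, xi2).

    alpha = beta * tau, and xi_j is chosen so the duplex gamete row of the
    two models coincides:

        xi_j = 1 - [(2/3) tau (1 - beta) + (1 - tau)(1 - gamma_j)]
                   / (1 - beta * tau).

    With ``beta <= dr_cap <= 1/6`` the denominator is bounded away from 0.
    """
    alpha = params.beta * params.tau
    denom = 1.0 - alpha

    def _xi(gamma: float) -> float:
        num = (2.0 / 3.0) * params.tau * (1.0 - params.beta)
        num += (1.0 - params.tau) * (1.0 - gamma)
        return 1.0 - num / denom

    return MeiosisParams2(
        alpha=alpha,
        xi1=_xi(params.gamma1),
        xi2=_xi(params.gamma2),
        dr_cap=params.dr_cap,
    )


def offspring_freq(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Convolve two parental gamete distributions into offspring genotype
    frequencies ``q`` over dosages 0..4 (each offspring dosage is the sum of
    two independent gamete dosages)."""
    p1 = _clip_simplex(np.asarray(p1, dtype=float))
    p2 = _clip_simplex(np.asarray(p2, dtype=float))
    return _clip_simplex(np.convolve(p1, p2))


def hypergeometric_gamete(ell: int, ploidy: int = 4) -> np.ndarray:
    """Gamete distribution of a strict-bivalent autopolyploid: dosages of a
    random half of the parent's ``ploidy`` chromosomes (hypergeometric)."""
    if ploidy % 2 != 0:
        raise ValueError("ploidy must be even")
    ell = _validate_dosage(ell, ploidy)
    k = np.arange(ploidy // 2 + 1)
    return _clip_simplex(hypergeom.pmf(k, ploidy, ell, ploidy // 2))


def xi_bounds(alpha: float, dr_cap: float = DEFAULT_DR_CAP) -> tuple[float, float]:
    """Feasible interval for the pairing parameter xi at a given double
    reduction rate.

    With maximum double-reduction rate ``c = dr_cap``:

        lo = (1/3) * (alpha / (1 - alpha)) * ((1 - c) / c),   hi = 1 - 2*lo.

    At alpha = c = 1/6 the interval collapses to {1/3}.
    """
    alpha = float(alpha)
    if dr_cap == 0.0:
        if alpha > 0:
            raise ValueError("alpha > 0 with a zero double-reduction cap")
        return (0.0, 1.0)
    if not 0.0 <= alpha <= dr_cap + 1e-12:
        raise ValueError(f"alpha must be in [0, {dr_cap}], got {alpha}")
    lo = (alpha / (1.0 - alpha)) * ((1.0 - dr_cap) / dr_cap) / 3.0
    hi = 1.0 - 2.0 * lo
    # collapse-point roundoff can leave lo marginally above hi
    if lo > hi:
        if lo - hi > 1e-9:
            raise ValueError(f"empty xi interval at alpha={alpha}, c={dr_cap}")
        lo = hi = (lo + hi) / 2.0
    return (lo, hi)


def possible_gamete_dosages(ell: int) -> frozenset[int]:
    """Gamete dosages reachable from a parent of dosage ``ell`` anywhere in
    the null parameter space (double reduction can produce dosage-2 gametes
    from a simplex parent, etc.)."""
    ell = _validate_dosage(ell)
    if ell == 0:
        return frozenset({0})
    if ell == 4:
        return frozenset({2})
    return frozenset({0, 1, 2})


def possible_offspring_genotypes(ell1: int, ell2: int) -> frozenset[int]:
    """Offspring dosages reachable under the null, i.e. the Minkowski sum of
    the two parents' reachable gamete dosage sets."""
    g1 = possible_gamete_dosages(ell1)
    g2 = possible_gamete_dosages(ell2)
    return frozenset(a + b for a in g1 for b in g2)
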