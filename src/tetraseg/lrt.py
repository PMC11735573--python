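"""Likelihood-ratio tests for segregation distortion.

The statistic is ``lambda = -2 (loglik_null - loglik_alt)`` where the null
maximizes over the meiosis model (double reduction + preferential pairing)
and the alternative over the whole 4-simplex of offspring genotype
frequencies.  Because the null parameters routinely sit on the boundary of
their box, a fixed chi-squared reference would be wrong; instead the test
uses a data-dependent degrees-of-freedom rule: the reference df is the
number of free parameters under the alternative minus the dimension of the
null manifold, with each null direction estimated on its boundary removed
from the count.

With known genotypes, any offspring genotype that is impossible under the
null for the given parental dosages (e.g. a triplex offspring from a
simplex x nullplex cross) yields an immediate p-value of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .gamete import DEFAULT_DR_CAP, possible_offspring_genotypes
from .likelihood import (
    NullFit,
    estimate_parents,
    loglik_counts,
    loglik_gl,
    mle_alt_counts,
    mle_alt_gl,
    mle_null,
    null_directions,
)

#: lambda values more negative than this indicate an optimizer failure
#: rather than roundoff; less negative ones are clipped to 0.
_STAT_CLIP = -1e-6

#: an EM frequency estimate below this counts as "estimated to be zero".
ZERO_QHAT_TOL = 1e-8

__all__ = ["LrtResult", "null_dimension", "lrt_counts", "lrt_gl",
           "lrt_gl_unknown_parents"]


@dataclass
class LrtResult:
    stat: float
    df: int
    p_value: float
    null_fit: NullFit | None
    alt_q: np.ndarray | None
    parents_used: tuple[int, int]
    method: str = "lrt"


def null_dimension(ells: tuple[int, int], boundary_flags: dict) -> int:
    """Dimension of the null manifold after removing boundary directions.

    The base dimension is the number of effective directions (shared
    double-reduction rate if any parent is simplex/triplex, plus one per
    duplex parent); each direction whose estimate landed on its boundary is
    subtracted, floored at zero.
    """
    dirs = null_directions(int(ells[0]), int(ells[1]))
    on_boundary = sum(bool(boundary_flags.get(d, False)) for d in dirs)
    return max(len(dirs) - on_boundary, 0)


def _pvalue(stat: float, df: int) -> float:
    if df == 0:
        # a zero-dimensional comparison: no evidence unless the statistic
        # is materially positive, in which case fall back to 1 df
        # (conservative).
        return 1.0 if stat <= 1e-8 else float(chi2.sf(stat, 1))
    return float(chi2.sf(stat, df))


def _clip_stat(stat: float) -> float:
    if stat < _STAT_CLIP:
        raise RuntimeError(f"negative likelihood-ratio statistic {stat}")
    return max(stat, 0.0)


def lrt_counts(x, ells: tuple[int, int], dr_cap: float = DEFAULT_DR_CAP) -> LrtResult:
    """LRT for known genotypes (a length-5 offspring dosage count vector)."""
    x = np.asarray(x, dtype=float)
    ells = (int(ells[0]), int(ells[1]))
    if x.sum() <= 0:
        raise ValueError("no observations")
    possible = possible_offspring_genotypes(*ells)
    observed = {k for k in range(5) if x[k] > 0}
    if not observed <= possible:
        # genotypes impossible under the null were observed
        return LrtResult(stat=np.inf, df=0, p_value=0.0, null_fit=None,
                         alt_q=mle_alt_counts(x), parents_used=ells)
    fit = mle_null(x, ells, dr_cap)
    q_alt = mle_alt_counts(x)
    stat = _clip_stat(2.0 * (loglik_counts(x, q_alt) - fit.loglik))
    alt_params = len(possible) - 1
    df = max(alt_params - null_dimension(ells, fit.boundary_flags), 0)
    return LrtResult(stat=stat, df=df, p_value=_pvalue(stat, df),
                     null_fit=fit, alt_q=q_alt, parents_used=ells)


def lrt_gl(log_g: np.ndarray, ells: tuple[int, int],
           dr_cap: float = DEFAULT_DR_CAP) -> LrtResult:
    """LRT for genotype-likelihood data (row-max-0 log GL matrix).

    The alternative parameter count is 4 minus the number of genotype
    categories that are both impossible under the null and estimated (by
    EM) to have zero frequency under the alternative.
    """
    ells = (int(ells[0]), int(ells[1]))
    fit = mle_null(log_g, ells, dr_cap)
    q_alt = mle_alt_gl(log_g)
    stat = _clip_stat(2.0 * (loglik_gl(log_g, q_alt) - fit.loglik))
    possible = possible_offspring_genotypes(*ells)
    impossible = set(range(5)) - possible
    n_zeroed = sum(1 for k in impossible if q_alt[k] <= ZERO_QHAT_TOL)
    alt_params = 4 - n_zeroed
    df = max(alt_params - null_dimension(ells, fit.boundary_flags), 0)
    return LrtResult(stat=stat, df=df, p_value=_pvalue(stat, df),
                     null_fit=fit, alt_q=q_alt, parents_used=ells)


def lrt_gl_unknown_parents(log_g: np.ndarray, a, b,
                           dr_cap: float = DEFAULT_DR_CAP) -> LrtResult:
    """Estimate parental dosages by maximum likelihood, then test as if
    they were known."""
    ells = estimate_parents(a, b, log_g, dr_cap)
    return lrt_gl(log_g, ells, dr_cap)
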