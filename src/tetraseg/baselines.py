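"""Competitor segregation-distortion tests.

Two baselines are provided for comparison with the model-based tests:

* the standard chi-squared test, which compares observed offspring dosage
  counts with the frequencies implied by strict polysomic inheritance with
  no double reduction (hypergeometric gametes) — anti-conservative
  whenever double reduction or preferential pairing is present;
* an approximate reimplementation of the checkF1-style test popularized by
  polymapR: every combination of fully polysomic / fully disomic
  segregation per parent is scored by the product of a chi-squared test on
  the "valid" genotypes and a one-sided binomial test of the "invalid"
  genotype count against a 3% ceiling, and the maximum product over
  patterns is reported.  Internal thresholds of the original software are
  not public, so this is faithful in spirit, not bit-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, chisquare

from .gamete import gamete_freq_2p, hypergeometric_gamete, offspring_freq

#: hard-coded ceiling on the expected proportion of invalid genotypes in
#: the checkF1-style binomial test
INVALID_GENOTYPE_RATE = 0.03

__all__ = ["BaselineResult", "chisq_test", "polymapr_like_test",
           "collapse_posteriors", "INVALID_GENOTYPE_RATE"]


@dataclass
class BaselineResult:
    p_value: float
    method: str
    details: dict = field(default_factory=dict)


def chisq_test(x, ells: tuple[int, int]) -> BaselineResult:
    """Pearson chi-squared test against no-double-reduction polysomic
    expectations; p = 0 when a zero-expectation category is occupied."""
    x = np.asarray(x, dtype=float)
    n = x.sum()
    if n <= 0:
        raise ValueError("no observations")
    q = offspring_freq(hypergeometric_gamete(int(ells[0])),
                       hypergeometric_gamete(int(ells[1])))
    pos = q > 0
    if np.any(x[~pos] > 0):
        return BaselineResult(p_value=0.0, method="chisq",
                              details={"expected": q,
                                       "invalid": float(x[~pos].sum())})
    if pos.sum() == 1:  # single possible category: nothing to test
        return BaselineResult(p_value=1.0, method="chisq",
                              details={"stat": 0.0, "expected": q, "df": 0})
    stat, p = chisquare(x[pos], n * q[pos] / q[pos].sum())
    return BaselineResult(p_value=float(p), method="chisq",
                          details={"stat": float(stat), "expected": q,
                                   "df": int(pos.sum() - 1)})


def collapse_posteriors(post: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """checkF1-style collapse of an ``n x 5`` genotype posterior matrix to
    a pseudo-count vector: sum posteriors per dosage, zero out sums below
    ``threshold`` (default ``0.1 * n * 0.01``), renormalize to n."""
    post = np.asarray(post, dtype=float)
    n = post.shape[0]
    if threshold is None:
        threshold = 0.1 * n * 0.01
    s = post.sum(axis=0)
    s[s < threshold] = 0.0
    if s.sum() <= 0:
        raise ValueError("all posterior mass removed by the collapse threshold")
    return s / s.sum() * n


def _pattern_gametes(ell: int) -> list[np.ndarray]:
    """Candidate segregation patterns for one parent: polysomic always;
    the two fully disomic alternatives when the parent is duplex (the only
    dosage where pairing changes the gamete law)."""
    if ell == 2:
        return [
            hypergeometric_gamete(2),            # polysomic 1:4:1
            gamete_freq_2p(2, 0.0, 0.0),         # disomic, unlike alleles pair
            gamete_freq_2p(2, 0.0, 1.0),         # disomic, like alleles pair
        ]
    return [hypergeometric_gamete(ell)]


def polymapr_like_test(
    data,
    ells: tuple[int, int],
    invalid_rate: float = INVALID_GENOTYPE_RATE,
    collapse_threshold: float | None = None,
) -> BaselineResult:
    """Approximate checkF1 segregation test.

    ``data`` is either a length-5 count vector or an ``n x 5`` genotype
    posterior matrix, which is first collapsed to pseudo-counts.  For each
    candidate disomic/polysomic pattern combination the score is
    ``p_chisq(valid counts) * p_binom(invalid count)`` and the reported
    p-value is the maximum score across patterns.
    """
    data = np.asarray(data, dtype=float)
    x = collapse_posteriors(data, collapse_threshold) if data.ndim == 2 else data
    n = x.sum()
    if n <= 0:
        raise ValueError("no observations")
    best = None
    for p1 in _pattern_gametes(int(ells[0])):
        for p2 in _pattern_gametes(int(ells[1])):
            q = offspring_freq(p1, p2)
            valid = q > 0
            n_invalid = float(x[~valid].sum())
            n_valid = float(x[valid].sum())
            if valid.sum() > 1 and n_valid > 0:
                _, p_chisq = chisquare(x[valid], n_valid * q[valid] / q[valid].sum())
            else:
                p_chisq = 1.0
            # one-sided: is the invalid count too large for a 3% rate?
            p_binom = float(binom.sf(np.ceil(n_invalid) - 1, int(round(n)),
                                     invalid_rate))
            score = float(p_chisq) * p_binom
            if best is None or score > best[0]:
                best = (score, q, n_invalid, float(p_chisq), p_binom)
    score, q, n_invalid, p_chisq, p_binom = best
    return BaselineResult(
        p_value=score,
        method="polymapr_like",
        details={"best_pattern_q": q, "invalid": n_invalid,
                 "p_chisq": p_chisq, "p_binom": p_binom},
    )
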