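"""Bayes-factor tests for segregation distortion.

The Bayes factor is the ratio of marginal likelihoods, null over
alternative, so **positive log BF favours no distortion**:

    BF = Pr(data | meiosis model) / Pr(data | free q).

Under the null the data likelihood is integrated over priors on the
meiosis parameters (quadrivalent rate ``tau`` uniform; double-reduction
rate given a quadrivalent ``beta`` uniform on [0, c]; pairing parameter
``gamma_j`` Beta(5/9, 10/9), which has mean 1/3 — the tetrasomic value —
and the variance of a uniform).  Under the alternative the offspring
frequency vector ``q`` gets a Dirichlet prior, by default the Jeffreys-type
Dirichlet(1/2,...,1/2); for known genotypes this marginal is the closed-form
Dirichlet-multinomial.

Integrals without closed form are estimated by plain Monte Carlo over
prior draws with log-sum-exp pooling — the active parameter space is at
most 4-dimensional and bounded, so prior sampling is adequate — and every
estimate carries a delta-method Monte-Carlo standard error.

A common working threshold reported alongside results: log BF below -16 is
very strong evidence of distortion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .gamete import DEFAULT_DR_CAP
from .likelihood import (
    _active_params,
    _q_from_theta,
    estimate_parents,
    loglik_counts,
    loglik_gl,
)

#: documented guidance level for "strong evidence of distortion" summaries
STRONG_DISTORTION_LOG_BF = -16.0

DEFAULT_DRAWS = 50_000
_CHUNK = 4096  # GL-likelihood draws evaluated per block to bound memory

__all__ = [
    "NullPrior",
    "AltPrior",
    "BayesResult",
    "log_marginal_alt_counts",
    "log_marginal_alt_gl",
    "log_marginal_null",
    "bayes_test",
    "STRONG_DISTORTION_LOG_BF",
]


@dataclass(frozen=True)
class NullPrior:
    """Priors over the meiosis-model parameters (all user-overridable).

    ``gamma_a``/``gamma_b`` are the Beta shape parameters of the pairing
    prior, shared by both parents.
    """

    dr_cap: float = DEFAULT_DR_CAP
    gamma_a: float = 5.0 / 9.0
    gamma_b: float = 10.0 / 9.0

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        return {
            "tau": rng.uniform(0.0, 1.0, n),
            "beta": rng.uniform(0.0, self.dr_cap, n),
            "gamma1": rng.beta(self.gamma_a, self.gamma_b, n),
            "gamma2": rng.beta(self.gamma_a, self.gamma_b, n),
        }


@dataclass(frozen=True)
class AltPrior:
    """Dirichlet prior over the free offspring-frequency vector."""

    concentration: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5, 0.5)

    def __post_init__(self):
        conc = np.asarray(self.concentration, dtype=float)
        if conc.shape != (5,) or np.any(conc <= 0):
            raise ValueError("concentration must be 5 positive reals")


@dataclass
class BayesResult:
    log_bf: float
    mc_se: float
    draws: int
    parents_used: tuple[int, int]
    details: dict = field(default_factory=dict)
    method: str = "bayes"


def log_marginal_alt_counts(x, prior: AltPrior = AltPrior()) -> float:
    """Closed-form Dirichlet-multinomial log marginal for known genotypes."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(prior.concentration, dtype=float)
    n, A = x.sum(), a.sum()
    coef = gammaln(n + 1.0) - gammaln(x + 1.0).sum()
    return float(coef + gammaln(A) - gammaln(n + A)
                 + (gammaln(x + a) - gammaln(a)).sum())


def _pool(loglik_draws: np.ndarray) -> tuple[float, float]:
    """Log of the mean of exp(loglik_draws), with delta-method SE."""
    n = loglik_draws.size
    finite = loglik_draws[np.isfinite(loglik_draws)]
    if finite.size == 0:
        warnings.warn("zero likelihood at every prior draw; marginal is -inf")
        return -np.inf, np.inf
    a = finite.max()
    w = np.exp(loglik_draws - a, where=np.isfinite(loglik_draws),
               out=np.zeros_like(loglik_draws))
    m = w.sum() / n
    se = float(w.std(ddof=1) / (m * np.sqrt(n))) if n > 1 else np.inf
    return float(a + np.log(m)), se


def _q_draws_fast(theta: dict[str, np.ndarray], ells, dr_cap: float) -> np.ndarray:
    """Vectorized offspring frequencies for prior draws (no per-draw Python
    loop); algebraically identical to the scalar model."""
    tau, beta = theta["tau"], theta["beta"]
    bt = beta * tau

    def gam_rows(ell: int, gamma: np.ndarray) -> np.ndarray:
        n = len(tau)
        if ell == 0:
            p = np.zeros((n, 3)); p[:, 0] = 1.0
        elif ell == 1:
            p = np.stack([0.5 + bt / 4, 0.5 - bt / 2, bt / 4], axis=1)
        elif ell == 2:
            outer = bt / 3 + tau / 6 + (1 - tau) * (1 - gamma) / 4
            mid = -2 * bt / 3 + 2 * tau / 3 + (1 - tau) * (1 + gamma) / 2
            p = np.stack([outer, mid, outer], axis=1)
        elif ell == 3:
            p = np.stack([bt / 4, 0.5 - bt / 2, 0.5 + bt / 4], axis=1)
        else:
            p = np.zeros((n, 3)); p[:, 2] = 1.0
        return p

    p1 = gam_rows(int(ells[0]), theta["gamma1"])
    p2 = gam_rows(int(ells[1]), theta["gamma2"])
    q = np.empty((len(tau), 5))
    q[:, 0] = p1[:, 0] * p2[:, 0]
    q[:, 1] = p1[:, 0] * p2[:, 1] + p1[:, 1] * p2[:, 0]
    q[:, 2] = p1[:, 0] * p2[:, 2] + p1[:, 1] * p2[:, 1] + p1[:, 2] * p2[:, 0]
    q[:, 3] = p1[:, 1] * p2[:, 2] + p1[:, 2] * p2[:, 1]
    q[:, 4] = p1[:, 2] * p2[:, 2]
    return np.clip(q, 0.0, 1.0)


def _loglik_draws(data: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Log-likelihood of the data at each of many q vectors."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.log(qs)
    if data.ndim == 1:  # counts
        x = data
        coef = gammaln(x.sum() + 1.0) - gammaln(x + 1.0).sum()
        contrib = np.where(x[None, :] > 0, logq, 0.0) * x[None, :]
        ll = coef + contrib.sum(axis=1)
        ll[np.any((x[None, :] > 0) & (qs <= 0), axis=1)] = -np.inf
        return ll
    out = np.empty(qs.shape[0])
    for start in range(0, qs.shape[0], _CHUNK):
        block = logq[start:start + _CHUNK]  # (b, 5)
        per = logsumexp(data[None, :, :] + block[:, None, :], axis=2)
        out[start:start + _CHUNK] = per.sum(axis=1)
    return out


def log_marginal_null(
    data,
    ells: tuple[int, int],
    prior: NullPrior = NullPrior(),
    n_draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate (and SE) of the null marginal likelihood.

    Integration runs only over the parameters active for the given
    parental dosages; with no active parameter the marginal is the exact
    likelihood at the fixed null point (SE 0).
    """
    data = np.asarray(data, dtype=float)
    ells = (int(ells[0]), int(ells[1]))
    active = _active_params(*ells)
    if not active:
        theta = {"tau": 0.0, "beta": 0.0, "gamma1": 1 / 3, "gamma2": 1 / 3}
        q = _q_from_theta(theta, *ells, prior.dr_cap)
        ll = loglik_counts(data, q) if data.ndim == 1 else loglik_gl(data, q)
        return float(ll), 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = prior.sample(n_draws, rng)
    qs = _q_draws_fast(theta, ells, prior.dr_cap)
    return _pool(_loglik_draws(data, qs))


def log_marginal_alt_gl(
    log_g: np.ndarray,
    prior: AltPrior = AltPrior(),
    n_draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate (and SE) of the alternative marginal for
    genotype-likelihood data, averaging over Dirichlet prior draws."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qs = rng.dirichlet(np.asarray(prior.concentration, dtype=float), size=n_draws)
    return _pool(_loglik_draws(np.asarray(log_g, dtype=float), qs))


def bayes_test(
    data,
    ells: tuple[int, int] | None = None,
    parent_liks: tuple | None = None,
    null_prior: NullPrior = NullPrior(),
    alt_prior: AltPrior = AltPrior(),
    n_draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = 0,
) -> BayesResult:
    """Bayes-factor test of no segregation distortion.

    Provide either known parental dosages ``ells`` or parent
    genotype-likelihood vectors ``parent_liks=(a, b)`` (dosages are then
    estimated by maximum likelihood first, and the test run as if known).
    Counts data use the closed-form Dirichlet-multinomial alternative
    marginal; GL data use Monte Carlo for both marginals.
    """
    data = np.asarray(data, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ells is None:
        if parent_liks is None:
            raise ValueError("need parental dosages or parent likelihoods")
        if data.ndim != 2:
            raise ValueError("parent estimation requires GL offspring data")
        ells = estimate_parents(parent_liks[0], parent_liks[1], data,
                                null_prior.dr_cap)
    ells = (int(ells[0]), int(ells[1]))

    lm0, se0 = log_marginal_null(data, ells, null_prior, n_draws, rng)
    if data.ndim == 1:
        lm1, se1 = log_marginal_alt_counts(data, alt_prior), 0.0
    else:
        lm1, se1 = log_marginal_alt_gl(data, alt_prior, n_draws, rng)
    return BayesResult(
        log_bf=lm0 - lm1,
        mc_se=float(np.hypot(se0, se1)),
        draws=n_draws,
        parents_used=ells,
        details={"log_marginal_null": lm0, "log_marginal_alt": lm1},
    )
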