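"""Likelihoods and maximum-likelihood fits for F1 tetraploid genotype data.

Two data representations are supported throughout:

* **known genotypes** — a length-5 vector of offspring counts per dosage,
  modelled as multinomial given the offspring genotype frequencies ``q``;
* **genotype likelihoods** — an ``n x 5`` matrix ``G`` where ``G[i, k]`` is
  the probability of individual *i*'s read data given dosage ``k``; the
  marginal likelihood of the data is then ``prod_i sum_k G[i, k] q_k``.

The null hypothesis of no segregation distortion constrains ``q`` to the
image of the meiosis model: ``q = p1 * p2`` (convolution) with each parental
gamete distribution given by the three-parameter model of
:mod:`tetraseg.gamete` at the parental dosages.  The null fit maximizes the
likelihood over ``(tau, beta, gamma1, gamma2)`` by bounded quasi-Newton
ascent with multistart, and reports boundary attainment along the
*effective* directions of the null manifold (the shared double-reduction
rate, and one free direction per duplex parent), which is what the
degrees-of-freedom rule of :mod:`tetraseg.lrt` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, xlogy

from .gamete import (
    DEFAULT_DR_CAP,
    MeiosisParams3,
    gamete_freq_3p,
    offspring_freq,
    xi_bounds,
)

#: A parameter is "on the boundary" if within this distance of its limit.
BOUNDARY_TOL = 1e-4

#: EM convergence: relative log-likelihood change below this, or max iters.
EM_RTOL = 1e-10
EM_MAX_ITER = 2000

#: Number of deterministic pseudo-random optimizer restarts (plus the one
#: canonical start).
N_RESTARTS = 4

__all__ = [
    "NullFit",
    "loglik_counts",
    "loglik_gl",
    "normalize_gl",
    "counts_to_gl",
    "mle_alt_counts",
    "mle_alt_gl",
    "mle_null",
    "estimate_parents",
]


def _as_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (5,):
        raise ValueError("genotype counts must be a length-5 vector")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("genotype counts must be non-negative integers")
    return x.astype(float)


def loglik_counts(x, q) -> float:
    """Multinomial log-likelihood of dosage counts ``x`` given frequencies
    ``q``, including the multinomial coefficient.  Returns ``-inf`` when a
    positive count falls in a zero-frequency category."""
    x = _as_counts(x)
    q = np.asarray(q, dtype=float)
    if np.any((x > 0) & (q <= 0.0)):
        return -np.inf
    n = x.sum()
    coef = gammaln(n + 1.0) - gammaln(x + 1.0).sum()
    return float(coef + xlogy(x, q).sum())


def normalize_gl(G) -> np.ndarray:
    """Validate an ``n x 5`` genotype-likelihood matrix and return it on the
    log scale with each row shifted to max 0 (likelihoods are scale-free per
    individual, so this only guards against underflow)."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] != 5:
        raise ValueError("genotype-likelihood matrix must have shape (n, 5)")
    if np.any(G < 0) or not np.all(np.isfinite(G)):
        raise ValueError("genotype likelihoods must be finite and >= 0")
    rowmax = G.max(axis=1)
    if np.any(rowmax <= 0):
        raise ValueError("each individual needs a positive likelihood somewhere")
    with np.errstate(divide="ignore"):
        return np.log(G / rowmax[:, None])


def counts_to_gl(x) -> np.ndarray:
    """Represent known genotype counts as an indicator-row GL matrix."""
    x = _as_counts(x).astype(int)
    rows = np.repeat(np.eye(5), x, axis=0)
    return normalize_gl(rows)


def loglik_gl(log_g: np.ndarray, q) -> float:
    """Log-likelihood ``sum_i log sum_k exp(log_g[i,k]) q_k``, stabilized
    with log-sum-exp.  ``log_g`` is a row-max-0 log GL matrix."""
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        logq = np.log(q)
    per_ind = logsumexp(log_g + logq[None, :], axis=1)
    return float(per_ind.sum())


def mle_alt_counts(x) -> np.ndarray:
    """Unconstrained MLE of ``q`` from known genotypes: ``x / n``."""
    x = _as_counts(x)
    n = x.sum()
    if n == 0:
        raise ValueError("no observations")
    return x / n


def mle_alt_gl(log_g: np.ndarray, *, return_path: bool = False):
    """Unconstrained MLE of ``q`` from genotype likelihoods via EM.

    Update: ``q_k <- mean_i g_ik q_k / sum_l g_il q_l`` from a uniform
    start; the log-likelihood is non-decreasing across iterations.  With
    ``return_path`` the per-iteration log-likelihoods are also returned
    (used by tests to assert monotonicity).
    """
    g = np.exp(log_g)
    n = g.shape[0]
    q = np.full(5, 0.2)
    ll = loglik_gl(log_g, q)
    path = [ll]
    for _ in range(EM_MAX_ITER):
        w = g * q[None, :]
        w /= w.sum(axis=1, keepdims=True)
        q = w.sum(axis=0) / n
        ll_new = loglik_gl(log_g, q)
        path.append(ll_new)
        if abs(ll_new - ll) <= EM_RTOL * max(1.0, abs(ll_new)):
            break
        ll = ll_new
    return (q, path) if return_path else q


# ---------------------------------------------------------------------------
# Constrained (null) maximum likelihood
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("tau", "beta", "gamma1", "gamma2")
_CANONICAL = {"tau": 0.5, "beta": None, "gamma1": 1.0 / 3.0, "gamma2": 1.0 / 3.0}


@dataclass
class NullFit:
    """Result of maximizing the likelihood over the meiosis-model null."""

    params: MeiosisParams3
    q0hat: np.ndarray
    loglik: float
    #: boundary attainment per *effective* null-manifold direction, keyed
    #: "alpha", "p1_1", "p1_2" (only the directions active for the parental
    #: dosage pair appear).
    boundary_flags: dict = field(default_factory=dict)

    @property
    def alpha_hat(self) -> float:
        """Fitted double reduction rate (beta * tau).  Single-locus
        estimates of this quantity are biased and highly variable; do not
        treat them as trustworthy point estimates."""
        return self.params.beta * self.params.tau


def _active_params(ell1: int, ell2: int) -> list[str]:
    active = []
    if ell1 in (1, 2, 3) or ell2 in (1, 2, 3):
        active += ["tau", "beta"]
    if ell1 == 2:
        active.append("gamma1")
    if ell2 == 2:
        active.append("gamma2")
    return active


def null_directions(ell1: int, ell2: int) -> list[str]:
    """Effective directions of the null manifold in offspring-frequency
    space: a shared double-reduction direction whenever a simplex or
    triplex parent is present, plus one free heterozygote-frequency
    direction per duplex parent."""
    dirs = []
    if ell1 in (1, 3) or ell2 in (1, 3):
        dirs.append("alpha")
    if ell1 == 2:
        dirs.append("p1_1")
    if ell2 == 2:
        dirs.append("p1_2")
    return dirs


def _q_from_theta(theta: dict, ell1: int, ell2: int, dr_cap: float) -> np.ndarray:
    p1 = gamete_freq_3p(ell1, theta["tau"], theta["beta"], theta["gamma1"], dr_cap)
    p2 = gamete_freq_3p(ell2, theta["tau"], theta["beta"], theta["gamma2"], dr_cap)
    return offspring_freq(p1, p2)


def _boundary_flags(theta: dict, ell1: int, ell2: int, dr_cap: float) -> dict:
    dirs = null_directions(ell1, ell2)
    flags = {}
    alpha = theta["beta"] * theta["tau"]
    if "alpha" in dirs:
        flags["alpha"] = alpha <= BOUNDARY_TOL or alpha >= dr_cap - BOUNDARY_TOL
    for name, ell, gamma in (
        ("p1_1", ell1, theta["gamma1"]),
        ("p1_2", ell2, theta["gamma2"]),
    ):
        if name not in dirs:
            continue
        p1 = gamete_freq_3p(2, theta["tau"], theta["beta"], gamma, dr_cap)[1]
        if "alpha" in dirs:
            # another parent pins alpha, so the duplex heterozygote
            # frequency moves within its alpha-conditional interval
            lo_xi, hi_xi = xi_bounds(min(alpha, dr_cap), dr_cap)
            lo = (1 - alpha) * (1 + lo_xi) / 2
            hi = (1 - alpha) * (1 + hi_xi) / 2
        else:
            lo, hi = 0.5, 1.0
        flags[name] = p1 <= lo + BOUNDARY_TOL or p1 >= hi - BOUNDARY_TOL
    return flags


def mle_null(
    data,
    ells: tuple[int, int],
    dr_cap: float = DEFAULT_DR_CAP,
) -> NullFit:
    """Maximize the likelihood over the meiosis-model null.

    ``data`` is either a length-5 count vector (known genotypes) or an
    ``n x 5`` log-scale GL matrix as produced by :func:`normalize_gl`.
    Only parameters that can affect the likelihood for the given parental
    dosages are optimized; the rest are frozen.  Five deterministic starts
    (one canonical, four pseudo-random from a fixed seed) guard against the
    ridges created by the model's non-identifiability.
    """
    ell1, ell2 = int(ells[0]), int(ells[1])
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        objective = lambda q: loglik_counts(data, q)  # noqa: E731
    else:
        objective = lambda q: loglik_gl(data, q)  # noqa: E731

    active = _active_params(ell1, ell2)
    frozen = {"tau": 0.0, "beta": 0.0, "gamma1": 1.0 / 3.0, "gamma2": 1.0 / 3.0}

    if not active:  # both parents homozygous: the null is a single point
        theta = dict(frozen)
        q0 = _q_from_theta(theta, ell1, ell2, dr_cap)
        params = MeiosisParams3(theta["tau"], theta["beta"], theta["gamma1"],
                                theta["gamma2"], dr_cap)
        return NullFit(params=params, q0hat=q0, loglik=objective(q0),
                       boundary_flags={})

    bounds = [(0.0, dr_cap) if name == "beta" else (0.0, 1.0) for name in active]

    def neg_ll(vec: np.ndarray) -> float:
        theta = dict(frozen)
        theta.update(zip(active, np.clip(vec, [b[0] for b in bounds],
                                         [b[1] for b in bounds])))
        q = _q_from_theta(theta, ell1, ell2, dr_cap)
        ll = objective(q)
        return 1e12 if not np.isfinite(ll) else -ll

    starts = [np.array([_CANONICAL[name] if _CANONICAL[name] is not None
                        else dr_cap / 2 for name in active])]
    rng = np.random.default_rng(0)
    for _ in range(N_RESTARTS):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    for x0 in starts:
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("null-model optimization failed for all restarts")

    theta = dict(frozen)
    theta.update(zip(active, np.clip(best.x, [b[0] for b in bounds],
                                     [b[1] for b in bounds])))
    q0 = _q_from_theta(theta, ell1, ell2, dr_cap)
    params = MeiosisParams3(theta["tau"], theta["beta"], theta["gamma1"],
                            theta["gamma2"], dr_cap)
    return NullFit(
        params=params,
        q0hat=q0,
        loglik=objective(q0),
        boundary_flags=_boundary_flags(theta, ell1, ell2, dr_cap),
    )


def estimate_parents(
    a,
    b,
    log_g: np.ndarray,
    dr_cap: float = DEFAULT_DR_CAP,
) -> tuple[int, int]:
    """Maximum-likelihood parental dosages from parent genotype-likelihood
    vectors ``a``, ``b`` and the offspring GL matrix.

    Exhaustively scores all 25 dosage pairs by
    ``a[l1] * b[l2] * max_params f(G | q(., l1, l2))`` and returns the
    argmax; ties break to the lexicographically smallest pair.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (5,) or b.shape != (5,):
        raise ValueError("parent likelihood vectors must have length 5")
    if np.any(a < 0) or np.any(b < 0) or a.max() <= 0 or b.max() <= 0:
        raise ValueError("parent likelihoods must be non-negative with a "
                         "positive entry")
    a = a / a.max()
    b = b / b.max()
    best_pair, best_score = None, -np.inf
    for ell1 in range(5):
        if a[ell1] == 0:
            continue
        for ell2 in range(5):
            if b[ell2] == 0:
                continue
            fit = mle_null(log_g, (ell1, ell2), dr_cap)
            score = np.log(a[ell1]) + np.log(b[ell2]) + fit.loglik
            if score > best_score + 1e-9:
                best_pair, best_score = (ell1, ell2), score
    return best_pair
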