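"""Synthetic F1 tetraploid data and the null/alternative simulation studies.

The generator mirrors the evaluation design the tests are meant for:

* offspring genotypes are multinomial draws from the meiosis model (null
  scenarios: parental dosages plus a shared double-reduction rate and
  per-parent pairing parameters) or from an arbitrary distorted frequency
  vector ``q`` (alternative scenarios);
* sequencing data are emulated by a beta-binomial read-count model at a
  fixed per-individual depth (default 10 reads) with sequencing error
  0.01, overdispersion 0.01 and no allele bias; genotype likelihoods are
  the exact beta-binomial masses of the simulated counts under each
  candidate dosage.

``run_null_study`` / ``run_alt_study`` drive the factorial experiments
(200 replicates per cell by default) and emit tidy long-format tables;
``roc_summary`` pools them into ROC curves per method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import betabinom

from .baselines import chisq_test, polymapr_like_test
from .bayes import bayes_test
from .gamete import (
    DEFAULT_DR_CAP,
    MeiosisParams2,
    gamete_freq_2p,
    offspring_freq,
    xi_bounds,
)
from .likelihood import counts_to_gl, normalize_gl
from .lrt import lrt_counts, lrt_gl

__all__ = [
    "ReadModel",
    "SimScenario",
    "sim_offspring_genotypes",
    "sim_genotype_likelihoods",
    "gl_to_posteriors",
    "posterior_mode_counts",
    "alternative_q_menu",
    "sample_simplex_q",
    "run_null_study",
    "run_alt_study",
    "roc_summary",
]


@dataclass(frozen=True)
class ReadModel:
    """Beta-binomial sequencing model for one individual's reads."""

    depth: int = 10
    seq_error: float = 0.01
    overdispersion: float = 0.01
    bias: float = 1.0

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 <= self.seq_error < 1 and 0 <= self.overdispersion < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.bias <= 0:
            raise ValueError("bias must be positive")

    def allele_fraction(self, dosage: int) -> float:
        """Expected alternative-read fraction for a dosage, after
        sequencing error and allele bias."""
        p = dosage / 4.0
        f = p * (1.0 - self.seq_error) + (1.0 - p) * self.seq_error
        return f / (f + self.bias * (1.0 - f))


@dataclass(frozen=True)
class SimScenario:
    """One simulation cell: either a null (parental dosages + meiosis
    parameters) or an alternative (explicit ``q``).  ``depth=None`` means
    known genotypes (infinite depth)."""

    n: int
    ells: tuple[int, int] | None = None
    alpha: float = 0.0
    xi1: float = 1.0 / 3.0
    xi2: float = 1.0 / 3.0
    q: tuple[float, ...] | None = None
    depth: int | None = None
    dr_cap: float = DEFAULT_DR_CAP

    def true_q(self) -> np.ndarray:
        if self.q is not None:
            q = np.asarray(self.q, dtype=float)
            if q.shape != (5,) or abs(q.sum() - 1) > 1e-9 or np.any(q < 0):
                raise ValueError(f"invalid offspring frequency vector {q}")
            return q
        if self.ells is None:
            raise ValueError("scenario needs parental dosages or explicit q")
        MeiosisParams2(self.alpha, self.xi1, self.xi2, self.dr_cap)  # validate
        p1 = gamete_freq_2p(self.ells[0], self.alpha, self.xi1, self.dr_cap)
        p2 = gamete_freq_2p(self.ells[1], self.alpha, self.xi2, self.dr_cap)
        return offspring_freq(p1, p2)


def sim_offspring_genotypes(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw offspring dosages: returns (count vector, per-individual
    dosage array)."""
    q = scenario.true_q()
    counts = rng.multinomial(scenario.n, q)
    dosages = np.repeat(np.arange(5), counts)
    return counts, dosages


def sim_genotype_likelihoods(
    dosages: np.ndarray,
    model: ReadModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate read counts and return the row-max-0 log GL matrix.

    Each individual's alternative-read count is beta-binomial around the
    dosage-implied allele fraction; the genotype likelihood under each
    candidate dosage is the beta-binomial mass of that count.
    """
    dosages = np.asarray(dosages, dtype=int)
    n = dosages.size
    if model.depth == 0:
        warnings.warn("zero read depth: genotype likelihoods are uniform")
        return normalize_gl(np.ones((n, 5)))
    f = np.array([model.allele_fraction(k) for k in range(5)])
    rho = model.overdispersion

    def _draw(fk: float, size: int) -> np.ndarray:
        if rho == 0:
            return rng.binomial(model.depth, fk, size)
        a = fk * (1 - rho) / rho
        b = (1 - fk) * (1 - rho) / rho
        return rng.binomial(model.depth, rng.beta(a, b, size))

    y = np.empty(n, dtype=int)
    for k in range(5):
        mask = dosages == k
        if mask.any():
            y[mask] = _draw(f[k], int(mask.sum()))

    G = np.empty((n, 5))
    for k in range(5):
        if rho == 0:
            from scipy.stats import binom as _binom
            G[:, k] = _binom.pmf(y, model.depth, f[k])
        else:
            a = f[k] * (1 - rho) / rho
            b = (1 - f[k]) * (1 - rho) / rho
            G[:, k] = betabinom.pmf(y, model.depth, a, b)
    return normalize_gl(G)


def gl_to_posteriors(log_g: np.ndarray) -> np.ndarray:
    """Genotype posteriors under a uniform dosage prior."""
    g = np.exp(log_g - log_g.max(axis=1, keepdims=True))
    return g / g.sum(axis=1, keepdims=True)


def posterior_mode_counts(log_g: np.ndarray) -> np.ndarray:
    """Dosage counts from per-individual posterior-mode genotypes (uniform
    prior); what the plain chi-squared baseline consumes at finite depth."""
    modes = np.argmax(log_g, axis=1)
    return np.bincount(modes, minlength=5).astype(float)


def alternative_q_menu() -> list[np.ndarray]:
    """The fixed menu of 14 distorted offspring-frequency vectors used by
    the alternative study (use :func:`sample_simplex_q` for random ones)."""
    menu = [
        (1 / 5, 1 / 5, 1 / 5, 1 / 5, 1 / 5),
        (1 / 4, 1 / 4, 1 / 4, 1 / 4, 0),
        (4 / 10, 3 / 10, 2 / 10, 1 / 10, 0),
        (1 / 10, 2 / 10, 3 / 10, 4 / 10, 0),
        (1 / 3, 1 / 3, 1 / 3, 0, 0),
        (0, 1 / 3, 1 / 3, 1 / 3, 0),
        (3 / 6, 2 / 6, 1 / 6, 0, 0),
        (0, 3 / 6, 2 / 6, 1 / 6, 0),
        (1 / 6, 2 / 6, 3 / 6, 0, 0),
        (0, 1 / 6, 2 / 6, 3 / 6, 0),
        (3 / 4, 1 / 4, 0, 0, 0),
        (1 / 4, 3 / 4, 0, 0, 0),
        (0, 3 / 4, 1 / 4, 0, 0),
        (0, 1 / 4, 3 / 4, 0, 0),
    ]
    return [np.asarray(q, dtype=float) for q in menu]


def sample_simplex_q(rng: np.random.Generator) -> np.ndarray:
    """One offspring-frequency vector uniform on the 4-simplex."""
    return rng.dirichlet(np.ones(5))


def default_null_grid(
    n_list=(20, 200), alpha_list=(0.0, 1 / 12, 1 / 6),
    depth_list=(10, None), dr_cap: float = DEFAULT_DR_CAP,
) -> list[SimScenario]:
    """The factorial null grid: parental dosage pairs {(0,1),(0,2),(1,1),
    (1,2),(2,2)}, with the pairing parameter varied over {lower bound, 1/3,
    upper bound} only for duplex parents."""
    ells_list = [(0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    scenarios = []
    for ells, n, alpha, depth in product(ells_list, n_list, alpha_list, depth_list):
        lo, hi = xi_bounds(alpha, dr_cap)
        xi_menu = sorted({round(v, 12) for v in (lo, 1 / 3, hi)})
        xi1_opts = xi_menu if ells[0] == 2 else [1 / 3]
        xi2_opts = xi_menu if ells[1] == 2 else [1 / 3]
        for xi1, xi2 in product(xi1_opts, xi2_opts):
            scenarios.append(SimScenario(n=n, ells=ells, alpha=alpha,
                                         xi1=xi1, xi2=xi2, depth=depth,
                                         dr_cap=dr_cap))
    return scenarios


def _run_methods(
    counts, dosages, scenario, methods, rng, ells_for_tests,
    bayes_draws: int,
) -> list[dict]:
    """Apply the requested tests to one simulated replicate."""
    rows = []
    if scenario.depth is None:
        log_g = None
    else:
        log_g = sim_genotype_likelihoods(
            dosages, ReadModel(depth=scenario.depth), rng)
    for method in methods:
        row = {"method": method}
        if method == "lrt":
            if log_g is None:
                res = lrt_counts(counts, ells_for_tests, scenario.dr_cap)
            else:
                res = lrt_gl(log_g, ells_for_tests, scenario.dr_cap)
            row.update(p_value=res.p_value, stat=res.stat, df=res.df)
        elif method == "bayes":
            data = counts if log_g is None else log_g
            res = bayes_test(data, ells=ells_for_tests, n_draws=bayes_draws,
                             seed=rng)
            row.update(log_bf=res.log_bf, mc_se=res.mc_se)
        elif method == "chisq":
            x = counts if log_g is None else posterior_mode_counts(log_g)
            row.update(p_value=chisq_test(x, ells_for_tests).p_value)
        elif method == "polymapr_like":
            data = counts if log_g is None else gl_to_posteriors(log_g)
            row.update(p_value=polymapr_like_test(data, ells_for_tests).p_value)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(row)
    return rows


def run_null_study(
    grid: list[SimScenario] | None = None,
    reps: int = 200,
    methods=("lrt", "bayes", "chisq", "polymapr_like"),
    seed: int = 0,
    bayes_draws: int = 10_000,
) -> pd.DataFrame:
    """Replicate the null experiments; one row per replicate x method."""
    if grid is None:
        grid = default_null_grid()
    rng = np.random.default_rng(seed)
    records = []
    for s_idx, scen in enumerate(grid):
        for rep in range(reps):
            counts, dosages = sim_offspring_genotypes(scen, rng)
            for row in _run_methods(counts, dosages, scen, methods, rng,
                                    scen.ells, bayes_draws):
                row.update(scenario=s_idx, rep=rep, n=scen.n,
                           ell1=scen.ells[0], ell2=scen.ells[1],
                           alpha=scen.alpha, xi1=scen.xi1, xi2=scen.xi2,
                           depth=scen.depth, truth="null")
                records.append(row)
    return pd.DataFrame.from_records(records)


def run_alt_study(
    q_list=None,
    n_list=(20, 200),
    depth_list=(10, None),
    reps: int = 200,
    methods=("lrt", "bayes", "chisq", "polymapr_like"),
    seed: int = 0,
    bayes_draws: int = 10_000,
) -> pd.DataFrame:
    """Replicate the alternative (distortion) experiments.

    Parental dosages are unknown here; each replicate estimates them by
    maximum likelihood (uniform parent likelihoods) before testing, as a
    practitioner without parent data would.
    """
    from .likelihood import estimate_parents

    if q_list is None:
        q_list = alternative_q_menu()
    rng = np.random.default_rng(seed)
    uniform_parent = np.ones(5)
    records = []
    for q_idx, q in enumerate(q_list):
        for n, depth in product(n_list, depth_list):
            scen = SimScenario(n=n, q=tuple(np.asarray(q, float)), depth=depth)
            for rep in range(reps):
                counts, dosages = sim_offspring_genotypes(scen, rng)
                if depth is None:
                    log_g = counts_to_gl(counts)
                else:
                    log_g = sim_genotype_likelihoods(
                        dosages, ReadModel(depth=depth), rng)
                ells = estimate_parents(uniform_parent, uniform_parent,
                                        log_g, scen.dr_cap)
                for row in _run_methods(counts, dosages, scen, methods, rng,
                                        ells, bayes_draws):
                    row.update(scenario=q_idx, rep=rep, n=n, depth=depth,
                               ell1=ells[0], ell2=ells[1], truth="alt")
                    records.append(row)
    return pd.DataFrame.from_records(records)


def _scores(table: pd.DataFrame) -> pd.Series:
    """Evidence-of-distortion score, larger = more distorted: -log BF for
    the Bayes test, 1 - p for the frequentist tests."""
    score = pd.Series(np.nan, index=table.index)
    is_bayes = table["method"] == "bayes"
    if "log_bf" in table:
        score[is_bayes] = -table.loc[is_bayes, "log_bf"]
    if "p_value" in table:
        score[~is_bayes] = 1.0 - table.loc[~is_bayes, "p_value"]
    return score


def roc_summary(
    null_table: pd.DataFrame,
    alt_table: pd.DataFrame,
    fpr_grid=None,
) -> pd.DataFrame:
    """Pool null and alternative tables into per-method ROC curves.

    Returns a tidy frame (method, fpr, tpr); with ``fpr_grid`` the curve
    is evaluated at the requested false-positive rates, otherwise at every
    achievable threshold.
    """
    if null_table.empty or alt_table.empty:
        raise ValueError("need non-empty null and alternative tables")
    out = []
    for method in sorted(set(null_table["method"]) & set(alt_table["method"])):
        s0 = _scores(null_table[null_table["method"] == method]).to_numpy()
        s1 = _scores(alt_table[alt_table["method"] == method]).to_numpy()
        thresholds = np.unique(np.concatenate([s0, s1, [np.inf]]))[::-1]
        fpr = np.array([(s0 >= t).mean() for t in thresholds])
        tpr = np.array([(s1 >= t).mean() for t in thresholds])
        if fpr_grid is not None:
            tpr = np.array([tpr[fpr <= f].max(initial=0.0) for f in fpr_grid])
            fpr = np.asarray(fpr_grid, dtype=float)
        out.append(pd.DataFrame({"method": method, "fpr": fpr, "tpr": tpr}))
    return pd.concat(out, ignore_index=True)
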