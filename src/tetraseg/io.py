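"""File input/output and the per-marker testing pipeline.

Input formats:

* **VCF** (via pysam) — biallelic tetraploid records; ``GT`` gives known
  dosages (number of alternative alleles among the four called), ``GL``
  (log10 likelihoods) or ``PL`` (phred-scaled) give genotype likelihoods.
  Multi-allelic or non-tetraploid records are skipped with a logged
  warning.
* **CSV/TSV counts tables** — columns ``marker, x0..x4, ell1, ell2``.

Output is a tidy table, one row per marker x method, with
Bonferroni-adjusted (and optionally Benjamini-Hochberg) p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .baselines import chisq_test, polymapr_like_test
from .bayes import bayes_test
from .gamete import DEFAULT_DR_CAP
from .likelihood import counts_to_gl, estimate_parents, mle_alt_counts, mle_alt_gl
from .lrt import lrt_counts, lrt_gl
from .simulate import gl_to_posteriors, posterior_mode_counts

logger = logging.getLogger("tetraseg")

#: markers whose estimated maximum genotype frequency exceeds this are
#: considered monomorphic by the optional pre-filter
MONOMORPHIC_THRESHOLD = 0.95

__all__ = ["SnpRecord", "read_vcf", "read_counts_table", "run_tests",
           "adjust_pvalues", "MONOMORPHIC_THRESHOLD"]


@dataclass
class SnpRecord:
    """One marker's data: exactly one of ``counts`` / ``log_gl`` is set."""

    id: str
    counts: np.ndarray | None = None
    log_gl: np.ndarray | None = None
    ells: tuple[int, int] | None = None
    parent_liks: tuple[np.ndarray, np.ndarray] | None = None
    provenance: str = ""
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if (self.counts is None) == (self.log_gl is None):
            raise ValueError("exactly one of counts/log_gl must be present")

    @property
    def n(self) -> int:
        if self.counts is not None:
            return int(np.sum(self.counts))
        return self.log_gl.shape[0]

    def qhat(self) -> np.ndarray:
        """Unconstrained genotype-frequency estimate (for filtering)."""
        if self.counts is not None:
            return mle_alt_counts(self.counts)
        return mle_alt_gl(self.log_gl)


def read_counts_table(path) -> Iterator[SnpRecord]:
    """Stream SnpRecords from a CSV/TSV with columns marker,x0..x4,ell1,ell2."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["marker", "x0", "x1", "x2", "x3", "x4", "ell1", "ell2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns {missing}")
    if df.empty:
        logger.warning("counts table %s is empty", path)
    for i, row in df.iterrows():
        counts = np.array([row[f"x{k}"] for k in range(5)], dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"negative count at marker {row['marker']}")
        ells = (int(row["ell1"]), int(row["ell2"]))
        if not all(0 <= e <= 4 for e in ells):
            raise ValueError(f"parent dosage out of range at {row['marker']}")
        yield SnpRecord(id=str(row["marker"]), counts=counts, ells=ells,
                        provenance=f"{path}:{i}")


def _gt_dosage(sample) -> int | None:
    alleles = sample.get("GT")
    if alleles is None or len(alleles) != 4 or any(a is None for a in alleles):
        return None
    return int(sum(1 for a in alleles if a == 1))


def _gl_vector(sample) -> np.ndarray | None:
    if "GL" in sample and sample["GL"] is not None:
        gl = np.asarray(sample["GL"], dtype=float)
        if gl.size != 5:
            return None
        return np.power(10.0, gl - gl.max())
    if "PL" in sample and sample["PL"] is not None:
        pl = np.asarray(sample["PL"], dtype=float)
        if pl.size != 5:
            return None
        return np.power(10.0, -(pl - pl.min()) / 10.0)
    return None


def read_vcf(
    path,
    parent_ids: tuple[str, str] | None = None,
    offspring_ids: Iterable[str] | None = None,
) -> Iterator[SnpRecord]:
    """Stream SnpRecords from a VCF of tetraploid genotypes.

    With GL/PL present, records carry genotype-likelihood matrices (and
    parent likelihood vectors when ``parent_ids`` are given); otherwise GT
    dosages are used.  Skipped records (multi-allelic, wrong ploidy,
    missing fields) are counted and logged.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if parent_ids is not None:
        for pid in parent_ids:
            if pid not in samples:
                raise ValueError(f"parent sample {pid!r} not in VCF")
    if offspring_ids is None:
        exclude = set(parent_ids) if parent_ids else set()
        offspring_ids = [s for s in samples if s not in exclude]
    else:
        offspring_ids = list(offspring_ids)
        for oid in offspring_ids:
            if oid not in samples:
                raise ValueError(f"offspring sample {oid!r} not in VCF")

    n_skipped = 0
    for rec in vcf:
        marker = rec.id or f"{rec.chrom}:{rec.pos}"
        if rec.alts is None or len(rec.alts) != 1:
            logger.warning("skipping non-biallelic record %s", marker)
            n_skipped += 1
            continue
        gl_rows = [_gl_vector(rec.samples[s]) for s in offspring_ids]
        if all(g is not None for g in gl_rows):
            G = np.vstack(gl_rows)
            parent_liks = None
            ells = None
            if parent_ids is not None:
                a = _gl_vector(rec.samples[parent_ids[0]])
                b = _gl_vector(rec.samples[parent_ids[1]])
                if a is not None and b is not None:
                    parent_liks = (a, b)
                else:
                    d1 = _gt_dosage(rec.samples[parent_ids[0]])
                    d2 = _gt_dosage(rec.samples[parent_ids[1]])
                    if d1 is not None and d2 is not None:
                        ells = (d1, d2)
            yield SnpRecord(id=marker, log_gl=np.log(np.clip(G, 1e-300, None)),
                            ells=ells, parent_liks=parent_liks,
                            provenance=str(path))
            continue
        dosages = [_gt_dosage(rec.samples[s]) for s in offspring_ids]
        if any(d is None for d in dosages):
            logger.warning("skipping record %s: missing or non-tetraploid GT",
                           marker)
            n_skipped += 1
            continue
        counts = np.bincount(dosages, minlength=5).astype(float)
        ells = None
        if parent_ids is not None:
            d1 = _gt_dosage(rec.samples[parent_ids[0]])
            d2 = _gt_dosage(rec.samples[parent_ids[1]])
            if d1 is not None and d2 is not None:
                ells = (d1, d2)
        yield SnpRecord(id=marker, counts=counts, ells=ells,
                        provenance=str(path))
    if n_skipped:
        logger.warning("skipped %d record(s) from %s", n_skipped, path)


def _test_one(record: SnpRecord, method: str, dr_cap: float, draws: int,
              rng: np.random.Generator) -> dict:
    row: dict = {"marker": record.id, "method": method, "n": record.n}
    ells = record.ells
    log_g = record.log_gl
    if ells is None:
        if log_g is None:
            log_g_est = counts_to_gl(record.counts)
        else:
            log_g_est = log_g
        if record.parent_liks is not None:
            a, b = record.parent_liks
        else:
            logger.info("marker %s: no parent data, estimating dosages "
                        "from offspring", record.id)
            a = b = np.ones(5)
        ells = estimate_parents(a, b, log_g_est, dr_cap)
    row["ell1_used"], row["ell2_used"] = ells

    if method == "lrt":
        res = (lrt_counts(record.counts, ells, dr_cap) if log_g is None
               else lrt_gl(log_g, ells, dr_cap))
        row.update(stat=res.stat, df=res.df, p_value=res.p_value)
        if res.null_fit is not None:
            # single-locus double-reduction estimates are unreliable;
            # exposed for diagnostics only
            row["alpha_hat_unreliable"] = res.null_fit.alpha_hat
    elif method == "bayes":
        data = record.counts if log_g is None else log_g
        res = bayes_test(data, ells=ells, n_draws=draws, seed=rng)
        row.update(log_bf=res.log_bf, mc_se=res.mc_se)
    elif method == "chisq":
        x = record.counts if log_g is None else posterior_mode_counts(log_g)
        row.update(p_value=chisq_test(x, ells).p_value)
    elif method == "polymapr":
        data = record.counts if log_g is None else gl_to_posteriors(log_g)
        row.update(p_value=polymapr_like_test(data, ells).p_value)
    else:
        raise ValueError(f"unknown method {method!r}")
    return row


def run_tests(
    records: Iterable[SnpRecord],
    methods=("lrt",),
    dr_cap: float = DEFAULT_DR_CAP,
    draws: int = 10_000,
    seed: int = 0,
    filter_monomorphic: bool = False,
    monomorphic_threshold: float = MONOMORPHIC_THRESHOLD,
) -> pd.DataFrame:
    """Run the requested tests on every marker, preserving input order."""
    rng = np.random.default_rng(seed)
    rows = []
    for record in records:
        if filter_monomorphic and record.qhat().max() > monomorphic_threshold:
            logger.info("marker %s filtered as monomorphic", record.id)
            continue
        for method in methods:
            rows.append(_test_one(record, method, dr_cap, draws, rng))
    df = pd.DataFrame.from_records(rows)
    return adjust_pvalues(df)


def adjust_pvalues(df: pd.DataFrame) -> pd.DataFrame:
    """Add Bonferroni and Benjamini-Hochberg adjusted p-values per method."""
    if df.empty or "p_value" not in df.columns:
        return df
    df = df.copy()
    df["p_bonferroni"] = np.nan
    df["p_bh"] = np.nan
    for method, idx in df.groupby("method").groups.items():
        p = df.loc[idx, "p_value"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if not ok.any():
            continue
        sub = np.asarray(idx)[ok]
        df.loc[sub, "p_bonferroni"] = np.minimum(p[ok] * ok.sum(), 1.0)
        df.loc[sub, "p_bh"] = multipletests(p[ok], method="fdr_bh")[1]
    return df
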