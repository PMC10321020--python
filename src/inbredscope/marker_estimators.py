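"""SNP-by-SNP inbreeding estimators and their supporting steps.

Quality control (call rate, MAF, exact Hardy-Weinberg test), allele
frequencies in a designated reference cohort, VanRaden's first genomic
relationship matrix

    G = M M' / sum_j 2 p_j (1 - p_j),       M = X - 2 p_j (columnwise),

and the three frequency-based inbreeding coefficients:

* ``F_GRM = diag(G) - 1``
* ``F_UNI``: mean over markers of (x^2 - (1+2p)x + 2p^2) / (2p(1-p)),
  the correlation between uniting gametes,
* ``F_HOM``: 1 - mean of x(2-x) / (2p(1-p)), observed vs expected
  homozygosity.

All three share the same reference allele frequencies; the reference
should mimic the founder population (the estimators measure inbreeding
relative to a population with those frequencies and go negative for
animals less homozygous than that reference expects).  Markers
monomorphic in the reference are excluded everywhere, including the GRM
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value by enumeration of heterozygote counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one
    (Wigginton-style exact test; no mid-p correction).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # probabilities over all het counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    # unnormalised log-prob recursion: P(h+2)/P(h) = ...
    for k in range(1, len(hets)):
        h = hets[k - 1]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        num = 4.0 * rare_hom * common_hom
        den = float((h + 2) * (h + 1))
        logp[k] = logp[k - 1] + np.log(num) - np.log(den)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    return float(np.minimum(p[p <= p[obs] * (1 + 1e-12)].sum(), 1.0))


@dataclass
class QCReport:
    n_input: int
    n_call_rate: int
    n_maf: int
    n_hwe: int
    n_retained: int


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-4,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers failing call rate, MAF or exact-HWE criteria.

    A marker is dropped when its call rate is below ``call_rate_min``, its
    minor allele frequency is below ``maf_min``, or its HWE exact p-value is
    below ``hwe_alpha``.  Returns the filtered matrix and a per-criterion
    removal report (a marker can fail several criteria; counts overlap).
    """
    codes = g.codes
    n = g.n_samples
    called = codes != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / n

    alt = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    maf = np.minimum(p, 1 - p)

    n_het = ((codes == 1) & called).sum(axis=0)
    n_hom2 = ((codes == 2) & called).sum(axis=0)
    n_hom1 = n_called - n_het - n_hom2
    hwe_p = np.array(
        [hwe_exact_pvalue(int(h), int(a), int(b))
         for h, a, b in zip(n_het, n_hom1, n_hom2)]
    )

    fail_cr = call_rate < call_rate_min
    fail_maf = ~(maf >= maf_min)   # NaN maf (no calls) also fails
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("empty panel: all markers removed by QC")
    report = QCReport(
        n_input=g.n_markers,
        n_call_rate=int(fail_cr.sum()),
        n_maf=int(fail_maf.sum()),
        n_hwe=int(fail_hwe.sum()),
        n_retained=int(keep.sum()),
    )
    return g.subset_markers(np.nonzero(keep)[0]), report


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Second-allele frequencies in a reference cohort.

    ``p`` has one entry per marker of the source matrix; ``usable`` flags
    markers polymorphic in the reference (0 < p < 1).  Monomorphic or
    uncallable markers are excluded from every estimator.
    """

    p: np.ndarray
    usable: np.ndarray
    reference_ids: list[str]


def allele_frequencies(
    g: GenotypeMatrix, reference_ids: list[str]
) -> AlleleFrequencies:
    """Frequencies of the second allele among the reference animals."""
    if not reference_ids:
        raise ValueError("reference id list is empty")
    idx = [g.sample_ids.index(s) for s in reference_ids]
    codes = g.codes[idx]
    called = codes != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    usable = (n_called > 0) & (p > 0) & (p < 1)
    return AlleleFrequencies(p=p, usable=usable, reference_ids=list(reference_ids))


def reference_ids_by_birth_year(
    sample_ids: list[str], birth_years: pd.Series, year_min: int, year_max: int
) -> list[str]:
    """Genotyped animals born within [year_min, year_max] — the cohort whose
    allele frequencies stand in for the founder population."""
    keep = []
    for s in sample_ids:
        y = birth_years.get(s, np.nan)
        if not np.isnan(y) and year_min <= y <= year_max:
            keep.append(s)
    return keep


# ---------------------------------------------------------------------------
# GRM and the three estimators
# ---------------------------------------------------------------------------

def grm_vanraden1(g: GenotypeMatrix, freqs: AlleleFrequencies) -> pd.DataFrame:
    """VanRaden's first genomic relationship matrix.

    Missing genotypes contribute zero to M (imputed to their expectation
    2p).  Markers unusable in the reference are dropped from both M and
    the denominator.
    """
    use = freqs.usable
    if not use.any():
        raise ValueError("no usable markers for the GRM")
    p = freqs.p[use]
    X = g.codes[:, use].astype(float)
    X[X == MISSING] = np.nan
    M = X - 2 * p
    M[np.isnan(M)] = 0.0
    denom = float(np.sum(2 * p * (1 - p)))
    G = (M @ M.T) / denom
    return pd.DataFrame(G, index=g.sample_ids, columns=g.sample_ids)


def f_grm(G: pd.DataFrame) -> pd.Series:
    """Inbreeding from the GRM diagonal: F = diag(G) - 1."""
    return pd.Series(np.diag(G.to_numpy()) - 1.0, index=G.index, name="F_GRM")


def _per_marker_terms(
    g: GenotypeMatrix, freqs: AlleleFrequencies
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    use = freqs.usable
    p = freqs.p[use]
    X = g.codes[:, use].astype(float)
    obs = X != MISSING
    return X, p, obs


def f_uni(g: GenotypeMatrix, freqs: AlleleFrequencies) -> pd.Series:
    """Uniting-gametes inbreeding coefficient, averaged over usable markers.

    Animals with no usable non-missing marker get NaN.
    """
    X, p, obs = _per_marker_terms(g, freqs)
    den = 2 * p * (1 - p)
    term = (X * X - (1 + 2 * p) * X + 2 * p * p) / den
    term[~obs] = 0.0
    m_i = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m_i > 0, term.sum(axis=1) / m_i, np.nan)
    return pd.Series(out, index=g.sample_ids, name="F_UNI")


def f_hom(g: GenotypeMatrix, freqs: AlleleFrequencies) -> pd.Series:
    """Excess-homozygosity inbreeding: 1 - mean of x(2-x)/(2p(1-p))."""
    X, p, obs = _per_marker_terms(g, freqs)
    den = 2 * p * (1 - p)
    term = X * (2 - X) / den
    term[~obs] = 0.0
    m_i = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m_i > 0, 1.0 - term.sum(axis=1) / m_i, np.nan)
    return pd.Series(out, index=g.sample_ids, name="F_HOM")


def mean_heterozygosity(g: GenotypeMatrix) -> float:
    """Mean observed SNP heterozygosity across all markers and animals
    (the ``het`` input of the minimum-run-length formula)."""
    called = g.codes != MISSING
    if not called.any():
        raise ValueError("no called genotypes")
    return float(((g.codes == 1) & called).sum() / called.sum())
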