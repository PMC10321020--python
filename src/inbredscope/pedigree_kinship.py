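"""Pedigree-based inbreeding (F_PED) and the numerator relationship matrix A.

F_PED for animal *i* is the expected fraction of the genome autozygous given
the pedigree, equal to the kinship of the parents; the numerator
relationship matrix A holds twice the kinship between all pairs, with
``diag(A) = 1 + F_PED``.  F_PED uses the Meuwissen & Luo ancestor-tracing
algorithm, which computes each diagonal of A without building the matrix;
A itself is built by the classical tabular recursion.

Animals with a single known parent are treated as having an unrelated,
non-inbred unknown parent on the missing side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import Pedigree


def _mendelian_variance(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family segregation variance D_i given parental inbreeding.

    D = 0.5 - 0.25 (F_s + F_d) with both parents known; a missing parent
    contributes as an unknown non-inbred founder.
    """
    n = len(ped)
    D = np.empty(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 1.0
    return D


def f_ped(ped: Pedigree) -> pd.Series:
    """Meuwissen-Luo inbreeding coefficients, indexed by animal id.

    For each animal the algorithm traces the ancestor set, accumulating the
    gene-contribution coefficients L (L[ancestor] = expected fraction of the
    animal's genes from that ancestor's segregation), and evaluates
    ``1 + F_i = sum_a L_a^2 D_a``.
    """
    n = len(ped)
    F = np.zeros(n)
    D = np.empty(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0          # no common ancestry possible through one side
            continue
        # accumulate L top-down: animals processed in decreasing index order,
        # so each L value is final before it is spent
        aii = 0.0
        L: dict[int, float] = {i: 1.0}
        frontier = {i}
        while frontier:
            j = max(frontier)
            frontier.discard(j)
            lj = L.pop(j)
            aii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    frontier.add(p)
        F[i] = aii - 1.0
    return pd.Series(F, index=ped.ids, name="F_PED")


def numerator_relationship_matrix(
    ped: Pedigree, subset: list[str] | None = None
) -> pd.DataFrame:
    """Tabular numerator relationship matrix, optionally restricted to subset ids.

    The recursion runs over the whole pedigree (the ancestor closure of any
    subset) and the result is then restricted, so restricted matrices remain
    consistent with the full pedigree.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        a_s = A[s, :i] if s >= 0 else 0.0
        a_d = A[d, :i] if d >= 0 else 0.0
        row = 0.5 * (np.asarray(a_s) + np.asarray(a_d))
        if s < 0 and d < 0:
            row = np.zeros(i)
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    df = pd.DataFrame(A, index=ped.ids, columns=ped.ids)
    if subset is not None:
        missing = [a for a in subset if a not in df.index]
        if missing:
            raise KeyError(f"subset ids not in pedigree: {missing[:5]}")
        df = df.loc[subset, subset]
    return df


def mean_f_by_cohort(
    inbreeding: pd.Series, birth_years: pd.Series
) -> pd.DataFrame:
    """Per-birth-year mean inbreeding and animal count.

    Animals with missing birth year are skipped; years with no animals are
    omitted.  Returns a DataFrame with columns (year, mean, count).
    """
    df = pd.DataFrame({"F": inbreeding, "year": birth_years.reindex(inbreeding.index)})
    df = df.dropna()
    if df.empty:
        return pd.DataFrame(columns=["year", "mean", "count"])
    g = df.groupby(df["year"].astype(int))["F"]
    out = pd.DataFrame({"year": g.mean().index, "mean": g.mean().to_numpy(),
                        "count": g.count().to_numpy()})
    return out.reset_index(drop=True)
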