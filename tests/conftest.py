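"""Shared fixtures: tiny canonical pedigrees, random-fixture helpers and one
session-scoped small-preset pipeline run reused by the heavier checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import inbredscope as ib
from inbredscope import depression_lmm, pipeline


@pytest.fixture()
def fullsib_pedigree() -> ib.Pedigree:
    """E is the offspring of full sibs C x D with unrelated founder parents."""
    return ib.Pedigree.from_records([
        ("A", "0", "0", 2000), ("B", "0", "0", 2000),
        ("C", "A", "B", 2001), ("D", "A", "B", 2001),
        ("E", "C", "D", 2002),
    ])


@pytest.fixture()
def halfsib_pedigree() -> ib.Pedigree:
    """X is the offspring of paternal half sibs (shared sire S)."""
    return ib.Pedigree.from_records([
        ("S", "0", "0"), ("D1", "0", "0"), ("D2", "0", "0"),
        ("H1", "S", "D1"), ("H2", "S", "D2"), ("X", "H1", "H2"),
    ])


def random_pedigree(rng: np.random.Generator, n: int) -> ib.Pedigree:
    """Random sorted pedigree: each animal's parents drawn from earlier
    animals (or unknown), allowing founders throughout."""
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(1, n):
        if rng.random() < 0.8:
            sire[i] = rng.integers(0, i)
        if rng.random() < 0.8:
            d = rng.integers(0, i)
            dam[i] = d if d != sire[i] else -1
    ids = [f"p{i}" for i in range(n)]
    year = 2000 + np.arange(n) // max(1, n // 10)
    return ib.Pedigree(ids, sire, dam, year.astype(float))


def coancestry_oracle(ped: ib.Pedigree):
    """Recursive-coancestry relationship matrix, independent of the tabular
    construction: f(i,i) = (1 + f(s,d))/2, f(i,j) = (f(s_i,j)+f(d_i,j))/2
    for i topologically after j; A = 2f."""
    import sys

    sys.setrecursionlimit(100_000)
    memo: dict[tuple[int, int], float] = {}

    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        s, d = ped.sire[i], ped.dam[i]
        if i == j:
            val = 0.5 * (1.0 + (f(s, d) if s >= 0 and d >= 0 else 0.0))
        else:
            val = 0.5 * (f(s, j) + f(d, j))
        memo[key] = val
        return val

    n = len(ped)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * f(i, j)
    return A


@pytest.fixture(scope="session")
def small_pipeline() -> pipeline.PipelineResult:
    """One full run of the scaled preset (~580 animals, ~4.9k markers),
    shared by the truth-recovery, comparison and end-to-end checks."""
    cfg = ib.cattle_50k_small(7)
    return pipeline.run_pipeline(
        cfg,
        trait_cfg=ib.TraitConfig(beta=-2.0, sigma2_u=1.0, sigma2_e=3.0),
        mcmc=depression_lmm.TEST_MCMC,
    )


def make_genotypes(
    rng: np.random.Generator,
    n: int,
    m: int,
    n_chrom: int = 1,
    spacing: int = 75_000,
    p_het: float = 0.3,
    p_missing: float = 0.0,
) -> ib.GenotypeMatrix:
    """Random genotype fixture with roughly even marker spacing."""
    per = m // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)
    pos = np.concatenate([
        np.cumsum(rng.integers(spacing // 2, spacing * 3 // 2, size=per))
        for _ in range(n_chrom)
    ])
    mk = pd.DataFrame({"chrom": chrom, "pos": pos, "a1": "A", "a2": "B"})
    codes = rng.choice(
        [0, 1, 2, ib.MISSING],
        size=(n, n_chrom * per),
        p=[(1 - p_het - p_missing) / 2, p_het, (1 - p_het - p_missing) / 2, p_missing],
    ).astype(np.int8)
    return ib.GenotypeMatrix([f"s{i}" for i in range(n)], mk, codes)
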