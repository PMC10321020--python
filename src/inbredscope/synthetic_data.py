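"""Gene-dropping simulator: pedigrees, genotypes with known autozygosity,
and phenotypes with injected inbreeding depression.

The generator emulates the structure of an intensively-managed beef-cattle
population: discrete generations in which a small fraction of males is
reused as sires (the driver of inbreeding accumulation), a 29-autosome
genome with evenly spaced SNP markers, and reproductive-trait phenotypes
following ``y = mu + fixed effects + beta * F_true + u + e``.

Gene dropping labels every founder haplotype with a unique id and drops
them through the pedigree with crossovers placed as a Poisson process on
the genetic map (no interference).  Realized autozygosity — the fraction
of the genome where both haplotypes carry the same founder label — is
recorded *before* genotyping error and missingness are applied, so the
simulated truth is the estimand, not the observation.  Marker genotypes
are then read off the founder labels via founder allele draws.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, Pedigree
from .pedigree_kinship import f_ped

MORGAN_PER_BP = 1e-8


@dataclass
class SimConfig:
    """Simulation settings.

    ``sire_fraction`` is the fraction of available males used as sires each
    generation — the knob that drives inbreeding accumulation.  Marker
    positions are evenly spaced ``marker_spacing_bp`` apart; chromosome
    genetic length follows at 1 cM/Mb.
    """

    seed: int
    n_founders: int = 60
    n_generations: int = 8
    n_offspring: int = 2                  # per dam per generation
    sire_fraction: float = 0.2
    n_chromosomes: int = 29
    markers_per_chromosome: int = 170
    marker_spacing_bp: int = 75_000
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    genotyping_error: float = 0.001
    missing_rate: float = 0.002
    base_year: int = 2000

    def __post_init__(self) -> None:
        if min(
            self.n_founders, self.n_generations, self.n_offspring,
            self.n_chromosomes, self.markers_per_chromosome, self.marker_spacing_bp,
        ) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 < self.sire_fraction <= 1:
            raise ValueError("sire_fraction must be in (0,1]")

    @property
    def chrom_length_morgans(self) -> float:
        return self.markers_per_chromosome * self.marker_spacing_bp * MORGAN_PER_BP

    def marker_positions_bp(self) -> np.ndarray:
        return self.marker_spacing_bp * np.arange(1, self.markers_per_chromosome + 1)


def cattle_50k(seed: int) -> SimConfig:
    """Full-scale preset at 50k-array cattle scale: 29 autosomes, ~34k
    evenly spaced SNPs, ~2.5k animals in the recent generations and a
    sire-reuse intensity calibrated so mean pedigree inbreeding sits near
    0.09."""
    return SimConfig(
        seed=seed,
        n_founders=300,
        n_generations=8,
        n_offspring=2,
        sire_fraction=0.04,
        n_chromosomes=29,
        markers_per_chromosome=1190,
        marker_spacing_bp=75_000,
    )


def cattle_50k_small(seed: int) -> SimConfig:
    """Scaled preset for fast seeded runs: same structure, ~500 animals and
    ~5,000 markers (29 x 170)."""
    return SimConfig(seed=seed)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

@dataclass
class SimPedigree:
    pedigree: Pedigree
    sex: pd.Series          # 'M'/'F' per animal id
    generation: pd.Series


def simulate_pedigree(cfg: SimConfig) -> SimPedigree:
    """Discrete-generation pedigree with repeated sire use.

    Generation 0 holds the founders (half of each sex).  Each later
    generation samples ``max(1, round(sire_fraction * males))`` sires from
    the previous generation and mates every previous-generation female to a
    random sire, producing ``n_offspring`` offspring of random sex.
    """
    rng = np.random.default_rng(cfg.seed)
    ids: list[str] = []
    sire_l: list[int] = []
    dam_l: list[int] = []
    year_l: list[float] = []
    sex_l: list[str] = []
    gen_l: list[int] = []

    males: list[int] = []
    females: list[int] = []
    for i in range(cfg.n_founders):
        ids.append(f"G0_{i}")
        sire_l.append(-1)
        dam_l.append(-1)
        year_l.append(cfg.base_year)
        s = "M" if i % 2 == 0 else "F"
        sex_l.append(s)
        gen_l.append(0)
        (males if s == "M" else females).append(i)

    for gen in range(1, cfg.n_generations + 1):
        if not males or not females:
            break
        n_sires = max(1, int(round(cfg.sire_fraction * len(males))))
        sires = rng.choice(males, size=n_sires, replace=False)
        next_m: list[int] = []
        next_f: list[int] = []
        k = 0
        for dam in females:
            sire = int(rng.choice(sires))
            for _ in range(cfg.n_offspring):
                idx = len(ids)
                ids.append(f"G{gen}_{k}")
                k += 1
                sire_l.append(sire)
                dam_l.append(dam)
                year_l.append(cfg.base_year + gen)
                s = "M" if rng.random() < 0.5 else "F"
                sex_l.append(s)
                gen_l.append(gen)
                (next_m if s == "M" else next_f).append(idx)
        males, females = next_m, next_f

    ped = Pedigree(ids, np.array(sire_l), np.array(dam_l), np.array(year_l))
    return SimPedigree(
        pedigree=ped,
        sex=pd.Series(sex_l, index=ids, name="sex"),
        generation=pd.Series(gen_l, index=ids, name="generation"),
    )


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

@dataclass
class TrueIBD:
    """Realized autozygosity from founder-label identity.

    ``segments``: (animal, chrom, start_bp, end_bp) autozygous tracts;
    ``autozygosity``: per-animal genome fraction; ``by_chromosome``:
    per-animal per-chromosome fraction.
    """

    segments: pd.DataFrame
    autozygosity: pd.Series
    by_chromosome: pd.DataFrame
    genome_length_morgans: float


def _meiosis(h0, h1, length: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's two haplotype mosaics.

    A mosaic is (starts, ids): segment start positions in Morgans (first is
    0.0) and founder labels.  Crossovers are Poisson(length) with uniform
    positions; the starting haplotype is chosen at random.
    """
    n_x = rng.poisson(length)
    if n_x == 0:
        return (h0 if rng.random() < 0.5 else h1)
    cuts = np.sort(rng.uniform(0.0, length, size=n_x))
    cur = int(rng.random() < 0.5)
    haps = (h0, h1)
    starts: list[float] = []
    out_ids: list[int] = []
    lo = 0.0
    for hi in np.append(cuts, length):
        st, ii = haps[cur]
        a = int(np.searchsorted(st, lo, side="right") - 1)
        b = int(np.searchsorted(st, hi, side="left"))
        for k in range(a, b):
            s = max(float(st[k]), lo)
            if not starts or out_ids[-1] != int(ii[k]):
                starts.append(s)
                out_ids.append(int(ii[k]))
        lo = hi
        cur = 1 - cur
    return np.array(starts), np.array(out_ids, dtype=np.int64)


def _autozygous_segments(h0, h1, length: float) -> list[tuple[float, float]]:
    """Intervals where the two mosaics carry the same founder label."""
    s0, i0 = h0
    s1, i1 = h1
    bounds = np.unique(np.concatenate([s0, s1, [length]]))
    segs: list[tuple[float, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        id0 = i0[np.searchsorted(s0, a, side="right") - 1]
        id1 = i1[np.searchsorted(s1, a, side="right") - 1]
        if id0 == id1:
            if segs and segs[-1][1] == a:
                segs[-1] = (segs[-1][0], b)
            else:
                segs.append((float(a), float(b)))
    return segs


def gene_drop(ped: Pedigree, cfg: SimConfig) -> tuple[GenotypeMatrix, TrueIBD]:
    """Drop labeled founder haplotypes through the pedigree.

    Animals with one unknown parent receive a fresh unique founder
    haplotype on the missing side (the unknown parent is unrelated by
    convention).  Returns the coded genotype matrix (with genotyping error
    and missingness applied) and the uncontaminated realized-autozygosity
    truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = len(ped)
    L = cfg.chrom_length_morgans
    n_chrom = cfg.n_chromosomes
    # haps[c][i] = (hap0, hap1); each hap = (starts, ids)
    haps: list[list] = [[None] * n for _ in range(n_chrom)]
    next_label = 0

    def fresh_hap() -> tuple[np.ndarray, np.ndarray]:
        nonlocal next_label
        h = (np.array([0.0]), np.array([next_label], dtype=np.int64))
        next_label += 1
        return h

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for c in range(n_chrom):
            if s >= 0:
                pat = _meiosis(*haps[c][s], L, rng)
            else:
                pat = fresh_hap()
            if d >= 0:
                mat = _meiosis(*haps[c][d], L, rng)
            else:
                mat = fresh_hap()
            haps[c][i] = (pat, mat)

    # truth before any observation noise
    seg_rows = []
    auto = np.zeros(n)
    by_chrom = np.zeros((n, n_chrom))
    for i in range(n):
        for c in range(n_chrom):
            tot = 0.0
            for a, b in _autozygous_segments(*haps[c][i], L):
                tot += b - a
                seg_rows.append(
                    (ped.ids[i], c + 1,
                     int(round(a / MORGAN_PER_BP)) + 1,
                     int(round(b / MORGAN_PER_BP)))
                )
            by_chrom[i, c] = tot / L
        auto[i] = by_chrom[i].mean()
    truth = TrueIBD(
        segments=pd.DataFrame(
            seg_rows, columns=["animal", "chrom", "start_bp", "end_bp"]
        ),
        autozygosity=pd.Series(auto, index=ped.ids, name="true_F"),
        by_chromosome=pd.DataFrame(
            by_chrom, index=ped.ids, columns=range(1, n_chrom + 1)
        ),
        genome_length_morgans=L * n_chrom,
    )

    # founder allele draws and genotype evaluation
    m_c = cfg.markers_per_chromosome
    pos_bp = cfg.marker_positions_bp()
    pos_m = pos_bp * MORGAN_PER_BP
    lo, hi = cfg.founder_freq_range
    codes = np.empty((n, n_chrom * m_c), dtype=np.int8)
    freqs = np.empty(n_chrom * m_c)
    for c in range(n_chrom):
        p = rng.uniform(lo, hi, size=m_c)
        freqs[c * m_c:(c + 1) * m_c] = p
        alleles = (rng.random((next_label, m_c)) < p).astype(np.int8)
        block = np.empty((n, m_c), dtype=np.int8)
        for i in range(n):
            h0, h1 = haps[c][i]
            lab0 = h0[1][np.searchsorted(h0[0], pos_m, side="right") - 1]
            lab1 = h1[1][np.searchsorted(h1[0], pos_m, side="right") - 1]
            a0 = alleles[lab0, np.arange(m_c)]
            a1 = alleles[lab1, np.arange(m_c)]
            block[i] = a0 + a1
        codes[:, c * m_c:(c + 1) * m_c] = block
    # genotyping error: flip one random allele with rate eps
    if cfg.genotyping_error > 0:
        err = rng.random(codes.shape) < cfg.genotyping_error
        which = rng.random(codes.shape) < 0.5
        delta = np.zeros_like(codes)
        delta[err & (codes == 0)] = 1
        delta[err & (codes == 2)] = -1
        het_err = err & (codes == 1)
        delta[het_err & which] = 1
        delta[het_err & ~which] = -1
        codes = codes + delta
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = MISSING
    markers = pd.DataFrame({
        "chrom": np.repeat(np.arange(1, n_chrom + 1), m_c),
        "pos": np.tile(pos_bp, n_chrom),
        "a1": "A",
        "a2": "B",
    })
    g = GenotypeMatrix(list(ped.ids), markers, codes)
    g.founder_freqs = freqs       # known simulation truth, handy for tests
    return g, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitConfig:
    """Phenotype-model settings: y = mu + fixed + beta*F_true + u + e."""

    mu: float = 285.0
    beta: float = -2.0
    sigma2_u: float = 4.0
    sigma2_e: float = 12.0
    n_months: int = 12
    n_herd_years: int = 8
    sex_effect: float = 1.0        # SD of the per-level fixed effects
    trait: str = "GL"
    ordinal_thresholds: tuple[float, ...] | None = None


def sample_polygenic(ped: Pedigree, sigma2_u: float, rng) -> np.ndarray:
    """Additive genetic values via the pedigree Cholesky recursion:
    u_i = (u_s + u_d)/2 + Mendelian deviation with the inbreeding-adjusted
    segregation variance."""
    F = f_ped(ped).to_numpy()
    n = len(ped)
    u = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            mean = 0.5 * (u[s] + u[d])
            var = (0.5 - 0.25 * (F[s] + F[d])) * sigma2_u
        elif s >= 0 or d >= 0:
            mean = 0.5 * u[max(s, d)]
            var = (0.75 - 0.25 * F[max(s, d)]) * sigma2_u
        else:
            mean, var = 0.0, sigma2_u
        u[i] = mean + rng.standard_normal() * np.sqrt(max(var, 0.0))
    return u


def simulate_phenotypes(
    ped: Pedigree,
    truth: TrueIBD,
    trait_cfg: TraitConfig,
    seed: int,
    phenotyped_ids: list[str] | None = None,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Phenotype table with injected inbreeding depression.

    Factor levels (calf sex, calving month, herd-year) are assigned at
    random; their effects are drawn once per level.  ``beta`` multiplies
    the *true* autozygosity, so downstream fits can be checked against a
    known effect size.  With ``ordinal_thresholds`` the continuous liability
    is cut into ordered scores (a calving-difficulty-like trait).
    """
    if trait_cfg.sigma2_u < 0 or trait_cfg.sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    animals = phenotyped_ids if phenotyped_ids is not None else list(ped.ids)
    missing = [a for a in animals if a not in truth.autozygosity.index]
    if missing:
        raise KeyError(f"animals without simulated truth: {missing[:5]}")
    u_all = sample_polygenic(ped, trait_cfg.sigma2_u, rng)
    u = pd.Series(u_all, index=ped.ids).loc[animals].to_numpy()
    n = len(animals)
    sex_lab = rng.integers(0, 2, size=n)
    month = rng.integers(1, trait_cfg.n_months + 1, size=n)
    herd = rng.integers(0, trait_cfg.n_herd_years, size=n)
    eff_sex = rng.normal(0, trait_cfg.sex_effect, size=2)
    eff_month = rng.normal(0, trait_cfg.sex_effect, size=trait_cfg.n_months + 1)
    eff_herd = rng.normal(0, trait_cfg.sex_effect, size=trait_cfg.n_herd_years)
    F_true = truth.autozygosity.loc[animals].to_numpy()
    e = rng.normal(0, np.sqrt(trait_cfg.sigma2_e), size=n)
    y = (
        trait_cfg.mu + eff_sex[sex_lab] + eff_month[month] + eff_herd[herd]
        + trait_cfg.beta * F_true + u + e
    )
    if trait_cfg.ordinal_thresholds is not None:
        y = 1.0 + np.searchsorted(np.asarray(trait_cfg.ordinal_thresholds), y)
    afc = rng.normal(790.0, 30.0, size=n)
    return pd.DataFrame({
        "id": animals,
        "trait": trait_cfg.trait,
        "value": y,
        "sex": np.where(sex_lab == 0, "M", "F"),
        "month": month,
        "herd_year": [f"H{h}" for h in herd],
        "afc": afc,
        "true_F": F_true,
        "true_u": u,
    })
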