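"""Runs-of-homozygosity detection and ROH-based inbreeding.

A run of homozygosity (ROH) is a long uninterrupted stretch of homozygous
genotypes, evidence that the two chromosome copies descend from a single
recent ancestor.  Detection is the classical two-phase sliding-window
procedure:

1. *Window phase* — every contiguous window of ``window_size_snps`` SNPs is
   eligible when it contains at most ``max_het_in_run`` heterozygotes and at
   most one missing call; a SNP passes when the fraction of eligible windows
   covering it exceeds ``window_threshold``.
2. *Run phase* — maximal blocks of passing SNPs are split wherever two
   consecutive SNPs are more than ``max_gap_bp`` apart, then split further,
   left to right, so that no piece carries more than ``max_het_in_run``
   heterozygotes (the offending heterozygote acts as the separator);
   each piece is trimmed so both ends sit on observed homozygous SNPs.  A
   piece is reported when it has at least ``L`` SNPs, spans at least
   ``min_length_bp``, and has SNP density at least ``min_density``.

Candidate pieces do not depend on ``L`` — the minimum-SNP rule is a final
filter — so the segment set at a stricter ``L`` is exactly a subset of the
set at a looser one, and F_ROH is monotone in ``L`` per animal.

Segment coordinates are closed ``[start_bp, end_bp]`` at the first/last SNP
of the run; segment length and genome coverage are both measured as
``end - start`` so that F_ROH (total ROH length over total SNP-covered
autosome length) is a clean ratio of like quantities.

The minimum run length ``L`` comes from the false-positive-control formula
``L = ln(alpha / (n_s * n_i)) / ln(1 - het)`` — the run length at which a
chance run of homozygosity among ``n_s`` SNPs in ``n_i`` individuals with
mean heterozygosity ``het`` has probability below ``alpha``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["animal", "chrom", "start_bp", "end_bp", "n_snps", "n_het"]


@dataclass
class ROHParams:
    """Detection settings; defaults are the seven-parameter panel used for
    array data at cattle scale (with L determined by the false-positive
    formula, here defaulted to 60)."""

    L: int = 60
    min_length_bp: int = 1_000_000
    min_density: float = 1.0 / 100_000     # SNPs per bp
    max_gap_bp: int = 1_000_000
    max_het_in_run: int = 1
    window_size_snps: int = 15
    window_threshold: float = 0.05
    max_missing_in_window: int = 1

    def __post_init__(self) -> None:
        if min(self.L, self.min_length_bp, self.max_gap_bp, self.window_size_snps) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not 0 <= self.window_threshold <= 1:
            raise ValueError("window_threshold must be in [0,1]")


def min_snp_threshold(alpha: float, n_s: int, n_i: int, het: float) -> int:
    """Minimum number of consecutive homozygous SNPs controlling the
    false-positive ROH rate at ``alpha``; rounded to the nearest integer."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if not 0 < het < 1:
        raise ValueError("het must be in (0,1) (het=0 gives log(1)=0)")
    if n_s < 1 or n_i < 1:
        raise ValueError("n_s and n_i must be >= 1")
    return int(round(math.log(alpha / (n_s * n_i)) / math.log(1.0 - het)))


@dataclass
class ROHSegmentSet:
    """All detected segments, one row per segment.

    ``segments`` columns: animal, chrom, start_bp, end_bp, n_snps, n_het.
    ``sample_ids`` preserves the full animal list (animals with no segment
    still get F_ROH = 0).
    """

    segments: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def for_animal(self, animal: str) -> pd.DataFrame:
        return self.segments[self.segments["animal"] == animal]


def _passing_mask(het: np.ndarray, mis: np.ndarray, params: ROHParams) -> np.ndarray:
    """Window-phase SNP mask for one chromosome of one animal."""
    n = het.size
    w = params.window_size_snps
    n_win = n - w + 1
    if n_win <= 0:
        return np.zeros(n, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(mis)])
    win_het = het_c[w:] - het_c[:-w]
    win_mis = mis_c[w:] - mis_c[:-w]
    eligible = (win_het <= params.max_het_in_run) & (
        win_mis <= params.max_missing_in_window
    )
    elig_c = np.concatenate([[0], np.cumsum(eligible)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    n_cover = hi - lo + 1
    n_elig = elig_c[hi + 1] - elig_c[lo]
    return n_elig / n_cover > params.window_threshold


def _het_split(a: int, b: int, het_idx: np.ndarray, budget: int):
    """Split [a, b] left to right so no piece exceeds the heterozygote
    budget; the first over-budget heterozygote separates pieces and belongs
    to neither."""
    hets = het_idx[(het_idx >= a) & (het_idx <= b)]
    pieces: list[tuple[int, int]] = []
    start = a
    j = 0
    while start <= b:
        while j < hets.size and hets[j] < start:
            j += 1
        if hets.size - j <= budget:
            pieces.append((start, b))
            break
        cut = int(hets[j + budget])
        if cut - 1 >= start:
            pieces.append((start, cut - 1))
        start = cut + 1
    return pieces


def _detect_chromosome(
    pos: np.ndarray, x: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Segment index ranges for one animal on one chromosome.

    Maximal passing blocks are split at large gaps, then at over-budget
    heterozygotes, trimmed to homozygous ends and filtered; none of the
    candidate construction depends on L.
    """
    het = x == 1
    mis = x == MISSING
    hom = (x == 0) | (x == 2)
    n = pos.size
    passing = _passing_mask(het, mis, params)
    het_idx = np.nonzero(het)[0]
    # next/prev homozygous index for endpoint trimming
    prev_hom = np.maximum.accumulate(np.where(hom, np.arange(n), -1))
    next_hom = np.minimum.accumulate(np.where(hom, np.arange(n), n)[::-1])[::-1]
    runs: list[tuple[int, int]] = []
    edges = np.nonzero(np.diff(passing.astype(np.int8)))[0] + 1
    starts = np.concatenate([[0], edges])
    for s, e in zip(starts, np.concatenate([edges, [n]])):
        if not passing[s]:
            continue
        gap_break = s + np.nonzero(np.diff(pos[s:e]) > params.max_gap_bp)[0]
        blk_starts = np.concatenate([[s], gap_break + 1])
        blk_ends = np.concatenate([gap_break, [e - 1]])
        for bs, be in zip(blk_starts, blk_ends):
            for u, v in _het_split(int(bs), int(be), het_idx,
                                   params.max_het_in_run):
                a = int(next_hom[u])
                b = int(prev_hom[v])
                if a > b:
                    continue
                n_snps = b - a + 1
                span = int(pos[b] - pos[a])
                if (
                    n_snps >= params.L
                    and span >= params.min_length_bp
                    and span > 0
                    and n_snps / span >= params.min_density
                ):
                    runs.append((a, b))
    return runs


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> ROHSegmentSet:
    """Detect ROH segments for every animal over all autosomes."""
    params = params or ROHParams()
    rows: list[tuple] = []
    chrom_arr = g.markers["chrom"].to_numpy()
    pos_all = g.markers["pos"].to_numpy()
    for chrom in g.chromosomes():
        sl = g.chrom_slice(int(chrom))
        pos = pos_all[sl]
        if pos.size < params.window_size_snps:
            logger.warning(
                "chromosome %s has %d SNPs < window size %d; skipped",
                chrom, pos.size, params.window_size_snps,
            )
            continue
        for i, animal in enumerate(g.sample_ids):
            x = g.codes[i, sl]
            for a, b in _detect_chromosome(pos, x, params):
                n_het = int(np.sum(x[a:b + 1] == 1))
                rows.append(
                    (animal, int(chrom), int(pos[a]), int(pos[b]), b - a + 1, n_het)
                )
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return ROHSegmentSet(segments=seg, sample_ids=list(g.sample_ids))


def chromosome_coverage(g: GenotypeMatrix) -> pd.Series:
    """SNP-covered length (last - first SNP position) per chromosome."""
    cov = {}
    pos = g.markers["pos"].to_numpy()
    for chrom in g.chromosomes():
        sl = g.chrom_slice(int(chrom))
        cov[int(chrom)] = int(pos[sl][-1] - pos[sl][0])
    return pd.Series(cov, name="coverage_bp")


def f_roh(
    segs: ROHSegmentSet, g: GenotypeMatrix, per_chromosome: bool = False
):
    """F_ROH: total ROH length over SNP-covered autosome length.

    With ``per_chromosome=True`` returns a DataFrame (animals x chromosomes)
    of chromosomal coefficients, each chromosome's coverage as denominator.
    """
    cov = chromosome_coverage(g)
    total_cov = float(cov.sum())
    if total_cov <= 0:
        raise ValueError("zero SNP coverage")
    seg = segs.segments
    length = seg["end_bp"] - seg["start_bp"]
    animals = segs.sample_ids or sorted(seg["animal"].unique())
    if per_chromosome:
        tab = (
            seg.assign(length=length)
            .groupby(["animal", "chrom"])["length"].sum()
            .unstack(fill_value=0)
            .reindex(index=animals, columns=cov.index, fill_value=0)
        )
        return tab.div(cov, axis=1).astype(float)
    tot = seg.assign(length=length).groupby("animal")["length"].sum()
    out = tot.reindex(animals).fillna(0.0) / total_cov
    return out.rename("F_ROH")


def roh_length_spectrum(
    segs: ROHSegmentSet, bin_edges_mb: tuple[float, ...] = (0, 1, 2, 4, 8, 16, float("inf"))
) -> pd.Series:
    """Histogram of segment lengths (Mb) pooled over animals."""
    edges = np.asarray(bin_edges_mb, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing")
    lengths = (
        (segs.segments["end_bp"] - segs.segments["start_bp"]).to_numpy() / 1e6
    )
    counts, _ = np.histogram(lengths, bins=edges)
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
    return pd.Series(counts, index=labels, name="n_segments")
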