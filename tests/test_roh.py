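"""ROH detection: the minimum-run-length formula, handcrafted segment
cases, brute-force oracle equality and nestedness in L."""

import numpy as np
import pandas as pd
import pytest

import inbredscope as ib
from inbredscope.roh import ROHParams


def oracle_runs(pos, x, params: ROHParams):
    """Brute-force run enumeration applying the run-phase rules directly
    (no window phase, no prefix structures): the chromosome is cut at large
    gaps, each piece is cut again at every over-budget heterozygote (which
    joins neither side), ends are walked in to homozygous SNPs, and the
    count/span/density thresholds are checked by explicit recount."""
    n = len(pos)
    hom = [xi in (0, 2) for xi in x]
    # gap-free blocks
    blocks = []
    start = 0
    for i in range(n - 1):
        if pos[i + 1] - pos[i] > params.max_gap_bp:
            blocks.append((start, i))
            start = i + 1
    blocks.append((start, n - 1))
    # heterozygote-budget split within each block
    pieces = []
    for a, b in blocks:
        s = a
        count = 0
        for i in range(a, b + 1):
            if x[i] == 1:
                count += 1
                if count > params.max_het_in_run:
                    if i - 1 >= s:
                        pieces.append((s, i - 1))
                    s = i + 1
                    count = 0
        if s <= b:
            pieces.append((s, b))
    runs = []
    for u, v in pieces:
        while u <= v and not hom[u]:
            u += 1
        while v >= u and not hom[v]:
            v -= 1
        if u > v:
            continue
        n_snps = v - u + 1
        span = pos[v] - pos[u]
        if (
            n_snps >= params.L
            and span >= params.min_length_bp
            and span > 0
            and n_snps / span >= params.min_density
        ):
            runs.append((int(pos[u]), int(pos[v]), n_snps,
                         int(sum(x[k] == 1 for k in range(u, v + 1)))))
    return runs


def random_roh_fixture(rng, n=500, window=15):
    """Random chromosome with fully-called genotypes whose heterozygotes
    are spaced beyond the scanning window, so every SNP passes the window
    phase and the detector can be compared with the run-phase oracle
    directly.  Occasional oversized gaps exercise run splitting."""
    spacing = rng.integers(40_000, 100_000, size=n)
    big = rng.random(n) < 0.004
    spacing[big] = rng.integers(1_100_000, 2_000_000, size=int(big.sum()))
    pos = np.cumsum(spacing)
    x = rng.choice([0, 2], size=n).astype(np.int8)
    last_het = -window - 1
    for i in range(n):
        if rng.random() < 0.05 and i - last_het > window:
            x[i] = 1
            last_het = i
    return pos, x


def one_chrom_matrix(pos, codes_rows):
    mk = pd.DataFrame({"chrom": 1, "pos": pos, "a1": "A", "a2": "B"})
    codes = np.asarray(codes_rows, dtype=np.int8)
    return ib.GenotypeMatrix([f"s{i}" for i in range(codes.shape[0])], mk, codes)


class TestMinSnpThreshold:
    @pytest.mark.parametrize("args,expected", [
        ((0.05, 1000, 100, 0.5), 21),       # ln(5e-7)/ln(0.5) = 20.93
        ((0.05, 34481, 2535, 0.30), 60),    # array-scale inputs
        ((0.999999, 1, 1, 0.3), 0),
    ])
    def test_values(self, args, expected):
        assert ib.min_snp_threshold(*args) == expected

    def test_het_zero_rejected(self):
        with pytest.raises(ValueError):
            ib.min_snp_threshold(0.05, 100, 10, 0.0)


class TestDetect:
    def test_clean_homozygous_stretch(self):
        pos = 10_000 * np.arange(1, 201)          # span 1.99 Mb
        g = one_chrom_matrix(pos, np.zeros((1, 200)))
        segs = ib.detect_roh(g, ROHParams(L=60)).segments
        assert len(segs) == 1
        assert segs.iloc[0][["start_bp", "end_bp", "n_snps", "n_het"]].tolist() == \
            [10_000, 2_000_000, 200, 0]

    def test_single_het_tolerated_or_splitting(self):
        pos = 10_000 * np.arange(1, 201)
        codes = np.zeros((1, 200)); codes[0, 99] = 1
        g = one_chrom_matrix(pos, codes)
        seg1 = ib.detect_roh(g, ROHParams(L=60)).segments
        assert len(seg1) == 1 and seg1.iloc[0]["n_het"] == 1
        # with no het allowed, both sub-runs span < 1 Mb
        seg0 = ib.detect_roh(g, ROHParams(L=60, max_het_in_run=0)).segments
        assert seg0.empty

    def test_all_heterozygous_empty(self):
        pos = 10_000 * np.arange(1, 101)
        g = one_chrom_matrix(pos, np.ones((1, 100)))
        assert ib.detect_roh(g, ROHParams(L=20)).segments.empty

    def test_short_chromosome_skipped(self):
        pos = np.array([100, 200])
        g = one_chrom_matrix(pos, np.zeros((1, 2)))
        assert ib.detect_roh(g, ROHParams()).segments.empty

    def test_gap_splits_runs(self):
        # 120 SNPs at 20 kb, with a 2 Mb hole in the middle
        pos = np.concatenate([20_000 * np.arange(1, 61),
                              20_000 * np.arange(1, 61) + 3_200_000])
        g = one_chrom_matrix(pos, np.zeros((1, 120)))
        segs = ib.detect_roh(g, ROHParams(L=30)).segments
        assert len(segs) == 2
        assert (segs["n_snps"] == 60).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_oracle(self, seed):
        """Detector equals the brute-force enumerator on random dense,
        fully-called chromosomes (window phase non-binding)."""
        rng = np.random.default_rng(seed)
        params = ROHParams(L=25)
        for rep in range(60):
            pos, x = random_roh_fixture(rng)
            g = one_chrom_matrix(pos, x[None, :])
            got = ib.detect_roh(g, params).segments
            want = oracle_runs(pos, x, params)
            got_t = [tuple(r) for r in
                     got[["start_bp", "end_bp", "n_snps", "n_het"]].to_numpy()]
            assert got_t == want, f"seed {seed} rep {rep}"

    def test_nestedness_in_L(self):
        """Stricter minimum-SNP thresholds select a subset of segments, so
        per-animal F_ROH is monotone: F(60) <= F(30) <= F(15)."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            pos, x = random_roh_fixture(rng)
            g = one_chrom_matrix(pos, x[None, :])
            segs = {L: ib.detect_roh(g, ROHParams(L=L)).segments for L in (60, 30, 15)}
            sets = {L: set(map(tuple, segs[L][["start_bp", "end_bp"]].to_numpy()))
                    for L in segs}
            assert sets[60] <= sets[30] <= sets[15]


class TestFRoh:
    def test_simple_ratio_and_empty(self):
        pos = np.concatenate([[1_000_000, 101_000_000]])
        mk = pd.DataFrame({"chrom": 1, "pos": pos, "a1": "A", "a2": "B"})
        g = ib.GenotypeMatrix(["x"], mk, np.zeros((1, 2), dtype=np.int8))
        segs = ib.ROHSegmentSet(
            segments=pd.DataFrame(
                [("x", 1, 2_000_000, 4_000_000, 50, 0)],
                columns=["animal", "chrom", "start_bp", "end_bp", "n_snps", "n_het"],
            ),
            sample_ids=["x", "y"],
        )
        f = ib.f_roh(segs, g)
        assert f["x"] == pytest.approx(0.02)
        assert f["y"] == 0.0

    def test_genome_equals_coverage_weighted_chromosomal_mean(self, small_pipeline):
        res = small_pipeline
        genome = ib.f_roh(res.roh_segments, res.genotypes)
        per_chrom = ib.f_roh(res.roh_segments, res.genotypes, per_chromosome=True)
        from inbredscope.roh import chromosome_coverage
        cov = chromosome_coverage(res.genotypes).reindex(per_chrom.columns)
        recon = (per_chrom * cov.to_numpy()).sum(axis=1) / cov.sum()
        assert np.max(np.abs(genome - recon.reindex(genome.index))) <= 1e-12


class TestTruthRecall:
    def test_long_true_segments_recovered(self, small_pipeline):
        """True autozygous tracts of at least 2 Mb are recovered by the
        loosest detection panel (minimum run ~1.1 Mb): at least 95% of them
        are majority-covered by a detected segment of the same animal."""
        res = small_pipeline
        det = res.extras["roh_all_L"]["F_ROH_15"].segments
        truth = res.truth.segments
        big = truth[(truth.end_bp - truth.start_bp) >= 2_000_000]
        assert len(big) > 100
        covered = []
        det_g = {k: v for k, v in det.groupby(["animal", "chrom"])}
        for _, row in big.iterrows():
            d = det_g.get((row.animal, row.chrom))
            if d is None:
                covered.append(0.0)
                continue
            ov = np.maximum(
                0, np.minimum(d.end_bp, row.end_bp)
                - np.maximum(d.start_bp, row.start_bp)
            ).sum()
            covered.append(ov / (row.end_bp - row.start_bp))
        recall = np.mean(np.asarray(covered) >= 0.5)
        assert recall >= 0.95


class TestSpectrum:
    def test_single_segment_binning_and_empty(self):
        seg = ib.ROHSegmentSet(
            segments=pd.DataFrame(
                [("x", 1, 1_000_000, 3_000_000, 50, 0)],
                columns=["animal", "chrom", "start_bp", "end_bp", "n_snps", "n_het"],
            ),
            sample_ids=["x"],
        )
        counts = ib.roh_length_spectrum(seg, (1, 4, 8, np.inf))
        assert counts.tolist() == [1, 0, 0]
        empty = ib.ROHSegmentSet(segments=seg.segments.iloc[:0], sample_ids=[])
        assert ib.roh_length_spectrum(empty, (1, 4, 8, np.inf)).sum() == 0

    def test_matches_direct_recount(self, small_pipeline):
        segs = small_pipeline.roh_segments
        edges = (0, 2, 4, 8, np.inf)
        counts = ib.roh_length_spectrum(segs, edges)
        lengths = (segs.segments["end_bp"] - segs.segments["start_bp"]) / 1e6
        direct = [((lengths >= lo) & (lengths < hi)).sum()
                  for lo, hi in zip(edges[:-1], edges[1:])]
        assert counts.tolist() == direct
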