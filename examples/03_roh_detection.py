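"""Runs of homozygosity: minimum run length, detection and F_ROH.

Computes the false-positive-controlled minimum number of consecutive
homozygous SNPs L (at array scale it gives 60), detects ROH at three L
values on a simulated population, and prints the segment-length spectrum
and mean F_ROH per setting.  Looser L admits many short segments and
inflates F_ROH - exactly the ordering F_ROH(60) <= F_ROH(30) <= F_ROH(15).
"""

import inbredscope as ib
from inbredscope.roh import ROHParams

L_toy = ib.min_snp_threshold(alpha=0.05, n_s=1000, n_i=100, het=0.5)
L_array = ib.min_snp_threshold(alpha=0.05, n_s=34481, n_i=2535, het=0.30)
print(f"minimum run length L: toy panel -> {L_toy}, array scale -> {L_array}")

cfg = ib.SimConfig(seed=5, n_founders=40, n_generations=7,
                   n_chromosomes=8, markers_per_chromosome=300)
sim = ib.simulate_pedigree(cfg)
g, truth = ib.gene_drop(sim.pedigree, cfg)

for L in (60, 30, 15):
    segs = ib.detect_roh(g, ROHParams(L=L))
    froh = ib.f_roh(segs, g)
    spectrum = ib.roh_length_spectrum(segs, (0, 2, 4, 8, 16, float("inf")))
    print(f"\nL = {L}: {len(segs.segments)} segments, mean F_ROH = {froh.mean():.3f}")
    print("  length spectrum (Mb):", {k: int(v) for k, v in spectrum.items()})
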