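# Methods

This note records the models, the conventions behind every tunable
parameter, and the design decisions taken where the methodology left
choices open.

## Inbreeding coefficients

**Pedigree (`F_PED`).**  The Meuwissen–Luo algorithm traces each animal's
ancestor set and evaluates `1 + F_i = Σ_a L²_a D_a`, where `L_a` is the
gene contribution of ancestor `a` and `D_a = ½ − ¼(F_s + F_d)` its
Mendelian segregation variance.  An animal with one known parent is
treated as having an unrelated, non-inbred unknown parent (`D = ¾ − ¼F` on
the known side; `D = 1` for founders) — the dominant convention when the
source is silent.  The numerator relationship matrix `A` is built by the
classical tabular recursion over the complete ancestor closure and then
restricted to any requested subset, so sub-matrices remain consistent with
the full pedigree.  `F_PED` is carried at full double precision; rounding
happens only at I/O, because the depression regressions are sensitive to
the covariate scale.

**Frequency-based (`F_GRM`, `F_UNI`, `F_HOM`).**  All three share one set
of second-allele frequencies `p_j`, taken from a caller-chosen reference
cohort meant to mimic the founder population (the pipeline default is the
earliest birth cohorts of the dataset; the window is configurable because
any choice of "first period" is somewhat arbitrary).  These estimators
measure homozygosity *relative to that reference*: animals less homozygous
than the reference expects come out negative.  Conventions where the
methodology is silent: missing genotypes are imputed to their expectation
`2p_j` in the GRM (zero contribution to `M`) and skipped in the per-animal
means of `F_UNI`/`F_HOM` (denominator = the animal's non-missing marker
count); markers monomorphic in the reference are excluded from all three
sums and from the GRM denominator, avoiding division by zero.

**Quality control.**  Markers are dropped for call rate < 0.95, minor
allele frequency < 0.01, or Hardy–Weinberg exact-test p < 1e-4 (defaults;
all configurable).  The HWE test enumerates heterozygote counts
conditional on the allele counts (no mid-p correction); a chi-square
approximation misbehaves exactly in the low-MAF tail where the threshold
operates.

**Runs of homozygosity (`F_ROH`).**  Detection is the two-phase sliding
window procedure with the seven-parameter panel standard for array data:
minimum run `L` SNPs, minimum span 1 Mb, density ≥ 1 SNP / 100 kb, maximum
inter-SNP gap 1 Mb, ≤ 1 heterozygote per run, window of 15 SNPs, window
threshold 0.05.  The window phase marks a SNP as passing when the fraction
of covering 15-SNP windows that are "eligible" (≤ 1 heterozygote, ≤ 1
missing call) exceeds 0.05.  The run phase splits maximal passing blocks
at gaps > 1 Mb, then left-to-right at every over-budget heterozygote (the
offending heterozygote joins neither piece), trims each piece to observed
homozygous endpoints, and keeps pieces meeting the count/span/density
thresholds.  Candidate pieces never depend on `L`; the minimum-SNP rule is
a final filter, which makes the segment set at a stricter `L` an exact
subset of the set at a looser one and `F_ROH` monotone in `L` per animal.
Missing calls inside a run neither break it nor count as heterozygous.
Segment coordinates are closed `[start_bp, end_bp]` at the first/last SNP;
lengths and chromosome coverages are both computed as `end − start`, so
`F_ROH` (total segment length over total SNP-covered autosome length) is a
ratio of like-defined quantities and the genome-wide value equals the
coverage-weighted mean of the chromosomal values identically.  The minimum
run length comes from `L = ln(α/(n_s n_i)) / ln(1 − het)` rounded to the
nearest integer (α = 0.05); at 34,481 SNPs × 2,535 individuals and mean
heterozygosity 0.30 this gives 60.  The mean heterozygosity is a required
input because it is a property of the data, not a constant.

**Homozygosity by descent (`F_HBD`).**  The hidden Markov model has K HBD
classes (default 10) plus one non-HBD class.  Class k's rate is `R_k = 2^k`
per Morgan — the doubling-rate layout conventional for multiple-class HBD
models — with the non-HBD class tied to the largest rate; segment lengths
are exponential, so small rates model long segments from recent common
ancestors.  Between markers `d` Morgans apart the chain stays with
probability `exp(−R_k d)` and otherwise re-enters a class drawn from the
individual's mixing weights π (the distance-dependent form of the
transition).  Emissions: non-HBD = Hardy–Weinberg probabilities at the
reference frequency; HBD = `(1−ε)`·(homozygote probabilities `1−p`, 0,
`p`) + `ε`·Hardy–Weinberg with genotyping-error rate ε = 0.001 (shared
across classes, configurable up to 0.1); missing genotypes are
uninformative.  Genetic distance uses 1 Mb = 1 cM when no genetic map is
supplied — the standard cattle-scale approximation.  Mixing weights are
estimated per individual by EM with rates fixed (stop at log-likelihood
gain < 1e-6 or 1,000 iterations); the complete-data view treats each
segment entry as a categorical draw from π, so the update is the expected
entry count per class and the likelihood is monotone.  Chromosomes are
concatenated into one chain with inter-chromosome stay probability 0,
which is exactly a restart from π.  Numerically the forward–backward pass
uses per-marker scaling with the log-likelihood accumulated from the scale
factors; the implementation is checked against exhaustive path enumeration
to 1e-9.  `F_HBD` weights each marker's total-HBD posterior by its
genome-length share (midpoint rule, half-intervals at chromosome ends),
because the quantity is a proportion of genome, not of markers.

## Inbreeding depression

The animal model `y = Xb + βF + Zu + e` with `u ~ N(0, Kσ²ᵤ)` is fitted by
Gibbs sampling.  Priors: flat on all location parameters; scaled inverse
chi-square with df 5 on each variance, scales set so the prior modes split
the phenotypic variance equally — conventional weakly-informative defaults
for this model class.  The additive effects are sampled in the eigenbasis
of `K` (diagonal full conditional), which requires one record per animal
(`Z = I` after alignment); the reproductive-trait setting this targets has
exactly one record per cow.  Eigenvalues below 1e-8 of the largest are treated as
null directions.  Default chain settings are 100,000 cycles, 50,000
burn-in, thinning 10; a reduced preset (5,000 / 2,500 / 5) is provided and
used for the seeded test runs — with the conjugate blocked updates the
effective sample size of β comfortably exceeds 200 there.  The fixed
design carries calf sex (2 levels), calving month (12), herd-year
contemporary groups, and centred linear + quadratic age-at-first-calving
covariates for the calving-difficulty and gestation-length traits;
age-at-first-calving records beyond ±3 SD and calving scores of 5 are
removed first.  The calving-difficulty score (ordinal 1–4) is modelled as
continuous, deliberately — no threshold model.  The chromosomal model
fits all 29 `β_i` jointly and refuses covariate pairs with |r| > 0.99,
since a joint fit cannot separate them.  Significance uses `t = β̂/PSD`
against standard-normal two-sided thresholds (1.959964, 2.575829); the
reference distribution is a choice, made explicit here, as no degrees of
freedom are implied by the posterior summary.  The regression of one
inbreeding coefficient on another reuses the same sampler without the
random effect — an assumption, since posterior SDs are wanted for those
slopes too.

## Synthetic data

The generator emulates a closed nucleus population under heavy sire
selection.  Discrete generations; each generation uses
`max(1, round(sire_fraction × males))` sires, and every female of the
previous generation produces `n_offspring` offspring of random sex.  The
scaled preset (`cattle_50k_small`) uses 60 founders, 8 generations, 2
offspring per dam and sire fraction 0.2 (~580 animals, mean pedigree
inbreeding ≈ 0.08 and realized autozygosity ≈ 0.09); the full preset
(`cattle_50k`) scales the same structure to 300 founders and 29 × 1,190
markers (~34.5k SNPs, ~2.7k animals) with sire fraction 0.04 so mean
inbreeding again sits near 0.09.  Markers are evenly spaced 75 kb apart
(the density of a 50k bovine array), founder frequencies are uniform on
[0.05, 0.95] (mean heterozygosity ≈ 0.33 among outbred animals),
genotyping error 0.001 and missingness 0.002.

Gene dropping assigns every founder haplotype a unique label; meioses
place crossovers as a Poisson process on the Morgan map (no crossover
interference — interference affects none of the identities being
validated).  An animal with an unknown parent receives a fresh founder
haplotype on that side, matching the pedigree convention.  Realized
autozygosity — the genome fraction where both haplotype labels agree — is
extracted *before* genotyping error and missingness are applied, so the
simulated truth is the estimand rather than the observation.  Phenotypes
follow `y = μ + fixed effects + β·(true autozygosity) + u + e`, with `u`
drawn by the pedigree Cholesky recursion (Mendelian variance
`(½ − ¼(F_s+F_d))σ²ᵤ`), randomly assigned factor levels, and optional
ordinal discretization for a calving-difficulty-like trait.  Everything is
bit-reproducible from (config, seed).

What the simulation does *not* emulate: linkage disequilibrium among
founders (founder alleles are drawn independently per marker), selection
on phenotype, genotyping-array ascertainment, imputation artefacts, or a
non-uniform recombination map.  Passing tests therefore demonstrate the
estimators' correctness and their calibration against realized IBD under
this generative model, not robustness to LD-driven false ROH or
imputation-induced homozygosity, which are properties of real array data.

## Problem sizes and numerical choices

Seeded validation runs use the scaled preset (~580 animals, 29 × 170
markers) and the reduced MCMC preset; these sizes are the package's choice
of a fixture that exercises every code path while keeping the whole
validation suite quick to run.  The HBD EM dominates runtime (a few
hundred EM iterations per animal over ~5k markers; the forward–backward
kernel is compiled with numba).  Mixed-model recovery checks use ~1,000
records, the scale at which a −2 effect is separated from zero by about
four posterior SDs.  Comparisons against closed-form oracles use
3-Monte-Carlo-SE bands (inflating by the chain's autocorrelation where
relevant); exact identities are asserted at 1e-9 to 1e-12.

## Known limitations

Only autosomes are handled; no phasing, imputation, or X-chromosome
logic.  The GRM is the VanRaden-1 form only.  `F_GRM`/`F_UNI` depend
strongly on the reference-cohort frequencies, which is intrinsic to those
estimators, not an implementation artefact — the panel analytics exist
precisely to make that visible.  The Gibbs sampler requires one record per
animal; repeated records would need a different sampling scheme for `u`.
Effective population size is not computed.
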