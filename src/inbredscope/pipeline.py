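"""End-to-end analysis on simulated data.

Chains the full comparative analysis: simulate a pedigree and gene-dropped
genotypes, compute every inbreeding coefficient (pedigree, GRM-based,
uniting-gametes, excess-homozygosity, three ROH variants, HBD), assemble
the comparison panel, and fit the inbreeding-depression mixed model on a
simulated trait.  Used by the example scripts, the acceptance runs and the
end-to-end tests; every step is also available individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparison, depression_lmm, hbd, marker_estimators, roh, synthetic_data
from .io_core import GenotypeMatrix, Pedigree
from .pedigree_kinship import f_ped, numerator_relationship_matrix


@dataclass
class PipelineResult:
    sim: synthetic_data.SimPedigree
    genotypes: GenotypeMatrix
    truth: synthetic_data.TrueIBD
    panel: pd.DataFrame
    L_formula: int
    qc_report: marker_estimators.QCReport
    roh_segments: roh.ROHSegmentSet
    froh_by_chrom: pd.DataFrame
    fhbd_by_chrom: pd.DataFrame
    depression: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def reference_cohort(sim: synthetic_data.SimPedigree, max_generation: int = 1) -> list[str]:
    """Animals of the earliest generations: the cohort whose allele
    frequencies mimic the founder population."""
    gens = sim.generation
    return [a for a in gens.index if gens[a] <= max_generation]


def run_pipeline(
    cfg: synthetic_data.SimConfig,
    trait_cfg: synthetic_data.TraitConfig | None = None,
    mcmc: tuple[int, int, int] = depression_lmm.TEST_MCMC,
    reference_max_generation: int = 1,
    fit_depression: bool = True,
    alpha: float = 0.05,
) -> PipelineResult:
    """Run the complete comparative analysis on one simulated population."""
    sim = synthetic_data.simulate_pedigree(cfg)
    ped = sim.pedigree
    g_raw, truth = synthetic_data.gene_drop(ped, cfg)
    g, qc_report = marker_estimators.qc_filter(g_raw)

    fped = f_ped(ped)

    ref_ids = reference_cohort(sim, reference_max_generation)
    freqs = marker_estimators.allele_frequencies(g, ref_ids)
    G = marker_estimators.grm_vanraden1(g, freqs)
    fgrm = marker_estimators.f_grm(G)
    funi = marker_estimators.f_uni(g, freqs)
    fhom = marker_estimators.f_hom(g, freqs)

    het = marker_estimators.mean_heterozygosity(g)
    L = roh.min_snp_threshold(alpha, g.n_markers, g.n_samples, het)
    segs = {}
    froh = {}
    for name, Lval in (("F_ROH", L), ("F_ROH_30", 30), ("F_ROH_15", 15)):
        segs[name] = roh.detect_roh(g, roh.ROHParams(L=Lval))
        froh[name] = roh.f_roh(segs[name], g).rename(name)
    froh_chrom = roh.f_roh(segs["F_ROH"], g, per_chromosome=True)

    post = hbd.compute_posteriors(g, freqs)

    fhbd = hbd.f_hbd(post).rename("F_HBD")
    fhbd_chrom = hbd.f_hbd(post, per_chromosome=True)

    years = pd.Series(ped.birth_year, index=ped.ids)
    panel = comparison.build_panel(
        {
            "F_PED": fped, "F_GRM": fgrm, "F_UNI": funi, "F_HOM": fhom,
            "F_ROH": froh["F_ROH"], "F_ROH_30": froh["F_ROH_30"],
            "F_ROH_15": froh["F_ROH_15"], "F_HBD": fhbd,
        },
        birth_years=years,
    )

    result = PipelineResult(
        sim=sim, genotypes=g, truth=truth, panel=panel, L_formula=L,
        qc_report=qc_report, roh_segments=segs["F_ROH"],
        froh_by_chrom=froh_chrom, fhbd_by_chrom=fhbd_chrom,
    )
    result.extras["G"] = G
    result.extras["freqs"] = freqs
    result.extras["het"] = het
    result.extras["hbd_posteriors"] = post
    result.extras["roh_all_L"] = segs
    result.extras["froh_all_L"] = froh

    if fit_depression:
        trait_cfg = trait_cfg or synthetic_data.TraitConfig()
        phen = synthetic_data.simulate_phenotypes(ped, truth, trait_cfg, seed=cfg.seed)
        result.extras["phenotypes"] = phen
        df, X, names = depression_lmm.build_design(phen, trait_cfg.trait)
        ids = df["id"].tolist()
        A = numerator_relationship_matrix(ped, subset=ids)
        spec = depression_lmm.LMMSpec(
            y=df["value"].to_numpy(), X=X,
            F=panel.loc[ids, "F_ROH"].to_numpy(),
            animal_ids=ids, fixed_names=names, f_names=["F_ROH"],
            trait=trait_cfg.trait,
        )
        result.depression["F_ROH"] = depression_lmm.gibbs_lmm(
            spec, A, mcmc=mcmc, seed=cfg.seed
        )
    return result
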