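"""Shared fixtures: seeded synthetic populations reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gasmgwas as gg
from gasmgwas.gwas import AssociationModel, GeneResult


def model_from_truth(sim, truth, gasms) -> AssociationModel:
    """Association model holding the generator's true allele effects.

    Marker alleles are matched to founder alleles by haplotype string; genes
    whose assembled alleles do not map one-to-one onto founders are skipped.
    """
    genes = []
    for marker in gasms:
        gid = marker.gene_id
        if gid not in truth.main_effects:
            continue
        founder = sim.founder_haps[gid]
        # skip genes whose rare alleles were merged: the marker partition no
        # longer maps one-to-one onto founder alleles
        realized = len(set(sim.assignment[gid]))
        if marker.n_alleles != realized:
            continue
        try:
            mapping = [founder.index(h) for h in marker.haplotype_strings]
        except ValueError:
            continue
        eff = truth.main_effects[gid][mapping]
        genes.append(
            GeneResult(
                gene_id=gid,
                chromosome=marker.chromosome,
                position=marker.start,
                allele_labels=list(marker.allele_labels),
                allele_freq=marker.allele_freq.copy(),
                main_effects=eff,
                gxe_effects=None,
                main_r2_pct=np.nan,
                gxe_r2_pct=np.nan,
                main_p=np.nan,
                gxe_p=np.nan,
            )
        )
    return AssociationModel(
        genes=genes,
        grand_mean=truth.grand_mean,
        h2=np.nan,
        threshold=np.nan,
        n_candidates=len(genes),
        env_labels=[],
    )


@pytest.fixture(scope="session")
def recovery_bundle():
    """300 accessions x 500 genes, 12 equal-variance causal genes, h2=0.9.

    The standing parameter-recovery scenario: every causal gene carries a
    true plot-level contribution of a few percent, well above detection."""
    cfg = gg.SimulationConfig(
        n_accessions=300,
        subpop_sizes={"ERA": 50, "ERB": 180, "ERC": 10, "ERD": 60},
        n_genes=500,
        n_causal=12,
        target_h2=0.9,
        effect_scale=0.03,
        gxe_fraction=0.25,
        gxe_scale=0.008,
        equalize_causal_variance=True,
        seed=11,
    )
    sim = gg.simulate_genotypes(cfg)
    truth = gg.make_true_model(sim, cfg)
    frame = gg.records_to_frame(gg.simulate_phenotypes(truth, sim, cfg))
    dec = gg.anova_components(frame)
    gasms = gg.build_gasm_set(sim.table, sim.genes)
    scan, model = gg.run_rtm_gwas(gasms, frame, dec.h2)
    return {
        "cfg": cfg, "sim": sim, "truth": truth, "frame": frame,
        "dec": dec, "gasms": gasms, "scan": scan, "model": model,
    }


@pytest.fixture(scope="session")
def nested_bundle():
    """Nested four-subpopulation panel with the generator's own effects as model."""
    cfg = gg.SimulationConfig(
        n_accessions=120,
        subpop_sizes={"ERA": 20, "ERB": 60, "ERC": 10, "ERD": 30},
        n_genes=40,
        n_causal=15,
        target_h2=0.95,
        effect_scale=0.02,
        gxe_fraction=0.2,
        emerged_fraction=0.25,
        seed=7,
    )
    sim = gg.simulate_genotypes(cfg)
    truth = gg.make_true_model(sim, cfg)
    gasms = gg.build_gasm_set(sim.table, sim.genes)
    model = model_from_truth(sim, truth, gasms)
    matrix = gg.build_matrix(model, gasms)
    return {"cfg": cfg, "sim": sim, "truth": truth, "gasms": gasms,
            "model": model, "matrix": matrix}


@pytest.fixture(scope="session")
def small_null_bundle():
    """Marker panel without any causal signal attached, for null calibration."""
    cfg = gg.SimulationConfig(
        n_accessions=150, subpop_sizes={"POP": 150}, n_genes=200,
        n_causal=5, target_h2=0.9, effect_scale=0.03, gxe_fraction=0.0, seed=5,
    )
    sim = gg.simulate_genotypes(cfg)
    gasms = gg.build_gasm_set(sim.table, sim.genes)
    struct = gg.allele_similarity(gasms, q=10)
    return {"cfg": cfg, "sim": sim, "gasms": gasms, "struct": struct}


def null_phenotypes(accessions, rng, n_envs=3, n_reps=3, mu=0.65, sd=0.05) -> pd.DataFrame:
    """Pure-noise plot-level phenotype frame."""
    rows = []
    vals = rng.normal(mu, sd, size=(len(accessions), n_envs * n_reps))
    for i, acc in enumerate(accessions):
        c = 0
        for e in range(n_envs):
            for r in range(n_reps):
                rows.append((acc, f"E{e + 1}", f"R{r + 1}", vals[i, c]))
                c += 1
    return pd.DataFrame(rows, columns=["accession", "environment", "replicate", "trait"])
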