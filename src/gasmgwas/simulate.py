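"""Synthetic germplasm generator.

Generates an inbred germplasm panel with the statistical structure the
downstream analysis assumes: genes laid out on chromosomes, each owning a
run of consecutive SNPs whose distinct founder haplotypes are the gene's
alleles; nested subpopulations (an ancestral pool, a derived pool enriched
with newly emerged alleles, and two sub-pools drawn with exclusions from the
derived pool); and a quantitative trait with additive multi-allelic main
effects, optional allele-by-environment effects, replicate effects and an
error variance solved so the entry-mean heritability hits its target in
expectation.

Defaults mirror the study conditions of a 361-accession northeast-China
soybean panel scored in 3 environments x 3 replicates; every size is
overridable for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ALT, HET, MISSING, REF, GeneModel, PhenotypeRecord, SnpGenotypeTable

_NUC = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


def _default_subpops() -> dict[str, int]:
    return {"ERA": 61, "ERB": 230, "ERC": 8, "ERD": 62}


@dataclass
class SimulationConfig:
    n_accessions: int = 361
    subpop_sizes: dict[str, int] = field(default_factory=_default_subpops)
    n_genes: int = 6503
    n_chromosomes: int = 20
    alleles_per_gene: tuple[int, int] = (2, 7)
    snps_per_gene: tuple[int, int] = (3, 6)
    n_causal: int = 132
    target_h2: float = 0.9843
    n_envs: int = 3
    n_reps: int = 3
    gxe_fraction: float = 35 / 132
    effect_scale: float = 0.012  # trait units per allele substitution
    gxe_scale: float = 0.004
    # rescale each causal gene's centered effects to a common realized
    # genotypic variance of effect_scale**2 (else raw i.i.d.-normal effects)
    equalize_causal_variance: bool = False
    grand_mean: float = 0.65
    env_sd: float = 0.02
    rep_sd: float = 0.005
    emerged_fraction: float = 0.12  # P(allele absent from the ancestral pool)
    excluded_fraction: dict[str, float] = field(
        default_factory=lambda: {"ERA": 0.12, "ERC": 0.40}
    )
    missing_rate: float = 0.0
    het_rate: float = 0.0
    overlap_fraction: float = 0.0  # fraction of genes given an overlapping decoy
    gene_spacing_bp: int = 20_000
    snp_spacing_bp: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subpop_sizes.values()) != self.n_accessions:
            raise ConfigError(
                f"subpopulation sizes sum to {sum(self.subpop_sizes.values())}, "
                f"expected n_accessions={self.n_accessions}"
            )
        if self.n_causal > self.n_genes:
            raise ConfigError("n_causal exceeds n_genes")
        if not 0 < self.target_h2 <= 1:
            raise ConfigError("target_h2 must be in (0, 1]")
        if self.alleles_per_gene[1] > 2 ** self.snps_per_gene[0]:
            raise ConfigError(
                f"up to {self.alleles_per_gene[1]} alleles cannot be encoded by "
                f"{self.snps_per_gene[0]} SNPs (haplotype space too small)"
            )


@dataclass
class SimulatedGenotypes:
    """Genotype bundle: the SNP table plus the generating truth."""

    table: SnpGenotypeTable
    genes: list[GeneModel]
    assignment: pd.DataFrame  # accessions x genes, 0-based founder-allele index
    subpops: pd.Series  # accession -> subpopulation label
    founder_freq: dict[str, np.ndarray]  # gene -> descending founder frequencies
    founder_haps: dict[str, list[str]]  # gene -> haplotype strings, freq order
    pools: dict[str, set]  # subpopulation -> {(gene_id, allele_idx)} designed pools


@dataclass
class TrueModel:
    """Generating-side trait model: per-causal-gene allele effects and variances."""

    grand_mean: float
    main_effects: dict[str, np.ndarray]  # causal gene -> (k,) freq-weighted zero-sum
    gxe_effects: dict[str, np.ndarray]  # subset of causal genes -> (k, n_envs) doubly centered
    sigma_g2: float
    sigma_ge2: float
    sigma_eps2: float

    def genotypic_values(self, assignment: pd.DataFrame) -> pd.Series:
        g = np.zeros(len(assignment))
        for gene, eff in self.main_effects.items():
            g += eff[assignment[gene].to_numpy()]
        return pd.Series(g, index=assignment.index)


def simulate_genotypes(config: SimulationConfig) -> SimulatedGenotypes:
    """Draw the genotype panel. Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    # accessions grouped by subpopulation, in declaration order
    acc_ids, subpop_of = [], []
    for sub, size in config.subpop_sizes.items():
        for i in range(size):
            acc_ids.append(f"{sub}_{i + 1:04d}")
            subpop_of.append(sub)
    subpops = pd.Series(subpop_of, index=acc_ids, name="subpopulation")
    n_acc = len(acc_ids)
    ancestral = "ERD"
    derived = "ERB"
    leaf_subs = [s for s in config.subpop_sizes if s not in (ancestral, derived)]

    genes: list[GeneModel] = []
    chroms, poss, refs, alts = [], [], [], []
    calls_cols: list[np.ndarray] = []
    assignment = np.empty((n_acc, config.n_genes), dtype=np.int16)
    founder_freq: dict[str, np.ndarray] = {}
    founder_haps: dict[str, list[str]] = {}
    pools: dict[str, set] = {s: set() for s in config.subpop_sizes}
    sub_masks = {s: (subpops == s).to_numpy() for s in config.subpop_sizes}

    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:05d}"
        chrom = f"Chr{gi // per_chrom + 1:02d}"
        within = gi % per_chrom
        s = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))
        k = int(rng.integers(config.alleles_per_gene[0], config.alleles_per_gene[1] + 1))
        k = min(k, 2**s)
        start = 1 + within * config.gene_spacing_bp
        snp_pos = start + np.arange(s) * config.snp_spacing_bp
        end = int(snp_pos[-1]) + 100
        genes.append(GeneModel(gene_id, chrom, start, end))

        # founder haplotypes: k distinct binary strings over the s SNPs
        hap_codes = rng.choice(2**s, size=k, replace=False)
        hap_bits = ((hap_codes[:, None] >> np.arange(s)) & 1).astype(np.int8)
        freq = np.sort(rng.dirichlet(np.ones(k)))[::-1]

        # subpopulation allele pools realizing the nesting:
        # derived pool = all alleles; ancestral pool lacks "emerged" alleles;
        # leaf pools are subsets of the derived pool
        present = {}
        if ancestral in config.subpop_sizes:
            present_anc = np.ones(k, dtype=bool)
            if k > 1:
                present_anc[1:] = rng.random(k - 1) >= config.emerged_fraction
            present[ancestral] = present_anc
        if derived in config.subpop_sizes:
            present[derived] = np.ones(k, dtype=bool)
        for sub in leaf_subs:
            p = np.ones(k, dtype=bool)
            if k > 1:
                p[1:] = rng.random(k - 1) >= config.excluded_fraction.get(sub, 0.0)
            present[sub] = p
        for sub, p in present.items():
            pools[sub].update((gene_id, int(a)) for a in np.flatnonzero(p))

        # accessions draw alleles with pool-restricted, renormalized frequencies
        gene_assign = np.empty(n_acc, dtype=np.int16)
        for sub, mask in sub_masks.items():
            p = freq * present[sub]
            p = p / p.sum()
            gene_assign[mask] = rng.choice(k, size=mask.sum(), p=p)
        assignment[:, gi] = gene_assign

        # SNP letters
        gene_ref, gene_alt = [], []
        for j in range(s):
            ref, alt = rng.choice(4, size=2, replace=False)
            chroms.append(chrom)
            poss.append(int(snp_pos[j]))
            refs.append(_NUC[ref])
            alts.append(_NUC[alt])
            gene_ref.append(_NUC[ref])
            gene_alt.append(_NUC[alt])
            col = np.where(hap_bits[gene_assign, j] == 0, REF, ALT).astype(np.int8)
            calls_cols.append(col)

        founder_freq[gene_id] = freq
        founder_haps[gene_id] = [
            "".join(gene_ref[j] if row[j] == 0 else gene_alt[j] for j in range(s))
            for row in hap_bits
        ]
    calls = np.stack(calls_cols, axis=1)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})

    # noise: missing / heterozygous calls
    if config.missing_rate > 0:
        m = rng.random(calls.shape) < config.missing_rate
        calls[m] = MISSING
    if config.het_rate > 0:
        h = rng.random(calls.shape) < config.het_rate
        calls[h & (calls != MISSING)] = HET

    table = SnpGenotypeTable(acc_ids, sites, calls)
    assign_df = pd.DataFrame(assignment, index=acc_ids, columns=[g.gene_id for g in genes])

    # overlapping decoy genes exercising overlap resolution (decoys are
    # shorter and nested, so the longer original always survives)
    if config.overlap_fraction > 0:
        n_decoys = int(round(config.overlap_fraction * len(genes)))
        targets = rng.choice(len(genes), size=n_decoys, replace=False)
        decoys = [
            GeneModel(f"{genes[t].gene_id}_ov", genes[t].chromosome,
                      genes[t].start + 10, genes[t].end - 10)
            for t in targets
            if genes[t].end - genes[t].start > 40
        ]
        genes = sorted(genes + decoys, key=lambda g: (g.chromosome, g.start))

    return SimulatedGenotypes(
        table=table,
        genes=genes,
        assignment=assign_df,
        subpops=subpops,
        founder_freq=founder_freq,
        founder_haps=founder_haps,
        pools=pools,
    )


def make_true_model(
    sim: SimulatedGenotypes, config: SimulationConfig, causal_genes: list[str] | None = None
) -> TrueModel:
    """Assign allele effects to causal genes and solve the error variance.

    Main effects are i.i.d. normal then centered to frequency-weighted
    zero-sum (realized frequencies); allele x environment effects are
    doubly centered.  The error variance is set so the plug-in entry-mean
    heritability equals ``target_h2`` for the realized genetic variances.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = list(sim.assignment.columns)
    if causal_genes is None:
        if config.n_causal == 0:
            raise ConfigError("target_h2 unreachable with no causal genes (sigma_g2 = 0)")
        causal_genes = [gene_ids[i] for i in
                        sorted(rng.choice(len(gene_ids), size=config.n_causal, replace=False))]
    n_acc = len(sim.assignment)

    main_effects: dict[str, np.ndarray] = {}
    for gene in causal_genes:
        idx = sim.assignment[gene].to_numpy()
        k = len(sim.founder_freq[gene])
        freq = np.bincount(idx, minlength=k) / n_acc
        eff = rng.normal(0.0, config.effect_scale, size=k)
        eff -= freq @ eff
        if config.equalize_causal_variance:
            v = np.var(eff[idx])
            if v > 0:
                eff *= config.effect_scale / np.sqrt(v)
        main_effects[gene] = eff

    n_gxe = int(round(config.gxe_fraction * len(causal_genes)))
    gxe_genes = [causal_genes[i] for i in
                 sorted(rng.choice(len(causal_genes), size=n_gxe, replace=False))]
    gxe_effects: dict[str, np.ndarray] = {}
    for gene in gxe_genes:
        k = len(sim.founder_freq[gene])
        m = rng.normal(0.0, config.gxe_scale, size=(k, config.n_envs))
        m = m - m.mean(axis=0, keepdims=True) - m.mean(axis=1, keepdims=True) + m.mean()
        gxe_effects[gene] = m

    g = np.zeros(n_acc)
    for gene, eff in main_effects.items():
        g += eff[sim.assignment[gene].to_numpy()]
    ge = np.zeros((n_acc, config.n_envs))
    for gene, m in gxe_effects.items():
        ge += m[sim.assignment[gene].to_numpy(), :]
    sigma_g2 = float(np.var(g))
    sigma_ge2 = float(np.var(ge))
    if sigma_g2 == 0:
        raise ConfigError("target_h2 unreachable: realized genetic variance is zero")
    n, r = config.n_envs, config.n_reps
    sigma_eps2 = r * n * (sigma_g2 * (1.0 / config.target_h2 - 1.0) - sigma_ge2 / n)
    if sigma_eps2 < -1e-12:
        raise ConfigError(
            f"target_h2={config.target_h2} unreachable: G x E variance {sigma_ge2:.3g} "
            f"already exceeds the allowed non-genetic share"
        )
    return TrueModel(
        grand_mean=config.grand_mean,
        main_effects=main_effects,
        gxe_effects=gxe_effects,
        sigma_g2=sigma_g2,
        sigma_ge2=sigma_ge2,
        sigma_eps2=max(sigma_eps2, 0.0),
    )


def simulate_phenotypes(
    truth: TrueModel, sim: SimulatedGenotypes, config: SimulationConfig
) -> list[PhenotypeRecord]:
    """Plot-level phenotypes under the generating model (seeded by config)."""
    rng = np.random.default_rng(config.seed + 2)
    accs = list(sim.assignment.index)
    if set(accs) != set(sim.subpops.index):
        raise ConfigError("assignment does not cover all accessions")
    n_acc = len(accs)
    g = truth.genotypic_values(sim.assignment).to_numpy()
    ge = np.zeros((n_acc, config.n_envs))
    for gene, m in truth.gxe_effects.items():
        ge += m[sim.assignment[gene].to_numpy(), :]
    env_eff = rng.normal(0.0, config.env_sd, size=config.n_envs)
    rep_eff = rng.normal(0.0, config.rep_sd, size=(config.n_envs, config.n_reps))
    eps_sd = np.sqrt(truth.sigma_eps2)
    records = []
    for j in range(config.n_envs):
        env = f"E{j + 1}"
        for k in range(config.n_reps):
            rep = f"R{k + 1}"
            eps = rng.normal(0.0, eps_sd, size=n_acc) if eps_sd > 0 else np.zeros(n_acc)
            y = truth.grand_mean + g + env_eff[j] + ge[:, j] + rep_eff[j, k] + eps
            for i, acc in enumerate(accs):
                records.append(
                    PhenotypeRecord(acc, env, rep, trait_value=max(float(y[i]), 0.0))
                )
    return records


# --- plain-text writers for the simulated bundle ---------------------------

_GT = {REF: "0/0", ALT: "1/1", HET: "0/1", MISSING: "./."}


def write_vcf(table: SnpGenotypeTable, path: str) -> None:
    """Minimal VCF 4.2 writer for the synthetic genotype table (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in table.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.accession_ids) + "\n")
        for j, row in enumerate(table.sites.itertuples(index=False)):
            gts = "\t".join(_GT[c] for c in table.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_gff3(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chromosome}\tsim\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n")


def write_phenotypes(records: list[PhenotypeRecord], path: str) -> None:
    rows = [(r.accession, r.environment, r.replicate, r.trait_value) for r in records]
    pd.DataFrame(rows, columns=["accession", "environment", "replicate", "trait"]).to_csv(
        path, sep="\t", index=False
    )


def write_subpops(subpops: pd.Series, path: str) -> None:
    subpops.rename_axis("accession").reset_index().to_csv(path, sep="\t", index=False)


def write_truth(truth: TrueModel, path: str) -> None:
    rows = []
    for gene, eff in truth.main_effects.items():
        for a, e in enumerate(eff):
            rows.append((gene, f"a{a + 1}", e))
    pd.DataFrame(rows, columns=["gene_id", "allele_label", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def default_genetic_map(genes: list[GeneModel], rate_cm_per_mb: float = 1.0) -> pd.DataFrame:
    """Uniform-rate map over the simulated gene positions."""
    rows = [(g.chromosome, g.start, g.start * rate_cm_per_mb / 1e6) for g in genes]
    return pd.DataFrame(rows, columns=["chromosome", "position_bp", "position_cM"])
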