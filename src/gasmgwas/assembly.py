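"""Assembly of multi-allelic gene-allele sequence markers (GASMs).

SNPs are filtered (missingness, heterozygosity, MAF), missing/het calls are
mode-imputed, overlapping genes are resolved in favour of the longer gene,
and the SNP alleles inside each retained gene are concatenated into
haplotype strings whose distinct values are the marker's alleles.  Rare
haplotypes (below a frequency threshold) are merged into the most frequent
one; genes left with fewer than two alleles carry no marker.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ALT, HET, MISSING, REF, GeneModel, SnpGenotypeTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    max_missing: float = 0.20
    max_het: float = 0.20
    min_maf: float = 0.01
    merge_threshold: float = 0.01

    def __post_init__(self) -> None:
        for name in ("max_missing", "max_het", "min_maf", "merge_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GasmMarker:
    """One gene's multi-allelic haplotype marker.

    Alleles are labelled a1..ak in descending frequency order;
    ``allele_of`` maps accession -> 0-based allele index.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    allele_labels: list[str]
    allele_of: pd.Series
    allele_freq: np.ndarray
    haplotype_strings: list[str]

    @property
    def n_alleles(self) -> int:
        return len(self.allele_labels)

    def validate(self, merge_threshold: float | None = None) -> None:
        k = self.n_alleles
        assert k >= 2, f"{self.gene_id}: marker needs >= 2 alleles"
        assert abs(self.allele_freq.sum() - 1.0) < 1e-9
        assert len(self.haplotype_strings) == k
        counts = np.bincount(self.allele_of.to_numpy(), minlength=k)
        assert counts.sum() == len(self.allele_of)
        if merge_threshold is not None:
            assert (self.allele_freq >= merge_threshold - 1e-12).all()


@dataclass
class GasmSet:
    markers: list[GasmMarker]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_alleles(self) -> int:
        return sum(m.n_alleles for m in self.markers)

    @property
    def mean_alleles_per_marker(self) -> float:
        return self.n_alleles / self.n_markers if self.markers else float("nan")

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, gene_id: str) -> GasmMarker:
        for m in self.markers:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)


def filter_snps(table: SnpGenotypeTable, params: FilterParams = FilterParams()) -> SnpGenotypeTable:
    """Remove sites failing the missingness, heterozygosity or MAF filters.

    MAF is computed from non-missing homozygous calls only (het calls are
    treated as missing for the frequency); the MAF bound is inclusive
    (a site at exactly ``min_maf`` is kept).
    """
    calls = table.calls
    n = table.n_accessions
    miss_frac = (calls == MISSING).mean(axis=0)
    het_frac = (calls == HET).mean(axis=0)
    n_ref = (calls == REF).sum(axis=0)
    n_alt = (calls == ALT).sum(axis=0)
    denom = np.maximum(n_ref + n_alt, 1)
    maf = np.minimum(n_ref, n_alt) / denom
    keep = (miss_frac <= params.max_missing) & (het_frac <= params.max_het) & (maf >= params.min_maf)
    if not keep.any():
        warnings.warn("all SNP sites removed by filtering", stacklevel=2)
    log.info("filter_snps: kept %d of %d sites", int(keep.sum()), len(keep))
    return SnpGenotypeTable(
        table.accession_ids,
        table.sites.loc[keep].reset_index(drop=True),
        calls[:, keep],
    )


def impute_missing(table: SnpGenotypeTable) -> SnpGenotypeTable:
    """Replace MISSING and HET calls by the site's majority homozygote (ties -> REF)."""
    calls = table.calls.copy()
    n_ref = (calls == REF).sum(axis=0)
    n_alt = (calls == ALT).sum(axis=0)
    fill = np.where(n_alt > n_ref, ALT, REF).astype(np.int8)
    mask = (calls == MISSING) | (calls == HET)
    calls[mask] = np.broadcast_to(fill, calls.shape)[mask]
    return SnpGenotypeTable(table.accession_ids, table.sites.copy(), calls)


def resolve_gene_overlaps(genes: list[GeneModel]) -> list[GeneModel]:
    """Among overlapping genes on a chromosome keep only the longer one.

    Equal lengths keep the smaller start.  Elimination is applied pairwise
    and transitively until no overlaps remain.
    """
    survivors = list(genes)
    changed = True
    while changed:
        changed = False
        survivors.sort(key=lambda g: (g.chromosome, g.start, g.end))
        for i in range(len(survivors) - 1):
            a, b = survivors[i], survivors[i + 1]
            if a.overlaps(b):
                if (a.length, -a.start) >= (b.length, -b.start):
                    survivors.pop(i + 1)
                else:
                    survivors.pop(i)
                changed = True
                break
    return survivors


def assemble_gene_haplotypes(table: SnpGenotypeTable, gene: GeneModel) -> GasmMarker | None:
    """Concatenate each accession's SNP alleles within the gene into a
    haplotype string; distinct strings are the raw alleles.

    Returns ``None`` for genes spanning no retained SNPs or with a single
    distinct haplotype (monomorphic genes carry no marker).  Expects an
    imputed table (no MISSING/HET calls).
    """
    in_gene = (
        (table.sites["chrom"] == gene.chromosome)
        & (table.sites["pos"] >= gene.start)
        & (table.sites["pos"] <= gene.end)
    ).to_numpy()
    if not in_gene.any():
        return None
    sub = table.calls[:, in_gene]
    if ((sub == MISSING) | (sub == HET)).any():
        raise ValueError(f"gene {gene.gene_id}: assemble requires an imputed table")
    ref = table.sites.loc[in_gene, "ref"].to_numpy()
    alt = table.sites.loc[in_gene, "alt"].to_numpy()
    letters = np.where(sub == REF, ref, alt)
    haps = np.array(["".join(row) for row in letters])
    uniq, inverse, counts = np.unique(haps, return_inverse=True, return_counts=True)
    if len(uniq) < 2:
        return None
    # rank by descending frequency, ties broken lexicographically by string
    order = np.lexsort((uniq, -counts))
    rank_of = np.empty(len(uniq), dtype=int)
    rank_of[order] = np.arange(len(uniq))
    idx = rank_of[inverse]
    freqs = counts[order] / len(haps)
    return GasmMarker(
        gene_id=gene.gene_id,
        chromosome=gene.chromosome,
        start=gene.start,
        end=gene.end,
        allele_labels=[f"a{i + 1}" for i in range(len(uniq))],
        allele_of=pd.Series(idx, index=table.accession_ids),
        allele_freq=freqs,
        haplotype_strings=[str(s) for s in uniq[order]],
    )


def merge_rare_alleles(
    marker: GasmMarker, merge_threshold: float = 0.01, nearest: bool = False
) -> GasmMarker | None:
    """Reassign carriers of alleles below ``merge_threshold``.

    By default rare carriers move to the gene's single most frequent allele;
    with ``nearest=True`` they move to the retained allele with the smallest
    Hamming distance to their haplotype (ties to the more frequent).  If
    fewer than two alleles remain the marker is dropped.
    """
    freq = marker.allele_freq
    rare = freq < merge_threshold
    if not rare.any():
        return marker
    keep_idx = np.flatnonzero(~rare)
    if len(keep_idx) < 2:
        return None
    idx = marker.allele_of.to_numpy().copy()
    if nearest:
        targets = {}
        for r in np.flatnonzero(rare):
            hs = marker.haplotype_strings[r]
            dists = [
                sum(c1 != c2 for c1, c2 in zip(hs, marker.haplotype_strings[k]))
                for k in keep_idx
            ]
            targets[r] = keep_idx[int(np.argmin(dists))]  # keep_idx is freq-ordered
        for r, t in targets.items():
            idx[idx == r] = t
    else:
        idx[np.isin(idx, np.flatnonzero(rare))] = 0  # index 0 = most frequent allele
    # recompute frequencies over surviving alleles and re-rank
    counts = np.bincount(idx, minlength=marker.n_alleles)[keep_idx]
    order = np.lexsort((np.array(marker.haplotype_strings, dtype=object)[keep_idx], -counts))
    new_old = keep_idx[order]
    remap = {old: new for new, old in enumerate(new_old)}
    new_idx = np.array([remap[i] for i in idx])
    new_counts = counts[order]
    return GasmMarker(
        gene_id=marker.gene_id,
        chromosome=marker.chromosome,
        start=marker.start,
        end=marker.end,
        allele_labels=[f"a{i + 1}" for i in range(len(new_old))],
        allele_of=pd.Series(new_idx, index=marker.allele_of.index),
        allele_freq=new_counts / new_counts.sum(),
        haplotype_strings=[marker.haplotype_strings[i] for i in new_old],
    )


def build_gasm_set(
    table: SnpGenotypeTable,
    genes: list[GeneModel],
    params: FilterParams = FilterParams(),
) -> GasmSet:
    """Full pipeline: filter -> impute -> overlap-resolve -> assemble -> merge."""
    filtered = filter_snps(table, params)
    imputed = impute_missing(filtered)
    resolved = resolve_gene_overlaps(genes)
    log.info("build_gasm_set: %d genes after overlap resolution (from %d)", len(resolved), len(genes))
    markers = []
    for gene in resolved:
        raw = assemble_gene_haplotypes(imputed, gene)
        if raw is None:
            continue
        merged = merge_rare_alleles(raw, params.merge_threshold)
        if merged is not None:
            markers.append(merged)
    out = GasmSet(markers)
    log.info(
        "build_gasm_set: %d markers, %d alleles (mean %.2f per marker)",
        out.n_markers, out.n_alleles, out.mean_alleles_per_marker,
    )
    return out


def gasm_set_to_frames(gasms: GasmSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format marker table and accession-assignment companion table."""
    rows, assign = [], []
    for m in gasms:
        for i, lab in enumerate(m.allele_labels):
            rows.append((m.gene_id, m.chromosome, m.start, m.end, lab,
                         m.allele_freq[i], m.haplotype_strings[i]))
        for acc, i in m.allele_of.items():
            assign.append((m.gene_id, acc, m.allele_labels[i]))
    markers = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "allele_label",
                       "frequency", "haplotype_string"])
    assignment = pd.DataFrame(assign, columns=["gene_id", "accession", "allele_label"])
    return markers, assignment
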