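"""Readers and writers for the pipeline's standard formats.

Genotypes come in as VCF (GT field only), gene annotations as GFF3 or BED4,
phenotypes and subpopulation labels as headered TSV.  All genomic coordinates
are held 1-based inclusive internally; BED input is converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# call codes for SnpGenotypeTable.calls
REF, ALT, HET, MISSING = 0, 1, 2, 3

CALL_NAMES = {REF: "REF", ALT: "ALT", HET: "HET", MISSING: "MISSING"}


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class InputError(ValueError):
    """A file is well-formed but its content violates a precondition."""


@dataclass
class SnpGenotypeTable:
    """Accessions x biallelic SNP sites with homozygous/het/missing calls.

    ``calls`` is an int8 array of shape (n_accessions, n_sites) holding the
    codes REF/ALT/HET/MISSING.  ``sites`` has columns chrom, pos, ref, alt
    with 1-based positions, strictly increasing within a chromosome.
    """

    accession_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise InputError("duplicate accession ids")
        if self.calls.shape != (len(self.accession_ids), len(self.sites)):
            raise InputError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.sites)} sites"
            )
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise InputError(f"positions not strictly increasing on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def equals(self, other: "SnpGenotypeTable") -> bool:
        return (
            self.accession_ids == other.accession_ids
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene interval, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GeneModel") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    """One plot observation: either both dry weights or a precomputed trait value."""

    accession: str
    environment: str
    replicate: str
    treatment_dry_weight: float | None = None
    control_dry_weight: float | None = None
    trait_value: float | None = None

    def __post_init__(self) -> None:
        has_weights = self.treatment_dry_weight is not None and self.control_dry_weight is not None
        if not has_weights and self.trait_value is None:
            raise InputError(
                f"record {(self.accession, self.environment, self.replicate)}: "
                "needs both dry weights or a trait value"
            )
        if has_weights and self.control_dry_weight <= 0:
            raise InputError(
                f"record {(self.accession, self.environment, self.replicate)}: "
                f"control dry weight must be > 0, got {self.control_dry_weight}"
            )
        if self.trait_value is not None and self.trait_value < 0:
            raise InputError("trait value must be >= 0")


def read_vcf(path: str) -> SnpGenotypeTable:
    """Read a VCF into a SnpGenotypeTable.

    Homozygous reference -> REF, homozygous alternate -> ALT, heterozygous ->
    HET, no-call -> MISSING.  Sites with more than one ALT allele are dropped
    (the pipeline is biallelic-SNP based) and the drop count is logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if "GT" not in (vcf.raw_header or ""):
        vcf.close()
        raise FormatError(f"{path}: no GT field in header")
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        vcf.close()
        raise InputError(f"{path}: duplicate sample ids")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    code = np.array([REF, HET, ALT, MISSING], dtype=np.int8)  # gts012 order
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        cols.append(code[np.asarray(v.gt_types)])
    vcf.close()
    if n_multi:
        log.info("%s: dropped %d multi-allelic site(s)", path, n_multi)
    if not cols:
        warnings.warn(f"{path}: VCF has no usable biallelic sites", stacklevel=2)
        calls = np.empty((len(samples), 0), dtype=np.int8)
    else:
        calls = np.stack(cols, axis=1)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    return SnpGenotypeTable(samples, sites, calls)


def read_gene_annotation(path: str, format: str = "GFF3") -> list[GeneModel]:
    """Read gene intervals from GFF3 (``gene``-type rows) or BED4.

    BED is 0-based half-open and converted to 1-based inclusive.  The result
    is sorted by (chromosome, start).
    """
    fmt = format.upper()
    genes: list[GeneModel] = []
    if fmt == "GFF3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
        )
        df = df[df["type"] == "gene"]
        for _, row in df.iterrows():
            gid = None
            for part in str(row["attrs"]).split(";"):
                k, _, val = part.partition("=")
                if k.strip() == "ID":
                    gid = val.strip()
                    break
            if gid is None:
                raise FormatError(f"{path}: gene row without ID attribute")
            genes.append(GeneModel(gid, row["seqid"], int(row["start"]), int(row["end"])))
    elif fmt == "BED":
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
        if df.shape[1] < 4:
            raise FormatError(f"{path}: BED4 requires 4 columns")
        for _, row in df.iterrows():
            genes.append(GeneModel(str(row[3]), str(row[0]), int(row[1]) + 1, int(row[2])))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def read_phenotype_table(path: str) -> list[PhenotypeRecord]:
    """Read the multi-environment replicated phenotype TSV.

    Expects columns accession, environment, replicate plus either
    (treatment_dw, control_dw) or trait.  Duplicated
    (accession, environment, replicate) keys are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"accession", "environment", "replicate"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    has_weights = {"treatment_dw", "control_dw"}.issubset(df.columns)
    has_trait = "trait" in df.columns
    if not (has_weights or has_trait):
        raise FormatError(f"{path}: needs treatment_dw+control_dw or trait columns")
    keys = list(zip(df["accession"], df["environment"], df["replicate"]))
    seen: set = set()
    for k in keys:
        if k in seen:
            raise InputError(f"{path}: duplicate phenotype key {k}")
        seen.add(k)
    records = []
    for i, row in df.iterrows():
        tdw = cdw = trait = None
        if has_weights and pd.notna(row.get("treatment_dw")) and pd.notna(row.get("control_dw")):
            tdw, cdw = float(row["treatment_dw"]), float(row["control_dw"])
            if cdw == 0:
                raise InputError(f"{path} row {i}: control dry weight is zero")
        if has_trait and pd.notna(row.get("trait")):
            trait = float(row["trait"])
        records.append(
            PhenotypeRecord(
                str(row["accession"]), str(row["environment"]), str(row["replicate"]),
                treatment_dry_weight=tdw, control_dry_weight=cdw, trait_value=trait,
            )
        )
    return records


def read_subpopulation_labels(path: str) -> pd.Series:
    """Read accession -> subpopulation labels from TSV (columns accession, subpopulation)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "subpopulation"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns accession, subpopulation")
    if df["accession"].duplicated().any():
        raise InputError(f"{path}: duplicate accession labels")
    return pd.Series(df["subpopulation"].values, index=df["accession"].values, name="subpopulation")


def read_genetic_map(path: str) -> pd.DataFrame:
    """Read a genetic map TSV with columns chromosome, position_bp, position_cM."""
    df = pd.read_csv(path, sep="\t")
    needed = {"chromosome", "position_bp", "position_cM"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(needed)}")
    for chrom, grp in df.groupby("chromosome"):
        grp = grp.sort_values("position_bp")
        if np.any(np.diff(grp["position_cM"].to_numpy()) < 0):
            raise InputError(f"{path}: cM not non-decreasing in bp on {chrom}")
    return df


# --- gene-allele matrix TSV round-trip -------------------------------------
# Layout: gene_id, allele_label, effect, then one 0/1 column per accession.

def write_gene_allele_matrix(matrix, path: str) -> None:
    """Write a GeneAlleleMatrix losslessly to TSV."""
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", index=False)


def read_gene_allele_matrix(path: str):
    """Read a gene-allele matrix TSV written by :func:`write_gene_allele_matrix`."""
    from .allele_matrix import GeneAlleleMatrix

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    fixed = ["gene_id", "allele_label", "effect"]
    if list(df.columns[:3]) != fixed:
        raise FormatError(f"{path}: expected leading columns {fixed}, got {list(df.columns[:3])}")
    acc_cols = list(df.columns[3:])
    if len(df):
        carriage = df[acc_cols].to_numpy()
        bad = ~np.isin(carriage, (0, 1))
        if bad.any():
            raise FormatError(f"{path}: carriage entries must be 0/1")
    return GeneAlleleMatrix.from_frame(df)
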