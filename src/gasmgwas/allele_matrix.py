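"""Gene-allele carriage/effect matrix and allele-dynamics accounting.

The matrix is the compact genetic structure of the panel: one row per
(gene, allele) with its estimated main effect, one 0/1 column per
accession, each accession carrying exactly one allele per gene.  On top of
it: group profiles (positive/negative allele counts and effect sums),
subpopulation allele sets, inherited/emerged/excluded accounting between a
reference and a derived subpopulation, and 4-set Venn region counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .assembly import GasmSet
from .io import InputError


@dataclass
class GeneAlleleMatrix:
    rows: pd.DataFrame  # gene_id, allele_label, effect
    carriage: pd.DataFrame  # same row index; columns = accessions; 0/1

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.carriage):
            raise InputError("rows and carriage must align")
        if len(self.rows):
            per_gene = self.carriage.groupby(self.rows["gene_id"].values).sum()
            if not (per_gene == 1).all().all():
                raise InputError("each accession must carry exactly one allele per gene")

    @property
    def accessions(self) -> list[str]:
        return list(self.carriage.columns)

    @property
    def n_genes(self) -> int:
        return self.rows["gene_id"].nunique()

    def effect_sign(self) -> pd.Series:
        """'positive' for effect >= 0 (exact zeros flagged), else 'negative'."""
        sign = np.where(self.rows["effect"] >= 0, "positive", "negative")
        return pd.Series(sign, index=self.rows.index)

    def zero_effect_flags(self) -> pd.Series:
        return self.rows["effect"] == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.rows.reset_index(drop=True),
                          self.carriage.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAlleleMatrix":
        rows = df[["gene_id", "allele_label", "effect"]].copy()
        carriage = df.drop(columns=["gene_id", "allele_label", "effect"]).astype(np.int8)
        return cls(rows, carriage)

    def equals(self, other: "GeneAlleleMatrix") -> bool:
        return (
            self.rows.reset_index(drop=True).equals(other.rows.reset_index(drop=True))
            and list(self.carriage.columns) == list(other.carriage.columns)
            and np.array_equal(self.carriage.to_numpy(), other.carriage.to_numpy())
        )


def build_matrix(model, gasms: GasmSet) -> GeneAlleleMatrix:
    """Carriage from the GASM assignments, effects from the fitted model.

    Only genes with estimated main effects enter; alleles with effect
    exactly 0 are kept and flagged via :meth:`GeneAlleleMatrix.zero_effect_flags`.
    """
    rows, mats = [], []
    accs = None
    for g in model.genes:
        if g.main_effects is None:
            continue
        marker = gasms[g.gene_id]
        if accs is None:
            accs = list(marker.allele_of.index)
        idx = marker.allele_of.reindex(accs)
        if idx.isna().any():
            raise InputError(f"gene {g.gene_id}: accession missing from GASM assignments")
        idx = idx.to_numpy(int)
        for a, lab in enumerate(marker.allele_labels):
            rows.append((g.gene_id, lab, float(g.main_effects[a])))
            mats.append((idx == a).astype(np.int8))
    rows_df = pd.DataFrame(rows, columns=["gene_id", "allele_label", "effect"])
    carriage = pd.DataFrame(np.array(mats) if mats else np.empty((0, 0), np.int8),
                            columns=accs or [])
    return GeneAlleleMatrix(rows_df, carriage)


def group_profile(matrix: GeneAlleleMatrix, group: list[str]) -> dict:
    """Mean positive/negative carried-allele counts and effect sums over a group."""
    if not group:
        raise InputError("group is empty")
    unknown = set(group) - set(matrix.accessions)
    if unknown:
        raise InputError(f"unknown accessions: {sorted(unknown)[:5]}")
    eff = matrix.rows["effect"].to_numpy()
    pos = eff >= 0
    sub = matrix.carriage[group].to_numpy(bool)
    pos_counts = sub[pos].sum(axis=0)
    neg_counts = sub[~pos].sum(axis=0)
    pos_sums = (sub[pos] * eff[pos, None]).sum(axis=0)
    neg_sums = (sub[~pos] * eff[~pos, None]).sum(axis=0)
    return {
        "mean_positive_count": float(pos_counts.mean()),
        "mean_positive_effect_sum": float(pos_sums.mean()),
        "mean_negative_count": float(neg_counts.mean()),
        "mean_negative_effect_sum": float(neg_sums.mean()),
        "mean_negative_abs_effect_sum": float(np.abs(neg_sums).mean()),
    }


def subpopulation_allele_sets(matrix: GeneAlleleMatrix, labels: pd.Series) -> dict[str, set]:
    """Per subpopulation, the set of (gene_id, allele_label) carried by >= 1 member."""
    missing = set(matrix.accessions) - set(labels.index)
    if missing:
        raise InputError(f"accessions without subpopulation label: {sorted(missing)[:5]}")
    keys = list(zip(matrix.rows["gene_id"], matrix.rows["allele_label"]))
    out: dict[str, set] = {}
    for sub in sorted(labels.loc[matrix.accessions].unique()):
        members = [a for a in matrix.accessions if labels[a] == sub]
        carried = matrix.carriage[members].to_numpy().sum(axis=1) > 0
        out[sub] = {keys[i] for i in np.flatnonzero(carried)}
    return out


@dataclass
class AlleleChangeAccount:
    reference: str
    derived: str
    reference_total: int
    derived_total: int
    inherited: int
    emerged_or_introduced: int
    excluded: int
    reference_split: tuple[int, int] | None = None  # (negative, positive)
    derived_split: tuple[int, int] | None = None
    inherited_split: tuple[int, int] | None = None
    emerged_split: tuple[int, int] | None = None
    excluded_split: tuple[int, int] | None = None

    @property
    def changed(self) -> int:
        return self.emerged_or_introduced + self.excluded

    def check_identities(self) -> None:
        assert self.derived_total == self.inherited + self.emerged_or_introduced
        assert self.reference_total == self.inherited + self.excluded
        for total, split in (
            (self.reference_total, self.reference_split),
            (self.derived_total, self.derived_split),
            (self.inherited, self.inherited_split),
            (self.emerged_or_introduced, self.emerged_split),
            (self.excluded, self.excluded_split),
        ):
            if split is not None:
                assert sum(split) == total


def allele_change_account(
    reference_set: set,
    derived_set: set,
    effect_signs: dict | None = None,
    reference_label: str = "reference",
    derived_label: str = "derived",
) -> AlleleChangeAccount:
    """Inherited / emerged-or-introduced / excluded accounting between two sets.

    ``effect_signs`` maps allele key -> 'positive'/'negative'; when given,
    every counted quantity also carries its (negative, positive) split.
    """
    inherited = reference_set & derived_set
    emerged = derived_set - reference_set
    excluded = reference_set - derived_set

    def split(s: set) -> tuple[int, int] | None:
        if effect_signs is None:
            return None
        missing = [a for a in s if a not in effect_signs]
        if missing:
            raise InputError(f"alleles with unknown effect sign: {sorted(missing)[:5]}")
        neg = sum(1 for a in s if effect_signs[a] == "negative")
        return (neg, len(s) - neg)

    acct = AlleleChangeAccount(
        reference=reference_label,
        derived=derived_label,
        reference_total=len(reference_set),
        derived_total=len(derived_set),
        inherited=len(inherited),
        emerged_or_introduced=len(emerged),
        excluded=len(excluded),
        reference_split=split(reference_set),
        derived_split=split(derived_set),
        inherited_split=split(inherited),
        emerged_split=split(emerged),
        excluded_split=split(excluded),
    )
    acct.check_identities()
    return acct


def shared_allele_venn(sets: dict[str, set]) -> dict[frozenset, int]:
    """Region counts of the n-set Venn diagram (exclusive regions).

    Keys are the non-empty label subsets; each allele is counted in exactly
    the region of the labels whose sets contain it.
    """
    labels = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            outside = set.union(*(sets[c] for c in labels if c not in combo), set())
            out[frozenset(combo)] = len(inside - outside)
    return out


def account_table(accounts: list[AlleleChangeAccount]) -> pd.DataFrame:
    """Long-form table of accounts, one row per contrast."""
    rows = []
    for a in accounts:
        rows.append({
            "contrast": f"{a.derived} vs. {a.reference}",
            "derived_total": a.derived_total,
            "reference_total": a.reference_total,
            "inherited": a.inherited,
            "emerged_or_introduced": a.emerged_or_introduced,
            "excluded": a.excluded,
            "changed": a.changed,
        })
    return pd.DataFrame(rows)
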