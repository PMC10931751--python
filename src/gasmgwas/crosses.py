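"""In-silico biparental cross prediction over inbred (RIL) progenies.

For each unordered parent pair, fully inbred progenies are simulated
directly from the limiting recombinant-inbred-line distribution: per
chromosome, parental origin follows a Markov chain whose switch probability
between adjacent segregating loci is the RIL-adjusted recombination
fraction R = 2r / (1 + 2r), with r from Haldane's map function on the map
distance (default 1 cM/Mb when no genetic map is supplied).  A progeny's
genotypic value is the model grand mean plus the sum of carried main-effect
allele effects; the 75th percentile of the simulated progeny values (linear
interpolation between order statistics) is the cross's predicted value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .gwas import AssociationModel
from .io import InputError


class GeneticMap:
    """Monotone bp -> cM mapping per chromosome.

    With a map table (columns chromosome, position_bp, position_cM) the cM
    position is linearly interpolated inside the mapped range and clamped
    outside it; chromosomes without map rows fall back to the uniform
    default rate.
    """

    def __init__(self, table: pd.DataFrame | None = None, default_rate_cm_per_mb: float = 1.0):
        self.rate = default_rate_cm_per_mb
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if table is not None:
            for chrom, grp in table.groupby("chromosome"):
                grp = grp.sort_values("position_bp")
                bp = grp["position_bp"].to_numpy(float)
                cm = grp["position_cM"].to_numpy(float)
                if np.any(np.diff(cm) < 0):
                    raise InputError(f"map not monotone on {chrom}")
                self._chrom[str(chrom)] = (bp, cm)

    def cm(self, chromosome: str, pos_bp: float) -> float:
        if chromosome in self._chrom:
            bp, cm = self._chrom[chromosome]
            return float(np.interp(pos_bp, bp, cm))
        return pos_bp * self.rate / 1e6


def count_crosses(n_parents: int) -> int:
    """Number of unordered biparental crosses among n parents."""
    if n_parents < 0:
        raise ValueError("n_parents must be >= 0")
    return n_parents * (n_parents - 1) // 2


def haldane_r(d_cm: float | np.ndarray) -> np.ndarray:
    """Recombination fraction from map distance (Haldane)."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0)) / 2.0


def ril_recombination_fraction(d_cm: float | np.ndarray) -> np.ndarray:
    """Effective recombination fraction among fully inbred lines, R = 2r/(1+2r)."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class CrossPrediction:
    parent1: str
    parent2: str
    parent1_value: float
    parent2_value: float
    midparent: float
    n_progeny: int
    progeny_mean: float
    progeny_sd: float
    progeny_sd_pct: float  # SD as percent of the progeny mean
    percentile75: float
    exceeds_threshold: bool | None = None


def _cross_frame(model: AssociationModel, geno1: dict, geno2: dict):
    """Segregating loci (sorted by genome position) and their effect pairs."""
    base = model.grand_mean
    seg = []
    for g in sorted(
        (g for g in model.genes if g.main_effects is not None),
        key=lambda g: (g.chromosome, g.position),
    ):
        if g.gene_id not in geno1 or g.gene_id not in geno2:
            raise InputError(f"parent not genotyped at model gene {g.gene_id}")
        a1, a2 = geno1[g.gene_id], geno2[g.gene_id]
        e1, e2 = float(g.main_effects[a1]), float(g.main_effects[a2])
        if a1 == a2:
            base += e1
        else:
            seg.append((g.chromosome, g.position, e1, e2))
    return base, seg


def progeny_value(genotype: dict, model: AssociationModel) -> float:
    """Genotypic value: grand mean + carried main-effect allele effects.

    ``genotype`` maps gene_id -> allele index; G x E effects are excluded
    from prediction.
    """
    v = model.grand_mean
    for g in model.genes:
        if g.main_effects is None:
            continue
        if g.gene_id not in genotype:
            raise InputError(f"genotype missing model gene {g.gene_id}")
        v += float(g.main_effects[genotype[g.gene_id]])
    return v


def simulate_ril_progeny_values(
    model: AssociationModel,
    geno1: dict,
    geno2: dict,
    gmap: GeneticMap | None = None,
    n_progeny: int = 2000,
    assortment: str = "linkage",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Genotypic values of simulated fully inbred progenies.

    ``assortment='independent'``: each segregating locus inherits either
    parental allele with probability 1/2 independently.  ``'linkage'``: per
    chromosome a Markov chain over parental origin with switch probability
    R(adjacent map distance).  Non-segregating loci are fixed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gmap is None:
        gmap = GeneticMap()
    base, seg = _cross_frame(model, geno1, geno2)
    if not seg:
        return np.full(n_progeny, base)
    e1 = np.array([s[2] for s in seg])
    e2 = np.array([s[3] for s in seg])
    L = len(seg)
    if assortment == "independent":
        origin = rng.integers(0, 2, size=(n_progeny, L)).astype(bool)
    elif assortment == "linkage":
        origin = np.empty((n_progeny, L), dtype=bool)
        chroms = np.array([s[0] for s in seg])
        cm = np.array([gmap.cm(s[0], s[1]) for s in seg])
        start = 0
        for chrom in pd.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            lc = len(idx)
            block = np.empty((n_progeny, lc), dtype=bool)
            block[:, 0] = rng.integers(0, 2, size=n_progeny, dtype=np.int64).astype(bool)
            if lc > 1:
                R = ril_recombination_fraction(np.diff(cm[idx]))
                switches = rng.random((n_progeny, lc - 1)) < R
                block[:, 1:] = np.logical_xor.accumulate(
                    np.column_stack([block[:, 0], switches]), axis=1
                )[:, 1:]
            origin[:, idx] = block
            start += lc
    else:
        raise ValueError(f"unknown assortment model {assortment!r}")
    # origin False -> parent 1 allele, True -> parent 2 allele
    return base + e1.sum() + origin @ (e2 - e1)


def exact_progeny_distribution(
    model: AssociationModel, geno1: dict, geno2: dict, max_loci: int = 16
) -> np.ndarray:
    """All 2^k equally likely progeny values under independent assortment."""
    base, seg = _cross_frame(model, geno1, geno2)
    if len(seg) > max_loci:
        raise InputError(f"{len(seg)} segregating loci exceeds max_loci={max_loci}")
    vals = np.array([base + sum(s[2] for s in seg)])
    for _, _, ea, eb in seg:
        vals = np.concatenate([vals, vals + (eb - ea)])
    return np.sort(vals)


def predict_cross(
    p1: str,
    p2: str,
    model: AssociationModel,
    genotypes: dict[str, dict],
    gmap: GeneticMap | None = None,
    n_progeny: int = 2000,
    assortment: str = "linkage",
    seed: int | np.random.Generator = 0,
    ceiling: float | None = None,
) -> CrossPrediction:
    """Summarize the simulated progeny distribution of one cross."""
    vals = simulate_ril_progeny_values(
        model, genotypes[p1], genotypes[p2], gmap, n_progeny, assortment, seed
    )
    v1 = progeny_value(genotypes[p1], model)
    v2 = progeny_value(genotypes[p2], model)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    p75 = float(np.percentile(vals, 75))
    return CrossPrediction(
        parent1=p1,
        parent2=p2,
        parent1_value=v1,
        parent2_value=v2,
        midparent=(v1 + v2) / 2,
        n_progeny=len(vals),
        progeny_mean=mean,
        progeny_sd=sd,
        progeny_sd_pct=100.0 * sd / mean if mean else np.nan,
        percentile75=p75,
        exceeds_threshold=None if ceiling is None else bool(p75 > ceiling),
    )


def genotypes_from_gasms(gasms, model: AssociationModel) -> dict[str, dict]:
    """Per-accession gene_id -> allele index mapping for the model genes."""
    out: dict[str, dict] = {}
    for g in model.genes:
        if g.main_effects is None:
            continue
        marker = gasms[g.gene_id]
        for acc, idx in marker.allele_of.items():
            out.setdefault(acc, {})[g.gene_id] = int(idx)
    return out


def enumerate_crosses(
    genotypes: dict[str, dict],
    model: AssociationModel,
    gmap: GeneticMap | None = None,
    n_progeny: int = 2000,
    assortment: str = "linkage",
    seed: int = 0,
    ceiling: float | None = None,
    labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every unordered parent pair; rank by the 75th percentile.

    Returns (ranked predictions, per-population counts above the ceiling).
    Ties in the predicted value break by progeny mean, then parent ids.
    """
    rng = np.random.default_rng(seed)
    parents = sorted(genotypes)
    preds = []
    for p1, p2 in combinations(parents, 2):
        preds.append(predict_cross(p1, p2, model, genotypes, gmap, n_progeny,
                                   assortment, rng, ceiling))
    df = pd.DataFrame([vars(c) for c in preds])
    if len(df):
        df = df.sort_values(
            ["percentile75", "progeny_mean", "parent1", "parent2"],
            ascending=[False, False, True, True], kind="stable",
        ).reset_index(drop=True)
    groups = {"Total": set(parents)}
    if labels is not None:
        for sub in sorted(labels.unique()):
            groups[sub] = set(labels.index[labels == sub]) & set(parents)
    rows = []
    for name, members in groups.items():
        if len(df):
            mask = df["parent1"].isin(members) & df["parent2"].isin(members)
            sub = df[mask]
        else:
            sub = df
        n_above = int(sub["exceeds_threshold"].sum()) if ceiling is not None and len(sub) else 0
        rows.append({
            "population": name,
            "n_crosses": len(sub),
            "mean_p75": float(sub["percentile75"].mean()) if len(sub) else np.nan,
            "min_p75": float(sub["percentile75"].min()) if len(sub) else np.nan,
            "max_p75": float(sub["percentile75"].max()) if len(sub) else np.nan,
            "n_above_ceiling": n_above,
            "pct_above_ceiling": 100.0 * n_above / len(sub) if len(sub) else np.nan,
        })
    return df, pd.DataFrame(rows)
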