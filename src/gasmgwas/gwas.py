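"""Restricted two-stage multilocus association on multi-allelic gene markers.

Stage 1 screens every marker with a single-locus fixed-effects model
(environment, replicate-within-environment and eigenvector population
structure covariates included) and preselects markers at p <= alpha.
Stage 2 builds a multilocus model by stepwise forward selection and
backward elimination of per-gene main-effect and allele-by-environment
terms, with the entry threshold set to alpha/m (m = candidate count, the
single-locus Bonferroni analogue) and the cumulative main-effect genetic
contribution restricted to the experiment heritability.  Per-gene
contributions are partial (last-entry) R-squared values, and allele effects
are reported under a frequency-weighted zero-sum constraint so that
positive/negative allele counts are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import GasmMarker, GasmSet
from .io import InputError

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# population structure
# --------------------------------------------------------------------------

@dataclass
class StructureCovariates:
    similarity: pd.DataFrame  # accession x accession allele-sharing proportion
    eigenvalues: np.ndarray  # descending
    covariates: pd.DataFrame  # accession x q, eigenvector * sqrt(eigenvalue)


def allele_similarity(gasms: GasmSet, q: int = 10, chunk: int = 256) -> StructureCovariates:
    """Allele-sharing similarity and its top-q scaled eigenvectors.

    similarity(i, j) is the fraction of markers at which accessions i and j
    carry the same allele.  The similarity matrix is double-centered before
    eigen-decomposition; covariates are eigenvectors scaled by the square
    root of their (non-negative) eigenvalues.
    """
    if gasms.n_markers < 2:
        raise InputError("allele similarity needs >= 2 markers")
    accs = list(gasms.markers[0].allele_of.index)
    n = len(accs)
    if q > n:
        raise ConfigError(f"q={q} exceeds accession count {n}")
    A = np.stack([m.allele_of.to_numpy() for m in gasms.markers])
    S = np.zeros((n, n))
    for lo in range(0, A.shape[0], chunk):
        B = A[lo : lo + chunk]
        S += (B[:, :, None] == B[:, None, :]).sum(axis=0)
    S /= A.shape[0]
    C = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    cov = evecs[:, :q] * np.sqrt(np.clip(evals[:q], 0.0, None))
    return StructureCovariates(
        similarity=pd.DataFrame(S, index=accs, columns=accs),
        eigenvalues=evals,
        covariates=pd.DataFrame(cov, index=accs, columns=[f"pc{i+1}" for i in range(q)]),
    )


# --------------------------------------------------------------------------
# plot-level design matrices
# --------------------------------------------------------------------------

class PlotDesign:
    """Base fixed-effects design over plot-level records.

    Columns: intercept, environment contrasts, replicate-within-environment
    contrasts, and the structure covariates mapped to each plot's accession.
    """

    def __init__(self, pheno: pd.DataFrame, covariates: pd.DataFrame | None = None):
        df = pheno.sort_values(["accession", "environment", "replicate"], kind="stable")
        df = df.reset_index(drop=True)
        self.frame = df
        self.y = df["trait"].to_numpy(float)
        self.accessions = df["accession"].to_numpy()
        self.env_labels = sorted(df["environment"].unique())
        self.rep_labels = sorted(df["replicate"].unique())
        self.n_env = len(self.env_labels)
        env_code = pd.Categorical(df["environment"], categories=self.env_labels).codes
        rep_code = pd.Categorical(df["replicate"], categories=self.rep_labels).codes
        self.env_code = env_code
        N = len(df)
        cols = [np.ones(N)]
        for j in range(1, self.n_env):
            cols.append((env_code == j).astype(float))
        for j in range(self.n_env):
            for k in range(1, len(self.rep_labels)):
                cols.append(((env_code == j) & (rep_code == k)).astype(float))
        if covariates is not None:
            missing = set(self.accessions) - set(covariates.index)
            if missing:
                raise InputError(f"accessions without structure covariates: {sorted(missing)[:5]}")
            cols.extend(covariates.reindex(self.accessions).to_numpy(float).T)
        self.X0 = np.column_stack(cols)
        self.rank0 = np.linalg.matrix_rank(self.X0)
        self.tss = float(np.sum((self.y - self.y.mean()) ** 2))

    def main_columns(self, marker: GasmMarker) -> np.ndarray:
        """Allele-class indicators for alleles 2..k (treatment coding)."""
        idx = marker.allele_of.reindex(self.accessions)
        if idx.isna().any():
            raise InputError(f"marker {marker.gene_id}: accessions missing from genotypes")
        idx = idx.to_numpy(int)
        k = marker.n_alleles
        return (idx[:, None] == np.arange(1, k)[None, :]).astype(float)

    def gxe_columns(self, marker: GasmMarker) -> np.ndarray:
        """Allele x environment product contrasts (alleles 2..k, envs 2..n)."""
        D = self.main_columns(marker)
        out = []
        for j in range(1, self.n_env):
            ind = (self.env_code == j).astype(float)[:, None]
            out.append(D * ind)
        return np.hstack(out) if out else np.empty((len(self.y), 0))


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of min-norm least squares, with design rank."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), rank
    r = y - X @ beta
    return float(r @ r), rank


def _partial_f(rss_red: float, rank_red: int, rss_full: float, rank_full: int,
               n: int) -> tuple[float, float, int]:
    """F statistic and p for the block distinguishing two nested designs."""
    df1 = rank_full - rank_red
    df2 = n - rank_full
    if df1 <= 0 or df2 <= 0 or rss_full <= 0:
        return np.nan, 1.0, max(df1, 0)
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return f, float(stats.f.sf(f, df1, df2)), df1


# --------------------------------------------------------------------------
# stage 1: single-locus preselection
# --------------------------------------------------------------------------

@dataclass
class Stage1Scan:
    table: pd.DataFrame  # gene_id, F, p, r2_pct, untestable, preselected
    alpha: float

    @property
    def preselected(self) -> list[str]:
        return list(self.table.loc[self.table["preselected"], "gene_id"])


def stage1_preselect(
    gasms: GasmSet,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> Stage1Scan:
    """Per-marker single-locus F test against the base design; preselect p <= alpha."""
    design = PlotDesign(phenotypes, covariates)
    geno_accs = set(gasms.markers[0].allele_of.index) if gasms.markers else set()
    missing = set(design.accessions) - geno_accs
    if missing:
        raise InputError(f"phenotyped accessions without genotypes: {sorted(missing)[:5]}")
    Q0, _ = np.linalg.qr(design.X0)
    ry = design.y - Q0 @ (Q0.T @ design.y)
    rss0 = float(ry @ ry)
    n = len(design.y)
    rows = []
    for m in gasms.markers:
        D = design.main_columns(m)
        RD = D - Q0 @ (Q0.T @ D)
        beta, res, rank, _ = np.linalg.lstsq(RD, ry, rcond=None)
        if rank == 0:
            rows.append((m.gene_id, np.nan, np.nan, np.nan, True, False))
            continue
        r = ry - RD @ beta
        rss1 = float(r @ r)
        df2 = n - design.rank0 - rank
        f = ((rss0 - rss1) / rank) / (rss1 / df2)
        p = float(stats.f.sf(f, rank, df2))
        r2 = 100.0 * (rss0 - rss1) / design.tss
        rows.append((m.gene_id, f, p, r2, False, p <= alpha))
    table = pd.DataFrame(rows, columns=["gene_id", "F", "p", "r2_pct", "untestable", "preselected"])
    log.info("stage1: preselected %d of %d markers at p <= %g",
             int(table["preselected"].sum()), len(table), alpha)
    return Stage1Scan(table=table, alpha=alpha)


# --------------------------------------------------------------------------
# stage 2: stepwise multilocus model
# --------------------------------------------------------------------------

@dataclass
class GeneResult:
    gene_id: str
    chromosome: str
    position: int
    allele_labels: list[str]
    allele_freq: np.ndarray
    main_effects: np.ndarray | None  # (k,) frequency-weighted zero-sum, or None
    gxe_effects: np.ndarray | None  # (k, n_env) doubly centered, or None
    main_r2_pct: float
    gxe_r2_pct: float
    main_p: float
    gxe_p: float
    classification: str = ""


@dataclass
class AssociationModel:
    genes: list[GeneResult]
    grand_mean: float
    h2: float
    threshold: float
    n_candidates: int
    env_labels: list[str]
    model_r2_pct: float = np.nan
    summary: pd.DataFrame | None = None

    @property
    def cumulative_main_r2_pct(self) -> float:
        return float(sum(g.main_r2_pct for g in self.genes if g.main_effects is not None))

    @property
    def cumulative_gxe_r2_pct(self) -> float:
        return float(sum(g.gxe_r2_pct for g in self.genes if g.gxe_effects is not None))

    @property
    def unmapped_minor_pct(self) -> float:
        return 100.0 * self.h2 - self.cumulative_main_r2_pct

    def gene(self, gene_id: str) -> GeneResult:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


class _Selection:
    """Bookkeeping for the stepwise model: active terms and their columns."""

    def __init__(self, design: PlotDesign, markers: list[GasmMarker], include_gxe: bool):
        self.design = design
        self.markers = {m.gene_id: m for m in markers}
        self.order = {m.gene_id: i for i, m in enumerate(markers)}
        self.include_gxe = include_gxe
        self._main_cols: dict[str, np.ndarray] = {}
        self._gxe_cols: dict[str, np.ndarray] = {}
        self.active: dict[str, set] = {}  # gene_id -> subset of {"main", "gxe"}

    def main_cols(self, g: str) -> np.ndarray:
        if g not in self._main_cols:
            self._main_cols[g] = self.design.main_columns(self.markers[g])
        return self._main_cols[g]

    def gxe_cols(self, g: str) -> np.ndarray:
        if g not in self._gxe_cols:
            self._gxe_cols[g] = self.design.gxe_columns(self.markers[g])
        return self._gxe_cols[g]

    def term_cols(self, g: str, term: str) -> np.ndarray:
        return self.main_cols(g) if term == "main" else self.gxe_cols(g)

    def design_matrix(self, exclude: tuple[str, str] | None = None,
                      extra: list[np.ndarray] | None = None) -> np.ndarray:
        cols = [self.design.X0]
        for g in sorted(self.active, key=self.order.get):
            for term in ("main", "gxe"):
                if term in self.active[g] and (g, term) != exclude:
                    cols.append(self.term_cols(g, term))
        if extra:
            cols.extend(extra)
        return np.hstack(cols)

    def main_r2_sum(self, rss_full: float, rank_full: int) -> float:
        """Cumulative partial main-effect R2 (percent) of the active model."""
        total = 0.0
        y = self.design.y
        for g in self.active:
            if "main" not in self.active[g]:
                continue
            rss_wo, _ = _rss(self.design_matrix(exclude=(g, "main")), y)
            total += 100.0 * max(rss_wo - rss_full, 0.0) / self.design.tss
        return total


def stage2_stepwise(
    gasms: GasmSet,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    h2: float,
    alpha_model: float = 0.05,
    preselected: list[str] | None = None,
    m_candidates: int | None = None,
    include_gxe: bool = True,
    max_iter: int = 200,
) -> AssociationModel:
    """Forward-selection / backward-elimination multilocus model building.

    The per-term threshold is ``alpha_model / m`` with m the candidate count;
    a forward step is accepted only while the cumulative partial main-effect
    R2 stays within 100*h2.  Completed effects and contributions come from
    :func:`partition_contributions`.
    """
    design = PlotDesign(phenotypes, covariates)
    if preselected is None:
        markers = list(gasms.markers)
    else:
        want = set(preselected)
        markers = [m for m in gasms.markers if m.gene_id in want]
    if not markers:
        raise InputError("no candidate markers for stage 2")
    m = m_candidates if m_candidates is not None else len(markers)
    threshold = alpha_model / m
    sel = _Selection(design, markers, include_gxe)
    y = design.y
    n = len(y)
    cap = 100.0 * h2 + 1e-9

    rss_cur, rank_cur = _rss(sel.design_matrix(), y)
    history: list[frozenset] = []
    blocked: set[str] = set()  # genes whose entry was immediately undone
    for it in range(max_iter):
        changed = False
        # ---- forward: best candidate block (main + gxe) by partial F p ----
        cand_stats = []
        for g in sel.markers:
            if g in sel.active or g in blocked:
                continue
            extra = [sel.main_cols(g)]
            if include_gxe:
                extra.append(sel.gxe_cols(g))
            rss_new, rank_new = _rss(sel.design_matrix(extra=extra), y)
            f, p, df1 = _partial_f(rss_cur, rank_cur, rss_new, rank_new, n)
            if df1 == 0:
                continue  # collinear with current model: cannot enter
            gain = 100.0 * (rss_cur - rss_new) / design.tss
            cand_stats.append((p, -gain, sel.order[g], g, rss_new, rank_new))
        cand_stats.sort()
        added: str | None = None
        for p, neg_gain, _, g, rss_new, rank_new in cand_stats:
            if p > threshold:
                break
            sel.active[g] = {"main"} | ({"gxe"} if include_gxe else set())
            if sel.main_r2_sum(rss_new, rank_new) <= cap:
                rss_cur, rank_cur = rss_new, rank_new
                changed = True
                added = g
                break  # one forward addition per cycle
            del sel.active[g]  # heritability restriction: skip this candidate

        # ---- backward: drop the worst term above the threshold ----
        while True:
            worst = None
            for g in list(sel.active):
                for term in list(sel.active[g]):
                    rss_wo, rank_wo = _rss(sel.design_matrix(exclude=(g, term)), y)
                    f, p, df1 = _partial_f(rss_wo, rank_wo, rss_cur, rank_cur, n)
                    p_eff = 1.0 if df1 == 0 else p
                    if p_eff > threshold and (worst is None or p_eff > worst[0]):
                        worst = (p_eff, g, term)
            if worst is None:
                break
            _, g, term = worst
            sel.active[g].discard(term)
            if not sel.active[g]:
                del sel.active[g]
            rss_cur, rank_cur = _rss(sel.design_matrix(), y)
            changed = True

        # a gene stripped of every term right after its own block passed entry
        # is jointly but not term-wise significant; bar it from re-entering
        if added is not None and added not in sel.active:
            blocked.add(added)

        state = frozenset(
            [(g, t) for g in sel.active for t in sel.active[g]]
            + [(g, "blocked") for g in blocked]
        )
        if not changed:
            break
        if state in history:
            log.warning("stepwise revisited a model state at cycle %d; stopping there", it)
            break
        history.append(state)
    else:
        raise ConvergenceError(f"stepwise did not converge in {max_iter} cycles")

    # partial R2 values drift as terms come and go, so re-enforce the
    # heritability restriction on the converged model: drop the least
    # significant main term until the cumulative main R2 fits under the cap
    while sel.active:
        rss_cur, rank_cur = _rss(sel.design_matrix(), y)
        if sel.main_r2_sum(rss_cur, rank_cur) <= cap:
            break
        worst = None
        for g in sel.active:
            if "main" not in sel.active[g]:
                continue
            rss_wo, rank_wo = _rss(sel.design_matrix(exclude=(g, "main")), y)
            _, p, df1 = _partial_f(rss_wo, rank_wo, rss_cur, rank_cur, n)
            p_eff = 1.0 if df1 == 0 else p
            if worst is None or p_eff > worst[0]:
                worst = (p_eff, g)
        if worst is None:
            break
        _, g = worst
        sel.active[g].discard("main")
        if not sel.active[g]:
            del sel.active[g]

    model = AssociationModel(
        genes=[],
        grand_mean=float(np.mean(y)),
        h2=h2,
        threshold=threshold,
        n_candidates=m,
        env_labels=design.env_labels,
    )
    return partition_contributions(model, sel)


def partition_contributions(model: AssociationModel, sel: _Selection) -> AssociationModel:
    """Finalize per-gene partial R2 values, p-values and allele effects."""
    design = sel.design
    y = design.y
    n = len(y)
    X_full = sel.design_matrix()
    rss_full, rank_full = _rss(X_full, y)
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    model.model_r2_pct = 100.0 * (design.tss - rss_full) / design.tss

    # column offsets per active term, in design_matrix order
    offsets: dict[tuple[str, str], slice] = {}
    pos = design.X0.shape[1]
    for g in sorted(sel.active, key=sel.order.get):
        for term in ("main", "gxe"):
            if term in sel.active[g]:
                w = sel.term_cols(g, term).shape[1]
                offsets[(g, term)] = slice(pos, pos + w)
                pos += w

    genes: list[GeneResult] = []
    for g in sorted(sel.active, key=sel.order.get):
        marker = sel.markers[g]
        k = marker.n_alleles
        freq = marker.allele_freq
        main_eff = gxe_eff = None
        main_r2 = gxe_r2 = 0.0
        main_p = gxe_p = np.nan
        if "main" in sel.active[g]:
            rss_wo, rank_wo = _rss(sel.design_matrix(exclude=(g, "main")), y)
            f, main_p, df1 = _partial_f(rss_wo, rank_wo, rss_full, rank_full, n)
            main_r2 = 100.0 * max(rss_wo - rss_full, 0.0) / design.tss
            if df1 == 0:
                log.warning("gene %s: singular design after removing main term", g)
                main_r2 = 0.0
            raw = np.concatenate([[0.0], beta[offsets[(g, "main")]]])
            main_eff = raw - freq @ raw
        if "gxe" in sel.active[g]:
            rss_wo, rank_wo = _rss(sel.design_matrix(exclude=(g, "gxe")), y)
            f, gxe_p, df1 = _partial_f(rss_wo, rank_wo, rss_full, rank_full, n)
            gxe_r2 = 100.0 * max(rss_wo - rss_full, 0.0) / design.tss
            if df1 == 0:
                log.warning("gene %s: singular design after removing GxE term", g)
                gxe_r2 = 0.0
            raw = np.zeros((k, design.n_env))
            b = beta[offsets[(g, "gxe")]].reshape(design.n_env - 1, k - 1)
            raw[1:, 1:] = b.T
            gxe_eff = raw - raw.mean(axis=0) - raw.mean(axis=1)[:, None] + raw.mean()
        genes.append(
            GeneResult(
                gene_id=g,
                chromosome=marker.chromosome,
                position=marker.start,
                allele_labels=list(marker.allele_labels),
                allele_freq=freq.copy(),
                main_effects=main_eff,
                gxe_effects=gxe_eff,
                main_r2_pct=main_r2,
                gxe_r2_pct=gxe_r2,
                main_p=main_p,
                gxe_p=gxe_p,
            )
        )
    model.genes = genes
    return classify_genes(model)


# --------------------------------------------------------------------------
# classification and bookkeeping
# --------------------------------------------------------------------------

def classify_genes(model: AssociationModel, threshold_pct: float = 1.0) -> AssociationModel:
    """Class labels per gene and a gene-system summary table.

    LC-major: main-effect R2 >= threshold; SC-major: positive main R2 below
    it; GxE-only: interaction term without a main term.  The summary carries
    the unmapped-minor remainder 100*h2 - sum(main R2).
    """
    for g in model.genes:
        if g.main_effects is None:
            g.classification = "GxE-only"
        elif g.main_r2_pct >= threshold_pct:
            g.classification = "LC-major"
        else:
            g.classification = "SC-major"
    rows = []
    for cls in ("LC-major", "SC-major", "GxE-only"):
        members = [g for g in model.genes if g.classification == cls]
        rows.append((cls, len(members),
                     sum(g.main_r2_pct for g in members),
                     sum(g.gxe_r2_pct for g in members)))
    main_genes = [g for g in model.genes if g.main_effects is not None]
    gxe_genes = [g for g in model.genes if g.gxe_effects is not None]
    rows.append(("main-effect total", len(main_genes),
                 sum(g.main_r2_pct for g in main_genes), np.nan))
    rows.append(("GxE total", len(gxe_genes), np.nan,
                 sum(g.gxe_r2_pct for g in gxe_genes)))
    rows.append(("unmapped minor", np.nan, model.unmapped_minor_pct, np.nan))
    model.summary = pd.DataFrame(rows, columns=["class", "n_genes", "main_r2_pct", "gxe_r2_pct"])
    return model


def summarize_gene_catalog(
    catalog: pd.DataFrame, h2_pct: float, threshold_pct: float = 1.0
) -> dict:
    """Bookkeeping over a per-gene catalog table.

    ``catalog`` columns: allele_count, main_r2_pct (blank/NaN if the gene has
    no main term), gxe_r2_pct (blank/NaN if no interaction term).  Returns
    the counts and totals a gene-system summary reports.
    """
    main = catalog["main_r2_pct"]
    gxe = catalog["gxe_r2_pct"]
    has_main = main.notna()
    has_gxe = gxe.notna()
    lc = has_main & (main >= threshold_pct)
    sc = has_main & (main < threshold_pct)
    return {
        "n_genes": int(len(catalog)),
        "n_main_genes": int(has_main.sum()),
        "n_gxe_genes": int(has_gxe.sum()),
        "n_lc_major": int(lc.sum()),
        "n_sc_major": int(sc.sum()),
        "allele_total": int(catalog["allele_count"].sum()),
        "mean_alleles_per_gene": float(catalog["allele_count"].mean()),
        "max_alleles_per_gene": int(catalog["allele_count"].max()),
        "main_r2_total_pct": float(main.sum()),
        "gxe_r2_total_pct": float(gxe.sum()),
        "unmapped_minor_pct": float(h2_pct - main.sum()),
    }


def run_rtm_gwas(
    gasms: GasmSet,
    phenotypes: pd.DataFrame,
    h2: float,
    q_eigenvectors: int = 10,
    alpha_preselect: float = 0.05,
    alpha_model: float = 0.05,
    include_gxe: bool = True,
) -> tuple[Stage1Scan, AssociationModel]:
    """Convenience pipeline: structure covariates -> stage 1 -> stage 2."""
    structure = allele_similarity(gasms, q=q_eigenvectors)
    scan = stage1_preselect(gasms, phenotypes, structure.covariates, alpha=alpha_preselect)
    model = stage2_stepwise(
        gasms, phenotypes, structure.covariates, h2,
        alpha_model=alpha_model, preselected=scan.preselected,
        include_gxe=include_gxe,
    )
    return scan, model
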