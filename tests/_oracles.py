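"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's own linear-algebra path: the stepwise
oracle is a straight-line statsmodels/pandas reimplementation of the same
add/drop rules, and the set/enumeration oracles are brute force.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm


def straightline_stepwise(
    gasms,
    pheno: pd.DataFrame,
    covariates: pd.DataFrame | None,
    h2: float,
    alpha_model: float = 0.05,
    m_candidates: int | None = None,
    include_gxe: bool = True,
    max_cycles: int = 50,
):
    """Plain re-implementation of the forward/backward stepwise rules.

    Returns the selected {gene_id: set of active terms} mapping.  Designs are
    assembled as pandas dummies and fitted with statsmodels OLS; partial F
    tests compare nested fits directly.
    """
    df = pheno.sort_values(["accession", "environment", "replicate"], kind="stable")
    df = df.reset_index(drop=True)
    y = df["trait"].to_numpy(float)
    n = len(df)
    tss = float(((y - y.mean()) ** 2).sum())

    base = pd.get_dummies(df["environment"], prefix="env", drop_first=True, dtype=float)
    rep_cols = {}
    envs = sorted(df["environment"].unique())
    reps = sorted(df["replicate"].unique())
    for e in envs:
        for r in reps[1:]:
            rep_cols[f"rep_{e}_{r}"] = ((df["environment"] == e) & (df["replicate"] == r)).astype(float)
    base = pd.concat([base, pd.DataFrame(rep_cols)], axis=1)
    if covariates is not None:
        base = pd.concat(
            [base, covariates.reindex(df["accession"]).reset_index(drop=True)], axis=1
        )
    base.insert(0, "const", 1.0)

    markers = {mk.gene_id: mk for mk in gasms.markers}
    order = {mk.gene_id: i for i, mk in enumerate(gasms.markers)}

    def term_frame(gene_id: str, term: str) -> pd.DataFrame:
        mk = markers[gene_id]
        idx = mk.allele_of.reindex(df["accession"]).to_numpy(int)
        cols = {}
        for a in range(1, mk.n_alleles):
            cols[f"{gene_id}_main_a{a}"] = (idx == a).astype(float)
        main = pd.DataFrame(cols)
        if term == "main":
            return main
        gxe = {}
        for j, e in enumerate(envs[1:], start=1):
            ind = (df["environment"] == e).astype(float)
            for c in main:
                gxe[f"{gene_id}_gxe_{e}_{c}"] = main[c] * ind
        return pd.DataFrame(gxe)

    def fit(X: pd.DataFrame):
        return sm.OLS(y, X.to_numpy()).fit()

    def design(active: dict, exclude=None, extra: pd.DataFrame | None = None) -> pd.DataFrame:
        parts = [base]
        for g in sorted(active, key=order.get):
            for term in ("main", "gxe"):
                if term in active[g] and (g, term) != exclude:
                    parts.append(term_frame(g, term))
        if extra is not None:
            parts.append(extra)
        return pd.concat(parts, axis=1)

    def rss_rank(X: pd.DataFrame):
        res = fit(X)
        return float(res.ssr), int(np.linalg.matrix_rank(X.to_numpy()))

    def partial_p(rss_red, rank_red, rss_full, rank_full):
        df1 = rank_full - rank_red
        df2 = n - rank_full
        if df1 <= 0 or df2 <= 0 or rss_full <= 0:
            return 1.0, df1
        from scipy.stats import f as fdist

        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
        return float(fdist.sf(F, df1, df2)), df1

    def cum_main_r2(active, rss_full):
        total = 0.0
        for g in active:
            if "main" not in active[g]:
                continue
            rss_wo, _ = rss_rank(design(active, exclude=(g, "main")))
            total += 100.0 * max(rss_wo - rss_full, 0.0) / tss
        return total

    m = m_candidates if m_candidates is not None else len(markers)
    threshold = alpha_model / m
    cap = 100.0 * h2 + 1e-9
    active: dict[str, set] = {}
    blocked: set[str] = set()
    rss_cur, rank_cur = rss_rank(design(active))

    for _ in range(max_cycles):
        changed = False
        cands = []
        for g in markers:
            if g in active or g in blocked:
                continue
            extra = term_frame(g, "main")
            if include_gxe:
                extra = pd.concat([extra, term_frame(g, "gxe")], axis=1)
            rss_new, rank_new = rss_rank(design(active, extra=extra))
            p, df1 = partial_p(rss_cur, rank_cur, rss_new, rank_new)
            if df1 == 0:
                continue
            gain = 100.0 * (rss_cur - rss_new) / tss
            cands.append((p, -gain, order[g], g, rss_new, rank_new))
        cands.sort()
        added = None
        for p, _, _, g, rss_new, rank_new in cands:
            if p > threshold:
                break
            active[g] = {"main"} | ({"gxe"} if include_gxe else set())
            if cum_main_r2(active, rss_new) <= cap:
                rss_cur, rank_cur = rss_new, rank_new
                changed = True
                added = g
                break
            del active[g]
        while True:
            worst = None
            for g in list(active):
                for term in list(active[g]):
                    rss_wo, rank_wo = rss_rank(design(active, exclude=(g, term)))
                    p, df1 = partial_p(rss_wo, rank_wo, rss_cur, rank_cur)
                    p_eff = 1.0 if df1 == 0 else p
                    if p_eff > threshold and (worst is None or p_eff > worst[0]):
                        worst = (p_eff, g, term)
            if worst is None:
                break
            _, g, term = worst
            active[g].discard(term)
            if not active[g]:
                del active[g]
            rss_cur, rank_cur = rss_rank(design(active))
            changed = True
        if added is not None and added not in active:
            blocked.add(added)
        if not changed:
            break

    # final heritability-restriction trim, mirroring the stated rule:
    # drop least significant main terms until the cumulative main R2 fits
    while active:
        rss_cur, rank_cur = rss_rank(design(active))
        if cum_main_r2(active, rss_cur) <= cap:
            break
        worst = None
        for g in active:
            if "main" not in active[g]:
                continue
            rss_wo, rank_wo = rss_rank(design(active, exclude=(g, "main")))
            p, df1 = partial_p(rss_wo, rank_wo, rss_cur, rank_cur)
            p_eff = 1.0 if df1 == 0 else p
            if worst is None or p_eff > worst[0]:
                worst = (p_eff, g)
        if worst is None:
            break
        _, g = worst
        active[g].discard("main")
        if not active[g]:
            del active[g]
    return {g: set(t) for g, t in active.items()}


def brute_force_overlap_resolution(genes):
    """Pairwise elimination oracle: drop the shorter of the first overlapping pair."""
    survivors = list(genes)
    while True:
        hit = None
        ordered = sorted(survivors, key=lambda g: (g.chromosome, g.start, g.end))
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                if ordered[i].overlaps(ordered[j]):
                    hit = (ordered[i], ordered[j])
                    break
            if hit:
                break
        if hit is None:
            return ordered
        a, b = hit
        loser = b if (a.length, -a.start) >= (b.length, -b.start) else a
        survivors.remove(loser)


def brute_force_venn(sets: dict[str, set]) -> dict[frozenset, int]:
    """Element-by-element membership counting for the exclusive Venn regions."""
    labels = list(sets)
    universe = set().union(*sets.values())
    out: dict[frozenset, int] = {}
    for element in universe:
        member = frozenset(l for l in labels if element in sets[l])
        out[member] = out.get(member, 0) + 1
    return out


def brute_force_progeny_values(base: float, deltas: list[float]) -> np.ndarray:
    """All 2^k progeny values by explicit enumeration of origin vectors."""
    vals = []
    for origins in product((0, 1), repeat=len(deltas)):
        vals.append(base + sum(d * o for d, o in zip(deltas, origins)))
    return np.sort(np.array(vals))
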