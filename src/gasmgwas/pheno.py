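"""Trait computation and variance-component analysis.

The trait is a stress-tolerance index: the ratio of treated to control
seedling dry weight per plot.  Multi-environment replicated trials are
decomposed with the balanced two-way model

    y_ijk = mu + a_i + b_j + (ab)_ij + g_k(j) + e_ijk

(genotype i, environment j, replicate k within environment), from which
entry-mean heritability h2 = sg2 / (sg2 + sge2/n + se2/(r n)) and the
genotypic coefficient of variation GCV = 100 * sg / mu are derived by the
expected-mean-squares method of moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError, PhenotypeRecord


def compute_ati(treatment_dw: float, control_dw: float) -> float:
    """Stress-tolerance index: treated dry weight over control dry weight."""
    if control_dw <= 0:
        raise InputError(f"control dry weight must be > 0, got {control_dw}")
    return treatment_dw / control_dw


def records_to_frame(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Tidy plot-level frame (accession, environment, replicate, trait).

    Trait values are taken as given when present, otherwise computed from
    the two dry weights.
    """
    rows = []
    for rec in records:
        if rec.trait_value is not None:
            y = rec.trait_value
        else:
            y = compute_ati(rec.treatment_dry_weight, rec.control_dry_weight)
        rows.append((rec.accession, rec.environment, rec.replicate, y))
    return pd.DataFrame(rows, columns=["accession", "environment", "replicate", "trait"])


def heritability(sigma_g2: float, sigma_ge2: float, sigma_e2: float, n_env: int, n_rep: int) -> float:
    """Entry-mean heritability from variance components."""
    denom = sigma_g2 + sigma_ge2 / n_env + sigma_e2 / (n_rep * n_env)
    if denom == 0:
        return 0.0
    return sigma_g2 / denom


def gcv(sigma_g: float, mu: float) -> float:
    """Genotypic coefficient of variation in percent."""
    if mu <= 0:
        raise InputError(f"population mean must be > 0, got {mu}")
    return 100.0 * sigma_g / mu


@dataclass
class VarianceDecomposition:
    grand_mean: float
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    n_env: int
    n_rep: int
    h2: float
    gcv_pct: float
    anova_table: pd.DataFrame  # source, df, SS, MS, F, p


def anova_components(records: list[PhenotypeRecord] | pd.DataFrame) -> VarianceDecomposition:
    """Two-way ANOVA with replicates-within-environments; variance components
    by expected mean squares.

    Requires >= 2 environments and >= 2 replicates; the design should be
    (near-)balanced — cell means are used, so mild imbalance only perturbs
    the moment estimators.  Negative component estimates truncate at zero.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    g = df["accession"].nunique()
    n = df["environment"].nunique()
    r = df["replicate"].nunique()
    if n < 2:
        raise InputError("need >= 2 environments to separate G x E from error")
    if r < 2:
        raise InputError("need >= 2 replicates to estimate error variance")

    y = df["trait"].to_numpy(float)
    N = len(y)
    mu = y.mean()
    ss_total = np.sum((y - mu) ** 2)

    acc_mean = df.groupby("accession")["trait"].mean()
    env_mean = df.groupby("environment")["trait"].mean()
    cell_mean = df.groupby(["accession", "environment"])["trait"].mean()
    rep_mean = df.groupby(["environment", "replicate"])["trait"].mean()

    ss_g = n * r * np.sum((acc_mean - mu) ** 2)
    ss_e = g * r * np.sum((env_mean - mu) ** 2)
    ss_rep = g * np.sum((rep_mean - rep_mean.groupby("environment").transform("mean")) ** 2)
    ge_dev = (
        cell_mean
        - acc_mean.reindex(cell_mean.index.get_level_values(0)).to_numpy()
        - env_mean.reindex(cell_mean.index.get_level_values(1)).to_numpy()
        + mu
    )
    ss_ge = r * np.sum(ge_dev**2)
    ss_err = ss_total - ss_g - ss_e - ss_ge - ss_rep

    df_g, df_e, df_ge = g - 1, n - 1, (g - 1) * (n - 1)
    df_rep = n * (r - 1)
    df_err = N - 1 - df_g - df_e - df_ge - df_rep
    ms_g, ms_e, ms_ge = ss_g / df_g, ss_e / df_e, ss_ge / df_ge
    ms_rep = ss_rep / df_rep if df_rep else np.nan
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    # genotype tested against G x E (genotype, G x E random); environment
    # against replicates-within-environments; the rest against error
    f_g, p_g = _ftest(ms_g, ms_ge, df_g, df_ge)
    f_e, p_e = _ftest(ms_e, ms_rep, df_e, df_rep)
    f_ge, p_ge = _ftest(ms_ge, ms_err, df_ge, df_err)
    f_rep, p_rep = _ftest(ms_rep, ms_err, df_rep, df_err)

    table = pd.DataFrame(
        {
            "source": ["genotype", "environment", "GxE", "rep(env)", "error", "total"],
            "df": [df_g, df_e, df_ge, df_rep, df_err, N - 1],
            "SS": [ss_g, ss_e, ss_ge, ss_rep, ss_err, ss_total],
            "MS": [ms_g, ms_e, ms_ge, ms_rep, ms_err, np.nan],
            "F": [f_g, f_e, f_ge, f_rep, np.nan, np.nan],
            "p": [p_g, p_e, p_ge, p_rep, np.nan, np.nan],
        }
    )

    sigma_e2 = max(ms_err, 0.0) if np.isfinite(ms_err) else 0.0
    sigma_ge2 = max((ms_ge - ms_err) / r, 0.0)
    sigma_g2 = max((ms_g - ms_ge) / (r * n), 0.0)
    h2 = heritability(sigma_g2, sigma_ge2, sigma_e2, n, r)
    return VarianceDecomposition(
        grand_mean=mu,
        sigma_g2=sigma_g2,
        sigma_ge2=sigma_ge2,
        sigma_e2=sigma_e2,
        n_env=n,
        n_rep=r,
        h2=h2,
        gcv_pct=gcv(np.sqrt(sigma_g2), mu) if mu > 0 else np.nan,
        anova_table=table,
    )


def _ftest(ms_num, ms_den, df_num, df_den):
    if not (np.isfinite(ms_num) and np.isfinite(ms_den)) or ms_den <= 0 or df_den <= 0:
        return np.nan, np.nan
    f = ms_num / ms_den
    return f, stats.f.sf(f, df_num, df_den)


@dataclass
class SubpopulationSummary:
    bins: np.ndarray  # bin midpoints
    table: pd.DataFrame  # per subpopulation: count, mean, min, max, gcv, h2, p_vs_reference
    bin_counts: pd.DataFrame  # subpopulation x bin midpoint counts


DEFAULT_BIN_MIDPOINTS = np.round(np.arange(0.38, 0.885, 0.05), 2)


def subpopulation_summary(
    records: list[PhenotypeRecord] | pd.DataFrame,
    labels: pd.Series,
    bins: np.ndarray | None = None,
    reference: str = "ERD",
    alpha: float = 0.05,
) -> SubpopulationSummary:
    """Descriptive statistics per subpopulation over fixed trait bins.

    Accession means are binned at the given midpoints (edges halfway
    between); per-subpopulation h2 and GCV come from a within-subpopulation
    ANOVA, and means are compared to the reference subpopulation with a
    two-sided t-test on accession means at level ``alpha``.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    unknown = set(df["accession"]) - set(labels.index)
    if unknown:
        raise InputError(f"accessions without subpopulation label: {sorted(unknown)[:5]}")
    if bins is None:
        bins = DEFAULT_BIN_MIDPOINTS
    bins = np.asarray(bins, float)
    step = np.diff(bins).mean() if len(bins) > 1 else 1.0
    edges = np.concatenate([[bins[0] - step / 2], (bins[:-1] + bins[1:]) / 2, [bins[-1] + step / 2]])

    acc_mean = df.groupby("accession")["trait"].mean()
    sub_of = labels.reindex(acc_mean.index)
    ref_means = acc_mean[sub_of == reference]

    rows, counts = [], {}
    for sub in sorted(sub_of.unique()):
        members = acc_mean.index[sub_of == sub]
        vals = acc_mean.loc[members]
        sub_df = df[df["accession"].isin(members)]
        try:
            dec = anova_components(sub_df)
            h2_s, gcv_s = dec.h2, dec.gcv_pct
        except InputError:
            h2_s = gcv_s = np.nan
        if sub != reference and len(ref_means) > 1 and len(vals) > 1:
            p_ref = stats.ttest_ind(vals, ref_means, equal_var=False).pvalue
        else:
            p_ref = np.nan
        rows.append((sub, len(vals), vals.mean(), vals.min(), vals.max(), gcv_s, h2_s,
                     p_ref, bool(p_ref < alpha) if np.isfinite(p_ref) else False))
        hist, _ = np.histogram(vals, bins=edges)
        # values outside the stated bins are counted into the end bins
        hist[0] += int((vals < edges[0]).sum())
        hist[-1] += int((vals >= edges[-1]).sum())
        counts[sub] = hist

    table = pd.DataFrame(
        rows,
        columns=["subpopulation", "count", "mean", "min", "max", "gcv_pct", "h2",
                 "p_vs_reference", "significant_vs_reference"],
    )
    bin_counts = pd.DataFrame(counts, index=bins).T
    return SubpopulationSummary(bins=bins, table=table, bin_counts=bin_counts)
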