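"""Two-stage multilocus association: structure, preselection, stepwise, partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gasmgwas as gg
from gasmgwas.assembly import GasmSet
from gasmgwas.gwas import (
    AssociationModel,
    ConfigError,
    GeneResult,
    classify_genes,
    stage1_preselect,
    stage2_stepwise,
)

from _oracles import straightline_stepwise
from conftest import null_phenotypes


def make_marker(gene_id, idx, accs, chrom="Chr1", start=1, k=None):
    idx = np.asarray(idx, int)
    k = k if k is not None else int(idx.max()) + 1
    counts = np.bincount(idx, minlength=k)
    return gg.GasmMarker(
        gene_id, chrom, start, start + 99,
        [f"a{i + 1}" for i in range(k)],
        pd.Series(idx, index=accs),
        counts / len(idx),
        [f"H{i}" for i in range(k)],
    )


def plots_from_values(accs, values, rng, noise=0.02, n_envs=3, n_reps=3):
    rows = []
    for acc, v in zip(accs, values):
        for e in range(n_envs):
            for r in range(n_reps):
                rows.append((acc, f"E{e + 1}", f"R{r + 1}", v + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["accession", "environment", "replicate", "trait"])


class TestAlleleSimilarity:
    def test_hand_counted_two_accessions(self):
        accs = ["X", "Y"]
        markers = [
            make_marker("g1", [0, 0], accs, k=2),  # shared
            make_marker("g2", [0, 1], accs),       # different
            make_marker("g3", [1, 1], accs, k=2),  # shared
        ]
        struct = gg.allele_similarity(GasmSet(markers), q=2)
        assert struct.similarity.loc["X", "Y"] == pytest.approx(2 / 3)
        assert struct.similarity.loc["X", "X"] == 1.0

    def test_identical_accessions_fully_similar(self):
        accs = [f"S{i}" for i in range(5)]
        markers = [make_marker(f"g{j}", [0] * 5, accs, k=2) for j in range(3)]
        struct = gg.allele_similarity(GasmSet(markers), q=3)
        assert np.allclose(struct.similarity.to_numpy(), 1.0)

    def test_accession_permutation_permutes_similarity(self):
        rng = np.random.default_rng(1)
        accs = [f"S{i}" for i in range(8)]
        idx = [rng.integers(0, 3, 8) for _ in range(6)]
        gasms1 = GasmSet([make_marker(f"g{j}", ix, accs, k=3) for j, ix in enumerate(idx)])
        perm = rng.permutation(8)
        accs_p = [accs[i] for i in perm]
        gasms2 = GasmSet(
            [make_marker(f"g{j}", np.asarray(ix)[perm], accs_p, k=3)
             for j, ix in enumerate(idx)]
        )
        s1 = gg.allele_similarity(gasms1, q=2).similarity
        s2 = gg.allele_similarity(gasms2, q=2).similarity
        assert np.allclose(s1.loc[accs, accs].to_numpy(), s2.loc[accs, accs].to_numpy())

    def test_q_exceeding_population_rejected(self):
        accs = ["X", "Y"]
        markers = [make_marker("g1", [0, 1], accs), make_marker("g2", [0, 1], accs)]
        with pytest.raises(ConfigError):
            gg.allele_similarity(GasmSet(markers), q=5)


class TestStage1:
    def test_causal_marker_has_tiny_p(self, recovery_bundle):
        scan = recovery_bundle["scan"].table.set_index("gene_id")
        causal = list(recovery_bundle["truth"].main_effects)
        assert min(scan.loc[c, "p"] for c in causal if c in scan.index) < 1e-6

    def test_permuted_phenotypes_preselect_near_alpha(self, small_null_bundle):
        # marker tests share the phenotype vector, so single-replicate
        # fractions overdisperse; the mean over replicates calibrates to alpha
        rng = np.random.default_rng(31)
        fracs = []
        for _ in range(10):
            frame = null_phenotypes(list(small_null_bundle["sim"].assignment.index), rng)
            scan = stage1_preselect(small_null_bundle["gasms"], frame,
                                    small_null_bundle["struct"].covariates, alpha=0.05)
            fracs.append(scan.table["preselected"].mean())
        assert abs(np.mean(fracs) - 0.05) <= 0.02

    def test_uniform_null_pvalues(self):
        cfg = gg.SimulationConfig(
            n_accessions=80, subpop_sizes={"POP": 80}, n_genes=500, n_causal=2,
            seed=41,
        )
        sim = gg.simulate_genotypes(cfg)
        gasms = gg.build_gasm_set(sim.table, sim.genes)
        rng = np.random.default_rng(19)
        frame = null_phenotypes(list(sim.assignment.index), rng)
        scan = stage1_preselect(gasms, frame, covariates=None, alpha=0.05)
        p = scan.table.loc[~scan.table["untestable"], "p"].to_numpy()
        assert len(p) >= 450
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_monomorphic_marker_untestable(self):
        accs = [f"S{i}" for i in range(30)]
        rng = np.random.default_rng(2)
        markers = [
            make_marker("flat", [0] * 30, accs, k=2),
            make_marker("poly", rng.integers(0, 2, 30), accs),
        ]
        frame = null_phenotypes(accs, rng)
        scan = stage1_preselect(GasmSet(markers), frame, None)
        tab = scan.table.set_index("gene_id")
        assert bool(tab.loc["flat", "untestable"])
        assert not bool(tab.loc["poly", "untestable"])


def subset_gasms(bundle, gene_ids):
    markers = [m for m in bundle["gasms"].markers if m.gene_id in set(gene_ids)]
    return GasmSet(sorted(markers, key=lambda m: gene_ids.index(m.gene_id)))


def small_instance(bundle, n_noise, n_causal, seed=0, n_accessions=150):
    """A <=10-marker stage-2 instance drawn from the recovery population."""
    rng = np.random.default_rng(seed)
    causal = sorted(bundle["truth"].main_effects)[:n_causal]
    noise = [m.gene_id for m in bundle["gasms"].markers
             if m.gene_id not in set(bundle["truth"].main_effects)]
    pick = list(rng.choice(noise, size=n_noise, replace=False))
    gasms = subset_gasms(bundle, causal + pick)
    accs = list(bundle["sim"].assignment.index)[:n_accessions]
    frame = bundle["frame"][bundle["frame"]["accession"].isin(accs)].reset_index(drop=True)
    return gasms, frame


class TestStage2Stepwise:
    @pytest.mark.parametrize("n_causal,h2,seed", [(2, 0.9, 1), (3, 0.05, 2), (0, 0.9, 3)])
    def test_matches_straightline_reimplementation(self, recovery_bundle, n_causal, h2, seed):
        gasms, frame = small_instance(recovery_bundle, 10 - n_causal, n_causal, seed=seed)
        model = stage2_stepwise(gasms, frame, None, h2=h2)
        got = {g.gene_id: set() for g in model.genes}
        for g in model.genes:
            if g.main_effects is not None:
                got[g.gene_id].add("main")
            if g.gxe_effects is not None:
                got[g.gene_id].add("gxe")
        expected = straightline_stepwise(gasms, frame, None, h2=h2)
        assert got == expected

    def test_duplicated_marker_enters_once(self, recovery_bundle):
        bundle = recovery_bundle
        causal = sorted(bundle["truth"].main_effects)[0]
        marker = bundle["gasms"][causal]
        twin = gg.GasmMarker(
            "twin", marker.chromosome, marker.start, marker.end,
            list(marker.allele_labels), marker.allele_of.copy(),
            marker.allele_freq.copy(), list(marker.haplotype_strings),
        )
        gasms = GasmSet([marker, twin])
        model = stage2_stepwise(gasms, bundle["frame"], None, h2=0.9)
        selected = [g.gene_id for g in model.genes]
        assert selected == [causal]  # first in marker order wins; never both

    def test_heritability_cap_restricts_model(self, recovery_bundle):
        gasms, frame = small_instance(recovery_bundle, 2, 6, seed=5)
        low = stage2_stepwise(gasms, frame, None, h2=0.08)
        high = stage2_stepwise(gasms, frame, None, h2=0.9)
        assert low.cumulative_main_r2_pct <= 8.0 + 1e-6
        assert len(low.genes) < len(high.genes)
        assert high.cumulative_main_r2_pct <= 90.0 + 1e-6

    def test_restriction_invariant_on_recovery_model(self, recovery_bundle):
        model = recovery_bundle["model"]
        assert model.cumulative_main_r2_pct <= 100 * model.h2 + 1e-6


class TestPartition:
    def test_single_gene_partial_equals_single_locus_r2(self, recovery_bundle):
        bundle = recovery_bundle
        causal = sorted(bundle["truth"].main_effects)[0]
        gasms = subset_gasms(bundle, [causal])
        frame = bundle["frame"]
        scan = stage1_preselect(gasms, frame, None)
        model = stage2_stepwise(gasms, frame, None, h2=0.9, include_gxe=False)
        assert len(model.genes) == 1
        assert model.genes[0].main_r2_pct == pytest.approx(
            scan.table["r2_pct"].iloc[0], abs=1e-8)

    def test_orthogonal_markers_partial_r2_sums_to_joint(self):
        rng = np.random.default_rng(8)
        n = 120
        accs = [f"S{i}" for i in range(n)]
        a_idx = np.repeat([0, 1], n // 2)
        b_idx = np.tile([0, 1], n // 2)  # balanced 2x2: orthogonal contrasts
        g = 0.08 * a_idx - 0.05 * b_idx
        frame = plots_from_values(accs, 0.6 + g, rng, noise=0.03)
        gasms = GasmSet([make_marker("gA", a_idx, accs), make_marker("gB", b_idx, accs)])
        model = stage2_stepwise(gasms, frame, None, h2=0.99, include_gxe=False)
        assert {g_.gene_id for g_ in model.genes} == {"gA", "gB"}
        # partial R2 values of orthogonal markers sum to their joint gain
        # over the base (env/rep) design
        frame_s = frame.sort_values(["accession", "environment", "replicate"])
        y = frame_s["trait"].to_numpy()
        base_cols = [np.ones(len(frame_s))]
        for e in sorted(frame_s["environment"].unique())[1:]:
            base_cols.append((frame_s["environment"] == e).to_numpy(float))
        for e in sorted(frame_s["environment"].unique()):
            for r in sorted(frame_s["replicate"].unique())[1:]:
                base_cols.append(((frame_s["environment"] == e)
                                  & (frame_s["replicate"] == r)).to_numpy(float))
        X0 = np.column_stack(base_cols)
        beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
        rss0 = float(((y - X0 @ beta) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        base_r2 = 100.0 * (tss - rss0) / tss
        assert model.cumulative_main_r2_pct == pytest.approx(
            model.model_r2_pct - base_r2, abs=1e-6)

    def test_allele_effects_frequency_weighted_zero_sum(self, recovery_bundle):
        for g in recovery_bundle["model"].genes:
            if g.main_effects is not None:
                assert g.allele_freq @ g.main_effects == pytest.approx(0.0, abs=1e-9)
            if g.gxe_effects is not None:
                assert np.allclose(g.gxe_effects.mean(axis=0), 0.0, atol=1e-9)
                assert np.allclose(g.gxe_effects.mean(axis=1), 0.0, atol=1e-9)

    def test_estimated_effects_track_truth(self, recovery_bundle):
        bundle = recovery_bundle
        est, tru = [], []
        for g in bundle["model"].genes:
            if g.main_effects is None or g.gene_id not in bundle["truth"].main_effects:
                continue
            marker = bundle["gasms"][g.gene_id]
            founder = bundle["sim"].founder_haps[g.gene_id]
            for i, hs in enumerate(marker.haplotype_strings):
                if hs in founder:
                    est.append(g.main_effects[i])
                    tru.append(bundle["truth"].main_effects[g.gene_id][founder.index(hs)])
        assert len(est) >= 20
        assert np.corrcoef(est, tru)[0, 1] >= 0.9


class TestClassification:
    def _gene(self, gid, main_r2, gxe_r2):
        has_main = main_r2 is not None
        has_gxe = gxe_r2 is not None
        return GeneResult(
            gene_id=gid, chromosome="Chr1", position=1,
            allele_labels=["a1", "a2"], allele_freq=np.array([0.6, 0.4]),
            main_effects=np.array([0.01, -0.015]) if has_main else None,
            gxe_effects=np.zeros((2, 3)) if has_gxe else None,
            main_r2_pct=main_r2 or 0.0, gxe_r2_pct=gxe_r2 or 0.0,
            main_p=np.nan, gxe_p=np.nan,
        )

    def test_threshold_classes_and_unmapped_minor(self):
        model = AssociationModel(
            genes=[self._gene("big", 4.66, None), self._gene("small", 0.98, None),
                   self._gene("inter", None, 0.03)],
            grand_mean=0.65, h2=0.9843, threshold=1e-5, n_candidates=100,
            env_labels=["E1", "E2", "E3"],
        )
        model = classify_genes(model, threshold_pct=1.0)
        classes = {g.gene_id: g.classification for g in model.genes}
        assert classes == {"big": "LC-major", "small": "SC-major", "inter": "GxE-only"}
        assert model.unmapped_minor_pct == pytest.approx(98.43 - 4.66 - 0.98, abs=1e-9)

    def test_catalog_bookkeeping_roundtrip(self):
        catalog = pd.DataFrame({
            "allele_count": [2, 3, 4],
            "main_r2_pct": [2.0, 0.5, np.nan],
            "gxe_r2_pct": [np.nan, 0.1, 0.05],
        })
        s = gg.summarize_gene_catalog(catalog, h2_pct=90.0)
        assert s["n_lc_major"] == 1 and s["n_sc_major"] == 1
        assert s["n_main_genes"] == 2 and s["n_gxe_genes"] == 2
        assert s["allele_total"] == 9 and s["max_alleles_per_gene"] == 4
        assert s["unmapped_minor_pct"] == pytest.approx(87.5)
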