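# Methods

This note documents the models, the numerical choices, and the design
decisions behind `gasmgwas`, in the order the pipeline runs.

## Marker assembly

A gene–allele sequence marker (GASM) treats one annotated gene as a single
multi-allelic locus: the accession's alleles at all retained SNPs inside
the gene interval are concatenated into a haplotype string, and the
distinct strings are the marker's alleles, labelled `a1…ak` in descending
frequency (ties broken lexicographically by string, for reproducible
naming).

Filtering precedes assembly: sites with missing fraction > 0.20,
heterozygous fraction > 0.20 or minor allele frequency < 0.01 are removed.
MAF is computed from homozygous calls only, with heterozygous calls treated
as missing; the MAF bound is inclusive (a site at exactly 0.01 is kept),
while the rare-haplotype merge bound is exclusive (a haplotype at exactly
the threshold survives). These boundary conventions are deliberate and
fixed.

Missing and heterozygous calls are replaced by the site's majority
homozygote, ties going to the reference allele. Mode imputation is exact
on the package's synthetic data (which is generated from homozygous founder
haplotypes) and adequate for haplotype grouping at the ≤ 20% missingness
the filter allows; it does not model linkage-informed phasing, so on real
data with clustered missingness a dedicated imputation tool upstream is
reasonable.

Rare haplotypes (frequency below the merge threshold, default 0.01) have
their carriers reassigned to the gene's single most frequent allele. A
nearest-by-Hamming-distance variant is available (`nearest=True`) but is
not the default: the frequency-based rule is simpler, order-independent
and matches the "highest-frequency substitution" reading of the procedure.
Genes left with fewer than two alleles carry no marker.

Overlapping genes on a chromosome are resolved by keeping the longer gene
(equal lengths: the smaller start), applied pairwise and transitively until
no overlaps remain. With equal-priority chains this is order-dependent in
principle; the implementation always removes the loser of the first
overlapping pair in genome order, which a brute-force pairwise-elimination
oracle in the test suite reproduces.

## Trait and variance components

The trait is a stress-tolerance index: treated over control seedling dry
weight per plot, dimensionless, typically in (0, 1.1). Plot-level values
are retained for association (no collapsing to accession means).

The two-way model `y_ijk = μ + α_i + β_j + (αβ)_ij + γ_k(j) + ε_ijk` is fit
by closed-form balanced sums of squares on cell means; genotype is tested
against G×E, environment against replicates-within-environments, G×E and
replicates against error. Components follow the expected mean squares:
σ̂ε² = MS_error, σ̂ge² = (MS_GE − MS_error)/r, σ̂g² = (MS_G − MS_GE)/(rn),
truncated at zero (standard practice; keeps h² in [0, 1]). Entry-mean
heritability and GCV use the formulas in the README. Method of moments was
chosen over REML because balanced designs make it exact and directly
comparable with the quoted formulas; mild imbalance only perturbs the
moment estimators and is accepted.

Subpopulation summaries bin accession means at fixed midpoints (default
0.38–0.88 step 0.05, edges halfway between) and compare each
subpopulation's mean with the reference subpopulation (default ERD) by a
two-sided Welch t-test on accession means at α = 0.05. The test choice is
the package's own; the underlying comparison is descriptive.

## Restricted two-stage multilocus association

Population structure is summarized by the allele-sharing similarity matrix
(fraction of markers at which two accessions carry the same allele), double
centered and eigen-decomposed; the covariates are the top q = 10
eigenvectors scaled by the square root of their eigenvalues, so eigenvalue
magnitude enters the model alongside direction.

Stage 1 fits, per marker, trait ~ environment + replicate(environment) +
structure covariates + marker allele classes (k−1 indicator contrasts) and
preselects markers whose F-test gives p ≤ 0.05. Markers monomorphic over
the phenotyped accessions are flagged untestable and excluded.

Stage 2 is stepwise: a forward step evaluates, for every candidate gene,
the partial F of adding its main + allele×environment block, and accepts
the smallest-p candidate if p ≤ α/m (α = 0.05, m = candidate count — the
single-locus Bonferroni analogue) *and* the cumulative partial main-effect
R² of the resulting model stays within 100·h². A backward pass then
removes any included term (main and G×E tested separately) whose partial p
exceeds the same threshold; a gene retaining only its interaction term is
classed G×E-only. Forward ties break by larger R² gain, then genome
order; duplicated (collinear) markers cannot add rank and therefore cannot
enter twice.

Two termination safeguards are the package's own. First, a gene whose
joint block passes entry but whose terms are each individually stripped by
the immediately following backward pass is barred from re-entering —
without this, jointly-but-not-termwise-significant genes cycle forever.
Second, if the active term set ever revisits a previous state the search
stops at the current model; exceeding the iteration cap (default 200
cycles) raises an error naming the oscillating terms. Finally, because
partial R² values drift as terms come and go, the heritability restriction
is re-enforced on the converged model by dropping the least significant
main terms until the cumulative main R² fits under the cap, so the
restriction invariant holds on every returned model.

Contributions are partial (last-entry) R² — the drop in model R² when the
gene's term is removed from the full model — which is order-independent,
unlike sequential R²; the two coincide for orthogonal markers. Allele main
effects are the least-squares allele-class estimates re-expressed under a
frequency-weighted zero-sum constraint (so "positive" and "negative"
alleles are well defined); allele×environment effects are doubly centered.
Alleles with effect exactly zero are flagged rather than forced into a sign
class.

**Known calibration property.** The two probes of the null behaviour are
per-stage: under permuted phenotypes stage 1 preselects ≈ 5% of markers
(single-replicate fractions overdisperse because all marker tests share one
phenotype vector; the rate calibrates on average), and the stepwise stage
run at its Bonferroni-style threshold over a full null panel returns an
empty model in ≥ 95% of replicates. Composing the stages changes this:
stage-1 preselection keeps exactly the markers with small p, so the
stage-2 candidate p-values are not uniform under the null and the composed
procedure's familywise error at threshold α/m (m = preselected count) is
larger than α — in simulation roughly 20% of pure-noise replicates admit
one marker. This selection effect is inherent to the two-stage design, not
to this implementation; the heritability cap and the backward pass are the
procedure's pragmatic counterweights, and with thousands of markers the
practical threshold (~1e-5) keeps false content low.

## Gene–allele matrix and allele dynamics

The matrix has one row per (gene, allele) with its estimated main effect
and one 0/1 carriage column per accession; each accession carries exactly
one allele per gene, which the container validates. Group profiles report
mean counts and effect sums of carried positive/negative alleles.
Subpopulation allele sets contain every (gene, allele) carried by at least
one member; the change accounting between a reference and derived set is
pure set algebra — inherited = |ref ∩ der|, emerged-or-introduced =
|der \ ref|, excluded = |ref \ der|, changed = emerged + excluded — and the
container asserts these identities on construction. Emergence and
introduction are not distinguishable from carriage data, so a single
bucket is reported. Venn region counts over the four subpopulation sets
are exclusive-region counts.

## Cross prediction

Fully inbred progenies are drawn directly from the limiting RIL
distribution rather than by simulating generations of selfing: per
chromosome, the first segregating locus takes either parental origin with
probability ½ and each subsequent locus switches origin with probability
R = 2r/(1 + 2r), where r is Haldane's recombination fraction at the
adjacent map distance. This one-draw-per-progeny construction equals the
limiting distribution of repeated selfing from an F2. Under independent
assortment every segregating locus is an independent coin flip. Map
positions default to 1 cM/Mb when no genetic map is supplied; a supplied
map is linearly interpolated within its range and clamped outside.

A progeny's genotypic value is the model grand mean plus its carried
main-effect allele effects; G×E effects are excluded from prediction (they
average to zero over environments by construction). Cross summaries store
the progeny mean, SD (absolute and as percent of the mean — both, since
either convention appears in practice), and the 75th percentile computed by
linear interpolation between order statistics (the numpy default; at 2,000
progenies the definition matters only at ties). Ranking ties break by
progeny mean, then parent ids. An exact 2^k enumeration of the
independent-assortment distribution (k ≤ 16 segregating loci) serves as the
simulator's oracle in the tests.

## Synthetic germplasm generator

The generator is first-class, tested code. Defaults mirror the motivating
population: 361 accessions in nested subpopulations (ERA 61, ERB 230,
ERC 8, ERD 62), 20 chromosomes, 6,503 genes with 2–7 alleles each, 132
causal genes of which 35/132 carry G×E effects, 3 environments × 3
replicates, target h² = 0.9843, grand mean 0.65. The remaining scales were
fixed once as realistic values: 3–6 SNPs per gene; per-allele effect scale 0.012
(≈ genotypic SD 0.13 over ~130 genes on a 0.65 mean, i.e. GCV ≈ 20%); G×E
effect scale 0.004 (small relative to main effects, matching a G×E
contribution two orders below the main total); environment SD 0.02 and
replicate SD 0.005; ancestral-pool emergence fraction 0.12 and leaf-pool
exclusion fractions 0.12 (ERA) / 0.40 (ERC), the scale of the observed
subregional allele turnover reported for such panels. The nesting
fractions are free configuration, not estimates.

Per gene, k founder haplotypes are distinct random binary strings over the
gene's SNPs with Dirichlet(1,…,1) frequencies sorted descending; accessions
draw alleles from their subpopulation's pool with renormalized
frequencies. Genes are drawn independently (linkage enters only through
chromosome placement plus the genetic map at prediction time), so the
generator is analyzable; it does not model LD decay, coalescent ancestry,
sequencing error, or correlated missingness — tests passing on it show the
machinery is correct under its assumptions, not that real-data nuisances
are handled.

Main effects are i.i.d. normal, centered to frequency-weighted zero-sum on
realized frequencies; with `equalize_causal_variance=True` each causal
gene's effects are rescaled to a common realized genotypic variance, the
configuration used to construct recovery scenarios in which every causal
gene is individually detectable. G×E effects are doubly centered. The
error variance is solved from the target heritability,
σε² = rn·(σg²/h² − σg² − σge²/n), using realized variances, so the ANOVA
estimate recovers the target up to sampling noise; an unreachable target
(G×E too large, or no causal genes) raises a configuration error.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run desk-scale versions of the
study conditions, chosen to finish in minutes on one CPU while keeping
every per-gene signal well above detection: the standing recovery scenario
uses 300 accessions × 500 genes with 12 equal-variance causal genes at
h² = 0.9 (each causal gene ≈ 4% of plot-level variance); null calibration
uses 150 accessions × 200 markers with 100 replicates; cross prediction
enumerates a 30-parent subset at 2,000 progenies per cross. The catalog
bookkeeping and allele-dynamics accounting operate on the published
132-gene summary shipped as a plain-text fixture, and the cross-enumeration
and heritability worked values are analytic.

## Known limitations

- Mixed-model (kinship) association, epistasis and multi-trait models are
  out of scope; structure correction is by eigenvector covariates only.
- The stepwise path with min-norm least squares is deterministic but, like
  all stepwise procedures, greedy: correlated causal genes can shadow each
  other.
- The heritability cap composition (main vs. G×E bookkeeping) follows the
  main-effect reading; the G×E share is reported but not separately capped.
- Progeny prediction is purely additive in main effects; dominance and
  epistasis in crosses are not modeled (inbred-line endpoints make
  dominance moot).
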