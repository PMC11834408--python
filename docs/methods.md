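# Methods

## Study setting and scope

The package targets two-breed feeding trials in which a fiber-tolerant
breed (Meishan, "MS") and a fiber-intolerant breed (Large White, "LW")
receive a control diet and wheat-bran replacement diets (0, 7, 10.5, 14%
inclusion; seven animals per breed × diet cell).  It consumes
post-annotation tables only — species relative abundances, a gene
catalog with CAZyme/KO annotations, host expression counts, SCFA
concentrations, marker-based digestibility records and morphometry
measurements.  Read QC, assembly, gene prediction and database
annotation are upstream of this package and out of scope.

## Digestibility

ATTD is the marker-ratio estimator
`100·[1 − (DC_F·AIA_D)/(DC_D·AIA_F)]` with acid-insoluble ash as the
endogenous marker; all four concentrations must share units, making the
estimator invariant to a common rescaling.  Values are capped above by
100 (attained when nothing of the nutrient is excreted) and deliberately
*not* clipped below zero: a negative ATTD diagnoses marker or sampling
error and is surfaced as a warning rather than hidden.

The linear diet-level contrast is ordinary regression of the per-animal
outcome on the actual numeric inclusion levels.  The levels are
unequally spaced (0/7/10.5/14), so equal-spacing orthogonal polynomial
coefficients would test the wrong contrast; metric regression is what a
"linear effect of fiber level" means at these levels.  Group
comparisons are reported as means ± SE; both the trend p and the raw
per-group summaries are emitted so either reporting convention can be
audited.

## Morphometrics

CRMP and DRCM are per-field area ratios averaged across the (by
convention six) microscopic fields of a sample — ratio-then-mean, not
pooled areas, because each field is an independent determination.
Goblet density is 100 × count/depth per crypt averaged across crypts;
positive-cell metrics are per-region percentages averaged across
regions (12 crypts for Ki-67, 7 regions × 200 cells for TUNEL in the
conventional protocol, though any region count ≥ 1 is accepted).  The
residual-polysaccharide and damaged-microfibril annotations may overlap
on a micrograph; when the caller asserts disjointness the module
enforces CRMP + DRCM ≤ 1 per field.  Areas can be supplied as tables or
derived from integer label masks (pixel counting; label 0 = background).

## Dual-contrast biomarker screen

The screen operationalises "stable in the tolerant breed, depleted in
the intolerant breed":

* species mode — (i) presence above a detection floor (default: strictly
  positive) in *every* MS sample of both diets; (ii) MS contrast
  Mann-Whitney two-sided p ≥ `alpha_ms` (default 0.05 — the
  non-significance threshold is an explicit, configurable choice);
  (iii) LW contrast one-sided (lower in high-fiber) p < `alpha_lw`
  (default 0.01, raw per-feature p; a BH-corrected variant is available
  but off by default).
* gene mode — LW contrast two-sided p converted to BH-FDR < 0.05,
  |log₂FC| > 1 on normalized counts with pseudocount 0.5 (applied on a
  counts-per-million scale), and MS stability p ≥ `alpha_ms`; candidates
  are partitioned by the sign of the LW fold change.

Count tables are closed per sample (CPM-like) before testing; species
tables are closed to relative abundance.  At n = 7 per group a rank test
is robust and fully specifiable, so the default differential test in
both modes is Mann-Whitney; an overdispersed count-model plug-in is a
straightforward extension point.

**Mann-Whitney implementation.**  The U statistic is computed from
midranks.  When both groups have ≤ 12 observations and the pooled sample
is tie-free, p-values come from the exact null distribution of U,
tabulated by the classic lattice recurrence
`c(n₁,n₂)[u] = c(n₁−1,n₂)[u−n₂] + c(n₁,n₂−1)[u]`; two-sided p is twice
the smaller tail, capped at 1 (the convention scipy also uses, verified
against it and against exhaustive relabeling enumeration in the tests).
With ties, or larger groups, the tie-corrected normal approximation with
continuity correction is used; all-tied data give p = 1.

## CAZyme specific-gene-set profiling

`build_sgs` restricts the gene catalog to candidate species and counts
CAZyme-encoding genes per species × class and per species × family.
Each gene counts once in its class and once in its family; genes
annotated to multiple families would count once per distinct family —
the counting rule is documented here because annotation pipelines
differ, and the catalog schema enforces one row per gene.  Candidate
species missing from the catalog are reported, not fatal.  Top-k
contributor shares sort species by gene count with lexicographic
tie-breaking for determinism; shares are monotone in k and reach 100% at
the number of contributing species (a conservation law asserted in the
tests).  Per-enzyme profiles count genes carrying each KO per candidate
species and normalise rows to proportions; enzymes no candidate encodes
stay as zero rows and are excluded from the annotated-enzyme count.
The MS/LW fold-change flag pools both diets by default, since the
breed contrast — not the diet contrast — is what the flag summarises.

## Correlation networks

Within-breed co-occurrence networks correlate species across the breed's
samples (both diets pooled, n = 14 at default design) and keep edges
with raw p below `alpha` (default 0.05); integration networks correlate
cross-layer pairs (gene↔SCFA, gene↔GH family, microbe↔SCFA,
microbe↔gene, GH↔SCFA) at `alpha` = 0.01, per breed.  No multiplicity
correction is applied to edges by default because the raw per-edge
threshold *is* the network-construction rule; a BH option exists and is
labelled as a deviation from that rule.  Species are pre-filtered by
prevalence (default: nonzero in ≥ 50% of breed samples) because
tie-dominated all-zero profiles produce spurious correlations; the
filter is an explicit parameter, since field practice varies.

**Spearman implementation.**  rho is the Pearson correlation of
midranks.  p-values:

* n ≤ 9 — exact, by enumerating all n! orderings of one rank vector
  (correct under ties, since midranks are permuted);
* 9 < n ≤ 14, tie-free — exact, from the null distribution of
  S = Σd² tabulated once per n by dynamic programming over rank subsets
  (≈ n·2ⁿ vector operations; counts stay below 2⁵³ so float64 is exact).
  This extension of the exact path was adopted after measuring the
  t-approximation's size at n = 14: 0.052 at nominal 0.05 over 99 000
  null pairs.  When raw per-edge p-values are the network rule, a 4%
  relative inflation of every edge test is a systematic bias worth
  removing, and at n ≤ 14 the exact null is cheap.
* otherwise — the t-approximation `t = ρ√((n−2)/(1−ρ²))` with n − 2 df.

`clique_check` audits whether every pair within a node set is a
positive significant edge — the pattern expected of cooperating
degrader species in the tolerant breed.

## Synthetic cohorts

The generator's defaults are the study conditions all recovery and
calibration tests run at; they are not tuned per test.

* **Abundances** — per-feature baseline log-means ~ N(0, 1.5²)
  (heavy-tailed relative abundances without claiming a particular
  empirical distribution), within-group log-noise σ = 0.45, samples
  closed to sum 1.  30 planted species among 470 nulls; planted species
  share one mean across all MS diets and have it divided by 4 in LW
  high-fiber samples (≥ 10.5% inclusion).  Null species are
  zero-inflated with probability 0.1 *identically in every group* —
  exchangeable under the null while making the prevalence gate
  informative.  Planted species are floored at 10⁻⁶ in MS samples so
  the all-MS-presence criterion is meaningful.  σ = 0.45 was chosen so
  a 4-fold depletion is a ≈ 2σ√2 shift (pairwise AUC ≈ 0.99), the
  regime the screen's published-style thresholds presume; the spread
  parameters are placeholders for test power, not claims about real
  microbiomes.
* **Latent clique** — the first `clique_size` planted species share a
  standard-normal per-sample factor with loading 1.2 on the log scale in
  MS samples only, giving pairwise rank correlations ≈ 0.8 — chosen a
  priori so that all six pairwise edges of a 4-clique are significant at
  p < 0.05 in ≈ 90% of cohorts at n = 14.
* **Expression** — negative-binomial counts (variance μ + 0.1·μ²) with
  log-normal library sizes (σ = 0.25); 40 planted genes among 1960
  nulls carry |log₂FC| = 2 with random sign in LW high-fiber samples
  and no effect in MS.  Planted-gene baseline means are drawn from the
  moderately-expressed range (log-normal around 200) — the planted
  contrast concerns genes a count-based test can see, not
  barely-detected transcripts.
* **Host tables** — SCFA concentrations are log-normal around
  literature-scale cecal values with configurable per-acid log₂ shifts
  in LW high-fiber (defaults: +0.4 on propionate and butyrate);
  digestibility records are generated backwards from target ATTD values
  (LW high-fiber depressed by 10 points) through the marker formula;
  morphometry tables use beta-distributed area fractions and
  Poisson/binomial counts with mild breed shifts.
* **Seeding** — one root seed spawns independent child streams
  (abundances, catalog, host tables) via `numpy.random.SeedSequence`
  in a fixed order; a fixed seed reproduces the full bundle
  byte-for-byte after serialization.

What passing tests show — and what they do not: the simulator plants
clean multiplicative effects in otherwise independent log-normal
features.  Real microbiome data carry compositional coupling between
features, phylogenetic correlation, batch structure and far heavier
zero-inflation; recovery rates measured here are upper bounds on what
identical thresholds would achieve on sequencing data, and the plain
Spearman networks inherit the usual compositionality caveats (no
SparCC/SPIEC-EASI-style correction is attempted, matching the analysis
convention the package reproduces).

## Pipeline and I/O

All tables are single-header UTF-8 TSV with '.' decimals for bit-exact
interchange.  The pipeline driver executes simulate/load → digestibility
→ morphometrics → species screen → gene screen → SGS → networks →
report, writes every intermediate, and emits `manifest.json` recording
versions, the seed, every threshold actually applied and the feature
counts surviving each filter.  Stage failures abort with the stage name;
earlier outputs are preserved.  Co-occurrence networks in the driver are
capped at the 50 most abundant candidate species to keep all-pairs
correlation tractable on large catalogs (the library functions
themselves accept any size).  Problem sizes used by the test suite and
the acceptance script — 500 species, 2000 genes, 7 animals per cell,
20–50 Monte-Carlo seeds — match the defaults above.

## Known limitations

* The differential-expression default is a rank test on normalized
  counts; it ignores gene-length effects and borrows no strength across
  genes (no dispersion shrinkage).  At n = 7 this is defensible but
  conservative relative to count-model methods.
* Exact Spearman p-values stop at n = 14; beyond that the t
  approximation's bias is small but nonzero.
* The non-significance gate ("stable in MS") is an accept-the-null
  decision at `alpha_ms`; it is not an equivalence test, and its pass
  probability under the null is 1 − alpha_ms by construction.
* Digestibility and morphometry group tests are reported descriptively
  (means ± SE, trend p); the package does not adjudicate between ANOVA
  letter displays and pairwise tests.
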