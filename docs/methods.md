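# Methods

## Risk-model harmonization

Association tables arrive with one row per study × SNP. Harmonization groups
rows by rsID (first-appearance order is preserved) and assigns each SNP the
arithmetic mean of its reported odds ratios as the weight βᵢ. Studies that
report a logistic β instead of an OR contribute exp(β) when `beta_to_or` is
on (the default); with it off they are ignored for weighting. A SNP whose
group has no usable effect size receives the neutral weight 1.0 and a
`no_effect_size` flag rather than being dropped, so the SNP still
contributes allele-frequency information downstream.

Policy choices where the inputs are genuinely messy:

* **Unknown risk alleles** (`rs123-?`) are retained and flagged
  (`unknown_allele`); `strict_unknown=True` drops them. Retention keeps the
  model faithful to the catalog; the flag makes the limitation auditable.
* **Conflicting effect alleles across studies** keep the allele backed by
  the odds ratio furthest from 1 (largest |log OR|), flagged
  `allele_conflict`. The magnitude criterion prefers the study with the
  strongest, hence usually best-powered, signal.
* **Strand-ambiguous SNPs** (A/T or C/G pairs) can only be recognized once
  both alleles are known, which happens at VCF matching time; the counts
  table carries the `strand_ambiguous` flag. No strand flipping is
  attempted.

## Allele counting

Counts are kept as integers (effect-allele count, total called haplotypes)
so exact tests remain well defined. From VCFs (read with cyvcf2), missing
allele calls are excluded from numerator and denominator; the VCF's ploidy
encoding is trusted, so a haploid chrX call contributes one haplotype and a
diploid call two. SNPs are matched by ID first, then by chrom:pos; in
multiallelic records only the ALT equal to the effect allele counts as
effect, all other alleles as non-effect. An effect allele matching neither
REF nor ALT yields 0/total with an `allele_mismatch` flag rather than a
silent drop.

Frequency-only tables (KRGDB-style) are converted to counts as
round(f × N) / N using the table's allele-number column when present, else a
declared `default_n` (default 2000 alleles); reconstructed counts are
flagged `reconstructed_counts` because the implied exact-test resolution is
an approximation.

## Signed enrichment score

Each population is tested against the pooled counts of the **other**
populations. A 2×2 exact test requires disjoint groups; pooling everything
including the focal population would double-count its alleles. With several
populations in the pool the difference from a truly global frequency is
negligible, and the choice is recorded in the matrix metadata and the run
manifest.

The two-sided p follows the probability-ordering convention: sum the
hypergeometric probabilities of all tables with the observed margins whose
probability is at most the observed table's, with a 1 + 1e−7 relative tie
tolerance (the same rule R's `fisher.test` uses). The pmf is evaluated in
log space via log-gamma, so 1000-genomes-scale haplotype counts (thousands
per margin) neither overflow nor lose the extreme tails. p is floored at
1e−300 before log₁₀, capping |s| at 300 per cell.

The score is s = −log₁₀ p with the sign of (focal frequency − pool
frequency), and exactly 0 when the two proportions are equal (such tables
are modal, p = 1). No multiple-testing correction is applied to the scores
or the divergence filter; a Bonferroni-adjusted column is emitted in the
long-format output purely for reference.

Matrix ordering for the heatmap uses agglomerative clustering with complete
linkage and Euclidean distance on the score matrix (and its transpose for
columns), with untestable cells imputed as 0 *for ordering only* — they stay
missing in the data. Scores, not raw frequencies, are the clustering
features: they carry both direction and evidence. The divergence filter
|s_A| + |s_B| > cutoff is strict; the default cutoff of 60 targets gene-level
follow-up, and 100 is the conventional choice for legible heatmaps.

## PRS normalization

The score is PRS = Σ βᵢXᵢ / (2 Σ βᵢ). The denominator is the weighted one,
2 Σ βᵢ, not 2I (I = SNP count): only the weighted form satisfies all three
calibration points — PRS = 1 at Xᵢ ≡ 2, PRS = 0 at Xᵢ ≡ 0, and E[PRS] = 0.5
under uniform random dosage — for arbitrary positive weights. The literal
2I normalization (equivalent when weights average 1) remains available via
`literal_denominator=True` and can exceed 1; both forms are named in the
run manifest.

Missing genotypes are excluded from numerator and denominator
(renormalization over observed SNPs) instead of being imputed at 2fᵢ;
`n_used`/`n_missing` are reported per value. Renormalization keeps the
[0, 1] calibration for the observed subset at the cost of comparing
individuals over slightly different SNP sets — acceptable at the
missingness levels of reference panels, and visible in the output.

Hemizygous X-chromosome calls contribute a doubled dosage {0, 2} by default,
preserving the score range for males at X-linked SNPs (the androgen-receptor
SNP being the motivating case); `hemizygous="as_is"` gives {0, 1}.

Population expectation: under HWE E[Xᵢ] = 2fᵢ, so E[PRS] = Σ βᵢfᵢ / Σ βᵢ —
computable from frequency tables alone, which is what allows panels known
only through aggregate frequencies (e.g. a Korean reference panel) to be
scored and placed on the fitted regression line.

## Ecological regression

Simple OLS (statsmodels) of each response (incidence, mortality; age-adjusted
per 100,000) on each available predictor (PRS, DHT:T, vitamin D), populations
equally weighted, incidence and mortality fitted separately. Degenerate
inputs fail loudly: fewer than 3 complete points, a constant predictor, or a
constant response (SS_tot = 0) each raise an error naming the offender.
These are regressions over ~5 population aggregates: R² is fragile and the
report exists to rank predictors, which is stated in its output notes.
Held-out populations are excluded from fitting and reported as
(prs, predicted, observed) triples.

## Synthetic study generator

The generator emulates the analysis inputs, not human genetics in full:

* **Catalog**: one row per SNP with OR = exp 𝒩(0, 0.1) (typical common-variant
  effect sizes), 4% duplicate-rsID rows from a second study, 10% of rows
  reporting β instead of OR — enough to exercise every harmonization path.
* **Frequencies**: ancestral p ~ U(0.05, 0.95) per SNP, population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols model, the minimal
  standard model giving E = p and Var = F·p(1−p) with an FST-like F per
  population. The default preset has five populations at
  F = 0.15/0.10/0.08/0.09/0.11 (AFR/EAS/EUR/SAS/AMR) with the 1000-Genomes
  phase-3 super-population sample sizes (661/504/503/489/347) — an
  *illustrative* structure, not an estimate of real human divergence.
* **Genotypes**: dosage ~ Binomial(2, f) (HWE), written as a plain VCF with
  the effect allele planted as REF or ALT with equal probability so the
  allele-flip path is exercised; sample map alongside.
* **Epidemiology**: incidence = −500 + 1500·E[PRS] + 𝒩(0, 5), mortality =
  −140 + 400·E[PRS] + 𝒩(0, 5), floored at 0. The intercepts keep rates
  positive for any E[PRS] ≳ 0.35 (the generator's scores essentially never
  leave (0.4, 0.6)), the slopes put populations in a realistic per-100,000
  range, and the noise level makes the genetic R² land near 0.9–0.99 over
  five points — the regime the method is meant for. The "true" PRS driving
  the rates is computed from the panel-quantized frequency tables the
  generator itself writes, so the noiseless study is recovered *exactly* by
  the frequency-table analysis route. DHT:T (≈0.12) and vitamin D
  (≈60 nmol/L) are coupled to the PRS far more weakly than their noise, so
  they rank below the PRS by construction.

What the generator deliberately lacks — linkage disequilibrium between
SNPs, realistic site-frequency spectra, genotyping error, population
substructure within panels, and any real coupling between genotype and
disease biology. Passing tests therefore demonstrate that the *pipeline
machinery* is correct and calibrated, not that the epidemiological
conclusions transfer to real cohorts.

All generators are pure functions of (config, seed); per-stage streams are
derived from the seed so stages are independently reproducible, and a fixed
seed yields byte-identical output files.

## Problem sizes and numerical choices

The test suite runs the exhaustive exact-test sweep over all 2×2 tables
with row sums ≤ 30 (≈245k tables) against an integer-arithmetic enumeration
oracle, and cross-checks random larger tables against
`scipy.stats.fisher_exact` (relative 1e−6; the two implementations share
the tie convention but not code). Regression-parameter recovery uses the
five-population preset at 200 SNPs — noiseless for exact recovery, 50 seeds
at the default noise for the <5% mean-slope-bias check. VCF round trips use
1000–5000 diploid samples, sized so binomial standard errors are small but
the files are written and parsed in seconds. Ties and floors: equal
proportions force s = 0 regardless of p; p is floored at 1e−300;
frequency-table counts are rounded half-to-even via numpy.

## Known limitations

* The enrichment comparison pool excludes the focal population; against a
  convention that includes it, scores differ slightly for large focal
  panels.
* The divergence filter is strict (>), so a SNP exactly at the cutoff is
  dropped.
* No LD pruning or shrinkage is applied to the risk model; duplicated
  signals in LD inflate the effective weight of a locus exactly as they do
  in the underlying published analyses of this design.
* Ecological regressions over ≤ 6 points cannot support inference beyond
  predictor ranking, and the report says so.
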