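# prscape

Cross-population polygenic risk scoring for case studies in genetic
epidemiology — built around the prostate-cancer setting, where GWAS-reported
risk-SNP frequencies differ sharply between African and East-Asian ancestry
groups and population-level disease rates track those differences.

`prscape` takes three kinds of input a working geneticist already has:

1. a **GWAS-catalog-style association table** (rsID, risk allele, OR or β,
   study, trait),
2. **population genotype panels** (VCF + sample→population map) or
   pre-aggregated allele-frequency tables (KRGDB-style TSV),
3. a small **epidemiology table** (age-adjusted incidence and mortality per
   100,000, optional DHT:T ratio and vitamin-D covariates),

and produces a harmonized per-SNP risk model, per-population enrichment
scores, normalized polygenic risk scores, and population-level regressions
of disease rates on genetic risk.

## The model

**Risk model.** Associations are deduplicated per rsID; the weight of SNP
*i* is β*ᵢ*, the arithmetic mean of its reported odds ratios (reported
logistic coefficients enter as exp β).

**Enrichment score.** For each SNP and population, the effect-allele count
is exact-tested (two-sided Fisher) against the pooled counts of the other
populations, and reported as a signed score

&nbsp;&nbsp;&nbsp;&nbsp;*s* = −log₁₀ *p* if the focal frequency exceeds the pool's,
+log₁₀ *p* (negative) if below, 0 at equality.

The SNP × population score matrix is hierarchically clustered (complete
linkage, Euclidean) and rendered as a red/blue heatmap; the SNPs most
diverged between two chosen populations are selected by
|*s*₍pop A₎| + |*s*₍pop B₎| > cutoff (default 60).

**Polygenic risk score.** For dosages *Xᵢ* ∈ {0, 1, 2} of the effect allele,

&nbsp;&nbsp;&nbsp;&nbsp;PRS = Σ βᵢ Xᵢ / (2 Σ βᵢ) ∈ [0, 1],

so a man homozygous for every risk allele scores exactly 1, one with no risk
alleles scores 0, and uniformly random dosages average 0.5 — for arbitrary
positive weights. A population's expected score under Hardy–Weinberg
equilibrium needs only allele frequencies: E[PRS] = Σ βᵢ fᵢ / Σ βᵢ.

**Ecological regression.** Population expected PRS (and, where supplied,
DHT:T ratio and vitamin D) are regressed by OLS against incidence and
mortality; predictors are ranked by R². Held-out populations (e.g. a Korean
panel known only through frequency tables) are placed on the fitted line as
predictions next to their observed rates. These are regressions over a
handful of population aggregates — R² here ranks predictors, it does not
estimate individual-level effects.

A fully synthetic study generator (Balding–Nichols frequency divergence with
per-population F, HWE genotype panels, linear-plus-noise epidemiology) makes
every stage testable end to end with known ground truth.

## Worked example

```bash
prscape simulate --seed 3 --out study          # synthetic 5-population study
cat > study/run.toml <<'EOF'
out_dir = "../run"
[inputs]
catalog = "catalog.tsv"
vcf = "genotypes.vcf"
sample_map = "samples.tsv"
epidemiology = "epidemiology.tsv"
[params]
cutoff = 60.0
pop_pair = ["AFR", "EAS"]
seed = 3
EOF
prscape run --config study/run.toml
```

`run/population_prs.tsv` then holds the expected PRS per population:

```
population  prs      n_used  n_missing
AFR         0.45243  200     0
EAS         0.47203  200     0
EUR         0.47504  200     0
SAS         0.48239  200     0
AMR         0.48999  200     0
```

and `run/regression_report.tsv` ranks the predictors:

```
predictor  response   slope     intercept  r_squared  n
PRS        incidence  1384.78   -446.65    0.991      5
VitD       incidence  -6.87     647.37     0.802      5
DHT:T      incidence  1622.44   35.18      0.205      5
PRS        mortality  696.87    -280.13    0.833      5
...
```

The genetic score explains the simulated incidence almost completely
(R² = 0.991; the generator built incidence from the true population PRS with
slope 1500 plus rate noise, and the fit recovers a slope of 1385 from five
points), while the weakly coupled hormone/vitamin covariates trail it —
the qualitative pattern this kind of analysis is designed to surface.
`run/divergent_snps.tsv` lists the 70 SNPs with |AFR|+|EAS| signed scores
above 60, and `run/heatmap.png`, `run/prs_bar.png`,
`run/prs_vs_incidence.png` hold the figures.

Each stage is also callable standalone (`prscape simulate / enrich / prs /
regress`) on the intermediate TSVs, and everything is importable as a
library (`import prscape`).

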