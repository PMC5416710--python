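# Methods

## Design

The pipeline estimates the causal effect of leukocyte telomere length (TL)
on cognitive traits using a genetic instrument, in three layers:

1. **Per-cohort models** (`cohort_models`). Raw T/S-ratio TL and each trait
   are Z-transformed within cohort (mean 0, sample s.d. with n−1
   denominator) — the raw T/S scale is lab-specific, so only standardized
   effects are comparable across cohorts. Three OLS fits per cohort and
   trait: trait~TL, TL~GRS, trait~GRS, each adjusted for sex, an age-group
   factor (0–29, 30–59, 60–79, 80+ years; youngest present group as
   reference) and declared study covariates. Age groups rather than linear
   age allow non-linear age effects. Missing data are removed listwise per
   model. Fits are delegated to `statsmodels.OLS`; adjuster columns without
   variation in the complete cases (a single-sex cohort, a single age
   group) are dropped with a logged warning rather than failing.
2. **Meta-analysis** (`meta_analysis`). Fixed-effect inverse-variance
   pooling, with Cochran's Q computed for k ≥ 2; when Q's P < 0.05 (the
   `switch_p` parameter) pooling is redone with DerSimonian–Laird random
   effects (method-of-moments τ², the standard choice when the
   random-effects variant is otherwise unspecified). CIs and P-values use
   the normal approximation (±1.96·se), matching how the consortium's
   printed CIs reconstruct from their betas.
3. **Causal stage** (`mr`). Wald ratio β_GY/β_GX with first-order
   delta-method SE (this SE convention reproduces the printed STROOP IV
   interval from the pooled inputs within rounding). Instrument strength
   F = (β_GX/se_GX)²; ratios with first-stage |Z| below `weak_z`
   (default 2) are refused. The observed-vs-causal difference Z-test
   treats the two estimates as independent — strictly conservative-ish in
   one-sample data where they are correlated, but it reproduces all six
   published difference P-values (0.13, 0.76, 0.34, 0.79, 0.04, 0.89) and
   is therefore taken as the consortium's procedure. Two-sample analysis
   uses the IVW estimator; a Z-score-only mode covers outcome GWAS that
   publish test statistics without effect sizes. A per-SNP ratio scan with
   heterogeneity Q is provided as a generic pleiotropy diagnostic.

## The genetic risk score

`grs` counts telomere-shortening alleles across the seven loci (range
0–14), unweighted. The counted allele is the shortening one so the pooled
first-stage slope is negative (≈ −0.05 s.d. TL per allele), matching the
reported instrument direction. Dosages may be fractional (imputed
genotypes). Missing dosages are mean-imputed at the Hardy–Weinberg
expectation 2·eaf (default), or the individual's score is set missing
(`drop`). Allele alignment handles swapped and strand-complemented
reporting; palindromic (A/T, C/G) variants with allele frequency in
[0.4, 0.6] are refused as strand-ambiguous, outside that band the
frequency resolves the orientation.

## Synthetic data

`synthetic_data` draws each cohort from a linear-Gaussian structural
model: Hardy–Weinberg genotypes G_j; latent standardized TL = Σ_j β_j(G_j −
2p_j) + γ·U + age-slope·(age − mean) + ε; raw T/S = μ_lab + σ_lab·Z(TL)
floored at 0.01; trait = θ*·Z(TL) + λ·U + age/sex effects + ε4 shift + ε,
with U ~ N(0,1) a shared confounder and θ* optionally modified in *APOE*
ε4 carriers. APOE genotypes come from two independent allele draws
(defaults ε2/ε3/ε4 = 0.08/0.77/0.15, ordinary European-ancestry values).

Defaults are the study-panel conditions: the 14 published cohort rows
(sizes 163–4117 summing to 17 052, their age distributions, T/S scales
0.68–3.7 and trait availability patterns); per-allele effects β_j = −0.05
s.d. and allele frequencies chosen so the score mean is 8.55 and s.d.
≈ 1.50 and the pooled standardized first stage lands near −0.05 s.d. per
allele (per-SNP truths are placeholders — the underlying TL GWAS values
are not asserted); θ = 0 for every trait with confounding γ = λ = 0.5, the
confounded-null configuration the coverage experiments assume; TL and
trait age slopes −0.02 s.d./year; ε4 trait shift −0.1 s.d.

What the generator does *not* emulate: linkage disequilibrium between the
seven loci (independence is what the unweighted score assumes), twin/family
relatedness within cohorts, qPCR measurement chemistry, longitudinal
attrition, and saliva-vs-blood tissue differences. Passing tests therefore
demonstrate correctness of the estimators under the stated structural
model, not robustness to those real-data features.

Two-sample summary statistics use the GWAS sampling approximation
se = 1/sqrt(2p(1−p)n) for a standardized phenotype; `exact=True` sets the
point estimates to their population values (the infinite-sample limit)
while keeping finite-n SEs, which makes IVW recover θ exactly — the
plug-in identity used as an oracle.

## Numerical choices and degenerate inputs

- All randomness flows from one master seed; per-cohort streams are
  `seed + seed_offset`, making runs bit-reproducible (the determinism test
  byte-compares two full report bundles).
- Z-transform refuses zero-variance input by name; it passes NaN through.
- Cochran's Q with k = 1 is undefined: pooling logs a note and stays
  fixed-effect. τ² is truncated at 0.
- A perfect OLS fit legitimately yields se = 0; the Wald stage guards
  against zero/weak denominators instead.
- Minimum complete cases per fitted stratum: 30 (configurable); smaller
  strata are skipped with a logged message, not an error, so sparse
  ε4-carrier strata degrade gracefully.
- File I/O uses shortest round-trip float formatting and round-trip
  parsing so `read(write(x)) == x` exactly, with `NA` missing markers and
  a `# seed=` header comment.

## Replicated-experiment problem sizes

Chosen once as the package's standard validation settings:

- Q calibration: 500 replicates of 12 homogeneous study estimates;
  rejection at 0.05 expected in [0.03, 0.07].
- Null calibration: 500 replicate cohorts of n = 200 under θ = 0 without
  confounding; observational P-values uniform by Kolmogorov–Smirnov.
- IV coverage: 1000 replicates of 4 cohorts × 3000 under the confounded
  null. This size gives pooled first-stage F ≈ 50, comparable to the
  published instrument (F ≈ 35 reconstructs from the printed pooled
  estimate); the delta-method Wald interval is mildly conservative and its
  coverage approaches the nominal 95% only when the instrument is strong,
  so weaker configurations over-cover. The weak-instrument floor is lifted
  (`weak_z=0`) inside the experiment so every replicate returns a ratio.

## Known limitations

- The difference Z-test ignores the one-sample correlation between
  observational and causal estimates (see above).
- The reconstructed first-stage F is 34.6 from the printed pooled estimate
  and CI, while the consortium prints 36 — their F likely comes from an
  individual-level first-stage regression unavailable here; the package
  reports the (β/se)² convention and does not force agreement.
- No MR-Egger / weighted-median estimators, Fieller intervals, or
  overlapping-sample corrections; the ratio scan is the only pleiotropy
  diagnostic.
- Family clustering is only addressable through study covariates.
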