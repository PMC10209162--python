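# Methods

This note documents the statistical model behind `mr2s`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for
reproducibility.

## The two-sample MR model

Each instrument *j* is a SNP with an estimated per-allele effect β̂ₓⱼ
(SE σₓⱼ) on the exposure from one GWAS and β̂ᵧⱼ (SE σᵧⱼ) on the outcome
from a second, non-overlapping GWAS.  Exposures are continuous traits
reported in SD units; outcomes are case-control traits reported as
log-odds, so causal effects are log-odds of outcome per SD of exposure
and are exponentiated to odds ratios in reports.  The identifying
assumptions are the usual ones: relevance (enforced by the p-value and
F-statistic screens), independence, and exclusion restriction (probed by
the Egger intercept and MR-PRESSO; partially relaxed by the weighted
median and RAPS).  Reverse-direction analyses use a disorder GWAS as
exposure; its betas are log-odds, so reverse effects are reported on the
beta scale (exposure SD per unit log-odds liability), not as odds
ratios.

## Pipeline stages and defaults

**QC** (`qc_filter`). Filters applied in the fixed order MAF →
biallelic → strand-ambiguous → INFO, each removed variant attributed to
the first filter that catches it so attrition counts are reproducible
(the order matches how the filters are conventionally listed; attribution
is otherwise arbitrary). Defaults: MAF ≥ 0.05 computed from the table's
own effect-allele frequency (an external reference-panel frequency table
can override it), palindromic A/T and C/G pairs always removed, INFO ≥
0.6 applied only where an INFO value exists.  Indels and multi-character
alleles are rejected at parse time; the pipeline is SNP-only.

**Clumping** (`clump`). Greedy index-SNP selection: restrict to
p ≤ p1, repeatedly promote the smallest-p unclaimed variant and discard
unclaimed same-chromosome variants within the window with r² ≥ r2_max.
Defaults window 10,000 kb, p1 = 10⁻⁶, r² = 0.05. Windows are measured
± window·1000 bp inclusive; p ties break by (chrom, pos, variant_id) so
output is row-order invariant; pairs absent from the LD table are
treated as unlinked, but a significant variant entirely missing from the
LD reference is a hard error (silently assuming independence would fake
instrument validity). Instrument strength uses the single-SNP
approximation F = (β̂ₓ/σₓ)², the standard for summary data, with a
strict F > 10 screen.

**Harmonization** (`harmonize`). Exposure orientation is the reference.
Outcome rows with swapped alleles get β̂ᵧ negated and eaf reflected;
rows matching only after complementing both outcome alleles are treated
as strand flips (unambiguous because palindromic SNPs were removed
upstream); anything else is dropped and counted. No allele-frequency
based inference is attempted.

**Estimators.** IVW defaults to multiplicative random effects — the SE
is never below the fixed-effect SE and grows with √(Q/(n−1)) under
heterogeneity; the fixed-effect variant is available via `re_mode`.
Egger pre-orients instruments to β̂ₓ ≥ 0, which the intercept's
identifiability requires, and applies the same multiplicative
overdispersion floor. The weighted median interpolates the weighted
empirical CDF of Wald ratios at probability 0.5 with weights
β̂ₓⱼ²/σᵧⱼ²; its SE is a parametric bootstrap (default 1000 replicates)
whose seed is a required argument — there is no silent nondeterminism.
RAPS defaults to the Huber score (c = 1.345) with a profiled
overdispersion variance τ² ≥ 0, the method's recommended robust
configuration; the τ² moment condition calibrates mean(ψ(t)·t) against
E[ψ(Z)Z] = 1 − 2Φ(−c) for standard normal Z. Its SE is an empirical
sandwich (score outer product over the squared numerical score
derivative). All CIs use the normal quantile 1.959964; p-values are
two-sided normal and floored at the smallest positive double.

**MR-PRESSO** (`presso_global`, `presso_outlier`, `trim_and_refit`).
The observed statistic is the leave-one-out weighted residual sum of
squares; the null is simulated by redrawing both outcome and exposure
betas from their estimated sampling distributions (the exposure side is
redrawn as well, following the original method) and recomputing the
statistic, leave-one-out estimates included, per replicate.  Monte-Carlo
p-values use the add-one estimator (1 + #{≥ obs})/(n_sim + 1), so the
smallest attainable p with the default n_sim = 1000 is 1/1001.  Outliers
are flagged at uncorrected per-SNP p < 0.05 (a Bonferroni option
exists); the pipeline trims flagged instruments only when the global
test is significant at 0.05, re-runs the global test on the trimmed set,
and reuses the trimmed set for the sensitivity estimators at that
threshold.  The distortion test is not implemented.  The per-replicate
simulated residuals are kept on the result object so the outlier test
never re-simulates; with a fixed seed results are bit-reproducible.

**Multiple testing.** Benjamini–Hochberg step-up across the outcomes of
one causal direction (the forward and reverse families are corrected
separately), delegated to `statsmodels.stats.multitest`.

## The synthetic generator

`simulate_pair` emulates what a summary-level MR analysis actually
consumes, directly on the summary scale:

- instrument effects γ: `n_instruments` (default 35, the scale of a
  well-powered biomarker GWAS) LD blocks carry γ ~ N(0, 0.25²) in
  exposure-SD units; proxies within a block carry r·γ with r = √r²
  (default block r² = 0.8, five variants per block, blocks 20 Mb apart);
- standard errors from the large-sample approximations
  σₓ = 1/√(n_exp·2f(1−f)) for a unit-variance exposure (default
  n_exp = 8,138, a neonatal-biomarker GWAS scale) and
  σᵧ = 1/√(n_out·v(1−v)·2f(1−f)) for a case-control outcome with case
  fraction v (default 0.5, n_out = 100,000), avoiding individual-level
  simulation that summary-level MR never sees;
- pleiotropy: a fraction `prop_invalid` of instrument blocks receives a
  direct outcome effect α, independent of γ in magnitude (InSIDE
  holds). Balanced mode pairs magnitudes antithetically so the mean is
  exactly zero (an odd invalid count is rounded down to even to keep
  this exact); directional mode draws N(alpha_mean, alpha_sd²) oriented
  to the exposure-increasing allele — the orientation that actually
  biases IVW and that the Egger intercept targets;
- allele bookkeeping: effect-allele frequencies uniform on [0.05, 0.5],
  random non-palindromic allele pairs plus a small palindromic fraction
  (2%) and a sprinkle of low-INFO variants so QC has work to do; 30% of
  outcome rows are allele-swapped and 30% strand-complemented so
  harmonization has work to do;
- two-sample noise: sampling errors independent between the exposure
  and outcome tables and across variants.

Not emulated: realistic genome-wide LD (blocks are equicorrelated
islands; cross-block r² is exactly zero), sample overlap between the two
GWAS, population stratification, winner's-curse-free three-sample
selection, allele-frequency differences between cohorts, and
individual-level covariate structure.  Passing tests therefore show the
machinery is correct under the stated model, not that real-data biases
(overlap, stratification, selection) are absent.

One emergent property worth knowing: instruments are selected on the
exposure GWAS's own p-values (as in the real two-sample design), so a
small winner's-curse attenuation (~1–2% of θ at the default sizes) is
visible in very tight CIs.  Tests that check CI coverage use replicated
designs where CI width dominates this bias.

## Experiment sizes

The statistical acceptance checks use: 2,000 replicates for IVW test
size and coverage under the null (30 instruments); 500 replicates for
the KS-uniformity check of the MR-PRESSO global p (the acceptance script
reports the KS distance at 2,000 replicates for a more precise value —
note the KS distance of a perfectly uniform sample exceeds 0.05 with
probability ≈ 0.16 at n = 500); 200 replicates for estimator recovery at
θ = 0.1 (50 instruments) and for the contaminated-instrument and
planted-outlier designs (30 instruments, MR-PRESSO n_sim = 1000).  These
sizes give Monte-Carlo SEs an order of magnitude below the effects being
checked.

## Known limitations

- The weighted median has an irreducible finite-sample bias under
  one-sided contamination: with 40% invalid weight the estimate sits at
  the ≈83rd weighted percentile of the valid ratio distribution, i.e.
  ≈ 0.97·σ_ratio above θ. This is far smaller than the corresponding
  IVW bias but is measurable at Monte-Carlo precision; it vanishes only
  as the invalid fraction shrinks or as per-ratio noise becomes balanced.
- Palindromic variants are dropped, never frequency-aligned; proxies
  are not searched for instruments missing from the outcome GWAS.
- Reproducing published disorder-by-disorder instrument counts requires
  the original cohort GWAS files and a 1000-Genomes European LD panel:
  supply the downloaded tables and a PLINK `--r2`-style long-format LD
  file through `mr2s run --config`, with instrument selection on the
  exposure p-values at 10⁻⁶ (primary) and 5×10⁻⁸ (sensitivity). Those
  inputs are access-controlled and large, so they are out of scope for
  the test suite.
- Liftover, imputation, genotype-level input, multivariable MR, mode
  estimators and SIMEX-corrected Egger are out of scope.
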