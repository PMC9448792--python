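# Methods

## Data model and coordinates

All intervals are held 0-based half-open internally. VCF positions (1-based)
are shifted at the read boundary; fragments, peaks, genes and region sets
(BED-like) pass through unchanged. Two intervals overlap iff they share at
least one base; a fragment covers a variant at internal position `p` iff
`start <= p < end`. Barcodes are matched as exact strings, including any
library suffix — silently normalising suffixes can collide cells across
libraries.

Only biallelic SNVs enter the allele model. Indels and multiallelic records
are skipped at VCF read time and tallied in the QC counters, as are records
with missing genotypes.

## Variant filtering

The hard filter removes variants with Fisher strand bias FS > 30 or
quality-by-depth QD < 2 (strict inequalities), then removes every member of
any run of `cluster_n` consecutive SNVs on a chromosome whose outermost
positions span at most `cluster_window` bp. Defaults are `cluster_n = 3`,
`cluster_window = 35` — the conventional short-variant clustering recipe
(3 SNVs / 35 bp); the cluster span is measured first-to-last within the run,
not pairwise, which is the standard and less aggressive reading. Records
with missing FS or QD pass the corresponding rule but are counted, so the
decision is auditable. Downstream analysis keeps heterozygous, phased
variants only; both filters commute and the selection is idempotent.

## Haplotype assignment and counting

Fragments, not reads, are the observation unit: a fragment contributes at
most one Bernoulli observation regardless of its read-pair support, so PCR
duplicates cannot be double-counted. Base observations below the quality
cutoff (default phred 20, the usual allele-counting convention) are dropped
before voting.

Each surviving observation implies a haplotype: an alt base places the
fragment on `hap_of_alt`, a ref base on the other haplotype, any other base
is recorded as `other`. A fragment is called `ref` or `alt` only when all
its informative observations agree on both the implied haplotype **and** the
ref/alt label. The label condition matters for multi-SNV fragments whose
markers have opposite phase orientation (alt of one SNV and ref of another
on the same haplotype): such a fragment is haplotype-resolved but has no
single ref/alt label, and is conservatively excluded as `ambiguous` rather
than being counted under either allele. Fragments whose observations are all
non-matching bases are `other` and excluded from ref:alt ratios and the
model response.

A fragment overlapping two abutting peaks contributes to both (peaks are the
analysis unit); the event count is reported in QC. Counting is sparse:
(peak, cell) pairs with no informative fragment are absent. Aggregation over
any partition of cells is exactly additive, and relabelling ref/alt together
with the phase swaps the ref and alt counts exactly — both properties are
enforced by tests against a brute-force oracle.

Mapping-bias correction (variant-aware realignment) is an upstream concern;
the simulator injects no reference bias by default and exposes a `ref_bias`
knob to probe robustness.

## Aggregate binomial ASCA test

Per-peak totals must satisfy ref+alt > 20, ref > 5 and alt > 5 (strict, as
these screens are conventionally printed) before testing. The test is the
exact two-sided binomial test of alt successes out of ref+alt trials against
p = 1/2, using the minimum-likelihood tail (the sum of outcome probabilities
no larger than the observed one), which is symmetric in ref and alt.
Benjamini–Hochberg step-up adjustment is applied across tested peaks.

A caution that the test suite makes explicit: the test is exactly calibrated
when every fragment is a fair coin (true proportion 1/2). If samples carry
genuine per-sample allelic imbalance — in the generator, a random intercept
u_s with σ_u > 0 entering every fragment's alt probability — the aggregated
counts are overdispersed relative to the binomial even though
E[logistic(u)] = 1/2, and the rejection rate of the aggregate test depends
on the single cohort draw of mean(logistic(u_s)) shared by all peaks. This
anti-conservatism under per-sample imbalance is precisely the
pseudo-replication problem that motivates the fragment-level mixed model.

## Peak–gene linking

For each gene, candidate peaks have midpoints within `window_bp` (default
500,000 bp, the convention of published gene-enhancer linking methods) of
the TSS (gene start on `+`, gene end on `-`; strand is required input). The
observed statistic is the Pearson correlation of per-cell peak counts with
per-cell expression. The null is the correlation of the same gene with
`k_background` (default 200) peaks drawn from outside the gene's window,
nearest to the candidate peak in z-scored (GC fraction, mean accessibility,
width) space, with deterministic (distance, peak_id) tie-breaking. The link
statistic is z = (r_obs − null_mean)/null_sd with a two-sided normal
p-value. Matching implements the correction for GC, accessibility and
width; distance is handled by the window restriction and reported per link
rather than regressed out. GC content is computed as (G+C)/(A+C+G+T) with
ambiguous bases excluded from the denominator. Zero-variance peaks or genes
skip the link with a recorded reason.

## The mixed-effect logistic models

For one peak–gene combination the design has one row per allele-informative
fragment: response y = 1 iff the fragment carries the alternate allele;
x = the linked gene's imputed expression in the fragment's cell, min–max
normalised per gene to [0, 100] over the analysed cell population (the
simplest reading of a 0–100 normalisation; a constant gene has no range and
is dropped); d = the disease indicator (control = 0). Models:

- `base`: logit P(y=1) = β₀ + β_expr·x + u_s
- `m2`:   + β_dia·d
- `m3`:   + β_dia·d + β_int·x·d

with u_s ~ N(0, σ_u²) per sample — a random intercept only, no random
slopes. Because expression is on a 0–100 scale, β_expr is the log-odds
change per 1 % of the expression range; exp(10·β_expr) is the odds
multiplier for a 10 % increase.

**Estimation.** The marginal likelihood integrates u_s by adaptive
Gauss–Hermite quadrature: per sample, a damped Newton search finds the
posterior mode and curvature of u (the per-group objective is strictly
concave), and the integral is evaluated on 9 mode-centred, curvature-scaled
Hermite nodes (1 node reproduces the Laplace approximation; both are
exposed). The outer optimisation is L-BFGS-B over (β, log σ_u) with an
analytic gradient from Fisher's identity (the posterior-weighted joint
score), followed by a few damped Newton steps on the objective itself with
finite-difference curvature — the σ profile is nearly flat near its
optimum, and quasi-Newton alone can stop visibly short of the ridge top.
Convergence requires gradient max-norm < 1e-5 (relative likelihood change
tolerance 1e-8, 200 iterations cap). σ_u is optimised on the log scale with
a lower bound; at the boundary the model is reported as the plain logistic
endpoint and σ's standard error is undefined. A pinned mode (`fix_sigma=0`)
computes the exact plain-logistic endpoint, used for boundary-identity
checks and conceptually by the per-donor fits.

**Inference.** Standard errors come from the observed information (central
finite differences of the marginal log-likelihood at the optimum, inverted;
the β block is reported). Wald z = β̂/SE, two-sided normal p, and 95 % CI =
β̂ ± 1.96·SE. No profile-likelihood intervals are computed. Fits with
|β̂| > 15 are flagged as likely separation and their CIs should not be
trusted. The implementation is cross-checked in the test suite against
`lme4::glmer` (nAGQ = 9) on identical datasets: coefficients and σ̂_u agree
to ~1e-4 and standard errors to better than 0.2 %.

Per-donor fits are ordinary maximum-likelihood logistic regressions of the
base model on one sample's fragments (no random effect). A combination is
"nominal" in a donor at Wald p < 0.05; among combinations nominal in two or
more donors, sign concordance means all nominal donors agree on the sign of
β_expr. Multiple-testing summaries count nominal and BH-adjusted discoveries
per model across all peak–gene combinations of that model.

## Interval overlap and enrichment

`overlap_with_flank` expands subject intervals by a flank (clipped at zero)
and reports query intervals with ≥1 bp intersection — "within 1 kb" is
flank-1000-then-intersect. Enrichment is the upper-tail hypergeometric
probability P(X ≥ hits) for drawing the query from an explicit universe; no
default universe is baked in because enrichment is meaningless without a
stated one (e.g. all tested peaks).

## The synthetic cohort generator

The generator emulates the study design generatively, at desk scale by
default: 12 libraries (6 control, 6 disease), 300 cells per library, 500
peaks on one synthetic chromosome, 400 genes, one phased het SNV per peak
(80 % of peaks; a multi-SNV mode exercises the haplotype-consistency
logic). Per-gene expression is lognormal across cells. Fragment coverage
per (cell, peak) is negative binomial (mean 0.1 fragments/cell/peak,
gamma-Poisson with dispersion 0.5) to mimic snATAC sparsity; linked peaks'
coverage is modulated by the target gene's standardised log-expression
(`link_strength`), so accessibility genuinely correlates with expression at
planted pairs. Each fragment overlapping its peak's SNV emits a base: alt
with probability logistic(β₀ + β_expr·x + β_dia·d + β_int·x·d + u_s), where
x is the gene's min–max-normalised expression and u_s the per-library
intercept. Truly linked peaks couple to their nearest gene TSS, mirroring
cis-regulation. Emitted files round-trip byte-exactly through the package's
readers, a truth table records every draw, and identical seeds give
byte-identical outputs.

What the generator does **not** emulate: real genome sequence (GC is an
independent peak attribute), mapping and reference bias (except via the
explicit `ref_bias` knob), doublets, ambient contamination, cell-type
mixtures, or label-transfer error in the imputed expression. Passing tests
therefore demonstrate statistical correctness of the estimators under the
stated generative model, not robustness to those real-data artefacts.

A separate lightweight generator produces peak×cell count and gene×cell
expression matrices with links planted as a shared latent Gaussian factor
(correlation ρ before Poisson/lognormal observation noise) and nuisance
features varied so background matching is nontrivial; it is the fixture for
link calibration and power checks.

`simulate_glmm_design` generates single peak–gene design tables directly
(12 samples × 2,000 fragments by default) and is the instrument for
parameter-recovery, coverage, type-I-error and boundary experiments.

## Problem sizes used in validation

Simulation scales were chosen to give stable Monte-Carlo estimates on a
single CPU in minutes: binomial calibration uses one cohort of 10,500
filtered peaks (~3.8 M fragments); mixed-model recovery uses 200 replicates
of 24,000 fragments; the counting oracle checks 1,000 random ≤50-fragment
instances against exhaustive enumeration; link calibration uses 500 cells,
300 peaks and 40 genes. The cross-donor concordance and interaction-power
experiments state their effect sizes in the corresponding tests.

## Known limitations

- The aggregate binomial test's calibration statement holds only under a
  fragment-level fair null (see above); per-sample imbalance inflates it.
- One random intercept per sample; random slopes and beta-binomial
  peak-level alternatives are out of scope.
- The matched-background null for links assumes background correlations are
  exchangeable with the candidate's null correlation after matching on
  (GC, accessibility, width); residual distance confounding within the
  window is reported, not removed.
- Wald inference near separation (rare alleles, small donors) is flagged
  but not replaced by exact or penalised alternatives.
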