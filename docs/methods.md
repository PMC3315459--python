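# Methods

## The detection model

Allele-specific expression is measured as allelic read counts `(b, c)` at
heterozygous SNPs distinguishing the two parental strains (labelled B =
C57BL/6J and C = CAST/EiJ throughout; crosses are written
maternal-strain-first, so BxC has a B mother). The elementary test is a
Pearson chi-square goodness-of-fit of `(b, c)` against the balanced
expectation `(n/2, n/2)`, one degree of freedom, **no Yates continuity
correction** — the statistic reduces to `(b - c)^2 / n`. The correction is
deliberately omitted: the procedure is defined by its uncorrected form
(e.g. a 30/70 split gives chi-square 16, p = 6.33e-5; with the correction
it would be ~9.6e-5, a different test).

An imprinting call combines one sample from each reciprocal cross and
requires, in both samples simultaneously:

1. depth `n >= min_reads` (default 10) — the *powering* rule; a unit
   failing it is `underpowered`, never `not_imprinted`;
2. chi-square `p < alpha` (strict inequality, matching the "p < 0.05" and
   "p < 1e-4" operating points; ties at the threshold do not call);
3. reciprocity: the maternal-strain allele carries more than half the
   reads in both samples, or less than half in both. An exact 50:50 tie
   has no direction and voids reciprocity.

Two operating points are preconfigured: `SNP_CRITERIA` (alpha = 0.05,
SNP-level replication) and `GENE_CRITERIA` (alpha = 1e-4, applied to
per-gene sums of allelic counts over the gene's SNPs; at this threshold
the empirical FDR on real datasets of this design is below 0.05).
Gene-level calls can alternatively be derived from SNP-level calls
(`call_gene_via_snps`: imprinted iff >= 1 imprinted SNP; direction from the
most significant imprinted SNP, ties broken by lowest genomic coordinate).

The signed imprinting score is `±(-log10 p_used)` with `p_used` the *less*
significant (larger) of the two per-cross p-values; the sign convention is
fixed here as maternal-positive. The score exists only for reciprocally
biased units.

Sex-specific calls compare the reciprocal analysis within each sex: a unit
is sex-specific only when imprinted in one sex and *powered but not
imprinted* in the other. If the other sex lacks coverage the verdict is
`underpowered` — lack of data is never promoted to evidence of
specificity.

The chi-square p is an asymptotic approximation to the exact binomial
two-sided p and is mildly **anti-conservative at moderate depths**: at
depth 50 the per-sample probability of reaching p < 0.05 with a majority
is 0.0325 rather than the nominal 0.025, so the two-cross null call rate
is ~2.1e-3 rather than the asymptotic 2·(alpha/2)^2 = 1.25e-3. The test
suite checks the caller against the exact binomial enumeration, not the
asymptotic value. This inflation is one more reason the pipeline relies on
*empirical* rather than nominal error control.

## Empirical false discovery via mock crosses

Because a call demands reciprocal bias, comparing two samples of the same
cross direction as if they were reciprocal (a **mock cross**) cannot detect
imprinting; everything it "finds" is technical/biological noise. The
empirical FDR at threshold `t` is the pooled significant-unit count over
mock pairs divided by the pooled count over reciprocal pairs, both computed
from the same depth-normalized count table. Pooling is by **summing**
counts across pairs (a union-of-sets mode is available via
`pooling="union"`); which of the two the original curve construction used
is not determinable, so both are provided and sum is the default.

Depth normalization drops SNPs on chrX and chrM (dosage differs between
sexes / is uniparental) and thins every sample to the smallest sample's
total by multivariate hypergeometric draws over its allelic counts —
removing reads without replacement, exactly what discarding aligned reads
does at the count level. Downsampling curves reuse the same thinning at a
grid of fractions (default 100 iterations per fraction, mean ± SE;
fraction 1.0 is a no-op and reported with SE 0).

Default mock pairing: within-cross, same sex when two same-sex samples
exist, otherwise mixed sex (empirically the two give equivalent
false-positive counts). Reciprocal pairs are sex-matched when possible.

Sensitivity is the fraction of *known* imprinted genes, powered for
detection (>= 1 SNP or the aggregate with >= 10 reads in both samples),
that meet significance in the reciprocal arm.

## Within-exon concordance and the sampling null

Two SNPs in one coding exon sample the same transcript pool, so their
directions of allelic bias must agree; discordance at stringent
significance measures sequence-dependent systematic error. Pairs are
enumerated within non-redundant coding exons (overlapping coding exons
resolved to the longest, ties to the lower start coordinate; non-coding /
UTR-bearing models excluded by their coding flag), keeping only pairs
separated by strictly more than 40 bp — one read length — so no single
read covers both SNPs. Each pair is thresholded on its less significant
p-value.

The simulated null regenerates the **more** significant SNP of each pair
under pure random sampling: its counts are replaced by the partner's
allelic ratio scaled to its own total depth, then perturbed by a
chi-square(1) deviate by inverting Pearson's formula
`(x - e_B)^2 (1/e_B + 1/e_C) = chi2` — a quadratic with two roots, one
chosen uniformly at random (no rule is implied by the construction;
the choice is seedable), rounded to integer counts and clamped to
`[0, n]`. The regenerated SNP is re-tested and the discordance curve
rebuilt; means and spreads are reported over iterations. Replacing the
more significant member keeps the pair's thresholding variable (the less
significant p) comparable with the observed curve; the alternate mode
(replace the less significant) yields still lower expected discordance and
is available for sensitivity analysis. Rounding before re-testing is the
default (the procedure as actually runnable on integer counts); an
exact-real mode is available via `round_counts=False`. Pairs whose
regenerated SNP lands on an exact tie, or whose partner ratio is degenerate
(0 or 1, leaving nothing to perturb), are excluded from that iteration and
tallied.

## Pyrosequencing-style validation

RNA allelic percentages are calibrated against the same assay run on F1
hybrid genomic DNA — a guaranteed 50:50 template — by subtracting the mean
DNA percentage; this removes assay-intrinsic bias (a transcript reading
57% B against a 57% DNA baseline carries no signal, while 64% vs a 57%
baseline is +7). The detection threshold is `k = 2` standard deviations of
the difference in allelic ratio between biological replicates (default
5.02 percentage points). A transcript is called imprinted when every
pairing of a BxC with a CxB replicate shows opposite-signed corrected
biases differing by more than the threshold; a replicate-averaged mode is
available (`per_replicate=False`) because the construction is ambiguous
about whether the rule binds each pairing or the averages — per-replicate
is the stricter reading and the default. The report carries `z_units`
(delta in replicate-SD units) rather than a p-value: mapping 2 SD to a
tail probability depends on one- vs two-sided conventions, so no p is
asserted.

## The synthetic-data generator

For SNP `k` of gene `g` in sample `s`, the B-allele probability is

    theta = logistic( s_g + e_k + b_{g,s} + I_g * beta_g * u(cross, dir, sex) )

with `count_B ~ BetaBinomial(n, theta, rho)` (binomial at rho = 0) at
per-SNP log-normal depths. The terms model distinct failure modes:

| parameter | scale | default | role |
| --- | --- | --- | --- |
| `strain_effect_sd` | logit | 0.3 | cross-symmetric cis strain bias (`s_g`) |
| `snp_bias_sd` | logit | 0 | per-SNP offset `e_k` shared by **all** samples: sequence-dependent library/alignment error. Inflates same-exon discordance, but being identical in both crosses it cannot mimic imprinting |
| `bio_sd` | logit | 0 | per-sample-by-gene deviation `b_{g,s}`: biological variation. This is what creates reciprocal-looking false positives in mock and reciprocal comparisons alike |
| `rho` | [0,1) | 0 | beta-binomial overdispersion (read-level non-independence) |
| `beta_imprint_mean/sd` | logit | 2.5 / 0.5 | imprinting effect `beta_g`; `u` = +1/-1/0 by cross, direction, and (for sex-specific genes) sample sex |
| `depth_median`, `depth_log_sd` | reads | 50, 1.0 | log-normal depths truncated at 1, spanning the 10-read powering rule |
| `snp_spacing_choices` | bp | (25, 60, 120, 300) | inter-SNP gaps producing both excluded (<= 40 bp) and eligible pairs |

The decomposition of "noise" into a cross-symmetric per-SNP term and a
per-sample biological term is this package's modelling choice: it lets one
dial reproduce the discordance pathology and the other the mock-cross
false positives, independently. Noise defaults are zero so that the
clean-null regime is the baseline; the scenario values used in tests are
set per analysis. Genes are laid out on 5 autosome labels with exons of at
most 3 SNPs (margins kept below half the minimum SNP gap so exons never
overlap); the truth table records every generative draw, and
`truth_eval` converts any gene-level comparison into TP/FP/FN/TN, true FDR
and recall per threshold.

What the generator does **not** emulate: read-level sequences and
alignment (so mapping bias enters only through `e_k`), reads spanning two
SNPs (aggregation double-counts them, as any count-level aggregation
must), transcript-length or expression-level structure beyond the depth
distribution, linkage between neighbouring genes, and chrX/chrM dosage
(excluded chromosomes are exercised by constructed fixtures instead).
Passing tests therefore demonstrate correctness of the *procedures* under
the stated generative assumptions, not calibration on any real library.

## Problem sizes and scenario parameters used by the test suite

Chosen to make every Monte-Carlo bound decisive at desk scale:

* null calibration: 25,000 genes (~123,000 SNPs) at fixed depth 50,
  checked against exact binomial enumeration within 3 SE; mock/reciprocal
  FDR ~ 1 within 3 SE of the count ratio;
* sampling-null discordance: 100,000 shared-ratio pairs (ratios 0.5–0.9,
  log-normal depths clipped to [20, 1000]), bound 0.1% at p <= 1e-4;
* systematic-bias scenario: 2,000 genes, `snp_bias_sd = strain_effect_sd
  = 0.5`, depth median 150;
* mock-FDR tracking: 600 genes, 15% imprinted, `bio_sd = 0.4`,
  `rho = 0.01`, thresholds 1e-2…1e-5, agreement within 3 SE of both
  estimators;
* power: beta = 2 at fixed depth 200/cross (noncentrality ~116 per cross),
  400 genes, against the analytic normal-approximation power oracle;
* downsampling: 120 genes, fractions (0.3, 0.6, 1.0), 100 iterations.

## Numerical and degenerate-input conventions

* Coordinates are 0-based half-open internally (BED native); VCF `POS` and
  the flat SNP TSV are 1-based on disk and shifted on ingest.
* Zero-depth units: chi-square and maternal fraction are undefined
  (`UndefinedTestError` scalar-wise, NaN vectorised); such units are
  underpowered, never called.
* A SNP inside two overlapping genes contributes to both gene aggregates
  and is flagged `multi_gene`.
* Strand is carried on gene models but ignored by all statistics (counts
  are allele-level).
* `p_used = max(p_1, p_2)` uses `fmax`, so a NaN p (zero depth on one
  side) does not poison the other side's value; calls still require both
  depths.
* Thresholding is strict (`p < t`) everywhere, including curve
  construction.
* The generic extrapolation of the total imprinted-gene count,
  `(confirmed + rate * untested) / sensitivity`, is supplied as stated;
  published applications of this kind of estimate do not always decompose
  into these operands, so it is a planning tool, not a reproduction of any
  particular figure.

## Known limitations

* The caller inherits every pathology of the chi-square ASE test by
  design; the package's contribution is measuring those pathologies, not
  fixing them (no beta-binomial likelihood test, no analytic FDR model —
  the estimator is deliberately empirical).
* Mock-FDR estimates are ratios of small counts at stringent thresholds
  and inherit the corresponding variance; the curves report the raw counts
  so users can judge.
* Candidate ranking's "extension of a known imprinted transcript" flag is
  purely positional (distance 0 to a catalog entry); transcript-evidence
  judgements are out of scope.
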