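# Methods

This note documents the models, conventions and numerical choices behind
`epimask`, and what the synthetic fixtures do and do not establish about
real array data.

## Probe geometry

All coordinates are 1-based inclusive internally; BED emission converts to
0-based half-open, and the BED reader converts back on ingest (the reader
logs the convention applied, since mixed interval conventions are the
classic silent bug in this space).

A probe interrogates the CpG dinucleotide at `[c, c+1]` where `c` is the
manifest position of the target C. With probe length `n` (default 50, the
standard Infinium probe length; configurable):

- **Type II** chemistry extends at the interrogated C itself. The body lies
  entirely on one side of the CpG, abutting it: `[c−n, c−1]` (body left) or
  `[c+2, c+1+n]` (body right). The SBE site is the target base adjacent to
  the body terminus (`c` left, `c+1` right), so SBE overlap is subsumed by
  target-CpG overlap for Type II.
- **Type I** chemistry extends at the base beyond the CpG: the body covers
  the CpG at its terminus (`[c−n+2, c+1]` left, `[c, c+n−1]` right) and the
  SBE site is the single base just past the CpG on the opposite side
  (`c+2` left, `c−1` right). It is disjoint from both the target and the
  body.

The *near-target body* is the set of body positions within 5 bases of either
target base, minus the target itself. The three variant-confounding
categories — target CpG, Type-I SBE, near-target body — therefore partition
positions cleanly, while one variant (e.g. a long deletion) can still hit a
probe in several categories, and its full reference span `[pos,
pos+len(ref)−1]` is used for closed-interval intersection. Full-span
intersection is the conservative choice: a deletion that merely brushes the
5-bp window still masks the probe.

Orientation (`left`/`right`: which side of the CpG holds the body) is
derived from the manifest strand column by a fixed documented table
(`F`/`TOP`/`+` → right, `R`/`BOT`/`−` → left), overridable per call, since
vendor strand semantics differ between manifest generations. Flipping
orientation mirrors the geometry about the CpG centre `c + 0.5`; this is
verified exhaustively in the tests.

## Consensus variants and MAF

Per-sample VCFs are merged by `(chrom, pos, ref, alts)`, keeping PASS (or
`.`) records only and summing allele counts. Missing genotype alleles
reduce the allele number AN rather than counting as reference — standard
allele-frequency semantics. The cohort MAF is the maximum over alternate
alleles of the folded frequency `min(AC/AN, 1 − AC/AN)`, so it lies in
[0, 0.5]. Masking keeps entries with MAF strictly greater than 0.01 by
default (a `>=` mode exists). Indels are not left-normalised; inputs are
assumed normalised upstream.

## DMP model

Per CpG, ordinary least squares of β on an intercept, a binary group
indicator (second sorted level coded 1) and the adjustment covariates
(categoricals dummy-coded). The group coefficient's t statistic with
`n − p` degrees of freedom gives a two-sided p; Benjamini–Hochberg step-up
q-values are computed across all tested probes. Significance requires both
q < FDR (default 0.05) and |Δβ| above the per-arm threshold (0.20 for
ancestry-style contrasts, 0.30 for tumour-vs-normal contrasts).

Δβ is reported on **raw group means**, because the effect threshold is
defined on the β difference between groups; the covariate-adjusted group
coefficient is emitted alongside (`adjusted_delta_beta`) for plotting and
sensitivity checks. Probes with any missing β or zero residual variance are
excluded and counted. An optional empirical-Bayes variance squeeze
(pooled-prior, `prior_df` pseudo-observations towards the cohort mean
residual variance) is available but off by default: at the simulated effect
sizes and n = 20/20 the moderated and plain t tests agree on every planted
call, so plain OLS is the simpler default.

## DMR model

Squared t statistics are smoothed per chromosome with a Gaussian kernel over
genomic distance: bandwidth λ = 1000 bp (kernel truncated there), kernel sd
σ = λ/C with scaling factor C = 2. Under the null each t² is treated as
χ²₁, so the weighted sum S = Σ wⱼ t²ⱼ is approximated by Satterthwaite
moment matching: S/c ~ χ²ₖ with c = Σw²/Σw and k = (Σw)²/Σw². Smoothed
p-values are BH-adjusted; CpGs with smoothed q < 0.05 are grouped into
regions whenever consecutive significant CpGs are ≤ λ apart; regions need
≥ 5 CpGs and |mean Δβ| above the per-arm threshold (0.10 / 0.20). The
region-level combined p is Fisher's method over the constituent raw
per-CpG p-values. As C → ∞ the kernel collapses to the probe itself and
the smoothed statistic degenerates to the per-CpG χ²₁ test (a limit the
tests check). For small cohorts a permutation null is available
(`null='permutation'` with a matrix of t statistics from label-permuted
refits) in place of the χ² approximation.

## Deconvolution

Bulk β is modelled as a non-negative mixture of sorted-cell reference
profiles: minimise ‖Rw − b‖² subject to w ≥ 0, Σw ≤ 1 (SLSQP; the contract
is the optimum, not the algorithm — tests verify the returned objective
beats 1,000 random feasible points). The inequality leaves an implicit
"other" compartment; an equality mode exists. Purity is the weight of the
designated tumour-lineage type (default `T-luminal`). The quartile filter
retains samples with purity ≥ the group's 75th percentile (linear
interpolation; boundary ties retained) and refuses groups smaller than 4.
The signature selector ranks candidate CpGs by between-type sum of squares
and balances hyper-/hypo-extremes of the leading contrast within the
top-2q pool, so a direction with no informative CpGs never displaces
genuinely discriminating ones.

## Enrichment and validation statistics

Fisher's exact test is two-sided by full enumeration of the conditional
hypergeometric likelihoods (tables at most as likely as observed — the
`fisher.test`/scipy convention); the odds ratio is the conditional MLE, so
zero cells still yield finite estimates. The permutation overlap test draws
size-matched sets uniformly without replacement from the tested background;
the empirical p is the plain proportion of draws with overlap ≥ observed
(no pseudocount, matching the definition of an empirical proportion; a
+1/(n+1) option exists because p = 0 is otherwise reportable). Note this p
is conservative (super-uniform) when the null overlap distribution is
concentrated on few values — e.g. small sets in a large background — which
is inherent to discrete empirical p-values, not an implementation artefact.
Composition-matched sampling (stratified by an annotation label) is
available as an optional mode. Region sets are matched by ≥ 1 bp overlap.

Wilcoxon rank-sum comparisons of per-sample context medians use exact
enumeration when both groups have ≤ 8 samples and the tie-corrected normal
approximation otherwise. Levene's test centres on the median by default
(Brown–Forsythe variant, robust for bounded skewed β) with a mean option.
Hierarchical clustering is Ward on Euclidean observation vectors — the
`ward.D2` variant, squaring distances inside the update. PCA centres probes
without unit-variance scaling (β values already share a scale) and reports
variance fractions recomputable from the scores to 1e−8.

## Synthetic data

The generators are the package's study conditions, fixed once:

- **Manifest + VCF**: probes at 1 kb spacing across two chromosomes, 16%
  Type I (the approximate EPIC chemistry mix), alternating orientations.
  Around every probe a variant is planted at each geometry-relevant offset
  class — on either target base, on the Type-I SBE base, 1 and 5 bases into
  the near-target body, 6 bases in (just outside the window), outside the
  probe, and a 4-base deletion straddling the window edge — with MAFs
  cycling through {0.005, 0.01, 0.02, 0.05, 0.2}. The cohort VCF carries
  100 diploid samples (AN = 200) so every planted MAF, including the 0.01
  boundary, is exactly representable as an allele count. Truth tables are
  computed from the design rules with arithmetic written independently of
  the geometry module.
- **β cohorts**: two groups of 20 samples; per-probe baselines from a
  bimodal mixture (CGI-like N(0.15, 0.05), open-sea-like N(0.85, 0.05));
  isolated planted DMPs of Δβ = 0.4 and 8-CpG regions at 100 bp spacing
  with a coherent Δβ = 0.3 on low-baseline (CGI-like) blocks; optional age
  slope; truncated Gaussian noise of sd 0.05 on the β scale. Truncated
  Gaussian noise is simple and bounded; a logit-normal mode would be more
  realistic near the boundaries and is the main place the noise model is
  idealised.
- **Replicates**: samples duplicated with independent truncated noise
  (sd 0.01 emulates cross-platform technical replication; sd 0 gives
  bit-identical pairs).
- **Mixtures**: three cell types with anchor-CpG profiles, Dirichlet(5, 3, 1)
  weights, noise sd 0.02.

What passing tests show: the classifier, the statistical machinery and the
pipeline behave exactly as specified on data whose generative model is
known. What they do not show: robustness to array normalisation artefacts,
batch and chip effects, probe cross-reactivity, cell-composition
confounding beyond the explicit mixture model, or β distributions with
heavy boundary inflation — those require real cohorts.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; the pipeline refuses
silent clock seeding and writes a provenance record (input hashes, config,
seed, version) per stage, skipping completed stages unless forced. The
acceptance script runs its checks at the sizes the properties are stated
for — 1,000 random mask configurations, 60 × 10,000-probe null cohorts for
FDR calibration, 100 planted DMPs for power, 20 planted regions among
50,000 CpGs for DMR recall with 10 null cohorts for specificity, 100
mixtures for deconvolution, 10,000 permutation draws — chosen so the full
script completes in well under a minute per check on one core.

## Known limitations

- No IDAT-level preprocessing, normalisation or batch correction: the
  toolkit consumes normalised β matrices.
- No liftover: probe and variant builds must match on input.
- No left-normalisation of indels; no phasing or LD awareness.
- The Satterthwaite null treats per-CpG t² as χ²₁, slightly liberal at very
  small n; the permutation null is the fallback there.
- Gene-set enrichment with array probe-bias correction and
  enhancer-target-gene inference are out of scope; generic interval overlap
  and the expression-support filters are provided instead.
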