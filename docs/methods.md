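# Methods

## Scope and model

`methage` analyses probes × samples matrices of methylation beta values in
[0, 1], as produced by Infinium-style arrays, together with per-sample
annotation (age, sex, AD/control/normal group, dataset id) and a reference
panel of purified leukocyte subtype profiles tagged myeloid (monocytes,
granulocytes, neutrophils) or lymphoid (B, NK, T cells). The central model is
additive at the probe level:

    β_bulk(probe, sample) = Σ_subtype w_s(sample) · β_s(probe)
                            + intrinsic effects + noise,

with nonnegative mixing weights w summing to one. Bulk association signal can
enter either through the intrinsic term or through age/disease-dependent
drift of w — the concordance framework's job is to tell these apart at the
list level, not to adjust individual regressions (no per-probe cell-count
covariates are used anywhere; that is a deliberate scope boundary).

## Preprocessing

β = max(M, 0)/(M + U + 100). The +100 offset is a fixed stabilising constant
of the definition, not a tunable. Entries with non-positive denominator
(possible when M < −100) are marked missing and counted in the QC report.
Stage order is fixed: sample-missingness filter (strict > 0.10), kNN
imputation, outlier removal, probe filter. Imputation precedes outlier
removal so the inter-array correlations need no pairwise-complete handling.

Imputation copies from the nearest *probe row* (k = 1 by default, the
expression-matrix convention): plain Euclidean distance over mutually
observed samples, donors restricted to rows observed at the target sample,
ties kept in input order. Outlier removal computes each sample's mean
Pearson correlation with all others and removes samples more than 2
population-SD *below* the mean of those means — only the low side, since an
above-mean sample is maximally typical — repeating up to 3 times or until
nothing is removed. With very few samples a single extreme array inflates the
SD enough to mask itself; roughly ten clean arrays are needed before the rule
engages reliably.

## Age associations

Per probe, OLS of β on age plus covariates (categoricals one-hot encoded,
intercept included). Because all probes of one dataset share the design
matrix, the fits are vectorised through a single (XᵀX)⁻¹Xᵀ; the age
coefficient's two-sided t p-value is reported (sidedness is a package
choice). Constant rows return slope 0, p = 1, flagged degenerate; rank
deficiency raises an error naming the collinear columns. BH adjustment is
applied within each dataset. Integration across datasets requires: q < 0.05
somewhere, unadjusted p < 0.05 in at least one *other* dataset, and no pair
of datasets where the probe is nominally significant with opposite signs — a
non-significant opposite sign is treated as noise, not contradiction.

## Rank-product differential methylation

For classes of sizes n₁, n₂, all n₁×n₂ between-class pairs contribute a
per-probe β difference (differences, not ratios: betas are bounded and may be
zero, so fold changes are ill-defined — a deliberate adaptation of the
expression-ratio original). Within each pair, probes are ranked with rank 1
most extreme in the tested direction (average ranks on ties); the statistic
is the geometric mean of ranks across pairs, computed for hyper and hypo
directions separately (the two are mirror images: average ranks of a vector
and its negation sum to m + 1).

The permutation null shuffles probe labels **within each array** and
recomputes pair differences and ranks. This detail matters: shuffling each
pair's ranks independently would destroy the correlation of a probe's ranks
across pairs sharing a sample and produces a grossly anticonservative null
(we measured ~30% of null probes at p < 0.01 in a 48 vs 9 design); the
per-array scheme preserves it and is calibrated. p-values come from the
pooled null (all probes × permutations): p_g = fraction of null rank
products ≤ observed; pfp_g = p_g · m / rank_g is the percentage of false
prediction used as the FDR analogue. Default 100 permutations, seed
mandatory; tiny instances can enumerate all (m!)ⁿ shuffle combinations
exactly, which the tests exploit against an independent brute-force oracle.

Known limitation: the pooled null cannot represent probe-specific variance,
so probes with strongly inflated dispersion (e.g. steep age slopes inside a
wide-age-range cohort) are over-called — one reason case/control cohorts
should be age-restricted and age-matched, as the synthetic AD cohort is.

ML-CpGs (myeloid vs lymphoid) use a per-probe Welch t-test across panel
replicates with BH-FDR, keeping the signed myeloid−lymphoid mean difference
for the concordance analyses.

## Deconvolution

Markers are the `n_markers` (default 500) probes with the largest variance of
*subtype-mean* betas (means, so heavily replicated subtypes do not dominate;
variance rather than range or F-statistic is a package choice), ties broken
by probe id. Per sample, `scipy.optimize.nnls` solves min‖A x − b‖², x ≥ 0 —
nonnegativity constrained, sum-to-one not enforced; the raw weight sum is
kept as a quality metric and weights are renormalised for lineage fractions.
Markers missing in a sample are dropped below 10% missingness, error above.
Lineage fractions are sums of normalised subtype weights; Spearman rank
correlation (two-sided) relates them to age. With two lineages the two
correlations are exact mirror images.

## Concordance and overlap

Signed CpG lists map probe → direction (+1/−1): sign of the age slope,
hyper/hypo in AD, hyper/hypo in myeloid vs lymphoid. Every comparison mode
reduces to sign agreement under these semantics. For k shared probes with s
agreements: rate = s/k, significance = upper binomial tail P(X ≥ s) with
p_e = 0.5 (exact rational arithmetic to k = 1000, scipy's survival function
beyond). Note the upper-tail form: the probability mass uses (1−p_e)^{k−i};
a printed source with exponent k−1 is not a probability mass and is treated
as a typo. Empty overlaps report rate undefined with p = 1 and a warning.

Threshold curves restrict the overlap with the ML list to probes whose
|myeloid−lymphoid| mean difference strictly exceeds t, reporting surviving
count and rate per threshold (cumulative, not binned): composition-driven
concordance grows toward 1 as the lineage difference grows.

Composition filtering removes from a signed list every probe that is also in
the ML list *with the same sign* — the signature of a composition-driven
call. The filtered age and AD lists are then tested for overlap with the
hypergeometric upper tail; the universe defaults to the analyzed
(post-filter) probe set, a choice that must be stated with any reported
p-value since the universe is otherwise ambiguous.

## Enrichment

Probes are mapped to genes and deduplicated (gene-level 2×2 tables, so
multi-probe genes are not double-counted). One-sided (greater) Fisher exact
test per term; both the raw p and a BH q are reported, with the `called`
column defaulting to raw p < 0.05. One-sided Fisher on these tables is
identical to the hypergeometric overlap tail, which the tests use as a
cross-module oracle.

## Synthetic data generator

The generator emulates a multi-cohort whole-blood aging/AD study and is the
package's test bed. Defaults (the study conditions): 2000 probes; a bulk
cohort of 120 samples, ages uniform 20–80, split over 2 datasets; an AD
case/control cohort of 57 samples (48 AD, 9 controls) with the elderly age
range 65–96 typical of clinical AD cohorts; 6 subtypes × 5 replicate
reference profiles; baseline betas drawn bimodally (Beta(0.4, 0.4)).

Planted signal: 100 Age-CpGs with slopes ±(0.002–0.004)/yr; 60 AD-CpGs with
shifts ±(0.05–0.15), 40% of them placed on Age-CpG probes with matching
signs (the shared intrinsic biology the downstream overlap test should
find); 200 ML-CpGs with lineage differences ±(0.2–0.6); 30 subtype-specific
signature loci per subtype (shifts 0.3–0.5) so the reference profiles are
identifiable below the lineage level. The three planted sets are disjoint.
The expected myeloid fraction is linear in age (0.5 at the youngest age,
+0.004/yr, reaching 0.74 at 80); realized weights are Dirichlet around the
expectation (concentration 200); AD samples get a +0.05 myeloid shift.
Composition-driven age/AD signal is therefore *emergent* at ML probes, not
planted. Noise is truncated Gaussian on the beta scale (sd 0.02, clipped to
[0, 1]; the analysis stays on beta values throughout, no M-values); 1%
missingness; 2 outlier samples replaced by uniform-random betas, which
guarantees low inter-array correlation. Which probes carry effects, and
their signs and sizes, derive from a separate `effects_seed`, so the age and
AD cohorts of one pipeline run share the same underlying biology while
drawing independent samples. AD/control labels are assigned by centered
systematic sampling over the age ordering — an age-matched design; an
uncentered assignment leaves a systematic group age gap that masquerades as
differential methylation at every age probe.

What the generator does **not** emulate: Infinium type I/II probe chemistry,
batch/plate effects, SNP-affected probes, realistic genome annotation, and
correlated probe blocks. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not robustness
to array artefacts.

## Numerical and design choices

* Binomial/hypergeometric tails: exact `fractions.Fraction` arithmetic for
  small problems (k ≤ 1000, N ≤ 30), scipy log-space survival functions
  otherwise; both paths are cross-checked against exhaustive enumeration in
  the tests.
* Rank-product pooled p-values use a 10⁻¹² absolute tolerance on the log
  scale when counting ties against the null pool.
* Pipeline problem sizes (2000 probes, 120 + 57 samples, 100 permutations,
  500 markers) keep a full run around 15 s while leaving every stage's
  statistics comfortably powered; they are the package's default study
  conditions, configurable via `PipelineConfig`/YAML.
* Determinism: every stochastic stage takes an explicit seed; rerunning a
  config reproduces the report exactly.
* The case/control cohort skips the inter-array outlier screen (that QC step
  is reserved for the age cohorts, whose larger sample counts support it).

## Known limitations

* Rank product over-calls high-variance probes (see above); pfp is an
  estimate, not a guarantee.
* NNLS weights are identifiable only up to the span of the reference
  profiles: subtypes without distinctive markers in the panel cannot be
  resolved (the generator plants signature loci precisely so that tests can
  demand exact recovery).
* The concordance framework is list-based; it cannot apportion a single
  probe's signal between composition and intrinsic change.
* The hypergeometric universe choice materially changes overlap p-values and
  must accompany any reported number.
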