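# Methods

This note documents the statistical procedures, the generative model
behind the synthetic cohort, the numerical conventions, and the design
choices that were genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Composite inflammatory index

The index is the ratio of the mean log2 intensity of the inflammatory
probe set to that of the regulatory probe set. Two constructions are
provided because the published construction averages the ratio over
four discovery data subsets whose probe membership is not public:

- `mode="pooled"` (default): one ratio over the full sets;
- `mode="grouped"`: the unweighted mean of the per-subset ratios, using
  the partition's subset tags.

Means are taken on the log2 scale by default (`scale="log"`); a
linearised option (`scale="raw"`, means of `2**x`) exists because both
conventions appear in practice. The index is invariant to probe and
sample ordering but *not* to adding a constant to all log intensities —
a ratio a/b maps to (a+c)/(b+c); the tests assert this exact algebra
rather than pretending shift invariance. Consequence: matrices must be
normalised consistently (e.g. global median) before indices are
compared across samples.

Responder binning uses strict inequalities; a change of exactly ±5 % is
"stable". The one-tailed direction of the paired t-test is always
declared by the caller (`direction="less"` for an anti-inflammatory
hypothesis); it is never inferred from the data.

## Differential induction

With exactly two paired conditions the per-probe ANOVA is the paired
t-test (F = t²), which is what is implemented. Probes whose pre and
post columns are identical have an undefined t; their p is set to 1
rather than propagating NaN. BH adjustment runs within the supplied
probe subset only (the index transcripts), so "k of m at FDR < rate"
refers to that family; array-wide adjustment is available by passing no
subset. The pass flag is strict (`q < rate`). BH itself is delegated to
statsmodels' step-up implementation; an independent brute-force
step-up serves as the oracle in the tests.

The regulator activation score implements only the publicly described
core of upstream-regulator analysis: z = (n_agree − n_disagree)/√n over
the overlap between a user-supplied signed target network and observed
induction directions, activation at z ≥ 2, inhibition at z ≤ −2. No
curated network ships with the package.

## Microbiome community analysis

Rank collapsing groups OTUs by the lineage prefix through the target
rank. Reads unassigned at that rank are pooled into an explicit
`unmapped` feature instead of being dropped: per-sample totals are
conserved exactly and the mapped-read fraction is reported. Collapsing
is idempotent.

Shannon diversity uses log base 2 (bits), configurable. No rarefaction
is applied by default since sequencing-depth normalisation is
study-specific; Bray–Curtis operates on raw counts (it is scale-free
per pair through its min/sum form on equal-depth designs, and the
generator's Poisson depths keep samples comparable). Bray–Curtis is a
semi-metric: symmetric, zero self-distance, but the triangle inequality
may fail, so PCoA can produce negative eigenvalues; these are reported
and their axes dropped from the returned coordinates.

The LDA effect size follows the two-class one-against-all scheme of the
LEfSe method: per-feature Kruskal–Wallis screen at α (for two classes
this coincides with the Wilcoxon rank-sum test, which resolves the
ambiguity of which rank test "the" screen is), then, for surviving
features jointly, 30 bootstrap rounds of within-class resampling, a
small multiplicative jitter (sd = max(5 % of the value, 1e-5)) to
regularise zero within-class variance, an LDA fit (eigen solver with
Ledoit–Wolf shrinkage; if the fit degenerates the raw mean difference
is used), and the per-feature combined effect
(|Δfeature mean| + |w_f · ΔLD|)/2 averaged over bootstraps. The score
is `sign · log10(1 + effect)` with the sign positive when the feature
is enriched in the class sorting last; significance requires p ≤ α and
|score| ≥ cutoff (defaults 0.05 and 2.0).

Relative abundances are scaled to one million per sample. A per-mille
scaling was considered and rejected: the conventional |LDA| ≥ 2 cutoff
is interpreted against per-million normalisation, and under per-mille
scaling that cutoff would demand a ≥ 20-percentage-point abundance
shift, making the procedure insensitive to any realistic signal. The
scale is a parameter (`abundance_scale`). Exact parity with the
original LEfSe package is not promised; the tests assert direction and
threshold behaviour (planted signals flagged with the right enriched
class, label-shuffle nulls controlled near α, monotonicity in α and in
the cutoff).

## Mediator and covariate statistics

The "paired Wilcoxon" procedure is the Wilcoxon signed-rank test on
paired differences. Zero differences are dropped before ranking
(Wilcoxon's treatment; Pratt's is available via `zero_method="pratt"`).
The exact null distribution is used for ≤ 25 tie-free nonzero
differences, otherwise the normal approximation with continuity
correction and mid-ranks.

Analyte percent changes are computed on group means by default
(`100·(post_mean − pre_mean)/pre_mean`), matching how cohort-level
percent figures are usually quoted; a mean-of-per-subject-changes
alternative is behind `change_on="subject_means"`. Whether published
cohort percentages are ratios of means or means of ratios is generally
unstated; the default is the former. The screening table retains
analytes with |change| > 5 % (strict) and signed-rank p < 0.2 (strict),
sorted by p; analytes missing a visit or with < 5 complete pairs are
excluded with a warning, never silently.

Fiber intake is standardised as a percentage of the 14 g per 1000 kcal
daily intake guideline: `100 · fiber_g / (14 · kcal/1000)` — exactly
linear in fiber and inverse-linear in energy. Pearson p-values come
from the t transform with n − 2 df; at r = 0.67, n = 14 this gives
p ≈ 0.009, consistent within method tolerance with permutation-style
values near 0.008. One-tailed tests are used only where a directional
hypothesis is declared (the index and SCFA contrasts); everything else
is two-sided.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is
validated; it is not a tuning dial.

**Expression.** Log2 intensity of probe p, subject s, visit v:

```
x = baseline_mean + probe_offset_p + subject_effect_s
    + v * response_s * delta(set(p)) + noise
```

with `probe_offset ~ N(0, 1)`, `subject_effect ~ N(0, 0.2)`,
`noise ~ N(0, 0.15)` and `response_s ~ N(1, 1.2)` a per-subject response
scale. Defaults: 307/1,067 probes, baseline 6.0 (a typical mid-range
log2 array intensity), `delta_inflammatory = −0.60`,
`delta_regulatory = +0.12`. These deltas were set once so the mean
paired index change is about −12 % — the direction and approximate
magnitude a modest anti-inflammatory intervention produces — and the
response-scale sd so that a 25-subject cohort spreads across the
responder bins rather than moving as one block. Known departures from
real assay data: the set-level shift is uniform across probes, so the
fraction of individually significant probes is far higher than a
heterogeneous real signature would give; and because the subject effect
cancels in the ratio, the between-subject dispersion of the index
*level* is much smaller than in real cohorts (the paired *change*
structure, which the tests exercise, is realistic). A lognormal
intensity model with additive random effects is the simplest model
consistent with array data; users can substitute their own matrices.

**Communities.** 173 OTUs assigned round-robin to ten named gut
families (2 % of OTUs left unassigned below order, to exercise
mapped-fraction reporting), Dirichlet concentrations ∝ 1/rank with
total mass 25 (strongly overdispersed, as stool profiles are), depth
Poisson around 20,600 reads/sample (`fixed_depth=True` for exact
depths). Post-visit samples multiply enriched-family concentrations by
exp(log-fold); defaults plant post-enrichment of Lachnospiraceae,
Bifidobacteriaceae and Lactobacillaceae (+0.8 to +0.9) and
pre-enrichment of Porphyromonadaceae, Peptostreptococcaceae and
Mogibacteriaceae (−0.4 to −0.5), emulating the direction pattern of a
probiotic trial. Compositional closure means unenriched families can
show significant relative shifts — a real feature of relative-abundance
analysis, not a bug.

**Covariates.** A covariate is coupled to a supplied per-subject index
change by standardising the change to z-scores and drawing
`rho·z + sqrt(1−rho²)·eps` with a normal marginal: the population
Pearson correlation is exactly `rho`. Note the *sample* correlation at
n = 14 is a biased estimator (conditioning on the exactly-standardised
z-scores and the nonlinearity of r both contribute terms of order
(1−ρ²)/n ≈ 0.02), so the recovery test asserts the 1,000-replicate
mean within ±0.03 of the target rather than within pure Monte-Carlo
error, which the bias alone would exceed. Defaults: T-cell
memory:naive ratio change coupled at +0.67 to the index change, fiber
%-of-guideline at −0.40; analyte panels plant the mediator shifts of a
few tens of percent (IL-12p40 −16.4 %, …, TRAIL +8.1 %) with lognormal
noise, three null analytes, and SCFAs with butyrate 1.4-fold higher
post.

All randomness flows from one integer seed per artifact through a
single `numpy.random.default_rng` stream; identical seeds give
bit-identical outputs, which the tests assert.

## Pipeline and problem sizes

`run_pipeline` executes cohort → index → differential → microbiome →
mediators → correlations, writes CSV/TSV outputs and a JSON manifest
(sorted keys, rounded floats, SHA-256 of inputs) that is byte-identical
under a fixed config and seed. The Monte-Carlo suites use 500
replicates at n = 25 for the paired-t calibration, 200 label shuffles
for the LDA null, and 1,000 replicates for correlation recovery —
sizes at which binomial error bands are a few percentage points and the
whole suite runs in well under a minute each.

## Known limitations

- The grouped ("four data subsets") index mode assigns synthetic
  subset tags in the generator; real subset membership must come from
  the user's annotation.
- The LDA effect size supports two classes (one-against-all); multi-way
  designs must be decomposed by the caller.
- No phylogenetic diversity metrics (no tree is consumed) and no
  read-level processing; the package starts at count tables.
- The activation z-score omits literature-bias corrections used by
  proprietary upstream-analysis tools.
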