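# coinflam

Analysis toolkit for paired pre/post-supplement trials that read out
systemic inflammation with a transcription bioassay and track the gut
microbiota alongside it. It was built around the design of open-label
probiotic pilot studies in relatives of type 1 diabetes patients: each
subject contributes a *pre* and a *post* sample per assay, and every
statistic is a paired contrast.

## What it computes

**Composite inflammatory index.** Plasma-induced transcription cultures a
fixed donor's PBMC with a subject's plasma and reads the induced
transcriptome as a reporter of plasma-borne mediators. Given a log2
expression matrix and a disjoint partition of index probes into an
*inflammatory* set **I** and a *regulatory* set **R** (307 and 1,067
probes by default), the index for sample *s* is

```
II(s) = mean_{p in I} x_ps / mean_{p in R} x_ps
```

High values mean inflammatory bias, low values regulatory bias. Per
subject the supplement effect is `100 * (II_post - II_pre) / II_pre`,
subjects are binned into responders (*reduced* / *increased* / *stable*
at a strict ±5 % threshold), and the cohort shift is tested with a
one-tailed paired t-test.

**Differential induction.** Per-probe paired t-tests (the two-condition
ANOVA) with Benjamini–Hochberg adjustment applied within the index
probe set, pass flag at q < 0.20; per-subject log2 fold-change
signatures; Pearson correlation to a reference signature; and a generic
activation z-score for a user-supplied signed regulator network,
`z = (n_agree − n_disagree) / sqrt(n_overlap)`, activation at z ≥ 2.

**Microbiome community.** OTU tables with Greengenes-style lineages:
rank collapsing with explicit pooling of unassigned reads (so
mapped-read fractions are reportable), Shannon diversity (base 2) and
richness, Bray–Curtis dissimilarity with classical PCoA, and a
LEfSe-style LDA effect size: Kruskal–Wallis screen at α = 0.05, then a
bootstrap-averaged linear-discriminant effect size on per-million
relative abundances, reported as log10 scores with significance at
|LDA| ≥ 2.

**Mediators and covariates.** Wilcoxon signed-rank tests on paired
analyte panels (exact null for n ≤ 25), the screening table of mediators
with |change| > 5 % and p < 0.2, fold changes and percent reductions of
group means, exclusion of the ≥ 2-autoantibody subgroup, dietary fiber
standardised against the 14 g / 1000 kcal intake guideline, CD4
memory:naive T-cell ratios, and Pearson correlations with index change.

**Synthetic cohort.** Seeded generators for every input type — the
paired expression assay, Dirichlet-multinomial stool communities with
planted family enrichments, and covariate tables coupled to the index
change through a Gaussian copula — so the whole pipeline runs and is
testable without any external data.

## Worked example

```python
import coinflam as cf

design = cf.CohortDesign(n_subjects=25, seed=1)
matrix, partition, pairs = cf.generate_expression(design, cf.ExpressionEffectModel())
res = cf.InflammatoryIndexModel(matrix, partition, pairs).fit(direction="less")
print(res.summary())
```

prints

```
Composite inflammatory index, paired pre/post analysis
  subjects: 25
  I.I. pre : 0.989 +/- 0.002 (mean +/- sd)
  I.I. post: 0.818 +/- 0.160
  paired t (less, 1-tail): t = -5.342, p = 0.0000
  responders (|change| > 5%): reduced = 19, increased = 2, stable = 4
```

i.e. the generator's planted anti-inflammatory shift lowers the mean
index (here by about 17 %), the one-tailed paired t-test rejects, and
most subjects fall in the > 5 %-reduction bin. The same objects feed the
other stages, e.g.:

```python
otu = cf.generate_otu_table(cf.CommunityEffectModel(), seed=2)
fam = cf.collapse_to_rank(otu, "family")
lefse = cf.LefseModel(fam.table, cf.visit_labels(fam.table)).fit(seed=3)
print(lefse.summary())   # post-enriched Lachnospiraceae et al., |LDA| >= 2
```

The command line mirrors the library: `coinflam simulate | iicom |
diffinduce | microbiome | mediators | correlate | report | run`, with
`coinflam run` executing every stage and writing a deterministic JSON
manifest.

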