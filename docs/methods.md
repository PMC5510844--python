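# Methods

`triohet` analyses an unreplicated RNA-seq trio — one maternal parent, one F1
hybrid, one paternal parent, each sequenced as a single library — together
with plant-level agronomic trait tables, to characterize heterosis at the
transcriptome and phenotype level. This note documents the models, the
defaults and why they were chosen, and what the synthetic data do and do not
emulate.

## Expression model and normalization

Counts are stored per gene and sample with gene lengths in bp
(`expression.CountMatrix`). Library size is defined as the column sum of the
supplied count matrix, which makes every downstream statistic a function of
the matrix alone. FPKM is the classic constant-factor form

    FPKM(g, s) = counts(g, s) · 10⁹ / (length_bp(g) · library_size(s))

with no effective-length or GC correction (deliberately out of scope).
Sample QC is the Pearson correlation between samples, computed on
log2(FPKM + 1) by default — the log transform is the stable convention for
heavy-tailed expression values; raw-scale correlation is retained as an
option. Pairs with r² < 0.8 are flagged.

## Differential expression without replicates

With one library per condition there is no within-condition variance to
estimate, so the test is conditional and exact: under the null of equal
expression rates, the count in library A given the total n = xA + xB is
Binomial(n, π₀) with π₀ = N_A/(N_A + N_B) fixed by the library sizes. The
two-sided p-value is the minimum-likelihood sum — the probability of all
outcomes no more likely than the observed one, ties included (the convention
of standard exact tests), with a 1 + 10⁻⁷ relative slack so floating-point
ties fall inside the rejection region. A normal-approximation z-test on the
same conditional model is available (`method="ma-z"`).

The fold change is computed from depth-normalized counts with a pseudocount
of 1 applied to counts only, never to the test statistic: the test stays
exact while log2FC stays finite for zero counts. Genes with xA + xB = 0 are
untestable and are excluded from the multiple-testing family rather than
erroring the batch.

Benjamini–Hochberg adjustment (delegated to `statsmodels`) is applied per
contrast across all testable genes. A gene is called differentially expressed
at padj ≤ 0.005 and |log2FC| ≥ 1 — a deliberately stringent operating point
appropriate for an unreplicated design, and the package default.

**Known limitation.** The exact test assumes Poisson (technical) counting
noise. Biological overdispersion between libraries is *not* modelled — there
are no replicates to estimate it from — so under negative-binomial noise the
test is anti-conservative (we measure a ~4× inflation of the nominal rate at
dispersion 0.05). This is the documented cost of the unreplicated design, not
an implementation artifact; validity checks therefore run under the Poisson
model the test assumes (see Testing below).

## The in-silico mid-parent and the 12-pattern classification

The additive null expectation for a hybrid is the mid-parent: the average of
the parental expression levels. We construct it at the count level by pooling
the parental libraries — mid(g) = maternal(g) + paternal(g) with library size
N_m + N_p — which is the depth-weighted mean of the parental rates and
preserves the count nature of the data so the exact test applies unchanged.

Three pairwise contrasts (maternal vs paternal, hybrid vs maternal, hybrid vs
paternal) yield a sign triple (s_pp, s_hm, s_hp) ∈ {−1, 0, +1}³ per gene. The
27 triples partition exactly into:

* **additivity** (2 triples, patterns I and XII): parents differ, hybrid
  significantly between them;
* **parental expression level dominance** (4 triples; II, XI, IV, IX):
  parents differ, hybrid statistically equal to exactly one of them;
* **transgressive up-/down-regulation** (3 + 3 triples; V, VI, VIII and
  III, VII, X): hybrid significantly above (below) both parents, sub-split by
  the parental contrast;
* the all-flat **null** triple; and
* 14 internally inconsistent **ambiguous** triples (e.g. hybrid above one
  parent while every other comparison is flat).

The Roman-numeral labels within the transgressive categories follow a
canonical table defined in `patterns.PATTERN_TABLE`; the category groupings
are the established ones, but numeral assignment within a category is a
package convention and downstream analyses (and all tests) use categories
only. A fourth contrast, hybrid vs mid-parent, sets the per-gene
`nonadditive` flag independently of the pattern call.

Summary tables count patterns and categories over the genes significant in
at least one of the four contrasts — the broadest defensible universe for an
"expressed and responsive" gene set. The two-hybrid intersection
(`common_degs`) reports genes carrying the same category in both crosses.

## Phenotype heterosis

For each trait, with hybrid mean F1 and parental means P1, P2:

    MPH = (F1 − MP)/MP · 100,  MP = (P1 + P2)/2
    HPH = (F1 − HP)/HP · 100,  HP = better(P1, P2)

`better` defaults to max but is overridable per trait ("min" for traits where
less is better, e.g. plant height in lodging-prone material); published
tables are not always consistent about the reference parent, so the package
exposes the choice rather than adjudicating. With positive means and HP =
max, HPH ≤ MPH algebraically.

Significance uses Welch's unequal-variance two-sided t-test: hybrid plants vs
the better parent's plants, and hybrid plants vs per-plant mid-parent
pseudo-values (the two parents' plants rank-matched within each field block
and averaged pairwise). When both groups are constant the p-value is defined
as 1 for equal means and 0 otherwise. A compact-letter display from pairwise
Welch tests with BH at 0.05 is provided for reporting only.

## Term enrichment

GO-style and pathway-style analyses share one over-representation engine:
the one-sided hypergeometric upper tail P(X ≥ k) for k of n selected genes in
a term covering K of N universe genes, BH across all terms with K ≥ 1, called
enriched at padj < 0.05. The universe is an explicit required input.

Length bias (long genes accrue more reads, hence more DE calls) is addressed
by a Monte-Carlo sampling null: the selection-probability-vs-length curve is
estimated in 10 length-quantile bins, isotonic-smoothed, and used as sampling
weights for resampled gene sets of the observed size; the empirical
upper-tail p uses the add-one estimator. This is a deliberately simple
sampling null — not a Wallenius noncentral-hypergeometric approximation — and
converges to the hypergeometric p when lengths carry no signal.

## qPCR relative quantification

The 2^−ΔΔCt method with amplification efficiency fixed at 2. Multiple
reference genes are aggregated by the arithmetic mean of their Ct values,
equivalent to the geometric mean of reference quantities. Technical
replicates are averaged first; biological replicates are summarized as
mean ± SD of per-replicate ratios against the calibrator's mean ΔCt. The
calibrator sample is an explicit input. Agreement with RNA-seq is quantified
by the Pearson r (and r²) of paired log2 fold changes.

## Synthetic data: what it emulates, what it does not

`simulate.generate_trio_counts` plants known expression categories into a
trio. Baseline rates are log-normal (σ = 1.2 by default), reproducing the
heavy-tailed spread of real expression without fitting any dataset. For a
planted effect δ (`effect_log2fc`, default 2.0 — comfortably above the
|log2FC| ≥ 1 gate): additive genes place the parents at ±δ/2 around baseline
with the hybrid at their arithmetic mean; dominance genes separate the
parents by δ with the hybrid pinned to one of them; transgressive genes keep
the parents equal and move the hybrid by ±δ. Which parent is elevated is a
fair coin per gene, exercising the mirror patterns. Counts are negative
binomial with dispersion α (variance μ + αμ²), α = 0 giving Poisson; the
default α = 0.05 adds mild biological-scale noise. Gene lengths are uniform
on 200–5000 bp. Each library is scaled to a common expected depth, so a large
one-sided planted fraction produces the same composition bias a real mixture
would; default planted fractions total 3%.

Default depth is 10⁶ reads per library: real libraries of this design run to
50–90 million reads over ~50 000 genes (≈ 1 000+ reads per gene), and the
desk-scale simulations preserve either the gene count (20 000 genes for
null-rate checks) or the per-gene coverage (2 000 genes ≈ 500 reads/gene for
recovery checks) depending on which property the check exercises.

The simulator does **not** emulate read-level artifacts (alignment error,
positional bias, isoform structure), genotype-specific GC or mappability
effects, or correlated gene-gene variation. Passing tests therefore
demonstrate correctness of the statistical machinery under its stated model,
not robustness to every failure mode of real sequencing data.

`generate_trait_table` draws plant values normal(mean, SD) per genotype and
block (default 10 plants × 3 blocks, the usual replicated-trial layout); it
models no block effects or genotype-by-environment interaction, so block
structure is plumbing for the rank-matching code path. `generate_term_map`
plants one term whose members are over-sampled from a designated gene set by
a chosen factor; factor 1 is an exact null.

## Numerical and testing choices

* Exact binomial p-values are cross-checked against exact rational-arithmetic
  tail summation (all totals ≤ 50) and against an independent library
  implementation; BH against a brute-force definition scan; hypergeometric
  tails against direct combinatorial summation (N ≤ 200).
* Statistical-validity simulations (null call rate ≤ nominal 0.005; ≥ 90%
  recovery of planted transgressive genes; ≥ 99% of additive genes consistent
  with the mid-parent) run at dispersion 0, the sampling model under which
  the exact test's guarantee is defined; the default dispersion 0.05 is used
  elsewhere to exercise robustness. Problem sizes are 20 000 genes × 10⁶
  reads (null) and 2 000 genes × 10⁶ reads (recovery), per the coverage
  argument above.
* Ties in the minimum-likelihood sum use a 1 + 10⁻⁷ relative slack;
  BH families are per contrast; the pipeline writes no timestamps so reruns
  are byte-identical; all randomness derives from one recorded seed.
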