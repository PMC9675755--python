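# Methods

`enhancersens` re-implements, as a tested library, a genome-wide analysis of
how two lipodystrophy-associated PPARγ point mutations — R212Q in the hinge,
which contacts the DNA minor groove at the 5' extension of the PPAR response
element (PPRE), and E379K in the ligand-binding domain, which stabilizes the
interface with the RXR DNA-binding domain — reshape the receptor's target-
enhancer landscape. The pipeline classifies receptor-bound enhancers by
activation status, mutation sensitivity, chromatin accessibility and
PPRE-segment strength, and links those classes to target-gene regulation.
Because the real sequencing data are not bundled, the package ships a
first-class synthetic-data generator that plants a known causal structure
and serves as the recovery oracle for every downstream claim.

## Peak calling (`peakcall`)

Tags are deduplicated read 5' positions (at most `tbp=1` per position;
strand is ignored throughout). Binding sites are fixed 500 bp windows.
Candidate windows are *every* 500 bp window at 1 bp steps; they are selected
greedily in decreasing tag order (leftmost window wins ties) under a
non-overlap constraint, which makes the caller bit-identical to exhaustive
enumeration — a property the tests verify directly. A selected window is
retained when

* `fold_local >= 4`, where the expected count comes from the surrounding
  20 kb (excluding the window itself), floored at the genome-wide average
  rate so empty neighborhoods cannot yield infinite folds;
* the Poisson upper tail `P(X >= tags)` at that expectation is `< 1e-4`
  (exact survival function, no continuity correction);
* when a control track is supplied, the fold over the library-size-scaled
  control count is also `>= 4`.

Finalized peaks are re-centered 500 bp intervals, clipped at chromosome ends
(with a logged warning), filtered against an optional blacklist (any 1 bp
overlap removes the peak) and required to hold at least 35 tags; a peak with
exactly 35 tags is kept. The 35-tag floor is evaluated on the pooled
wild-type tag directory, since peaks are called on pooled replicates.

## Quantification and differential testing (`diffcount`)

Signal is counted in half-open windows around peak centers: ±1500 bp for
H3K27ac (histone marks spread broadly), ±250 bp for Med1, receptor ChIP and
ATAC. Counts are raw; normalization enters only through size factors:

* ChIP and ATAC matrices use **tag-directory totals** (whole-library size,
  rescaled to geometric mean 1). Window-sum factors would be distorted here
  because most quantified windows carry condition-dependent signal.
* RNA counts use the **median-of-ratios** estimator, which is identifiable
  as long as most genes are unchanged.

The differential test is a deliberately transparent negative-binomial Wald
test (Var = μ + dμ²), not a DESeq2 call: per-feature dispersion is estimated
by method of moments on per-condition-centered normalized counts, then
moderated toward the across-feature mean with 20 prior degrees of freedom
(the limma/edgeR idea — with two replicates the raw 2-df estimate is
useless alone). The log2 fold change uses a pseudo-mean ε = 0.5 to stay
finite at zero counts; its delta-method standard error is
`se² = (1/ln2)² Σ_g (1/n_g)(1/μ_g + d)`, and `z = L2FC/se` is referred to
the normal. Moderation by the *mean* rather than the median matters: the
method-of-moments sampling distribution is right-skewed, and median pooling
underestimates the dispersion enough to inflate the null type-I level. As
implemented, simulated nulls (n = 3, 2000 features, dispersions 0.01–0.05)
reject at 0.04–0.06 at nominal 0.05, and power at a planted four-fold
change with n = 2 is ≈ 1. When a config-wide dispersion is supplied (the
n = 1 escape hatch), moderation is skipped. There is no fold shrinkage,
Cook's filtering or independent filtering. Benjamini–Hochberg adjustment is
applied separately per assay and contrast.

## Motif scanning (`motif`)

PWM scores are natural-log odds against the background (uniform by
default); the caller threshold of −2 is inclusive (score = −2 is a call).
Windows of ±100 bp around peak centers are scanned on both strands; the
best placement wins, ties resolved to the lower offset and then the +
strand. Positions containing N are skipped. The DR1 architecture is
dissected in plus-strand motif coordinates: 5' extension (bases 1–4), PPAR
half-site (bases 5–10), spacer (base 11) and RXR half-site (bases 12–17);
segment scores are exactly additive to the full score. For minus-strand
hits the genomic sequence is reverse-complemented before segment
extraction. The bundled 17-column PPRE-like matrix
(consensus `AACT AGGTCA A AGGTCA`, 79:7:7:7 column counts) is a synthetic
stand-in constructed for the simulated study, not a database matrix; any
JASPAR-format matrix can be supplied instead.

## Enhancer taxonomy (`enhancer_class`)

* **Target enhancer**: padj < 0.1 and L2FC > 0 for H3K27ac and/or Med1,
  wild type vs control. Union counts obey inclusion–exclusion by
  construction.
* **Sensitivity groups**: a mutant "loses" an enhancer when padj < 0.05 and
  the binding ratio drops by ≥ 25% (L2FC ≤ log2 0.75); symmetric for gains.
  Groups — `dual`, `E379K_only`, `R212Q_only`, `gained` (gained by either,
  lost by none), `insensitive` — are disjoint and exhaustive over targets.
* **Accessibility**: mean normalized nucleosome-free ATAC count in control
  cells > 15 ⇒ accessible; exactly 15 is pinned to inaccessible (the
  published definition uses two strict inequalities and leaves the boundary
  unassigned).
* **Remodeled by WT**: ATAC padj < 0.05 and L2FC > 0, WT vs control.
* **ROC**: AUC by the rank (Mann–Whitney) statistic with ties counted 1/2;
  for "low basal activity predicts sensitivity" the score is negated, which
  the output records.

## Genes and vicinity enrichment (`expression`)

Induced/repressed genes: padj < 0.05 and fold change strictly beyond 1.5.
Gene-level mutation sensitivity mirrors the enhancer rule at a 1.25-fold
cut; "insensitive" requires both mutants within ±25%. Enrichment of an
enhancer set near a gene group counts enhancers whose center falls within a
window of any group TSS, normalized by the mean count over 10 random draws
of 200 non-regulated genes, scaled linearly to the group's size. The linear
scaling is exact only while vicinity windows rarely overlap; the null test
in the suite is built in that regime. The window defaults to 100 kb (a
mammalian-genome interpretation, since no number is published); the
synthetic pipeline uses 5 kb, matched to the toy genome's enhancer density.

## Spectroscopy utilities (`spectro`)

Percent helix from far-UV CD uses the linear single-wavelength estimate
%H = ([θ]₂₂₂ − 3000)/(−36000 − 3000) × 100 on the mean residue ellipticity
at 222 nm (interpolated when 222 nm is bracketed but absent); both the raw
and [0,100]-clipped values are reported, since the literature formula can
exceed the range on real spectra. Cα secondary chemical shifts are
observed minus random-coil reference; the random-coil set is a required
input table, not a bundled constant. A transient helix is any maximal run
of ≥ 4 consecutive residues (contiguous numbering) with positive SCS — the
run length follows the canonical four-residue exemplar and is configurable.

## Synthetic study design (`synthetic`)

The generator encodes the causal structure the analysis is meant to
recover, with effect sizes chosen once as "strong":

* 6 uniform-random chromosomes × 1.25 Mb; 400 target enhancers (100 per
  sensitivity group) plus 200 bound-but-never-activated background sites,
  12 kb apart so sites do not sit in each other's 20 kb local background.
* Hinge-sensitive groups (`dual`, `R212Q_only`) carry consensus 5'
  extensions and PPAR half-sites (one RXR half-site mismatch) and sit in
  inaccessible chromatin with low basal Med1/H3K27ac; `E379K_only` and
  `insensitive` carry weaker motifs (2+2+1 mismatches) in accessible
  chromatin. `E379K_only` basal activity is intermediate, below
  `insensitive`, matching the published ordering.
* Window counts are NB with dispersion 0.02 and Var = m + dm²; tags spread
  triangularly with half-width equal to the counting window (±250 bp;
  ±1500 bp for H3K27ac), so window counts match planted means. Uniform
  background runs at 10 tags/kb/replicate — tag-directory totals are
  background-dominated, as in real ChIP libraries. The receptor-null
  control has background only in the receptor ChIP.
* Wild-type binding means 60 (targets) / 40 (background sites) tags per
  window per replicate; each sensitive group's mutant rate is the WT rate ×
  0.25 (a four-fold loss — the paper reports severely compromised binding
  but no effect size). Activation folds: 6 at closed sites, 3 at open ones.
* ATAC fragments are a two-component length mixture (sub-nucleosomal
  N(70, 25), mono-nucleosomal N(180, 20), clipped to [10, 500]); accessible
  sites emit 85% sub-nucleosomal fragments, closed ones 35%. Closed target
  enhancers gain accessibility six-fold under WT; mutants retain 60%
  (E379K) / 20% (R212Q) of that gain. Control means 40 (open) vs 5
  (closed) tags per ±250 bp window put the two classes on either side of
  the 15-count threshold without tuning it.
* 800 genes with baseline mean 100: 100 linked genes (25 per group) placed
  within 2.5 kb of their enhancer, induced four-fold by WT, with mutant
  expression = WT × the linked enhancer's penalty; 700 unlinked pool genes.
  Keeping the induced fraction near 12% keeps median-of-ratios
  normalization identifiable.
* Every random stage draws from a seed stably hashed from (global seed,
  stage name), so runs are deterministic and adding a stage never perturbs
  earlier randomness.

What the generator does **not** emulate: sequence-composition and
mappability bias, PCR duplicates, fragment-level read simulation,
enhancer–promoter loops (gene links are explicit in the truth table),
dispersion heterogeneity across features, and distance-decaying regulatory
effects. Passing recovery tests therefore demonstrate the statistical
machinery under the assumed model, not robustness to those artifacts.

## Problem sizes

The default study (5.7M tags pooled across 16 ChIP samples, 600 sites, 800
genes) runs the full pipeline in seconds on one core; the acceptance script
additionally re-runs the caller against exhaustive enumeration on 20 random
50–100 kb chromosomes and the motif scanner against brute force on 1000
random 200-mers. These sizes were chosen so the whole evidence chain is
cheap to re-run while every statistical claim retains clear margins.

## Known limitations

* The NB test is intentionally simpler than DESeq2 (no shrinkage of fold
  changes, no outlier handling); with the planted strong effects the
  classifications are insensitive to this, but near-threshold real data
  would not be.
* The 25%-change sensitivity rule is applied on the test's L2FC scale; the
  original analysis may have used normalized mean ratios, which differ
  slightly at low counts.
* Greedy full-enumeration calling is exact but O(genome); for mammalian
  genomes a local-maxima pre-pass would be needed.
* The vicinity baseline's linear scaling to group size understates the
  baseline when windows overlap heavily (dense gene sets or large windows),
  inflating ratios toward larger groups.
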