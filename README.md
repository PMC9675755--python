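# enhancersens

Classification of nuclear-receptor target enhancers by activation status,
mutation sensitivity, chromatin accessibility and response-element strength.

## The scientific problem

PPARγ drives adipocyte differentiation by binding, as a heterodimer with
RXR, to PPAR response elements (PPREs) — degenerate direct repeats of
`AGGTCA` spaced by one base (DR1), with a 5' extension read by the
receptor's hinge. Familial partial lipodystrophy mutations such as R212Q
(hinge–DNA contact) and E379K (LBD–RXR-DBD interface) impair the receptor
on only a *subset* of its target enhancers. Dissecting which enhancers are
sensitive to which mutation — and why — requires a chain of genome-wide
analyses: ChIP-seq peak calling against a local background, differential
binding and activation tests, PPRE motif-segment scoring, ATAC-seq
accessibility stratification, and enrichment of enhancers near regulated
genes.

`enhancersens` implements that chain as a reusable library for
computational biologists, together with a synthetic-data generator that
plants a known causal structure (motif strength × accessibility ×
mutation penalty) so every classification step can be validated against a
truth table.

## The core statistics

* **Peak calling**: fixed 500 bp windows, greedy selection in decreasing
  tag order, retained at fold ≥ 4 over the surrounding 20 kb and Poisson
  upper-tail p < 1e-4 (plus a fold-4 filter against a scaled control); ≥ 35
  tags after finalization. The greedy caller is provably identical to
  exhaustive window enumeration, and the tests check that.
* **Differential testing**: a negative-binomial Wald test with
  Var = μ + dμ², moderated method-of-moments dispersion (prior toward the
  across-feature mean), delta-method standard error of the log2 fold
  change, and Benjamini–Hochberg correction.
* **Enhancer taxonomy**: targets gain H3K27ac and/or Med1 (padj < 0.1);
  a mutant "loses" a target at padj < 0.05 with ≥ 25% reduced binding,
  yielding disjoint dual / E379K-only / R212Q-only / insensitive groups;
  accessibility splits at 15 normalized nucleosome-free ATAC counts;
  ROC AUC (Mann–Whitney form) evaluates predictors of sensitivity.
* **Motif dissection**: natural-log-odds PWM scanning on both strands,
  best hit within ±100 bp of the peak center, segment scores for the 5'
  extension (bases 1–4), PPAR half-site (5–10) and RXR half-site (12–17).
* **Gene analysis**: induced/repressed calls (padj < 0.05, fold > 1.5),
  mutation-sensitive gene classes, and enhancer enrichment near gene
  groups normalized by 10 random draws of 200 non-regulated genes.
* **Spectroscopy utilities**: percent helix from CD mean residue
  ellipticity, %H = ([θ]₂₂₂ − 3000)/(−39000) × 100, and transient-helix
  calling from runs of positive Cα secondary chemical shifts.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Run a small synthetic study (two 650 kb chromosomes, 40 target enhancers in
four planted groups of 10, 20 background binding sites, two replicates per
condition) and recover the planted structure:

```python
from enhancersens import pipeline
from enhancersens.synthetic import SimulationConfig

cfg = SimulationConfig(
    chrom_count=2, chrom_length=650_000,
    enhancers_per_group=10, n_background_sites=20,
    linked_genes_per_group=5, n_pool_genes=220,
)
res = pipeline.run_all(cfg, seed=7)
print(res.manifest["n_peaks"], res.manifest["target_counts"])
print(res.manifest["sensitivity_counts"])
print(pipeline.recovery_metrics(res))
```

prints

```
60 {'n_h3k27ac': 40, 'n_med1': 40, 'n_both': 40, 'n_union': 40}
{'dual': 10, 'E379K_only': 10, 'R212Q_only': 10, 'gained': 0, 'insensitive': 10, 'other': 0}
{'group_accuracy': 1.0, 'basal_med1_auc': 1.0, 'wilcoxon_basal_med1_p': 5.96e-06,
 'wilcoxon_ext5_p': 4.20e-08, 'remodel_recovery': 1.0, 'n_matched': 60.0}
```

Reading this: all 60 planted binding sites are called as peaks; exactly the
40 planted target enhancers gain activation marks; every target lands in
its planted sensitivity group (`group_accuracy` 1.0); low basal Med1
perfectly predicts mutation sensitivity (AUC 1.0); and the planted
orderings — hinge-sensitive enhancers have lower basal activity and
stronger 5' extensions than insensitive ones — are recovered with small
Wilcoxon p-values. At the full default scale (400 targets) accuracy is
~0.97–0.99 rather than 1.0, since a few borderline enhancers fall on the
wrong side of the significance cuts.

The same pipeline is scriptable from the shell:

```sh
enhancersens run-all --config run.yaml --outdir out/
enhancersens spectro helicity --cd cd_spectrum.tsv
```

writing peak BEDs, annotation TSVs and a manifest JSON whose count
arithmetic (`validate_manifest`) is checked for internal consistency.

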