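# riboteq

Spike-in anchored ribosome-profiling analysis of **global** translational-
efficiency change — built for experiments, such as yeast replicative aging,
where translation collapses across the whole transcriptome and ordinary
per-library normalization would hide it.

## Why spike-ins

Sequencing libraries report proportions, not amounts.  Translational
efficiency (TE) of gene *g* in sample *s* is

```
TE(g, s) = ribo(g, s) / rna(g, s)
```

with `ribo` the footprint (Ribo-seq) expression and `rna` the mRNA (RNA-seq)
expression.  If every gene's TE falls by the same factor k, FPKM-style
normalization rescales both assays back to a fixed total and reports
log2FC ≈ 0 everywhere.  With external spike-in RNAs added per cell-equivalent
of input, each library gets a scale factor

```
factor_s = Σ_spike count(spike, s) / Σ_spike (length_kb × molecules_per_cell)
```

and `count / (length_kb × factor_s)` is expression **per cell-equivalent**,
in which the collapse is visible as log2FC ≈ −log2 k.  Per-gene contrasts use
a variance-moderated t on log2 TE replicate values (prior weight d0 = 4,
Benjamini–Hochberg FDR); "significantly decreased" means q < 0.05 with a
negative log2 fold change.

The package ships:

* `riboteq.synthetic` — a ground-truth generator for complete aging
  experiments: three age groups × two assays × three replicates, heavy-tailed
  mRNA abundance, a 136-gene ribosomal-protein class, abundance-coupled TE
  reductions up to 40-fold in 3472 of 6553 genes, confounded per-library
  depth, ERCC-like spike-ins, and uORF-dominated footprint profiles for a
  GCN4-like regulator;
* `riboteq.normalization` — spike-anchored per-cell expression, naive FPKM as
  a contrast mode, within-group mean/quantile replicate alignment;
* `riboteq.te` — TE tables, moderated differential tests with FDR control,
  gene ranking, Wilcoxon class contrasts, abundance–effect correlation;
* `riboteq.positional` — metagene profiles, pause scores, start-proximal
  enrichment, uORF/main-ORF density ratios, body-slope z-tests;
* `riboteq.comparative` — binned cross-dataset correlation, Fisher-exact set
  overlap, multi-set enrichment over GMT collections;
* a `riboteq` command line (`simulate`, `normalize`, `diffte`, `positional`,
  `compare`, `enrich`, `run`).

## Worked example

```python
from riboteq import AgingScenario, make_gene_models, make_spikein_reference
from riboteq.synthetic import simulate_experiment
from riboteq.pipeline import analyze_experiment
from riboteq.te import differential_expression

scenario = AgingScenario(seed=1)                  # default aging conditions
models = make_gene_models(scenario)
spikes = make_spikein_reference(scenario.n_spikes, scenario.seed)
counts, truth = simulate_experiment(models, spikes, scenario)

tetable, rna, ribo = analyze_experiment(counts, spikes, models)
called = tetable.table["significant_decrease"]
print(f"genes tested:            {len(tetable.table)}")
print(f"significantly decreased: {int(called.sum())} (configured: {scenario.n_affected})")
print(f"median log2 TE change:   {tetable.table['log2fc_old'].median():.2f}")

de = differential_expression(rna)                 # transcript-level contrast
rpg = truth.genes.index[truth.genes["is_rpg"]]
print(f"RPG transcript change:   {(1 - 2**de.loc[rpg, 'log2fc'].mean())*100:.1f}% decrease")
print(f"RPGs called decreased:   {int(de.loc[rpg, 'significant_decrease'].sum())}/136")
```

prints

```
genes tested:            6553
significantly decreased: 3546 (configured: 3472)
median log2 TE change:   -0.90
RPG transcript change:   21.7% decrease
RPGs called decreased:   135/136
```

The pipeline recovers the configured prevalence of TE loss (3546 calls vs
3472 planted effects; the excess is the expected share of false discoveries
at q < 0.05), sees the global decline directly in the negative median log2
TE change, and detects the deliberately subtle ~23% per-cell transcript
decrease of the ribosomal-protein class gene by gene — a contrast that only
exists after spike normalization, since those transcripts barely move
relative to the rising total mRNA pool.

The same analysis from the shell:

```
riboteq simulate --scenario default --seed 1 --outdir demo
riboteq run --scenario default --seed 1 --outdir demo_run   # full pipeline + manifest
```

## Layout

```
src/riboteq/      models, synthetic, normalization, te, positional,
                  comparative, io, pipeline, cli
tests/            unit + property tests, end-to-end recovery suite
docs/methods.md   model, estimators, calibration rationale, limitations
scripts/          acceptance.py
```
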