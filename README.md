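# pentalayout

Multi-level co-expression analysis of the 19-gene GABA-A receptor subunit
panel (α1–6, β1–3, γ1–3, δ, ε, π, θ, ρ1–3), from bulk regional expression
down to single nuclei:

- **expression_io** — parsers/writers for three table dialects
  (`allen_microarray` log2 intensities, `adtbi_fpkm`, `nuclei_counts`),
  an anatomical ontology (111 substructures shipped as package data), and
  substructure aggregation with hemisphere pooling.
- **synthetic** — seeded generators for multi-subject regional expression
  with planted enrichments and signed co-expression pairs, redundant
  probe panels with one faithful probe per gene, and single-nucleus
  compositions concentrated near the 2:2:1 family split with dropout.
- **preprocess** — representative-probe selection (first-PC loadings plus
  a cross-subject consistency score), age correction, proportional
  contribution (per-sample panel percentages), linear-scale fold
  enrichment, and noise / region-specific / global-high profile classes.
- **clustering** — Ward hierarchical clustering (Newick export),
  PCA whitening, quantum clustering (scale-space potential descent),
  spectral co-clustering, and consensus co-occurrence over parameter
  sweeps.
- **stoichiometry** — family sums Σα/Σβ/Σχ, the 40/40/20 ± 5 gate,
  subsampling convergence curves, pairwise Pearson reports at four
  analysis levels, and the cross-level consensus pair table.
- **layout** — 171-entry pairwise distance vectors per profile, consensus
  vectors across subjects, stereotypy correlations against whole-brain or
  reference-structure consensus, and one-way ANOVA with simulated
  Dunnett many-to-one contrasts.
- **pipeline / cli** — YAML-configured end-to-end runs with deterministic
  per-stage seed fan-out.

## CLI

```bash
# full synthetic run (writes CSV/JSON/Newick bundle to results/)
pentalayout run --seed 1 --out results/

# individual stages
pentalayout simulate   --seed 1 --out results/sim       # write dialect files
pentalayout preprocess --seed 1 --out results/pre
pentalayout cluster    --seed 1 --out results/clust
pentalayout stoich     --seed 1 --out results/stoich
pentalayout layout     --seed 1 --out results/layout

# summarize a finished run
pentalayout report --out results/
```

A YAML config (`--config config.yaml`) can override any `RunConfig`
field: thresholds (`noise_log2`, `enrich_fold`, `alpha`, `min_support`),
gate windows, the clustering sweep grids, the reference structure, and
the synthetic-truth parameters. Identical `(config, seed)` pairs produce
bit-identical output bundles.

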