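# dmfkit

Fragment-level differential-methylation analysis for reduced-representation
bisulphite sequencing (RRBS), built for comparing small matched patient
cohorts — e.g. ME/CFS and Long COVID patients against healthy controls —
where the unit of analysis is the MspI fragment rather than the single CpG.

## What it does

RRBS enriches CpG-dense genome fractions by digesting DNA with MspI
(recognition site CCGG, cut C^CGG) and size-selecting doubly-cut fragments
of 40–220 bp. `dmfkit` reproduces this design in silico and analyses the
resulting fragments:

1. **Digestion** (`dmfkit.digest`) — scan a FASTA reference for CCGG sites,
   enumerate fragments in 0-based half-open coordinates, size-select, and
   record each fragment's plus-strand CpG positions.
2. **Aggregation** (`dmfkit.coverage`) — parse per-CpG calls in the Bismark
   coverage dialect, pool counts to per-sample fragment methylation
   (read-count-weighted: `100 · Σ meth / Σ (meth+unmeth)`), and keep only
   fragments measurable in every sample of every group (the
   complete-coverage filter).
3. **Testing** (`dmfkit.stats`) — a per-fragment one-way ANOVA,
   `F = MS_between / MS_within` on `(k−1, N−k)` degrees of freedom, applied
   to raw methylation percentages. A *differentially methylated fragment*
   (DMF) passes raw `p < 0.05` with `|Δ| ≥ 10` percentage points, where
   `Δ = mean(case) − mean(reference)`; no FDR correction by default
   (a deliberate choice for very small cohorts; Benjamini–Hochberg is
   available via `adjust_bh`).
4. **Annotation** (`dmfkit.annotation`) — classify fragments against gene
   models as promoter (TSS −1 kb to +5 kb, strand-aware), exon, intron,
   exon/intron boundary, or intergenic, with precedence
   promoter > boundary > exon > intron.
5. **Comparison** (`dmfkit.comparative`) — intersect two disease-vs-control
   DMF sets on exact coordinates, compute cross-cohort differences
   `Δ_AB = Δ_A − Δ_B`, concordance classes (both hyper, both hypo,
   opposite), the divergent subset (`|Δ_AB| > 10` pp), per-region
   inventories, and the Pearson correlation of the common fragments.
6. **Multivariate views** (`dmfkit.multivariate`) — sample PCA and
   hierarchical clustering (Euclidean/complete by default) with
   heatmap-ready exports.
7. **Simulation** (`dmfkit.simulate`) — seeded synthetic genomes, gene
   models, and beta-binomial coverage files with planted fragment-level
   effects and a truth table, so every stage can be validated against known
   ground truth.

## Worked example

Simulate a cohort (3 groups × 5 samples, 30× coverage, 42/21 planted DMFs
with 12 shared) and run the whole pipeline:

```sh
dmfkit run --outdir demo --simulate-seed 6
```

prints the stage-count chain

```
[600, 436, 59, 7, 2]
```

meaning: 600 size-selected fragments → 436 with complete coverage in all
15 samples → 59 significant in the three-group ANOVA (p < 0.05) → 7 DMFs
common to both disease contrasts (30 LC-vs-HC and 14 ME-vs-HC DMFs
individually, see `demo/manifest.json`) → 2 of those diverging by more than
10 pp between the two disease cohorts. Per-stage tables (`fragments.bed`,
`matrix.tsv`, `dmf_LC_vs_HC.tsv`, `common_dmfs.tsv`, `divergent_dmfs.tsv`)
are written alongside the manifest. Each subcommand (`digest`, `aggregate`,
`test`, `annotate`, `compare`, `pca`, `cluster`, `simulate`, `recover`) is
also available on its own; the library functions mirror them one-to-one.

The package also ships small reference tables (`dmfkit.datasets`) from a
published ME/CFS vs Long COVID comparison — the 26 shared DMFs with >10 pp
cross-cohort divergence and the promoter/exon inventory of the shared
fragments — used as worked examples for the comparative engine:

```python
>>> from dmfkit import comparative, datasets
>>> t = datasets.load_divergent_dmf_table()
>>> s = comparative.concordance_summary(comparative.select_divergent(t))
>>> s.both_hyper, s.both_hypo, s.opposite
(12, 8, 6)
```

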