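# Methods

## The analysis model

`dmfkit` analyses methylation at the level of MspI restriction fragments.
The biological rationale: RRBS libraries are built from doubly-cut MspI
fragments in a fixed size window, so the fragment is the natural,
reproducible unit that every sample of a cohort measures at the same
genomic coordinates; pooling the reads of a fragment's CpGs also stabilises
the per-sample methylation estimate when per-CpG coverage is modest.

**Digestion.** The cut model is one cut per CCGG occurrence at C^CGG on the
plus strand; overlapping occurrences each cut. MspI's 2-nt 5' overhangs are
not modelled — fragment intervals abut — because fragment membership of
CpGs, the only thing downstream analysis consumes, is unaffected. Size
selection keeps lengths in [40, 220] bp with both bounds inclusive (the
conventional reading of a 40–220 bp window), and drops terminal
(singly-cut) fragments by default since library construction requires MspI
ends on both sides. Only the plus-strand C of each CpG is recorded; the CG
inside each boundary CCGG belongs to the downstream fragment, which starts
at that C, making CpG assignment a partition.

**Aggregation.** Per sample and fragment, methylation is read-count
weighted: `100 · Σ meth / Σ (meth + unmeth)` over the fragment's covered
CpGs. This conserves counts (testable: fragment totals equal the sum of
CpG totals) and matches count-based RRBS practice; an unweighted per-CpG
mean is available behind a flag. A value is reported only when the sample
has ≥ `min_total_reads` (default 10) reads over ≥ `min_cpgs` (default 2)
distinct CpGs of the fragment; otherwise the cell is explicitly missing,
never zero. The complete-coverage filter then retains exactly the
fragments with values for every sample of every group. The coverage
defaults are configurable; they are conventional values for
fragment-level RRBS pipelines rather than identifiable from any published
count chain.

**Testing.** Each fragment is tested with a one-way ANOVA F statistic on
raw percentages, `F = MS_between / MS_within`, with p from the upper tail
of F(k−1, N−k). No variance-stabilising transform is applied by default
(hooks exist), and no multiplicity adjustment is made by default: with
n = 5 per group, a stringent raw-p threshold avoids discarding true
positives, and the effect-size threshold provides the practical false
positive control. Benjamini–Hochberg adjustment is available for users who
prefer FDR control. A pairwise DMF passes when `p < 0.05` and
`|Δ| ≥ 10` percentage points (Δ = case mean − reference mean); the
difference threshold is inclusive, with a strict mode behind a flag.
Fragments whose within-group variance is numerically zero while group
means differ are flagged `degenerate` (F infinite, p reported 0) so
downstream filtering can treat them deliberately. The three-group test
(all cohorts jointly) uses the same machinery with k = 3 and produces the
"significant" layer used for PCA/clustering; pairwise contrasts are
separate calls.

**Annotation.** Gene models are collapsed to one representative transcript
per gene (the longest). The promoter is the strand-oriented window from
1 kb upstream to 5 kb downstream of the TSS; introns are the gene-body
complement of the exons; a fragment overlapping both an exon and an intron
of the same gene is an exon/intron boundary. Precedence is
promoter > boundary > exon > intron, ties across genes resolved by smaller
absolute TSS distance then lexicographic gene id, so exactly one label per
fragment. Intergenic means no overlap with any gene span or promoter
window; this generalises "more than 5 kb upstream of the nearest TSS" to
the downstream flank as well, which the promoter-window phrasing does not
address. Intergenic fragments carry no gene id.

**Comparison.** Fragment identity across contrasts is exact coordinate
equality (both contrasts derive from one catalog), so no reciprocal-overlap
matching is needed. For common fragments, `Δ_AB = Δ_A − Δ_B`; the
divergent subset uses a strict `|Δ_AB| > 10` pp rule and is reported
sorted by Δ_AB ascending. Concordance classes come from the signs of the
two deltas; exact zeros go to an `unchanged` bucket rather than being
forced into a direction. The Pearson correlation of the common fragments
defaults to cohort-mean methylation levels (mode `cohort_means`), the more
natural reading of "methylation data within the common fragments"; a
`deltas` mode correlates the differences instead.

When the comparative engine is validated against *printed* tables, the
reported Δ_AB column is allowed to deviate from the recomputed
`Δ_A − Δ_B` by up to 0.2 pp: printed inputs are rounded to 0.1 pp, and
0.1 + 0.1 is the exact worst case of that rounding. In the bundled
26-fragment table, 25 rows reproduce to the printed precision and one
(chr1:59090260, like the CTSZ promoter row of the promoter/exon table)
differs by exactly 0.2.

**Multivariate views.** PCA centres each fragment across samples (no
unit-variance scaling by default; a flag enables it) and takes scores from
the SVD; each component's loading vector is flipped so its
largest-magnitude entry is positive, making outputs deterministic across
BLAS builds. Clustering defaults to Euclidean distance with complete
linkage — chosen for determinism and monotone merge heights — with metric
and linkage configurable.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
sequencing itself. Defaults (all configurable, all driven by one seed):

| parameter | default | meaning |
| --- | --- | --- |
| `group_sizes` | HC/ME/LC × 5 | the matched three-cohort design |
| `n_fragments` | 600 | in-size fragments requested from the genome |
| `frag_len_range` | 40–220 bp | RRBS size-selection window |
| `cpg_rate` | 0.08 | per-position chance of emitting a CG in fragment bodies (≈ 1 CpG / 13 bp, CpG-island-like density) |
| `high_mode` / `low_mode` | 0.89 / 0.15 | baseline methylation modes for non-promoter / promoter fragments |
| `baseline_concentration` | 60 | Beta concentration of the baseline draw |
| `coverage_mean`, `coverage_dispersion` | 30×, 0.2 | negative-binomial per-CpG read depth |
| `rho` | 0.05 | beta-binomial dispersion of methylated counts |
| `dropout` | 0.02 | per-(sample, fragment) missingness, so the complete-coverage filter has work to do |
| `n_dmf`, `n_shared` | 42/21, 12 shared | planted DMFs per contrast — a 429/214-with-118-shared overlap structure at one-tenth scale |
| `effect_range` | 10–37 pp | planted fragment-level effect sizes |
| `hyper_fraction` | 2/3 | hyper:hypo ratio of planted effects (2:1) |

Genomes are chains of `CCGG + body` segments whose bodies are CCGG-free,
so the number of in-size fragments is controlled exactly; occasional long
bodies produce oversize fragments for size selection to remove. Gene
models are laid out deterministically (alternating strands, 12 kb spans
with 300/400 bp exon/intron alternation, 8 kb gaps) so that promoter,
exon, intron, boundary and intergenic fragments all occur. Methylation
baselines are Beta draws around the high mode, except promoter-labelled
fragments, which use the low mode — reproducing the globally
hypermethylated, promoter-hypomethylated landscape of PBMC methylomes.

Fragments chosen to carry planted effects have their baselines redrawn
from a mid-range band with headroom for the effect in either direction, so
the planted size survives the [0.001, 0.999] clipping exactly and
estimated-vs-planted regression is meaningful. This also reflects what
cohort studies observe: differential fragments sit in
variable-methylation regions (control medians spanning roughly 9–75 %),
not at the saturated high mode. Shared DMFs receive one direction and
independent per-contrast magnitudes.

Counts are drawn per CpG: total reads NB(mean 30, dispersion 0.2), then
methylated reads via a Beta(μ, ρ)–Binomial mixture, independently across
CpGs, samples and fragments.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artefacts (bisulphite-conversion
failure, mapping bias, strand asymmetries), spatial correlation of
methylation along a fragment beyond the shared fragment mean, covariate
structure (age and sex are carried in the sample sheet but have no effect
on methylation), CpG-island/shore geography, and between-fragment
correlation. Type-I-error and recovery results therefore validate the
statistical machinery under its own assumptions, not robustness to those
real-data features.

## Recovery scoring

`evaluate_recovery` scores called DMF tables against the truth table.
Sensitivity is reported conditional on *evaluable* planted fragments —
those present in the tested (complete-coverage) matrix — because fragments
lost to the coverage model cannot be recovered by any caller; the
unconditional figure is reported alongside. The false-discovery proportion
is called-but-null over called (undefined, not zero, when nothing is
called). The effect-size regression (`delta_slope`) fits estimated Δ on
signed planted effect over **all** evaluable planted fragments, not only
the called ones, so threshold selection cannot inflate the slope
(winner's curse avoidance).

## Problem sizes and numerical choices

The validation suites run at desk scale, chosen so the whole test suite and
the reproduction script complete in minutes: the default simulated cohort
uses 600 fragments (≈ 80 kb of genome), the null-calibration suite 10,000
tested null fragments (generated without dropout so the tested count is
controlled), and the separation suite 400 fragments with effects of
20–37 pp. Degenerate-variance detection uses a relative threshold of
1e-12 on SS_within / SS_total; constant fragments return F = 0, p = 1.
Ties in hierarchical clustering follow scipy's deterministic linkage
order; Venn counts and concordance tallies are exact integer arithmetic.

## Known limitations

* The ANOVA on raw percentages assumes approximate normality of per-sample
  fragment methylation; this holds well at ≥ 2 CpGs × ~30 reads but will
  degrade for low-coverage fragments near 0 % or 100 %.
* One representative transcript per gene ignores alternative promoters;
  fragments near a secondary TSS may be labelled intronic.
* Destranding without a known CpG set falls back to a p/p+1 adjacency
  heuristic that can mis-merge directly adjacent CpGs (CGCG runs); supply
  catalog CpG positions for exact destranding.
* The two-contrast comparison assumes both DMF sets derive from the same
  fragment catalog; cross-study comparison with different coordinates is
  out of scope.
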