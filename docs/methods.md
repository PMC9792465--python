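# Methods

This note documents the models, statistical procedures, parameter choices
and known limitations of the package. Defaults quoted here are the values
in `AnalysisConfig` and `SimConfig`.

## Ohnolog pair calling

Input is a pair of best-HSP-collapsed similarity hit tables (L-genes vs
S-genes, both directions) and a goldfish→outgroup best-hit table. Hits with
E-value ≥ `evalue_max` (default 1e-40, strict `<` survives) are discarded
*before* best-hit selection; the best hit per query is chosen by maximal
bitscore, then minimal E-value, then lexicographically smallest subject id
— a deterministic, input-order-independent rule. Multi-HSP inputs are
collapsed to the best HSP by the same rule (`collapse_best_hsp`).

A reciprocal best-hit (RBH) pair is retained as an ohnolog pair iff

1. its two genes lie on a homeologous chromosome pair, and
2. both genes share one and the same outgroup best-hit gene, and that gene
   lies on the chromosome recorded as orthologous to the pair's
   chromosomes (the strictest reading: the shared ortholog must be the
   best hit of *both* copies).

Small-scale (tandem) duplicates need no separate filter: a gene whose best
partner sits on a non-homeologous chromosome is removed by condition 1.

The homeologous chromosome map is normally supplied (karyotypes are known
for published assemblies, and the CLI accepts a TSV override); when absent
it is inferred by majority vote of RBH partner chromosomes, resolved
greedily in decreasing vote order into a bijection. An exact vote tie for
the same S-chromosome, or an L-chromosome left partnerless, is an error
that asks for an explicit map — silent guessing would corrupt every
downstream stage. A warning is emitted when a winning vote share is below
0.5.

### Collinearity

MCScanX-style scored synteny detection is replaced by a transparent
monotone-chain criterion: within one homeologous chromosome pair, pairs
ordered by L-gene start form a collinear block if ≥ `min_block` (default 5)
of them have strictly monotone S-rank order (increasing or decreasing, so
inversions count) with at most `max_gap` (default 25) intervening pairs
between consecutive members on either chromosome. The defaults mirror
common MCScanX settings (`-s 5 -m 25`). The implementation is an O(n²)
longest-chain dynamic program; a pair is flagged iff the longest valid
chain through it reaches `min_block`. The criterion is invariant under
reversing either chromosome's coordinate axis. This simplification is
reproducible at desk scale but is *not* MCScanX's statistical model, so
published collinearity percentages are not directly comparable.

## Expression model and statistics

Normalization follows the standard library-size + log recipe:
`norm_cg = ln(1 + s · c_cg / Σ_g c_cg)` with scale factor `s = 10,000`.
Cells with zero total get all-zero rows and are reported, not dropped.
Scaling is per-gene z-scoring with the sample standard deviation (n−1),
zero-variance genes mapping to zero (with a relative tolerance of 1e-12 so
float cancellation noise in a constant gene is not mistaken for variance),
clipped at ±10.

Fold changes are always computed on **de-logged** normalized values
(`e^norm − 1`): means of log values are not ratio-interpretable. A
pseudocount of 1e-9 enters numerator and denominator.

### Wilcoxon rank-sum

The L-vs-S comparison within a cell type is an **unpaired** two-sample
rank-sum over the same cells, mirroring the marker-test contract of the
single-cell toolkits this analysis style comes from; a paired signed-rank
alternative is exposed via `pair_bias_table(..., paired=True)`. For
combined sample sizes ≤ 25 the exact two-sided p is computed by a
subset-sum dynamic program over doubled mid-ranks (exact under ties);
larger samples use the tie-corrected normal approximation (scipy's
Mann-Whitney implementation). Two-sided p is the doubled smaller tail,
capped at 1; a comparison with all values identical returns p = 1.

Bonferroni correction uses as family the number of pairs (or genes) tested
within one group — the per-group convention of marker methods. No
additional correction is applied across cell types for the
"balanced in every cell type" call; the summary report records the family
sizes actually used, since they determine the adjusted p-values.

A pair is biased in a group iff `p_adj < alpha` (0.05) **and**
`|log2 fc| > log2(2)`; the same two gates apply to specificity calls,
which additionally require detection (count > 0) in ≥ `min_pct` (0.1) of
in-type cells. The detection filter is deliberately *not* applied to L/S
bias tests, where dropout asymmetry between the copies is itself signal.

### Per-cell subgenome balance

Per cell, L- and S-copy de-logged normalized values are summed over all
pairs (sums of log values are not additive in expression, hence the
de-logged scale) and summarized as `log2((l+ε)/(s+ε))`. Cells with both
sums zero get ratio 0 with a `both_zero` flag instead of NaN. The per-cell-
type summary reports the mean plain fold change, the fraction of cells
with l strictly greater than s, and a paired signed-rank p.

### Fate classification

`n_biased_celltypes` counts cell types with a bias call; pairs partition
into `balanced_all` (0), `biased_one` (1) and `biased_multi` (≥ 2).
Overall dominance (L / S / comparable) comes from the all-cells test.
Cell-type specificity of the pair's *total* expression uses per-pair
summed counts and the relogged sum of de-logged member values, so the
pseudo-gene stays on the library-normalized scale. Divergence is defined
only when both copies have nonempty specificity sets: `similar` iff the
sets are equal, `divergent` otherwise. Sub- and neo-functionalization are
therefore reported jointly as `divergent`; the synthetic truth retains the
distinction for finer evaluation.

The dominance-asymmetry test is the exact two-sided binomial (doubled tail
of `Bin(n_L + n_S, 0.5)` at `max(n_L, n_S)`, capped at 1; exact summation,
no normal approximation). Subcluster divergence uses the per-expressing-
cell L-fraction `l/(l+s)` and a Kruskal–Wallis test across subclusters
(subclusters with < 3 expressing cells are dropped; ≥ 2 must remain).

## Chromatin accessibility

Gene activity counts every fragment (weighted by its duplicate-count
multiplicity; `ignore_dup_counts` switches to once-per-fragment) toward
every gene whose activity region it overlaps by ≥ 1 bp, with no fractional
assignment. The activity region is gene body plus a strand-aware 2 kb
upstream window (the convention of the standard scATAC gene-activity
scorers): `[start−2000, end)` for `+` genes, `[start, end+2000)` for `−`
genes, clipped at zero. Fragments files are 0-based half-open; GFF3 input
(1-based inclusive) is converted at the I/O boundary.

Promoter L/S balance reuses the expression-side per-cell balance on the
normalized activity matrix and adds per-cell-type medians (medians are
robust to the long per-cell coverage tail).

Motif analysis is an exact string match of the Otx2/Crx consensus hexamer
TAATCC on both strands (GGATTA in reference orientation on −), sequences
upper-cased, ambiguous bases never matching, overlapping hits all
reported; position-weight-matrix scoring is out of scope. Each hit carries
a ±100 bp window clipped at sequence ends. Window signal is per-cell
library-scaled fragment coverage (to 10,000 total per cell — the formula
behind "normalized signal" had to be fixed somewhere; library scaling
matches the expression side) summed over the window; the reported profile
is the median over windows per cell type, and enrichment is a two-sided
rank-sum comparing per-window mean signals of the focus cell types against
the others. This per-window, focus-vs-other construction is one
formalization of "motif enrichment in the OCRs of these cell types" and is
labelled as such in outputs; a single window cannot support the two-sample
test and raises an error.

RNA–ATAC concordance is the Pearson matrix between cell-type mean
expression and cell-type mean activity over a gene set (pair members as
separate features). Zero-variance profiles produce deliberate NaN entries
rather than arithmetic warnings.

## Synthetic cohort

The generator's defaults define the reference evaluation scenario:

| parameter | default | meaning |
|---|---|---|
| `n_chrom_pairs × genes_per_chrom` | 5 × 200 | 1,000 candidate ohnolog pairs |
| `shuffle_frac` | 0.1 | fraction of S-genes breaking collinear order |
| `frac_*_violators` | 0.03 each | planted E-value / reciprocity / condition-1 / condition-2 violators |
| `n_cell_types × cells_per_type` | 8 × 200 | 1,600 cells |
| fate mix | 0.30 / 0.20 / 0.20 / 0.10 / 0.10 / 0.10 | balanced / L-biased / S-biased / cell-type-specific / sub- / neo-functionalized |
| `bias_fc` | 4 | planted L:S fold change of biased pairs |
| `spec_fc` | 8 | in-type vs out-type fold change of specific genes |
| `base_mean`, `low_mean` | 2.0, 0.25 | NB means (counts per cell) |
| `nb_dispersion` | 0.5 | var = μ + 0.5 μ² |
| `libsize_lognorm_sd` | 0.3 | log-normal per-cell library factor (mean 1) |
| `frag_per_cell`, `promoter_frac` | 200, 0.5 | ATAC fragments per cell; share placed in expressed promoters |
| `motif_frac` | 0.5 | focus-coupled promoters receiving a planted TAATCC |

Counts are negative-binomial around the planted per-type mean times the
cell's library factor. Sub-functionalization partitions a two-type
ancestral set disjointly between the copies; neo-functionalization keeps
the ancestral type in both and adds a novel type to one copy (coin flip).
Genes are laid on a fixed grid (spacing 3,000 bp, body 400 bp), anchored
inside their slot strand-aware so that neighbouring activity regions never
overlap — this keeps planted accessibility ratios identifiable and makes
the activity matrix equal its per-gene oracle totals. Chromosome sequences
are random ACGT scrubbed of TAATCC/GGATTA; motifs are inserted mid-promoter
only at focus-coupled genes (specificity set intersecting the designated
photoreceptor/bipolar-like focus types), and any spurious occurrence
created at an insertion boundary is mutated away outside planted hexamers,
so a motif scan recovers exactly the planted set (scrubbing can be judged
by comparing the scan to `motif_truth`).

What the generator does **not** emulate: doublets and ambient RNA,
batch/sample effects, realistic sequence evolution between copies (hit
tables are constructed, not aligned), gene-length effects, chromatin
fragment-size periodicity, and peak structure beyond promoters (OCRs enter
as inputs). Passing recovery tests therefore demonstrates the statistical
machinery under the stated noise model, not robustness to these artifacts.

## Numerical and design choices

* Degenerate inputs return defined sentinels with flags (ratio 0 +
  `both_zero`, NaN-flagged correlation entries, p = 1 for all-tied tests)
  rather than propagating NaN.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configs give byte-identical files.
* The problem sizes used by the test suite and the acceptance script
  (1,000 pairs × 1,600 cells for recovery; a few hundred cells and ~200
  motif windows for the chromatin analyses) were chosen as the smallest
  cohorts at which the planted effects are comfortably detectable under
  the default noise model.
* Exit codes: 0 success, 2 validation/format error, 3 missing upstream
  stage output.

## Known limitations

* The collinearity criterion is a simplification (see above); its fraction
  on real data is not comparable to MCScanX percentages.
* Bonferroni is conservative at 10⁴-pair scale; a false-discovery-rate
  option would be a natural extension but would change the balanced/biased
  census definitions.
* The exact rank-sum path is O(n² · Σranks) per test and intentionally
  capped at n = 25.
* Cell-type and subcluster labels are inputs; no clustering is performed.
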