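"""Single-cell chromatin accessibility scoring and motif-window analysis.

ATAC fragments (BED-like 0-based half-open intervals with a cell barcode
and duplicate-count multiplicity) are converted into a per-cell gene
activity matrix by counting fragments over each gene's body plus a 2 kb
strand-aware upstream promoter window.  The resulting matrix reuses the
expression container and normalization from :mod:`ohnofate.scexpr`, so the
L/S promoter-accessibility balance is computed with the same contract as
the expression-side subgenome balance.

The photoreceptor/bipolar transcription factors Otx2 and Crx bind the
consensus hexamer TAATCC; :func:`scan_motif` finds exact occurrences on
both strands and attaches a +/-100 bp window to each hit, and
:func:`motif_window_profile` compares normalized fragment coverage in
those windows between cell-type groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ValidationError
from .ohnopair import GeneModel, OhnologPair
from .scexpr import AnalysisConfig, CellMatrix, per_cell_subgenome_balance, rank_sum_test

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
MOTIF_WINDOW = 100  # bp of flank attached on each side of a motif match


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    """One ATAC fragment: 0-based half-open interval, barcode, multiplicity."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.count < 1:
            raise ValidationError("fragment count (multiplicity) must be >= 1")


@dataclass(frozen=True)
class MotifHit:
    """An exact motif occurrence with its flanking analysis window."""

    chrom: str
    position: int  # 0-based start of the match
    strand: str
    window_start: int
    window_end: int


# --------------------------------------------------------------------------
# gene activity
# --------------------------------------------------------------------------


def gene_activity_region(gene: GeneModel, upstream: int = 2000) -> tuple[int, int]:
    """Gene body extended by a strand-aware upstream promoter window.

    For a + strand gene the region is [start - upstream, end); for a -
    strand gene, [start, end + upstream); clipped at 0.  Returned as a
    single half-open interval (body and upstream are contiguous).
    """
    if gene.strand == "+":
        return max(0, gene.start - upstream), gene.end
    return gene.start, gene.end + upstream


def gene_activity_matrix(
    fragments: Iterable[Fragment],
    gene_models: Mapping[str, GeneModel],
    upstream: int = 2000,
    barcodes: Sequence[str] | None = None,
    cell_labels: Mapping[str, str] | None = None,
    ignore_dup_counts: bool = False,
) -> CellMatrix:
    """Count fragments per cell over gene body + upstream promoter regions.

    Every fragment contributes its multiplicity to every gene whose activity
    region it overlaps by >= 1 bp (no fractional assignment).  Fragments on
    chromosomes absent from the gene models are skipped with a tallied
    warning.  ``barcodes`` fixes the cell universe (default: barcodes seen
    in the fragments, sorted); ``ignore_dup_counts`` counts each fragment
    once regardless of its multiplicity column.
    """
    genes = sorted(gene_models.values(), key=lambda g: (g.chrom, g.start, g.gene_id))
    gene_ids = [g.gene_id for g in genes]
    gene_col = {g.gene_id: j for j, g in enumerate(genes)}
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = gene_activity_region(g, upstream)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)

    if barcodes is not None:
        cell_ids = list(barcodes)
    else:
        fragments = list(fragments)
        cell_ids = sorted({f.barcode for f in fragments})
    row = {bc: i for i, bc in enumerate(cell_ids)}
    counts = np.zeros((len(cell_ids), len(gene_ids)), dtype=np.int64)
    skipped_chrom = 0
    skipped_barcode = 0
    for f in fragments:
        tree = trees.get(f.chrom)
        if tree is None:
            skipped_chrom += 1
            continue
        i = row.get(f.barcode)
        if i is None:
            skipped_barcode += 1
            continue
        w = 1 if ignore_dup_counts else f.count
        for iv in tree.overlap(f.start, f.end):
            counts[i, gene_col[iv.data]] += w
    if skipped_chrom:
        logger.warning("%d fragments on unknown chromosomes skipped", skipped_chrom)
    if skipped_barcode:
        logger.warning("%d fragments with out-of-universe barcodes skipped", skipped_barcode)

    cell_type = None
    if cell_labels is not None:
        cell_type = np.array([cell_labels.get(bc, "unknown") for bc in cell_ids], dtype=object)
    return CellMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, cell_type=cell_type)


def promoter_balance(
    activity: CellMatrix,
    pairs: Sequence[OhnologPair],
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """L/S promoter-accessibility balance per cell and cell type.

    Identical computation contract to the expression-side per-cell
    subgenome balance, applied to the normalized gene-activity matrix; the
    per-cell-type summary additionally reports the median log2 ratio.
    Cells with no fragments over either subgenome carry the ``both_zero``
    sentinel flag.
    """
    per_cell, summary = per_cell_subgenome_balance(activity, pairs, config)
    medians = per_cell.groupby("cell_type")["log2_ratio"].median()
    summary = summary.merge(
        medians.rename("median_log2_ratio"), left_on="cell_type", right_index=True
    )
    return per_cell, summary


# --------------------------------------------------------------------------
# motif scanning
# --------------------------------------------------------------------------


def scan_motif(
    genome: Mapping[str, str],
    motif: str = "TAATCC",
    regions: Sequence[tuple[str, int, int]] | None = None,
    window: int = MOTIF_WINDOW,
) -> list[MotifHit]:
    """Exact occurrences of a motif (both strands) with flanking windows.

    Sequences are upper-cased before matching; ambiguous bases never match.
    Overlapping occurrences are all reported.  A - strand hit is an
    occurrence of the reverse complement in reference orientation, recorded
    at its reference-coordinate start.  When ``regions`` is given, only
    hits whose match lies fully within some region are kept.  Windows
    extend ``window`` bp on each side and are clipped at sequence ends.
    """
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValidationError(f"motif must be a non-empty ACGT string, got {motif!r}")
    rc = revcomp(motif)
    region_by_chrom: dict[str, list[tuple[int, int]]] | None = None
    if regions is not None:
        region_by_chrom = {}
        for chrom, lo, hi in regions:
            region_by_chrom.setdefault(chrom, []).append((lo, hi))

    def _in_region(chrom: str, lo: int, hi: int) -> bool:
        if region_by_chrom is None:
            return True
        return any(lo >= a and hi <= b for a, b in region_by_chrom.get(chrom, ()))

    hits: list[MotifHit] = []
    m = len(motif)
    for chrom in sorted(genome):
        seq = str(genome[chrom]).upper()
        for pattern, strand in ((motif, "+"), (rc, "-")):
            start = seq.find(pattern)
            while start != -1:
                if _in_region(chrom, start, start + m):
                    hits.append(
                        MotifHit(
                            chrom=chrom,
                            position=start,
                            strand=strand,
                            window_start=max(0, start - window),
                            window_end=min(len(seq), start + m + window),
                        )
                    )
                start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.chrom, h.position, h.strand))
    return hits


# --------------------------------------------------------------------------
# motif window signal
# --------------------------------------------------------------------------


def motif_window_profile(
    fragments: Iterable[Fragment],
    hits: Sequence[MotifHit],
    cell_labels: Mapping[str, str],
    focus_types: set[str],
    other_types: set[str],
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Normalized fragment signal in motif windows, focus vs other cell types.

    Per-cell fragment counts are library-scaled to ``scale_factor`` total;
    the signal of a window in a cell type is the scaled coverage summed over
    the window and averaged over that type's cells.  The returned profile
    holds the median over windows per cell type; the enrichment p-value is
    a two-sided Wilcoxon rank-sum comparing per-window mean signals of the
    focus-type cells against the other-type cells.  Windows with zero
    coverage everywhere are retained as zeros.
    """
    config = config or AnalysisConfig()
    if not hits:
        raise ValidationError("motif_window_profile requires >= 1 motif hit")
    if not focus_types or not other_types:
        raise ValidationError("both cell-type sets must be non-empty")
    if focus_types & other_types:
        raise ValidationError("focus and other cell-type sets must be disjoint")
    if len(hits) < 2:
        raise ValidationError(
            "a single motif window cannot support a two-sample enrichment test"
        )

    fragments = list(fragments)
    lib = {}
    for f in fragments:
        lib[f.barcode] = lib.get(f.barcode, 0) + f.count
    trees: dict[str, IntervalTree] = {}
    for w, h in enumerate(hits):
        trees.setdefault(h.chrom, IntervalTree()).addi(h.window_start, h.window_end, w)

    cells = sorted(bc for bc in lib if bc in cell_labels)
    row = {bc: i for i, bc in enumerate(cells)}
    signal = np.zeros((len(cells), len(hits)))
    for f in fragments:
        i = row.get(f.barcode)
        tree = trees.get(f.chrom)
        if i is None or tree is None:
            continue
        w_scaled = f.count * config.scale_factor / lib[f.barcode]
        for iv in tree.overlap(f.start, f.end):
            signal[i, iv.data] += w_scaled

    types = np.array([cell_labels[bc] for bc in cells], dtype=object)
    profile_rows = []
    per_type_window: dict[str, np.ndarray] = {}
    for ct in sorted(set(types)):
        mean_per_window = signal[types == ct].mean(axis=0)
        per_type_window[ct] = mean_per_window
        profile_rows.append(
            {"cell_type": ct, "median_window_signal": float(np.median(mean_per_window))}
        )

    focus_mask = np.isin(types, sorted(focus_types))
    other_mask = np.isin(types, sorted(other_types))
    if not focus_mask.any() or not other_mask.any():
        raise ValidationError("no cells found for one of the cell-type sets")
    focus_per_window = signal[focus_mask].mean(axis=0)
    other_per_window = signal[other_mask].mean(axis=0)
    p = rank_sum_test(focus_per_window, other_per_window)
    return pd.DataFrame(profile_rows), p


# --------------------------------------------------------------------------
# RNA-ATAC concordance
# --------------------------------------------------------------------------


def celltype_means(matrix: CellMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Cell types x genes table of mean de-logged normalized values."""
    if matrix.cell_type is None:
        raise ValidationError("celltype_means requires cell_type labels")
    genes = list(genes) if genes is not None else list(matrix.gene_ids)
    gidx = matrix.gene_idx(genes)
    expr = np.expm1(matrix.norm[:, gidx]) if matrix.norm is not None else matrix.counts[:, gidx]
    rows = {}
    for ct in matrix.cell_types():
        rows[ct] = expr[matrix.cell_type == ct].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes)


def rna_atac_correlation(
    expr_celltype_means: pd.DataFrame,
    activity_celltype_means: pd.DataFrame,
    geneset: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation of expression vs accessibility cell-type profiles.

    Entry (i, j) correlates cell type i's mean expression with cell type
    j's mean gene activity over ``geneset`` (pair members enter as separate
    features).  On concordant data the matched diagonal dominates.
    Zero-variance profiles yield deliberate NaN entries (undefined flag)
    rather than warnings from degenerate arithmetic.
    """
    geneset = list(geneset)
    missing = [g for g in geneset if g not in expr_celltype_means.columns]
    missing += [g for g in geneset if g not in activity_celltype_means.columns]
    if missing:
        raise ValidationError(f"geneset members missing from profiles: {missing[:5]}")
    E = expr_celltype_means[geneset].to_numpy(dtype=float)
    A = activity_celltype_means[geneset].to_numpy(dtype=float)
    out = np.full((E.shape[0], A.shape[0]), np.nan)
    e_sd = E.std(axis=1)
    a_sd = A.std(axis=1)
    for i in range(E.shape[0]):
        if e_sd[i] == 0:
            continue
        for j in range(A.shape[0]):
            if a_sd[j] == 0:
                continue
            out[i, j] = float(np.corrcoef(E[i], A[j])[0, 1])
    return pd.DataFrame(out, index=expr_celltype_means.index, columns=activity_celltype_means.index)
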