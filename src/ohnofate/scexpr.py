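"""Single-cell expression statistics for ohnolog fate classification.

The questions this module answers, per ohnolog pair and per retinal cell
type, are:

* Is the per-cell transcriptome globally biased toward one subgenome?
  (per-cell sums of L- vs S-copy expression, paired signed-rank test)
* Is a given pair's L-copy expressed differently from its S-copy within a
  cell type?  (unpaired Wilcoxon rank-sum on library-normalized expression,
  Bonferroni-corrected, with a fold-change gate)
* Is a gene (or a pair's summed expression) a positive marker of specific
  cell types?  (one-vs-rest rank-sum with a detection-rate filter)
* Combining these: is the pair dosage-balanced in every cell type, biased,
  or sub-/neo-functionalized (both copies cell-type specific, with equal vs
  diverged specificity sets)?

Counts are library-normalized per cell to a fixed total (default 10,000),
natural-log transformed (``ln(1 + x)``), and optionally z-scaled per gene.
Rank tests operate on the log-normalized layer; means and fold changes are
computed on the de-logged (library-normalized) scale, since means of logs
are not ratio-interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .errors import ValidationError
from .ohnopair import OhnologPair

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# containers and configuration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Scalar thresholds shared by all expression/accessibility statistics.

    scale_factor
        per-cell library-normalization target total (counts scale).
    alpha
        significance level on Bonferroni-adjusted p-values.
    fc_threshold
        minimal fold change (plain ratio, not log) for a bias/marker call.
    min_pct
        minimal fraction of in-group cells detecting (count > 0) a gene for
        marker (specificity) calls; not applied to L-vs-S bias tests so that
        dropout asymmetry between copies stays visible.
    scale_clip
        absolute cap on per-gene z-scores.
    pseudo
        pseudocount added to both sides of fold-change ratios.
    """

    scale_factor: float = 10_000.0
    alpha: float = 0.05
    fc_threshold: float = 2.0
    min_pct: float = 0.1
    scale_clip: float = 10.0
    pseudo: float = 1e-9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.fc_threshold <= 1:
            raise ValidationError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if not 0 <= self.min_pct < 1:
            raise ValidationError(f"min_pct must be in [0,1), got {self.min_pct}")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be > 0")


@dataclass
class CellMatrix:
    """Cells x genes matrix with raw, normalized and scaled layers."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_type: np.ndarray | None = None  # per-cell labels, aligned to cell_ids
    norm: np.ndarray | None = None
    scaled: np.ndarray | None = None
    zero_total_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if len(self.cell_type) != len(self.cell_ids):
                raise ValidationError("cell_type length does not match cell count")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_idx(self, genes: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._gene_index[g] for g in genes], dtype=int)
        except KeyError as e:
            raise ValidationError(f"gene {e.args[0]!r} not in matrix") from e

    def cells_of(self, group: str) -> np.ndarray:
        """Boolean mask of cells belonging to a cell-type group ('ALL' = all)."""
        if group == "ALL":
            return np.ones(self.n_cells, dtype=bool)
        if self.cell_type is None:
            raise ValidationError("matrix has no cell_type labels")
        mask = self.cell_type == group
        if not mask.any():
            raise ValidationError(f"unknown cell-type group {group!r}")
        return mask

    def cell_types(self) -> list[str]:
        if self.cell_type is None:
            return []
        return sorted(set(self.cell_type))

    def to_anndata(self):
        """Optional AnnData view (requires anndata to be installed)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(
                {"cell_type": self.cell_type if self.cell_type is not None else ""},
                index=self.cell_ids,
            ),
            var=pd.DataFrame(index=self.gene_ids),
        )
        if self.norm is not None:
            adata.layers["norm"] = self.norm.copy()
        if self.scaled is not None:
            adata.layers["scaled"] = self.scaled.copy()
        return adata


# --------------------------------------------------------------------------
# Wilcoxon rank-sum machinery
# --------------------------------------------------------------------------

EXACT_MAX_N = 25  # exact null enumeration up to this combined sample size


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by dynamic programming over rank sums.

    Handles ties: mid-ranks are doubled to integers and the exact null
    distribution of the size-n1 rank-sum is built by subset-sum counting.
    Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    allv = np.concatenate([x, y])
    r2 = np.round(stats.rankdata(allv) * 2).astype(np.int64)
    n1 = len(x)
    total = int(r2.sum())
    counts = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    counts[0, 0] = 1
    for val in r2:
        v = int(val)
        for k in range(n1, 0, -1):
            counts[k, v:] += counts[k - 1, : total + 1 - v]
    dist = counts[n1]
    w = int(r2[:n1].sum())
    denom = dist.sum()
    cdf = dist[: w + 1].sum()
    sf = dist[w:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf) / denom))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration (tie-aware) when the combined sample size is at
    most ``EXACT_MAX_N``, otherwise the tie-corrected normal approximation.
    A comparison where every value is identical returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank_sum_test requires non-empty samples")
    allv = np.concatenate([x, y])
    if np.all(allv == allv[0]):
        return 1.0
    if len(allv) <= EXACT_MAX_N:
        return _exact_ranksum_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def rank_sum_batch(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values for (n1 x G) vs (n2 x G).

    Dispatches on the combined sample size exactly as ``rank_sum_test``;
    the asymptotic branch is vectorized across columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_total = X.shape[0] + Y.shape[0]
    if n_total <= EXACT_MAX_N:
        return np.array([rank_sum_test(X[:, g], Y[:, g]) for g in range(X.shape[1])])
    stacked = np.vstack([X, Y])
    constant = np.all(stacked == stacked[0, :], axis=0)
    pvals = np.ones(X.shape[1])
    if (~constant).any():
        res = stats.mannwhitneyu(
            X[:, ~constant], Y[:, ~constant], alternative="two-sided",
            method="asymptotic", axis=0,
        )
        pvals[~constant] = res.pvalue
    return pvals


def bonferroni(p: np.ndarray, family_size: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * family_size)."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * family_size)


# --------------------------------------------------------------------------
# normalization and scaling
# --------------------------------------------------------------------------


def normalize_counts(matrix: CellMatrix, config: AnalysisConfig | None = None) -> CellMatrix:
    """Library-normalize and log-transform: norm = ln(1 + sf * c / total).

    Cells with zero total get all-zero rows and are recorded in
    ``matrix.zero_total_cells``.  After this step the de-logged values of a
    nonzero cell sum exactly to ``scale_factor``.
    """
    config = config or AnalysisConfig()
    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    safe_totals = np.where(zero, 1.0, totals)
    norm = np.log1p(config.scale_factor * counts / safe_totals[:, None])
    norm[zero, :] = 0.0
    matrix.norm = norm
    matrix.zero_total_cells = [c for c, z in zip(matrix.cell_ids, zero) if z]
    if matrix.zero_total_cells:
        logger.warning(
            "%d cells with zero total counts set to all-zero normalized rows",
            len(matrix.zero_total_cells),
        )
    return matrix


def scale_genes(matrix: CellMatrix, config: AnalysisConfig | None = None) -> CellMatrix:
    """Per-gene z-scaling of the normalized layer, clipped to +/- scale_clip.

    Uses the sample standard deviation (n-1 divisor).  Zero-variance genes
    map to all-zero columns.
    """
    config = config or AnalysisConfig()
    if matrix.norm is None:
        raise ValidationError("normalize_counts must run before scale_genes")
    if matrix.n_cells < 2:
        raise ValidationError("scaling undefined for a single cell (sd needs n >= 2)")
    mean = matrix.norm.mean(axis=0)
    sd = matrix.norm.std(axis=0, ddof=1)
    # constant genes: a relative tolerance absorbs float cancellation noise
    zero_var = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    safe_sd = np.where(zero_var, 1.0, sd)
    scaled = (matrix.norm - mean) / safe_sd
    scaled[:, zero_var] = 0.0
    matrix.scaled = np.clip(scaled, -config.scale_clip, config.scale_clip)
    return matrix


def _delogged(matrix: CellMatrix) -> np.ndarray:
    if matrix.norm is None:
        raise ValidationError("normalized layer missing; run normalize_counts first")
    return np.expm1(matrix.norm)


# --------------------------------------------------------------------------
# per-cell subgenome balance
# --------------------------------------------------------------------------


def per_cell_subgenome_balance(
    matrix: CellMatrix,
    pairs: Sequence[OhnologPair],
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell L vs S total expression over ohnolog pairs.

    For each cell, sums de-logged normalized expression over all L-copies
    and all S-copies and reports log2((l+pseudo)/(s+pseudo)).  Cells where
    both sums are zero get ratio 0 with ``both_zero`` flagged.  The per-
    cell-type summary gives the mean plain fold change l/s, the fraction of
    cells with l strictly greater than s, and a paired Wilcoxon signed-rank
    p across cells.
    """
    config = config or AnalysisConfig()
    if not pairs:
        raise ValidationError("per_cell_subgenome_balance requires >= 1 ohnolog pair")
    expr = _delogged(matrix)
    l_idx = matrix.gene_idx(p.l_gene for p in pairs)
    s_idx = matrix.gene_idx(p.s_gene for p in pairs)
    l_sum = expr[:, l_idx].sum(axis=1)
    s_sum = expr[:, s_idx].sum(axis=1)
    both_zero = (l_sum == 0) & (s_sum == 0)
    log2_ratio = np.where(
        both_zero,
        0.0,
        np.log2((l_sum + config.pseudo) / (s_sum + config.pseudo)),
    )
    per_cell = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "cell_type": matrix.cell_type if matrix.cell_type is not None else "ALL",
            "l_sum": l_sum,
            "s_sum": s_sum,
            "log2_ratio": log2_ratio,
            "both_zero": both_zero,
        }
    )

    rows = []
    for ct, sub in per_cell.groupby("cell_type", sort=True):
        fold = (sub["l_sum"] + config.pseudo) / (sub["s_sum"] + config.pseudo)
        diffs = sub["l_sum"] - sub["s_sum"]
        if np.all(diffs == 0):
            p_signed = 1.0
        else:
            p_signed = float(stats.wilcoxon(sub["l_sum"], sub["s_sum"]).pvalue)
        rows.append(
            {
                "cell_type": ct,
                "n_cells": len(sub),
                "mean_ratio": float(fold.mean()),
                "frac_l_dominant": float((sub["l_sum"] > sub["s_sum"]).mean()),
                "p_signed_rank": p_signed,
            }
        )
    return per_cell, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# per-pair L vs S bias
# --------------------------------------------------------------------------


def pair_bias_table(
    matrix: CellMatrix,
    pairs: Sequence[OhnologPair],
    config: AnalysisConfig | None = None,
    group: str = "ALL",
    paired: bool = False,
) -> pd.DataFrame:
    """Per-pair L-vs-S expression test within one cell-type group.

    For each pair, compares the L-copy and S-copy normalized expression
    vectors over the same cells with an unpaired two-sided Wilcoxon
    rank-sum (``paired=True`` switches to the signed-rank alternative).
    Bonferroni family = number of pairs tested in this group.  A pair is
    flagged L- or S-biased iff adjusted p < alpha AND the de-logged fold
    change exceeds ``fc_threshold``.
    """
    config = config or AnalysisConfig()
    mask = matrix.cells_of(group)
    if mask.sum() < 3:
        raise ValidationError(
            f"group {group!r} has {int(mask.sum())} cells; >= 3 required"
        )
    if not pairs:
        raise ValidationError("pair_bias_table requires >= 1 ohnolog pair")
    norm = matrix.norm
    if norm is None:
        raise ValidationError("normalized layer missing; run normalize_counts first")
    l_idx = matrix.gene_idx(p.l_gene for p in pairs)
    s_idx = matrix.gene_idx(p.s_gene for p in pairs)
    L = norm[np.ix_(mask, l_idx)]
    S = norm[np.ix_(mask, s_idx)]
    mean_l = np.expm1(L).mean(axis=0)
    mean_s = np.expm1(S).mean(axis=0)
    log2fc = np.log2((mean_l + config.pseudo) / (mean_s + config.pseudo))
    if paired:
        pvals = np.ones(len(pairs))
        for g in range(len(pairs)):
            d = L[:, g] - S[:, g]
            pvals[g] = 1.0 if np.all(d == 0) else float(stats.wilcoxon(L[:, g], S[:, g]).pvalue)
    else:
        pvals = rank_sum_batch(L, S)
    p_adj = bonferroni(pvals, len(pairs))
    thr = np.log2(config.fc_threshold)
    biased = np.where(
        (p_adj < config.alpha) & (log2fc > thr),
        "L",
        np.where((p_adj < config.alpha) & (log2fc < -thr), "S", "none"),
    )
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "cell_type": group,
            "mean_l": mean_l,
            "mean_s": mean_s,
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "biased": biased,
        }
    )


# --------------------------------------------------------------------------
# cell-type specificity (one-vs-rest markers)
# --------------------------------------------------------------------------


def celltype_specificity(
    matrix: CellMatrix,
    config: AnalysisConfig | None = None,
    genes: Sequence[str] | None = None,
) -> dict[str, set[str]]:
    """Cell types in which each gene is a significant positive marker.

    One-vs-rest rank-sum per gene and cell type; a gene is specific to a
    type iff Bonferroni-adjusted p < alpha (family = genes tested per type),
    the de-logged in-type/rest fold change exceeds ``fc_threshold`` in favor
    of the in-type cells, and the gene is detected (count > 0) in at least
    ``min_pct`` of in-type cells.  Cell types with fewer than 3 cells are
    skipped with a warning.
    """
    config = config or AnalysisConfig()
    if matrix.cell_type is None:
        raise ValidationError("celltype_specificity requires cell_type labels")
    types = matrix.cell_types()
    if len(types) < 2:
        raise ValidationError("celltype_specificity requires >= 2 cell types")
    genes = list(genes) if genes is not None else list(matrix.gene_ids)
    gidx = matrix.gene_idx(genes)
    norm = matrix.norm
    if norm is None:
        raise ValidationError("normalized layer missing; run normalize_counts first")
    expr = np.expm1(norm[:, gidx])
    detected = matrix.counts[:, gidx] > 0
    result: dict[str, set[str]] = {g: set() for g in genes}
    thr = np.log2(config.fc_threshold)
    for ct in types:
        mask = matrix.cell_type == ct
        if mask.sum() < 3:
            logger.warning("cell type %r has < 3 cells; skipped in specificity", ct)
            continue
        X = norm[np.ix_(mask, gidx)]
        Y = norm[np.ix_(~mask, gidx)]
        pvals = rank_sum_batch(X, Y)
        p_adj = bonferroni(pvals, len(genes))
        mean_in = expr[mask].mean(axis=0)
        mean_out = expr[~mask].mean(axis=0)
        log2fc = np.log2((mean_in + config.pseudo) / (mean_out + config.pseudo))
        pct_in = detected[mask].mean(axis=0)
        hit = (p_adj < config.alpha) & (log2fc > thr) & (pct_in >= config.min_pct)
        for g, h in zip(genes, hit):
            if h:
                result[g].add(ct)
    return result


def pair_sum_matrix(matrix: CellMatrix, pairs: Sequence[OhnologPair]) -> CellMatrix:
    """Pseudo-gene matrix of per-pair summed (L + S) expression.

    Counts are summed per pair; the normalized layer is rebuilt as
    ``ln(1 + expm1(norm_L) + expm1(norm_S))`` so the pair total stays on the
    library-normalized scale of the parent matrix.
    """
    l_idx = matrix.gene_idx(p.l_gene for p in pairs)
    s_idx = matrix.gene_idx(p.s_gene for p in pairs)
    out = CellMatrix(
        counts=matrix.counts[:, l_idx] + matrix.counts[:, s_idx],
        cell_ids=list(matrix.cell_ids),
        gene_ids=[p.pair_id for p in pairs],
        cell_type=matrix.cell_type,
    )
    if matrix.norm is not None:
        out.norm = np.log1p(np.expm1(matrix.norm[:, l_idx]) + np.expm1(matrix.norm[:, s_idx]))
    return out


# --------------------------------------------------------------------------
# fate classification
# --------------------------------------------------------------------------


@dataclass
class FateCall:
    """Per-pair evolutionary fate summary."""

    pair_id: str
    n_biased_celltypes: int
    fate: str  # balanced_all | biased_one | biased_multi
    dominance: str  # L | S | comparable (from the all-cells test)
    pair_specific: bool
    spec_l: frozenset[str]
    spec_s: frozenset[str]
    divergence: str  # not_applicable | similar | divergent


def classify_fates(
    bias_tables: Mapping[str, pd.DataFrame],
    spec_l: Mapping[str, set[str]],
    spec_s: Mapping[str, set[str]],
    spec_pair: Mapping[str, set[str]],
    pairs: Sequence[OhnologPair],
) -> list[FateCall]:
    """Combine per-cell-type bias tests and specificity sets into fate calls.

    ``bias_tables`` maps each cell type (plus the mandatory "ALL" group) to
    the output of :func:`pair_bias_table`.  ``spec_l``/``spec_s`` map member
    gene ids to specificity sets; ``spec_pair`` maps pair ids to the
    specificity set of the pair's summed expression.

    * fate: balanced_all (no cell type biased), biased_one, biased_multi;
    * dominance: biased direction in the all-cells test;
    * divergence: defined only when BOTH copies have nonempty specificity
      sets — similar if the sets are equal, divergent otherwise.
    """
    if "ALL" not in bias_tables:
        raise ValidationError('bias_tables must include the "ALL" group')
    universe = [p.pair_id for p in pairs]
    uset = set(universe)
    per_type: dict[str, pd.Series] = {}
    for ct, tab in bias_tables.items():
        if set(tab["pair_id"]) != uset:
            raise ValidationError(
                f"bias table for {ct!r} covers a different pair universe"
            )
        per_type[ct] = tab.set_index("pair_id")["biased"]
    celltypes = [ct for ct in bias_tables if ct != "ALL"]

    calls: list[FateCall] = []
    for p in pairs:
        pid = p.pair_id
        n_biased = sum(per_type[ct][pid] != "none" for ct in celltypes)
        if n_biased == 0:
            fate = "balanced_all"
        elif n_biased == 1:
            fate = "biased_one"
        else:
            fate = "biased_multi"
        overall = per_type["ALL"][pid]
        dominance = overall if overall != "none" else "comparable"
        sl = frozenset(spec_l.get(p.l_gene, set()))
        ss = frozenset(spec_s.get(p.s_gene, set()))
        if sl and ss:
            divergence = "similar" if sl == ss else "divergent"
        else:
            divergence = "not_applicable"
        calls.append(
            FateCall(
                pair_id=pid,
                n_biased_celltypes=n_biased,
                fate=fate,
                dominance=dominance,
                pair_specific=bool(spec_pair.get(pid)),
                spec_l=sl,
                spec_s=ss,
                divergence=divergence,
            )
        )
    return calls


def fate_calls_frame(calls: Sequence[FateCall]) -> pd.DataFrame:
    """Tabular view of fate calls (sets serialized as comma-joined strings)."""
    return pd.DataFrame(
        {
            "pair_id": [c.pair_id for c in calls],
            "n_biased_celltypes": [c.n_biased_celltypes for c in calls],
            "fate": [c.fate for c in calls],
            "dominance": [c.dominance for c in calls],
            "pair_specific": [c.pair_specific for c in calls],
            "spec_l": [",".join(sorted(c.spec_l)) for c in calls],
            "spec_s": [",".join(sorted(c.spec_s)) for c in calls],
            "divergence": [c.divergence for c in calls],
        }
    )


# --------------------------------------------------------------------------
# auxiliary tests
# --------------------------------------------------------------------------


def binomial_asymmetry_test(n_l: int, n_s: int) -> float:
    """Exact two-sided binomial test of L-count vs S-count at p = 0.5.

    Doubles the one-tail probability of observing at least ``max(n_l, n_s)``
    successes in ``n_l + n_s`` fair trials, capped at 1.  Exact summation;
    no normal approximation.
    """
    if n_l < 0 or n_s < 0:
        raise ValidationError("counts must be non-negative")
    n = n_l + n_s
    if n < 1:
        raise ValidationError("at least one observation required")
    k = max(n_l, n_s)
    p = 2.0 * float(stats.binom.sf(k - 1, n, 0.5))
    return min(1.0, p)


def subpopulation_divergence(
    matrix: CellMatrix,
    pair: OhnologPair,
    subcluster_labels: np.ndarray,
    config: AnalysisConfig | None = None,
    min_cells: int = 3,
) -> tuple[float, float]:
    """Kruskal-Wallis test of per-cell L-fraction across subclusters.

    For cells expressing the pair (de-logged L + S > 0) the L-fraction
    f = l / (l + s) is compared across subclusters.  Subclusters with fewer
    than ``min_cells`` expressing cells are dropped; at least two must
    remain.  Returns (H statistic, p).
    """
    config = config or AnalysisConfig()
    labels = np.asarray(subcluster_labels, dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValidationError("subcluster labels length does not match cell count")
    expr = _delogged(matrix)
    l = expr[:, matrix.gene_idx([pair.l_gene])[0]]
    s = expr[:, matrix.gene_idx([pair.s_gene])[0]]
    expressing = (l + s) > 0
    groups = []
    for sc in sorted(set(labels)):
        mask = expressing & (labels == sc)
        if mask.sum() >= min_cells:
            groups.append(l[mask] / (l[mask] + s[mask]))
    if len(groups) < 2:
        raise ValidationError(
            "subpopulation_divergence needs >= 2 subclusters with "
            f">= {min_cells} expressing cells"
        )
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
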