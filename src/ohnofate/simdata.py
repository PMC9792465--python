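"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a recently duplicated
allotetraploid genome profiled at single-cell resolution:

* toy L/S genomes with homeologous chromosomes, collinear gene order up to
  a seeded shuffled fraction, an unduplicated outgroup genome, and
  similarity hit tables that encode the true pairs as mutual best hits plus
  decoys violating reciprocity, the E-value cutoff, or either ohnolog-
  calling condition;
* UMI count matrices over K cell types where each ohnolog pair carries a
  planted evolutionary fate (dosage-balanced, L-/S-biased at a stated fold
  change, cell-type specific, sub-functionalized with a disjoint partition
  of the ancestral cell-type set, or neo-functionalized with one copy
  gaining a novel type), with negative-binomial noise and log-normal
  library sizes;
* ATAC fragments whose placement is coupled to the planted expression
  means, with TAATCC motifs inserted into a stated fraction of promoters of
  genes specific to the designated focus (photoreceptor/bipolar-like) cell
  types and scrubbed everywhere else.

Every stochastic draw is governed by the config seed, so identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ohnopair import GeneModel, HitRecord, HomeologMap, OhnologPair
from .scatac import Fragment
from .scexpr import CellMatrix

FATE_NAMES = (
    "balanced",
    "l_biased",
    "s_biased",
    "celltype_specific",
    "subfunctionalized",
    "neofunctionalized",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    The defaults describe the reference evaluation scenario: 5 homeologous
    chromosome pairs x 200 genes (1,000 ohnolog pairs), 8 cell types with
    200 cells each, a planted bias fold change of 4, negative-binomial
    dispersion 0.5, and log-normal library-size spread 0.3.
    """

    n_chrom_pairs: int = 5
    genes_per_chrom: int = 200
    shuffle_frac: float = 0.1
    gene_length: int = 400
    gene_spacing: int = 3000  # > gene_length + upstream, so activity regions stay disjoint
    # hit-table decoys
    frac_evalue_violators: float = 0.03
    frac_nonreciprocal: float = 0.03
    frac_c1_violators: float = 0.03
    frac_c2_violators: float = 0.03
    evalue_cutoff: float = 1e-40
    # expression
    n_cell_types: int = 8
    cells_per_type: int = 200
    fates: dict[str, float] = field(
        default_factory=lambda: {
            "balanced": 0.30,
            "l_biased": 0.20,
            "s_biased": 0.20,
            "celltype_specific": 0.10,
            "subfunctionalized": 0.10,
            "neofunctionalized": 0.10,
        }
    )
    bias_fc: float = 4.0
    spec_fc: float = 8.0
    base_mean: float = 2.0
    low_mean: float = 0.25
    nb_dispersion: float = 0.5
    libsize_lognorm_sd: float = 0.3
    # chromatin
    frag_per_cell: int = 200
    promoter_frac: float = 0.5
    frag_ls_ratio: float = 1.0
    motif_frac: float = 0.5
    n_focus_types: int = 2
    upstream: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fates.get(f, 0.0) for f in FATE_NAMES)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fate proportions must sum to 1, got {total}")
        if set(self.fates) - set(FATE_NAMES):
            raise ValidationError(f"unknown fate names: {set(self.fates) - set(FATE_NAMES)}")
        if self.bias_fc <= 1:
            raise ValidationError("bias_fc must be > 1")
        if self.n_cell_types < 2:
            raise ValidationError("need >= 2 cell types")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.gene_spacing < self.gene_length + self.upstream + 400:
            raise ValidationError(
                "gene_spacing must exceed gene_length + upstream + 400 so that "
                "promoter/activity regions of neighbouring genes stay disjoint"
            )

    @property
    def cell_types(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_cell_types)]

    @property
    def focus_types(self) -> set[str]:
        return set(self.cell_types[: self.n_focus_types])


# --------------------------------------------------------------------------
# genomes and hit tables
# --------------------------------------------------------------------------


@dataclass
class SimGenome:
    """Toy genome bundle: annotations, hit tables, orthology, pair truth."""

    gene_models: dict[str, GeneModel]
    homeolog_map: HomeologMap
    hits_ls: list[HitRecord]
    hits_sl: list[HitRecord]
    outgroup_hits: list[HitRecord]
    outgroup_rbh: dict[str, tuple[str, str]]
    outgroup_gene_chrom: dict[str, str]
    pair_truth: pd.DataFrame  # l_gene, s_gene, status
    true_pairs: list[OhnologPair]
    chrom_lengths: dict[str, int]  # includes outgroup chromosomes
    focal_chroms: list[str] = field(default_factory=list)  # L/S chromosomes only
    sequences: dict[str, str] | None = None


_MOTIF_RE = re.compile("TAATCC|GGATTA")


def _scrub_motifs(seq: str) -> str:
    """Mutate the genome until it carries no TAATCC/GGATTA occurrence."""

    def fix(m: re.Match) -> str:
        s = m.group()
        repl = "G" if s[3] != "G" else "C"
        return s[:3] + repl + s[4:]

    while _MOTIF_RE.search(seq):
        seq = _MOTIF_RE.sub(fix, seq)
    return seq


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_genomes(config: SimConfig, with_fasta: bool = False) -> SimGenome:
    """Build toy L/S/outgroup genomes, hit tables and the pair truth table.

    Gene order on each S-chromosome mirrors its L homeolog except for a
    seeded ``shuffle_frac`` of genes whose order is permuted (breaking
    collinearity).  The hit tables encode true pairs as mutual best hits
    with a >= 2x bitscore margin over decoy paralogs; planted violators
    cover the E-value cutoff, reciprocity, the homeologous-chromosome
    condition and the shared-outgroup-ortholog condition.  With
    ``with_fasta`` random chromosome sequences (scrubbed of the Otx2/Crx
    hexamer) are attached.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.genes_per_chrom
    spacing, glen = config.gene_spacing, config.gene_length
    chrom_len = n * spacing + spacing

    gene_models: dict[str, GeneModel] = {}
    homeolog_pairs: dict[str, str] = {}
    orthology: dict[str, str] = {}
    outgroup_gene_chrom: dict[str, str] = {}
    hits_ls: list[HitRecord] = []
    hits_sl: list[HitRecord] = []
    outgroup_hits: list[HitRecord] = []
    outgroup_rbh: dict[str, tuple[str, str]] = {}
    truth_rows: list[dict] = []
    chrom_lengths: dict[str, int] = {}

    # collect (candidate pair records) per chromosome pair, then plant
    # cross-chromosome (condition-1) violators by swapping partners between
    # consecutive chromosome pairs
    per_chrom_pairs: list[list[dict]] = []
    for c in range(1, config.n_chrom_pairs + 1):
        lc, sc, zc = f"L{c}", f"S{c}", f"Z{c}"
        homeolog_pairs[lc] = sc
        orthology[lc] = zc
        orthology[sc] = zc
        chrom_lengths[lc] = chrom_lengths[sc] = chrom_lengths[zc] = chrom_len

        # L gene order is the identity; S order shuffles a seeded fraction
        order = np.arange(n)
        k = int(round(config.shuffle_frac * n))
        if k >= 2:
            moved = rng.choice(n, size=k, replace=False)
            perm = rng.permutation(moved)
            order[moved] = order[perm]
        s_position = np.empty(n, dtype=int)
        s_position[np.argsort(order, kind="stable")] = np.arange(n)

        recs: list[dict] = []
        for i in range(n):
            lg, sg, zg = f"g{lc}_{i:04d}", f"g{sc}_{i:04d}", f"z{zc}_{i:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            # anchor each gene inside its slot so body + 2 kb promoter regions
            # of neighbouring genes never overlap, regardless of strand
            offset = config.upstream + 200 if strand == "+" else 200
            l_start = spacing * i + offset
            s_start = spacing * int(s_position[i]) + offset
            gene_models[lg] = GeneModel(lg, lc, l_start, l_start + glen, strand, "L")
            gene_models[sg] = GeneModel(sg, sc, s_start, s_start + glen, strand, "S")
            outgroup_gene_chrom[zg] = zc
            recs.append({"l_gene": lg, "s_gene": sg, "z_gene": zg, "z_chrom": zc})
        per_chrom_pairs.append(recs)

    # assign statuses
    all_recs = [r for recs in per_chrom_pairs for r in recs]
    n_total = len(all_recs)
    statuses = np.array(["true"] * n_total, dtype=object)
    n_ev = int(round(config.frac_evalue_violators * n_total))
    n_nr = int(round(config.frac_nonreciprocal * n_total))
    n_c1 = int(round(config.frac_c1_violators * n_total))
    n_c1 -= n_c1 % 2  # condition-1 violators are planted as swapped couples
    n_c2 = int(round(config.frac_c2_violators * n_total))
    chosen = rng.choice(n_total, size=n_ev + n_nr + n_c1 + n_c2, replace=False)
    statuses[chosen[:n_ev]] = "evalue_violator"
    statuses[chosen[n_ev : n_ev + n_nr]] = "nonreciprocal"
    statuses[chosen[n_ev + n_nr : n_ev + n_nr + n_c1]] = "c1_violator"
    statuses[chosen[n_ev + n_nr + n_c1 :]] = "c2_violator"

    c1_queue: list[dict] = []
    for rec, status in zip(all_recs, statuses):
        lg, sg, zg, zc = rec["l_gene"], rec["s_gene"], rec["z_gene"], rec["z_chrom"]
        bit_hi, bit_lo = 500.0, 200.0
        ev_good = 1e-100
        if status == "evalue_violator":
            # mutual best, but the link fails the E-value cutoff
            hits_ls.append(HitRecord(lg, sg, 1e-30, bit_hi))
            hits_sl.append(HitRecord(sg, lg, 1e-30, bit_hi))
        elif status == "nonreciprocal":
            # L's best hit points at S, but S's best points elsewhere
            hits_ls.append(HitRecord(lg, sg, ev_good, bit_hi))
            other = f"decoyL_{sg}"
            gene_models.setdefault(
                other,
                GeneModel(other, gene_models[lg].chrom, chrom_len - glen - 1, chrom_len - 1, "+", "L"),
            )
            hits_sl.append(HitRecord(sg, other, ev_good, bit_hi))
            hits_sl.append(HitRecord(sg, lg, ev_good, bit_lo))
        elif status == "c1_violator":
            c1_queue.append(rec)
            continue
        else:  # true or c2_violator: mutual best + a weaker decoy paralog hit
            hits_ls.append(HitRecord(lg, sg, ev_good, bit_hi))
            hits_sl.append(HitRecord(sg, lg, ev_good, bit_hi))
            if rng.random() < 0.3:
                hits_ls.append(HitRecord(lg, f"decoy_{lg}", 1e-50, bit_lo))
        # outgroup best hits
        if status == "c2_violator":
            alt = f"z{zc}_alt_{lg}"
            outgroup_gene_chrom[alt] = zc
            outgroup_rbh[lg] = (zg, zc)
            outgroup_rbh[sg] = (alt, zc)
            outgroup_hits.append(HitRecord(lg, zg, ev_good, bit_hi))
            outgroup_hits.append(HitRecord(sg, alt, ev_good, bit_hi))
        else:
            outgroup_rbh[lg] = (zg, zc)
            outgroup_rbh[sg] = (zg, zc)
            outgroup_hits.append(HitRecord(lg, zg, ev_good, bit_hi))
            outgroup_hits.append(HitRecord(sg, zg, ev_good, bit_hi))
        truth_rows.append({"l_gene": lg, "s_gene": sg, "status": status})

    # condition-1 violators: swap S partners between couples so both mutual
    # best hits cross non-homeologous chromosomes
    for a, b in zip(c1_queue[0::2], c1_queue[1::2]):
        for rec, partner in ((a, b), (b, a)):
            lg, sg = rec["l_gene"], partner["s_gene"]
            hits_ls.append(HitRecord(lg, sg, 1e-100, 500.0))
            hits_sl.append(HitRecord(sg, lg, 1e-100, 500.0))
            outgroup_rbh[lg] = (rec["z_gene"], rec["z_chrom"])
            outgroup_rbh[sg] = (partner["z_gene"], partner["z_chrom"])
            outgroup_hits.append(HitRecord(lg, rec["z_gene"], 1e-100, 500.0))
            outgroup_hits.append(HitRecord(sg, partner["z_gene"], 1e-100, 500.0))
            truth_rows.append({"l_gene": lg, "s_gene": sg, "status": "c1_violator"})
    if len(c1_queue) % 2:  # odd leftover becomes a plain true pair
        rec = c1_queue[-1]
        lg, sg, zg, zc = rec["l_gene"], rec["s_gene"], rec["z_gene"], rec["z_chrom"]
        hits_ls.append(HitRecord(lg, sg, 1e-100, 500.0))
        hits_sl.append(HitRecord(sg, lg, 1e-100, 500.0))
        outgroup_rbh[lg] = (zg, zc)
        outgroup_rbh[sg] = (zg, zc)
        outgroup_hits.append(HitRecord(lg, zg, 1e-100, 500.0))
        outgroup_hits.append(HitRecord(sg, zg, 1e-100, 500.0))
        truth_rows.append({"l_gene": lg, "s_gene": sg, "status": "true"})

    pair_truth = pd.DataFrame(truth_rows).sort_values(["l_gene"]).reset_index(drop=True)
    true_pairs = [
        OhnologPair(
            l_gene=row.l_gene,
            s_gene=row.s_gene,
            outgroup_gene=outgroup_rbh[row.l_gene][0],
            l_chrom=gene_models[row.l_gene].chrom,
            s_chrom=gene_models[row.s_gene].chrom,
        )
        for row in pair_truth.itertuples()
        if row.status == "true"
    ]
    true_pairs.sort(key=lambda p: (p.l_chrom, gene_models[p.l_gene].start))

    focal_chroms = sorted(set(homeolog_pairs) | set(homeolog_pairs.values()))
    sequences = None
    if with_fasta:
        sequences = {
            chrom: _scrub_motifs(_random_sequence(rng, chrom_lengths[chrom]))
            for chrom in focal_chroms
        }

    return SimGenome(
        gene_models=gene_models,
        homeolog_map=HomeologMap(pairs=homeolog_pairs, outgroup_orthology=orthology),
        hits_ls=hits_ls,
        hits_sl=hits_sl,
        outgroup_hits=outgroup_hits,
        outgroup_rbh=outgroup_rbh,
        outgroup_gene_chrom=outgroup_gene_chrom,
        pair_truth=pair_truth,
        true_pairs=true_pairs,
        chrom_lengths=chrom_lengths,
        focal_chroms=focal_chroms,
        sequences=sequences,
    )


# --------------------------------------------------------------------------
# expression counts
# --------------------------------------------------------------------------


def _draw_nb(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    mu = np.maximum(mu, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(
    config: SimConfig, pairs: Sequence[OhnologPair]
) -> tuple[CellMatrix, pd.DataFrame]:
    """UMI counts with planted per-pair fates, plus the truth table.

    Per pair a fate is drawn from ``config.fates``; cell-type means follow
    the fate (balanced: equal means everywhere; biased: ``bias_fc`` ratio;
    cell-type specific: both copies high on a drawn type subset; sub-
    functionalized: a two-type ancestral set split disjointly between
    copies; neo-functionalized: one copy keeps the ancestral type, the
    other gains a novel one).  Counts are negative-binomial around the
    planted mean scaled by a per-cell log-normal library factor.  Returns
    the count matrix (genes = all pair members) with cell-type labels and
    the truth table (fate, specificity sets, planted fold change).
    """
    if not pairs:
        raise ValidationError("simulate_counts requires >= 1 pair")
    rng = np.random.default_rng([config.seed, 2])
    K = config.n_cell_types
    types = config.cell_types
    if K < 2 and any(f in config.fates and config.fates[f] > 0 for f in ("subfunctionalized",)):
        raise ValidationError("sub-functionalization needs >= 2 cell types to partition")

    n_cells = K * config.cells_per_type
    cell_type = np.repeat(types, config.cells_per_type)
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    type_index = np.repeat(np.arange(K), config.cells_per_type)

    fate_names = [f for f in FATE_NAMES if config.fates.get(f, 0) > 0]
    fate_probs = np.array([config.fates[f] for f in fate_names])
    fate_draw = rng.choice(len(fate_names), size=len(pairs), p=fate_probs / fate_probs.sum())

    mu_l = np.zeros((K, len(pairs)))
    mu_s = np.zeros((K, len(pairs)))
    truth_rows = []
    for j, pair in enumerate(pairs):
        fate = fate_names[fate_draw[j]]
        spec_l: set[str] = set()
        spec_s: set[str] = set()
        fc = 1.0
        if fate == "balanced":
            mu_l[:, j] = mu_s[:, j] = config.base_mean
        elif fate in ("l_biased", "s_biased"):
            fc = config.bias_fc
            hi, lo = config.base_mean * config.bias_fc, config.base_mean
            if fate == "l_biased":
                mu_l[:, j], mu_s[:, j] = hi, lo
            else:
                mu_l[:, j], mu_s[:, j] = lo, hi
        elif fate == "celltype_specific":
            size = int(rng.integers(1, min(2, K - 1) + 1))
            subset = sorted(rng.choice(K, size=size, replace=False).tolist())
            mu_l[:, j] = mu_s[:, j] = config.low_mean
            for t in subset:
                mu_l[t, j] = mu_s[t, j] = config.low_mean * config.spec_fc
            spec_l = spec_s = {types[t] for t in subset}
            fc = config.spec_fc
        elif fate == "subfunctionalized":
            a, b = sorted(rng.choice(K, size=2, replace=False).tolist())
            mu_l[:, j] = mu_s[:, j] = config.low_mean
            mu_l[a, j] = config.low_mean * config.spec_fc
            mu_s[b, j] = config.low_mean * config.spec_fc
            spec_l, spec_s = {types[a]}, {types[b]}
            fc = config.spec_fc
        else:  # neofunctionalized
            a, b = sorted(rng.choice(K, size=2, replace=False).tolist())
            mu_l[:, j] = mu_s[:, j] = config.low_mean
            gainer_is_l = rng.random() < 0.5
            mu_l[a, j] = config.low_mean * config.spec_fc
            mu_s[a, j] = config.low_mean * config.spec_fc
            if gainer_is_l:
                mu_l[b, j] = config.low_mean * config.spec_fc
                spec_l, spec_s = {types[a], types[b]}, {types[a]}
            else:
                mu_s[b, j] = config.low_mean * config.spec_fc
                spec_l, spec_s = {types[a]}, {types[a], types[b]}
            fc = config.spec_fc
        truth_rows.append(
            {
                "pair_id": pair.pair_id,
                "l_gene": pair.l_gene,
                "s_gene": pair.s_gene,
                "fate": fate,
                "spec_l": ",".join(sorted(spec_l)),
                "spec_s": ",".join(sorted(spec_s)),
                "fold_change": fc,
            }
        )

    sd = config.libsize_lognorm_sd
    libfactor = rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=n_cells)

    gene_ids = [p.l_gene for p in pairs] + [p.s_gene for p in pairs]
    counts = np.zeros((n_cells, 2 * len(pairs)), dtype=np.int64)
    mu_all = np.concatenate([mu_l, mu_s], axis=1)  # K x 2P
    for j in range(mu_all.shape[1]):
        mu_cells = mu_all[type_index, j] * libfactor
        counts[:, j] = _draw_nb(rng, mu_cells, config.nb_dispersion)

    matrix = CellMatrix(
        counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, cell_type=cell_type
    )
    truth = pd.DataFrame(truth_rows)
    return matrix, truth


# --------------------------------------------------------------------------
# fragments, OCR truth and motif planting
# --------------------------------------------------------------------------


@dataclass
class SimFragments:
    """Synthetic chromatin bundle: fragments, OCR truth, motif truth, FASTA."""

    fragments: list[Fragment]
    ocr_truth: pd.DataFrame  # chrom, start, end, gene_id, focus_coupled, motif_planted
    motif_truth: pd.DataFrame  # chrom, position, strand
    sequences: dict[str, str]


def _promoter_interval(gene: GeneModel, upstream: int) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.start - upstream), gene.start
    return gene.end, gene.end + upstream


def simulate_fragments(
    config: SimConfig,
    genome: SimGenome,
    counts_truth: pd.DataFrame,
    labels: Mapping[str, str] | None = None,
    barcodes: Sequence[str] | None = None,
    cell_type: Sequence[str] | None = None,
) -> SimFragments:
    """ATAC fragments coupled to planted expression, with motif planting.

    Per cell, ``frag_per_cell`` fragments are drawn: a ``promoter_frac``
    share lands uniformly within promoter + gene-body regions of pair-member
    genes, choosing genes with probability proportional to the planted
    expression mean of the cell's type (L-gene weights additionally scaled
    by ``frag_ls_ratio``); the remainder is uniform genomic background.
    TAATCC is inserted into ``motif_frac`` of the promoters of genes
    specific to the focus cell types; everywhere else the sequence is kept
    free of the motif, so a motif scan recovers exactly the planted set.
    """
    if genome.sequences is None:
        raise ValidationError("simulate_fragments requires genome sequences (with_fasta=True)")
    rng = np.random.default_rng([config.seed, 3])
    if barcodes is None or cell_type is None:
        if labels is None:
            raise ValidationError("either labels or (barcodes, cell_type) required")
        barcodes = list(labels)
        cell_type = [labels[bc] for bc in barcodes]
    types = config.cell_types
    type_pos = {t: i for i, t in enumerate(types)}

    # planted per-type means for each pair member gene
    member_genes: list[str] = []
    member_mu = []
    fate_by_gene: dict[str, dict] = {}
    for row in counts_truth.itertuples():
        for gene, spec_col in ((row.l_gene, row.spec_l), (row.s_gene, row.spec_s)):
            member_genes.append(gene)
            fate_by_gene[gene] = {
                "fate": row.fate,
                "spec": set(spec_col.split(",")) if spec_col else set(),
            }
    mu = np.zeros((len(types), len(member_genes)))
    for j, gene in enumerate(member_genes):
        info = fate_by_gene[gene]
        is_l = genome.gene_models[gene].subgenome == "L"
        if info["fate"] in ("celltype_specific", "subfunctionalized", "neofunctionalized"):
            mu[:, j] = config.low_mean
            for t in info["spec"]:
                mu[type_pos[t], j] = config.low_mean * config.spec_fc
        elif info["fate"] == "l_biased":
            mu[:, j] = config.base_mean * (config.bias_fc if is_l else 1.0)
        elif info["fate"] == "s_biased":
            mu[:, j] = config.base_mean * (1.0 if is_l else config.bias_fc)
        else:
            mu[:, j] = config.base_mean
        if is_l:
            mu[:, j] *= config.frag_ls_ratio

    regions = []
    for gene in member_genes:
        g = genome.gene_models[gene]
        plo, phi = _promoter_interval(g, config.upstream)
        lo, hi = min(plo, g.start), max(phi, g.end)
        regions.append((g.chrom, lo, hi))
    region_len = np.array([hi - lo for _, lo, hi in regions])

    # per-type gene choice probabilities (accessibility ~ expression mean)
    probs = mu / mu.sum(axis=1, keepdims=True)

    chroms = list(genome.focal_chroms)  # background stays on the focal genome
    chrom_len = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_probs = chrom_len / chrom_len.sum()

    fragments: list[Fragment] = []
    for bc, ct in zip(barcodes, cell_type):
        t = type_pos.get(ct)
        n_prom = rng.binomial(config.frag_per_cell, config.promoter_frac) if t is not None else 0
        n_bg = config.frag_per_cell - n_prom
        if n_prom:
            gidx = rng.choice(len(member_genes), size=n_prom, p=probs[t])
            for gi in gidx:
                chrom, lo, hi = regions[gi]
                flen = int(rng.integers(80, 250))
                start = int(rng.integers(lo, max(lo + 1, hi - flen)))
                end = min(start + flen, genome.chrom_lengths[chrom])
                fragments.append(Fragment(chrom, start, end, bc, 1))
        if n_bg:
            cidx = rng.choice(len(chroms), size=n_bg, p=chrom_probs)
            for ci in cidx:
                chrom = chroms[ci]
                flen = int(rng.integers(80, 250))
                start = int(rng.integers(0, genome.chrom_lengths[chrom] - flen))
                fragments.append(Fragment(chrom, start, int(start + flen), bc, 1))

    # OCR truth: promoter windows of all pair-member genes
    focus = config.focus_types
    ocr_rows = []
    seqs = {c: list(genome.sequences[c]) for c in genome.sequences}
    motif_rows = []
    for gene in member_genes:
        g = genome.gene_models[gene]
        plo, phi = _promoter_interval(g, config.upstream)
        focus_coupled = bool(fate_by_gene[gene]["spec"] & focus)
        planted = False
        if focus_coupled and rng.random() < config.motif_frac:
            pos = (plo + phi) // 2
            seqs[g.chrom][pos : pos + 6] = list("TAATCC")
            motif_rows.append({"chrom": g.chrom, "position": pos, "strand": "+"})
            planted = True
        ocr_rows.append(
            {
                "chrom": g.chrom,
                "start": plo,
                "end": phi,
                "gene_id": gene,
                "focus_coupled": focus_coupled,
                "motif_planted": planted,
            }
        )

    sequences = {c: "".join(s) for c, s in seqs.items()}
    # remove any spurious occurrence created at planting boundaries,
    # mutating only bases outside planted hexamers
    planted_iv = {(r["chrom"], r["position"]) for r in motif_rows}
    for chrom in sequences:
        seq = sequences[chrom]
        changed = True
        while changed:
            changed = False
            for m in _MOTIF_RE.finditer(seq):
                if (chrom, m.start()) in planted_iv and m.group() == "TAATCC":
                    continue
                protected = set()
                for c2, p2 in planted_iv:
                    if c2 == chrom:
                        protected.update(range(p2, p2 + 6))
                for off in range(6):
                    idx = m.start() + off
                    if idx not in protected:
                        base = seq[idx]
                        seq = seq[:idx] + ("G" if base != "G" else "C") + seq[idx + 1 :]
                        changed = True
                        break
                if changed:
                    break
        sequences[chrom] = seq

    fragments.sort(key=lambda f: (f.chrom, f.start, f.end, f.barcode))
    return SimFragments(
        fragments=fragments,
        ocr_truth=pd.DataFrame(ocr_rows),
        motif_truth=pd.DataFrame(motif_rows, columns=["chrom", "position", "strand"]),
        sequences=sequences,
    )
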