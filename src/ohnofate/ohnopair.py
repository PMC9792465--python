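"""Ohnolog-pair calling for an allotetraploid genome.

After an allotetraploid whole-genome duplication the genome carries two
subgenomes (here L and S) whose chromosomes come in homeologous pairs.  Each
ancestral gene is potentially retained as an L-copy and an S-copy (an ohnolog
pair).  This module reconstructs high-confidence ohnolog pairs from pairwise
similarity hit tables under three constraints:

1. the two genes are reciprocal best hits (RBH) of each other at a stringent
   E-value cutoff;
2. they reside on a homeologous chromosome pair;
3. both map to one and the same ortholog in an unduplicated outgroup genome,
   and that ortholog lies on the outgroup chromosome orthologous to the
   pair's chromosomes.

A simplified collinearity check (monotone gap-bounded chains of pair order
along the homeologous chromosomes) flags pairs that sit in syntenic blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, TieError, ValidationError

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: 0-based half-open coordinates plus subgenome tag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subgenome: str  # "L", "S" or "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.subgenome not in ("L", "S", "other"):
            raise ValidationError(
                f"gene {self.gene_id}: subgenome must be 'L', 'S' or 'other'"
            )


@dataclass(frozen=True)
class HitRecord:
    """One best-HSP-collapsed similarity hit (query -> subject)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise FormatError(f"hit record missing gene id: {self!r}")
        if self.evalue < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value {self.evalue}"
            )
        if self.bitscore < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative bitscore {self.bitscore}"
            )


@dataclass
class HomeologMap:
    """Bijection between L- and S-chromosomes plus outgroup chromosome orthology."""

    pairs: dict[str, str]  # L chrom -> S chrom
    outgroup_orthology: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s_chroms = list(self.pairs.values())
        if len(set(s_chroms)) != len(s_chroms):
            raise ValidationError("homeolog map is not a bijection: duplicate S-chromosome")

    def s_partner(self, l_chrom: str) -> str | None:
        return self.pairs.get(l_chrom)


@dataclass
class OhnologPair:
    """A validated L/S ohnolog pair with its shared outgroup ortholog."""

    l_gene: str
    s_gene: str
    outgroup_gene: str
    l_chrom: str = ""
    s_chrom: str = ""
    collinear: bool = False

    @property
    def pair_id(self) -> str:
        return f"{self.l_gene}|{self.s_gene}"


# --------------------------------------------------------------------------
# reciprocal best hits
# --------------------------------------------------------------------------


def _best_hits(hits: Iterable[HitRecord], evalue_max: float) -> dict[str, str]:
    """Best surviving subject per query.

    Hits with evalue >= evalue_max are discarded before selection.  Ties are
    broken deterministically: max bitscore, then min e-value, then
    lexicographically smallest subject_id.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue >= evalue_max:
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bitscore, h.evalue, h.subject_id)
        key_cur = (-cur.bitscore, cur.evalue, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def collapse_best_hsp(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Collapse multiple HSPs per (query, subject) to the best one.

    Keeps the record with maximal bitscore (min e-value, then input order as
    tie-breaks), yielding one record per (query, subject) pair.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (-h.bitscore, h.evalue) < (-cur.bitscore, cur.evalue):
            best[key] = h
    return list(best.values())


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    evalue_max: float = 1e-40,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between gene sets A and B.

    Returns pairs ``(a, b)`` where ``b`` is ``a``'s best surviving hit in
    ``hits_ab`` and ``a`` is ``b``'s best surviving hit in ``hits_ba``.  The
    E-value cutoff is applied before best-hit selection (strict ``<``), so a
    pair whose only link fails the cutoff is excluded.  Each gene appears in
    at most one returned pair.
    """
    if evalue_max <= 0:
        raise ValidationError(f"evalue_max must be > 0, got {evalue_max}")
    fwd = _best_hits(hits_ab, evalue_max)
    rev = _best_hits(hits_ba, evalue_max)
    out = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    out.sort()
    return out


# --------------------------------------------------------------------------
# homeologous chromosome map inference
# --------------------------------------------------------------------------


def infer_homeolog_map(
    rbh_pairs: Sequence[tuple[str, str]],
    gene_models: Mapping[str, GeneModel],
) -> HomeologMap:
    """Infer the L<->S homeologous chromosome bijection by majority vote.

    Each RBH pair casts a vote (L-gene's chromosome -> S-gene's chromosome).
    Votes are resolved greedily in decreasing count order into a bijection.
    A warning lists L-chromosomes whose winning share is below 0.5; an
    L-chromosome left without an available S-partner, or an exact vote tie
    competing for the same S-chromosome, raises an error instructing explicit
    map input.
    """
    votes: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for a, b in rbh_pairs:
        ga, gb = gene_models.get(a), gene_models.get(b)
        if ga is None or gb is None:
            missing = a if ga is None else b
            raise ValidationError(f"RBH gene {missing!r} absent from gene models")
        if ga.subgenome == "L" and gb.subgenome == "S":
            l, s = ga.chrom, gb.chrom
        elif ga.subgenome == "S" and gb.subgenome == "L":
            l, s = gb.chrom, ga.chrom
        else:
            continue
        votes[(l, s)] = votes.get((l, s), 0) + 1
        totals[l] = totals.get(l, 0) + 1

    edges = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    assigned_l: dict[str, str] = {}
    taken_s: dict[str, int] = {}  # S chrom -> vote count that claimed it
    for (l, s), n in edges:
        if l in assigned_l:
            continue
        if s in taken_s:
            if taken_s[s] == n:
                raise TieError(
                    f"L-chromosomes tie at {n} votes for S-chromosome {s!r}; "
                    "supply an explicit homeolog map"
                )
            continue
        assigned_l[l] = s
        taken_s[s] = n

    unassigned = sorted(set(totals) - set(assigned_l))
    if unassigned:
        raise ValidationError(
            f"L-chromosomes {unassigned} could not be assigned an S-partner; "
            "supply an explicit homeolog map"
        )
    low_share = [
        l for l, s in assigned_l.items() if votes[(l, s)] / totals[l] < 0.5
    ]
    if low_share:
        logger.warning(
            "homeolog map: top vote share < 0.5 for L-chromosomes %s",
            sorted(low_share),
        )
    return HomeologMap(pairs=assigned_l)


# --------------------------------------------------------------------------
# ohnolog pair calling
# --------------------------------------------------------------------------


def call_ohnolog_pairs(
    rbh_pairs: Sequence[tuple[str, str]],
    gene_models: Mapping[str, GeneModel],
    homeolog_map: HomeologMap,
    outgroup_rbh: Mapping[str, tuple[str, str]],
) -> list[OhnologPair]:
    """Filter RBH pairs down to validated ohnolog pairs.

    A pair is retained iff (a) its genes lie on a mapped homeologous
    chromosome pair, and (b) both genes have the SAME outgroup best hit and
    that outgroup gene lies on the chromosome recorded as orthologous to the
    pair's chromosomes.  ``outgroup_rbh`` maps each gene to
    ``(outgroup_gene, outgroup_chrom)``; genes absent from it fail (b).
    Output is sorted by (L-chromosome, L-gene start).
    """
    out: list[OhnologPair] = []
    ortho = homeolog_map.outgroup_orthology
    for a, b in rbh_pairs:
        ga, gb = gene_models.get(a), gene_models.get(b)
        if ga is None or gb is None:
            missing = a if ga is None else b
            raise ValidationError(f"gene {missing!r} in RBH pairs absent from gene models")
        if ga.subgenome == "L" and gb.subgenome == "S":
            gl, gs = ga, gb
        elif ga.subgenome == "S" and gb.subgenome == "L":
            gl, gs = gb, ga
        else:
            continue
        # condition (1): homeologous chromosome pair
        if homeolog_map.s_partner(gl.chrom) != gs.chrom:
            continue
        # condition (2): one shared outgroup ortholog on the orthologous chromosome
        hit_l = outgroup_rbh.get(gl.gene_id)
        hit_s = outgroup_rbh.get(gs.gene_id)
        if hit_l is None or hit_s is None:
            continue
        if hit_l[0] != hit_s[0]:
            continue
        og_gene, og_chrom = hit_l
        expect_l = ortho.get(gl.chrom)
        expect_s = ortho.get(gs.chrom)
        if expect_l is None or expect_l != og_chrom or expect_s != og_chrom:
            continue
        out.append(
            OhnologPair(
                l_gene=gl.gene_id,
                s_gene=gs.gene_id,
                outgroup_gene=og_gene,
                l_chrom=gl.chrom,
                s_chrom=gs.chrom,
            )
        )
    out.sort(key=lambda p: (p.l_chrom, gene_models[p.l_gene].start, p.l_gene))
    return out


# --------------------------------------------------------------------------
# collinearity
# --------------------------------------------------------------------------


def _chain_flags(s_ranks: Sequence[int], min_block: int, max_gap: int) -> list[bool]:
    """Flag pairs lying on a monotone gap-bounded chain of length >= min_block.

    Pairs are indexed in L order; ``s_ranks[i]`` is the rank of pair i's
    S-gene along the S-chromosome.  A chain is strictly monotone (increasing
    or decreasing) in S-rank, with at most ``max_gap`` intervening pairs
    between consecutive members on either chromosome.  A pair is flagged if
    the longest chain through it reaches ``min_block``.
    """
    n = len(s_ranks)
    flags = [False] * n
    for direction in (+1, -1):
        # fwd[i]: longest chain ending at i; bwd[i]: longest chain starting at i
        fwd = [1] * n
        bwd = [1] * n
        for i in range(n):
            for j in range(max(0, i - max_gap - 1), i):
                if (s_ranks[i] - s_ranks[j]) * direction <= 0:
                    continue
                if abs(s_ranks[i] - s_ranks[j]) - 1 > max_gap:
                    continue
                if fwd[j] + 1 > fwd[i]:
                    fwd[i] = fwd[j] + 1
        for i in range(n - 1, -1, -1):
            for j in range(i + 1, min(n, i + max_gap + 2)):
                if (s_ranks[j] - s_ranks[i]) * direction <= 0:
                    continue
                if abs(s_ranks[j] - s_ranks[i]) - 1 > max_gap:
                    continue
                if bwd[j] + 1 > bwd[i]:
                    bwd[i] = bwd[j] + 1
        for i in range(n):
            if fwd[i] + bwd[i] - 1 >= min_block:
                flags[i] = True
    return flags


def collinear_fraction(
    pairs: Sequence[OhnologPair],
    gene_models: Mapping[str, GeneModel],
    min_block: int = 5,
    max_gap: int = 25,
) -> tuple[float, list[bool]]:
    """Fraction of ohnolog pairs lying in collinear blocks.

    Within each homeologous chromosome pair, pairs are ordered by L-gene
    start; a collinear block is a chain of >= ``min_block`` pairs whose
    S-gene order is strictly monotone (either orientation, so inversions
    still count) with gaps of at most ``max_gap`` intervening pairs on
    either chromosome.  Returns the flagged fraction and per-pair flags in
    input order.
    """
    if min_block < 2:
        raise ValidationError(f"min_block must be >= 2, got {min_block}")
    if max_gap < 0:
        raise ValidationError(f"max_gap must be >= 0, got {max_gap}")
    if not pairs:
        raise ValidationError("collinear_fraction undefined for an empty pair list")

    by_chrompair: dict[tuple[str, str], list[int]] = {}
    for idx, p in enumerate(pairs):
        by_chrompair.setdefault((p.l_chrom, p.s_chrom), []).append(idx)

    flags = [False] * len(pairs)
    for idxs in by_chrompair.values():
        idxs_sorted = sorted(
            idxs, key=lambda i: (gene_models[pairs[i].l_gene].start, pairs[i].l_gene)
        )
        s_starts = [gene_models[pairs[i].s_gene].start for i in idxs_sorted]
        order = sorted(range(len(s_starts)), key=lambda k: s_starts[k])
        s_ranks = [0] * len(s_starts)
        for rank, k in enumerate(order):
            s_ranks[k] = rank
        for i, flag in zip(idxs_sorted, _chain_flags(s_ranks, min_block, max_gap)):
            flags[i] = flag
            pairs[i].collinear = flag
    return sum(flags) / len(pairs), flags
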