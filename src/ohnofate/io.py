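"""Readers and writers for the standard formats the pipeline consumes.

Coordinate conventions: GFF3 is 1-based inclusive on disk and converted to
the internal 0-based half-open convention at this boundary; BED and
fragments files are 0-based half-open and pass through unchanged.  Every
writer here produces files its paired reader parses back to equal
in-memory values.  Gzip-compressed text inputs are handled transparently
(by file suffix).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .ohnopair import GeneModel, HitRecord, OhnologPair
from .scatac import Fragment, MotifHit
from .scexpr import CellMatrix


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# BLAST outfmt-6 hit tables
# --------------------------------------------------------------------------

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column BLAST outfmt-6 TSV (columns 1, 2, 11, 12 consumed)."""
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 outfmt-6 columns, got {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except (ValueError, FormatError) as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
            records.append(rec)
    return records


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t100.0\t100\t0\t0\t1\t100\t1\t100\t"
                f"{h.evalue:g}\t{h.bitscore:g}\n"
            )


# --------------------------------------------------------------------------
# gene models
# --------------------------------------------------------------------------


def read_gff3(
    path: str | Path, subgenome_of: Mapping[str, str], feature: str = "gene"
) -> dict[str, GeneModel]:
    """Gene models from GFF3 (1-based inclusive -> 0-based half-open).

    The subgenome tag is assigned solely by chromosome membership in
    ``subgenome_of`` (the karyotype table); chromosomes absent from it get
    the tag "other".
    """
    out: dict[str, GeneModel] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != feature:
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            out[gene_id] = GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                subgenome=subgenome_of.get(chrom, "other"),
            )
    return out


def write_gff3(gene_models: Mapping[str, GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(gene_models.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tohnofate\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed_genes(path: str | Path, subgenome_of: Mapping[str, str]) -> dict[str, GeneModel]:
    """Gene models from BED6 (0-based half-open, name = gene id)."""
    out: dict[str, GeneModel] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            out[name] = GeneModel(
                gene_id=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                subgenome=subgenome_of.get(chrom, "other"),
            )
    return out


# --------------------------------------------------------------------------
# two-column chromosome tables
# --------------------------------------------------------------------------


def read_two_column_tsv(path: str | Path) -> dict[str, str]:
    """Generic 2-column TSV (key, value) -> dict, used for karyotype,
    homeology and chromosome-orthology tables."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out[fields[0]] = fields[1]
    return out


def write_two_column_tsv(mapping: Mapping[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]}\n")


def read_outgroup_hits(path: str | Path) -> dict[str, tuple[str, str]]:
    """3-column TSV (gene, outgroup_gene, outgroup_chrom) -> best-hit map."""
    out: dict[str, tuple[str, str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            out[fields[0]] = (fields[1], fields[2])
    return out


def write_outgroup_hits(mapping: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for gene in sorted(mapping):
            og, chrom = mapping[gene]
            fh.write(f"{gene}\t{og}\t{chrom}\n")


# --------------------------------------------------------------------------
# ohnolog pair tables
# --------------------------------------------------------------------------

PAIR_COLUMNS = ["l_gene", "s_gene", "outgroup_gene", "l_chrom", "s_chrom", "collinear"]


def write_pairs(pairs: Sequence[OhnologPair], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.l_gene}\t{p.s_gene}\t{p.outgroup_gene}\t{p.l_chrom}\t"
                f"{p.s_chrom}\t{int(p.collinear)}\n"
            )


def read_pairs(path: str | Path) -> list[OhnologPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing pair columns {sorted(missing)}")
    return [
        OhnologPair(
            l_gene=r.l_gene,
            s_gene=r.s_gene,
            outgroup_gene=r.outgroup_gene,
            l_chrom=r.l_chrom,
            s_chrom=r.s_chrom,
            collinear=bool(int(r.collinear)),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# count matrices
# --------------------------------------------------------------------------


def load_counts(
    path: str | Path,
    barcodes: str | Path | None = None,
    features: str | Path | None = None,
    labels: str | Path | None = None,
) -> CellMatrix:
    """Load a cells x genes count matrix.

    ``path`` is either a MatrixMarket .mtx (genes x cells on disk, the
    droplet convention, with ``barcodes``/``features`` TSVs) or a dense TSV
    (genes x cells with a header row of cell ids and gene ids in the first
    column).  ``labels`` optionally attaches a 2-column (barcode,
    cell_type) TSV.
    """
    path = Path(path)
    if path.suffix in (".mtx", ".gz") and ".mtx" in path.name:
        if barcodes is None or features is None:
            raise FormatError("MTX input requires barcodes and features files")
        with _open_text(path, "rb" if path.suffix == ".gz" else "r") as fh:
            mat = scipy.io.mmread(fh)
        cell_ids = [
            l.split("\t")[0].strip()
            for l in _open_text(barcodes).read().splitlines()
            if l.strip()
        ]
        gene_ids = [
            l.split("\t")[0].strip()
            for l in _open_text(features).read().splitlines()
            if l.strip()
        ]
        mat = sp.coo_matrix(mat)
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"MTX header {mat.shape} does not match {len(gene_ids)} features "
                f"x {len(cell_ids)} barcodes"
            )
        counts = np.asarray(mat.T.todense()).astype(np.int64)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        counts = df.to_numpy().T.astype(np.int64)

    cell_type = None
    if labels is not None:
        label_map = read_two_column_tsv(labels)
        cell_type = np.array([label_map.get(bc, "unknown") for bc in cell_ids], dtype=object)
    return CellMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, cell_type=cell_type)


def write_counts(matrix: CellMatrix, outdir: str | Path, prefix: str = "matrix") -> None:
    """Write the counts layer as an MTX triplet (genes x cells on disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts.T)
    scipy.io.mmwrite(str(outdir / f"{prefix}.mtx"), coo, field="integer")
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in matrix.cell_ids))
    (outdir / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    if matrix.cell_type is not None:
        with open(outdir / "labels.tsv", "w") as fh:
            for bc, ct in zip(matrix.cell_ids, matrix.cell_type):
                fh.write(f"{bc}\t{ct}\n")


# --------------------------------------------------------------------------
# fragments, FASTA, BED
# --------------------------------------------------------------------------


def read_fragments(path: str | Path) -> list[Fragment]:
    """5-column fragments TSV: chrom, start, end, barcode, count."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fragment columns")
            try:
                out.append(
                    Fragment(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        barcode=fields[3],
                        count=int(fields[4]),
                    )
                )
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return out


def write_fragments(fragments: Iterable[Fragment], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\t{f.count}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(sequences[name]), id=name, description="")
        for name in sorted(sequences)
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED3+ intervals (only the first three columns are consumed)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_motif_hits(hits: Sequence[MotifHit], path: str | Path, motif: str = "TAATCC") -> None:
    """Motif hits as BED: match interval in columns 2-3, analysis window in
    thickStart/thickEnd."""
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.position}\t{h.position + len(motif)}\t{motif}\t0\t"
                f"{h.strand}\t{h.window_start}\t{h.window_end}\n"
            )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
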