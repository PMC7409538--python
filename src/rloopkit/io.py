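"""Readers and writers for the standard text formats the pipeline consumes.

Genes can come in as GTF (gene/transcript/exon/CDS lines) or BED12; in both
cases only the longest transcript of each gene is kept.  BED and chrom-sizes
files are written 0-based half-open; GTF is written 1-based inclusive.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomeAssembly, GenomicInterval

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    names = tuple(df["chrom"].astype(str))
    lengths = dict(zip(names, df["length"].astype(int)))
    return GenomeAssembly(chrom_names=names, chrom_lengths=lengths)


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in assembly.chrom_names:
            fh.write(f"{chrom}\t{assembly.chrom_lengths[chrom]}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(assembly: GenomeAssembly, path: str | Path) -> None:
    if assembly.sequence is None:
        raise ValueError("assembly carries no sequence")
    records = [
        SeqRecord(Seq(assembly.sequence[chrom]), id=chrom, description="")
        for chrom in assembly.chrom_names
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> GenomeAssembly:
    names, lengths, seqs = [], {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
        lengths[rec.id] = len(rec.seq)
    return GenomeAssembly(chrom_names=tuple(names), chrom_lengths=lengths, sequence=seqs)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based inclusive), one transcript per gene."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            chrom = g.interval.chrom
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_biotype "{g.biotype}";'
            )
            rows = [
                (chrom, "rloopkit", "gene", g.interval.start + 1, g.interval.end, g.strand),
                (chrom, "rloopkit", "transcript", g.interval.start + 1, g.interval.end, g.strand),
            ]
            for s, e in g.exons:
                rows.append((chrom, "rloopkit", "exon", s + 1, e, g.strand))
            if g.cds is not None:
                cs, ce = g.cds
                for s, e in g.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ < oe:
                        rows.append((chrom, "rloopkit", "CDS", os_ + 1, oe, g.strand))
            for chrom_, src, feat, start1, end1, strand in rows:
                fh.write(
                    f"{chrom_}\t{src}\t{feat}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF, keeping the longest transcript per gene."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes",
        ],
        dtype={"chrom": str},
    )
    transcripts: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        attrs = dict(_ATTR_RE.findall(row.attributes))
        gene_id = attrs.get("gene_id")
        tx_id = attrs.get("transcript_id", f"{gene_id}.t1")
        if gene_id is None or row.feature not in ("exon", "CDS"):
            continue
        key = (gene_id, tx_id)
        rec = transcripts.setdefault(
            key,
            {
                "chrom": row.chrom,
                "strand": row.strand,
                "exons": [],
                "cds": [],
                "biotype": attrs.get("gene_biotype", "protein_coding"),
            },
        )
        if row.feature == "exon":
            rec["exons"].append((int(row.start) - 1, int(row.end)))
        else:
            rec["cds"].append((int(row.start) - 1, int(row.end)))

    best: dict[str, tuple[int, str, dict]] = {}
    for (gene_id, tx_id), rec in transcripts.items():
        span = sum(e - s for s, e in rec["exons"])
        cur = best.get(gene_id)
        # longest transcript wins; ties broken by transcript id
        if cur is None or (span, ) > (cur[0], ) or (span == cur[0] and tx_id < cur[1]):
            best[gene_id] = (span, tx_id, rec)

    genes = []
    for gene_id, (_, _, rec) in best.items():
        exons = sorted(rec["exons"])
        start, end = exons[0][0], exons[-1][1]
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(rec["chrom"], start, end, rec["strand"]),
                exons=tuple(exons),
                biotype=rec["biotype"],
                cds=cds,
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            if g.cds is not None:
                thick_s, thick_e = g.cds
            else:
                thick_s = thick_e = iv.start
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offsets = ",".join(str(s - iv.start) for s, _ in g.exons) + ","
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            iv.chrom, iv.start, iv.end, g.gene_id, 0, g.strand,
                            thick_s, thick_e, "0,0,0", len(g.exons), sizes, offsets,
                        ],
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            cds = (thick_s, thick_e) if thick_e > thick_s else None
            biotype = "protein_coding" if cds is not None else "noncoding"
            genes.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    biotype=biotype,
                    cds=cds,
                )
            )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def write_feature_map_bed(fmap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, category in fmap.to_bed_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{category}\n")
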