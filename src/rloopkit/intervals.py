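"""Genomic coordinate primitives shared by every stage of the pipeline.

Coordinates are 0-based half-open throughout (BED convention).  The module
provides the assembly / interval / gene-model types, interval arithmetic
(merging, distances, nearest-gene ranking) and the per-base feature-category
partition ("feature map") used to classify peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Feature categories in priority order (lower index wins on overlap).
CATEGORIES: tuple[str, ...] = (
    "promoter-TSS",
    "TTS",
    "5UTR",
    "3UTR",
    "exon",
    "intron",
    "noncoding",
    "intergenic",
)
CATEGORY_CODE: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES)}

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base; even-length intervals use start + length // 2."""
        return self.start + (self.end - self.start) // 2


@dataclass
class GenomeAssembly:
    """Ordered chromosome set with lengths and optional sequence."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.chrom_names = tuple(self.chrom_names)
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if set(self.chrom_names) != set(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths disagree")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.sequence is not None:
            for name, seq in self.sequence.items():
                if len(seq) != self.chrom_lengths[name]:
                    raise ValueError(
                        f"sequence length for {name} ({len(seq)}) does not "
                        f"match chrom_length ({self.chrom_lengths[name]})"
                    )

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def contains(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.chrom_lengths and iv.end <= self.chrom_lengths[iv.chrom]


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model (the longest transcript of a gene).

    ``exons`` are (start, end) pairs, sorted and non-overlapping, inside the
    gene body.  ``cds`` bounds, when present, split exonic bases into
    5'UTR / exon / 3'UTR.  Genes with biotype other than ``protein_coding``
    are treated as noncoding in the feature map.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = self.interval.start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint "
                    "and inside the gene body"
                )
            prev_end = e

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start base (5' end by strand)."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination base (3' end by strand)."""
        if self.strand == "+":
            return self.interval.end - 1
        return self.interval.start

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons[:-1], self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class FeatureMap:
    """Per-base partition of the genome into feature categories.

    Every base belongs to exactly one category; codes index ``CATEGORIES``.
    """

    assembly: GenomeAssembly
    codes: dict[str, np.ndarray]

    def category_at(self, chrom: str, pos: int) -> str:
        return CATEGORIES[int(self.codes[chrom][pos])]

    def bp_totals(self) -> dict[str, int]:
        totals = {c: 0 for c in CATEGORIES}
        for arr in self.codes.values():
            counts = np.bincount(arr, minlength=len(CATEGORIES))
            for i, c in enumerate(CATEGORIES):
                totals[c] += int(counts[i])
        return totals

    def to_bed_records(self) -> list[tuple[str, int, int, str]]:
        """Run-length encode the map as (chrom, start, end, category)."""
        records = []
        for chrom in self.assembly.chrom_names:
            arr = self.codes[chrom]
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                records.append((chrom, int(s), int(e), CATEGORIES[int(arr[s])]))
        return records


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap (next.start - prev.end) is <= max_gap.

    Returns a sorted, disjoint list.  Strand is dropped ('.').
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[list] = []
    for iv in ordered:
        if merged and merged[-1][0] == iv.chrom and iv.start - merged[-1][2] <= max_gap:
            merged[-1][2] = max(merged[-1][2], iv.end)
        else:
            merged.append([iv.chrom, iv.start, iv.end])
    return [GenomicInterval(c, s, e) for c, s, e in merged]


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if they overlap.

    Returns None (undefined) when the intervals sit on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if b.start >= a.end:
        return b.start - a.end
    return a.start - b.end


def nearest_genes(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    mode: str = "endpoint",
) -> list[tuple[str, int]]:
    """Rank genes by distance to the peak; rank 1 = nearest, rank 2 = neighbor.

    ``endpoint`` mode measures min(|midpoint - tss|, |midpoint - tts|);
    ``interval`` mode measures the bp gap to the gene body (0 on overlap).
    Genes on other chromosomes are excluded.  Ties break on
    (gene start, gene_id) so output is deterministic.
    """
    if mode not in ("endpoint", "interval"):
        raise ValueError(f"unknown mode {mode!r}")
    mid = peak.midpoint
    scored = []
    for g in genes:
        if g.interval.chrom != peak.chrom:
            continue
        if mode == "endpoint":
            d = min(abs(mid - g.tss), abs(mid - g.tts))
        else:
            d = interval_distance(peak, g.interval)
        scored.append((d, g.interval.start, g.gene_id))
    scored.sort()
    return [(gid, d) for d, _, gid in scored]


def tss_tts_side(peak: GenomicInterval, gene: GeneModel) -> tuple[str, int]:
    """Which gene end (TSS or TTS) the peak midpoint is nearer to.

    Ties go to TSS.  Cross-chromosome comparison is an error.
    """
    if gene.interval.chrom != peak.chrom:
        raise ValueError(
            f"peak on {peak.chrom} cannot be compared with gene "
            f"{gene.gene_id} on {gene.interval.chrom}"
        )
    mid = peak.midpoint
    d_tss = abs(mid - gene.tss)
    d_tts = abs(mid - gene.tts)
    if d_tss <= d_tts:
        return ("TSS", d_tss)
    return ("TTS", d_tts)


# ---------------------------------------------------------------------------
# feature map construction
# ---------------------------------------------------------------------------

def build_feature_map(
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    promoter_up: int = 1000,
    promoter_down: int = 100,
    tts_up: int = 100,
    tts_down: int = 1000,
) -> FeatureMap:
    """Partition every base into one category.

    Priority on overlap: promoter-TSS > TTS > 5'UTR > 3'UTR > exon > intron
    > noncoding > intergenic.  Windows are strand-aware: the promoter spans
    promoter_up bases upstream and promoter_down downstream of the TSS, the
    TTS window tts_up upstream and tts_down downstream of the TTS.
    """
    codes = {
        chrom: np.full(length, CATEGORY_CODE["intergenic"], dtype=np.uint8)
        for chrom, length in assembly.chrom_lengths.items()
    }
    for g in genes:
        if g.interval.chrom not in assembly.chrom_lengths or not assembly.contains(
            g.interval
        ):
            raise ValueError(f"gene {g.gene_id} lies outside the assembly")

    def paint(chrom: str, start: int, end: int, category: str) -> None:
        length = assembly.chrom_lengths[chrom]
        s, e = max(0, start), min(length, end)
        if s < e:
            codes[chrom][s:e] = CATEGORY_CODE[category]

    coding = [g for g in genes if g.biotype == "protein_coding"]
    noncoding = [g for g in genes if g.biotype != "protein_coding"]

    # painted in reverse priority order so higher priority overwrites
    for g in noncoding:
        paint(g.interval.chrom, g.interval.start, g.interval.end, "noncoding")
    for g in coding:
        paint(g.interval.chrom, g.interval.start, g.interval.end, "intron")
    for g in coding:
        chrom = g.interval.chrom
        for s, e in g.exons:
            paint(chrom, s, e, "exon")
        if g.cds is not None:
            cs, ce = g.cds
            for s, e in g.exons:
                # 3'UTR first, then 5'UTR (5' has higher priority)
                if g.strand == "+":
                    if e > ce:
                        paint(chrom, max(s, ce), e, "3UTR")
                else:
                    if s < cs:
                        paint(chrom, s, min(e, cs), "3UTR")
            for s, e in g.exons:
                if g.strand == "+":
                    if s < cs:
                        paint(chrom, s, min(e, cs), "5UTR")
                else:
                    if e > ce:
                        paint(chrom, max(s, ce), e, "5UTR")
    for g in genes:
        chrom = g.interval.chrom
        if g.strand == "+":
            paint(chrom, g.tts - tts_up, g.tts + tts_down, "TTS")
        else:
            paint(chrom, g.tts - tts_down + 1, g.tts + tts_up + 1, "TTS")
    for g in genes:
        chrom = g.interval.chrom
        if g.strand == "+":
            paint(chrom, g.tss - promoter_up, g.tss + promoter_down, "promoter-TSS")
        else:
            paint(chrom, g.tss - promoter_down + 1, g.tss + promoter_up + 1, "promoter-TSS")
    return FeatureMap(assembly=assembly, codes=codes)


def assign_feature(peak: GenomicInterval, fmap: FeatureMap) -> str:
    """Category of the peak midpoint base."""
    return fmap.category_at(peak.chrom, peak.midpoint)


def complement_intervals(
    intervals: Sequence[GenomicInterval], assembly: GenomeAssembly
) -> list[GenomicInterval]:
    """Sorted, disjoint complement of the merged input over the assembly."""
    merged = merge_intervals(list(intervals), max_gap=0)
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in assembly.chrom_names}
    for iv in merged:
        by_chrom[iv.chrom].append(iv)
    out = []
    for chrom in assembly.chrom_names:
        length = assembly.chrom_lengths[chrom]
        cursor = 0
        for iv in by_chrom[chrom]:
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return out


def subtract_intervals(
    iv: GenomicInterval, blockers: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Pieces of ``iv`` not covered by any blocker (same chromosome only)."""
    pieces = [(iv.start, iv.end)]
    for b in sorted(
        (b for b in blockers if b.chrom == iv.chrom), key=lambda x: x.start
    ):
        nxt = []
        for s, e in pieces:
            if b.end <= s or b.start >= e:
                nxt.append((s, e))
                continue
            if b.start > s:
                nxt.append((s, b.start))
            if b.end < e:
                nxt.append((b.end, e))
        pieces = nxt
    return [GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in pieces]
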