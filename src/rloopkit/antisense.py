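"""Intergenic antisense-transcription calling near R-loop gain peaks.

For every gene anchoring a gain peak, a 5-kb flank window (and its 2-kb
sub-window adjacent to the gene end) is placed upstream of the TSS and
downstream of the TTS, restricted to intergenic space.  Stranded RNA-seq
reads falling in those windows are tested for differential signal, and
hits must pass four thresholds: positive adjacent-window log2FC, nearest
gene log2FC below 2, associated peak log2FC above 1, and peak FDR below
0.1.  Strand purity of the window reads then classifies the transcript as
antisense or sense read-through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import (
    ContrastSpec,
    CountMatrix,
    count_reads_in_intervals,
    estimate_dispersion,
    wald_test,
)
from .intervals import (
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    complement_intervals,
    interval_distance,
    merge_intervals,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

ORIENTATION_PURITY = 0.75


def intergenic_mask(
    assembly: GenomeAssembly, genes: Sequence[GeneModel]
) -> list[GenomicInterval]:
    """Sorted, disjoint complement of the union of gene bodies."""
    return complement_intervals([g.interval for g in genes], assembly)


@dataclass
class FlankWindow:
    """Intergenic-restricted flank window beside one gene end.

    full_pieces / adjacent_pieces are the intergenic fragments of the raw
    5-kb and 2-kb windows; peak_ids are the gain peaks within 5 kb.
    """

    gene_id: str
    gene_strand: str
    side: str  # TSS-upstream or TTS-downstream
    full_window: GenomicInterval
    adjacent_window: GenomicInterval
    full_pieces: list
    adjacent_pieces: list
    peak_ids: list = field(default_factory=list)

    @property
    def uid(self) -> str:
        return f"{self.gene_id}|{self.side}"

    @property
    def masked_length(self) -> int:
        return sum(p.length for p in self.adjacent_pieces)


def _raw_windows(
    gene: GeneModel, assembly: GenomeAssembly, full: int, adjacent: int
) -> dict[str, tuple[GenomicInterval, GenomicInterval] | None]:
    """Unmasked (full, adjacent) windows for both sides, clipped to bounds."""
    chrom = gene.interval.chrom
    L = assembly.chrom_lengths[chrom]

    def clip(s: int, e: int) -> GenomicInterval | None:
        s, e = max(0, s), min(L, e)
        if s >= e:
            return None
        return GenomicInterval(chrom, s, e)

    out: dict = {}
    if gene.strand == "+":
        tss_full = clip(gene.tss - full, gene.tss)
        tss_adj = clip(gene.tss - adjacent, gene.tss)
        tts_full = clip(gene.tts + 1, gene.tts + 1 + full)
        tts_adj = clip(gene.tts + 1, gene.tts + 1 + adjacent)
    else:
        tss_full = clip(gene.tss + 1, gene.tss + 1 + full)
        tss_adj = clip(gene.tss + 1, gene.tss + 1 + adjacent)
        tts_full = clip(gene.tts - full, gene.tts)
        tts_adj = clip(gene.tts - adjacent, gene.tts)
    out["TSS-upstream"] = None if tss_full is None or tss_adj is None else (tss_full, tss_adj)
    out["TTS-downstream"] = None if tts_full is None or tts_adj is None else (tts_full, tts_adj)
    return out


def make_flank_windows(
    annot: pd.DataFrame,
    gain_peak_ids: Sequence[str],
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    full: int = 5000,
    adjacent: int = 2000,
    min_masked: int = 200,
    max_peak_distance: int = 5000,
) -> list[FlankWindow]:
    """TSS-upstream and TTS-downstream windows for each distinct nearest
    gene of the gain peaks, intersected with the intergenic mask.

    Windows whose masked adjacent length falls below min_masked are
    dropped; each retained window records the gain peaks within
    max_peak_distance bp.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    bodies = merge_intervals([g.interval for g in genes])
    gain_set = set(gain_peak_ids)
    sub = annot[annot["peak_id"].isin(gain_set)]
    peak_iv = {
        r.peak_id: GenomicInterval(r.chrom, r.start, r.end)
        for r in sub.itertuples(index=False)
    }
    implicated = sorted(set(sub["nearest_gene"].dropna()))

    windows: list[FlankWindow] = []
    for gene_id in implicated:
        gene = gene_by_id[gene_id]
        for side, pair in _raw_windows(gene, assembly, full, adjacent).items():
            if pair is None:
                continue
            full_iv, adj_iv = pair
            full_pieces = subtract_intervals(full_iv, bodies)
            adj_pieces = subtract_intervals(adj_iv, bodies)
            if sum(p.length for p in adj_pieces) < min_masked:
                continue
            near = [
                pid
                for pid, iv in peak_iv.items()
                if (d := interval_distance(full_iv, iv)) is not None
                and d <= max_peak_distance
            ]
            if not near:
                continue
            windows.append(
                FlankWindow(
                    gene_id=gene_id,
                    gene_strand=gene.strand,
                    side=side,
                    full_window=full_iv,
                    adjacent_window=adj_iv,
                    full_pieces=full_pieces,
                    adjacent_pieces=adj_pieces,
                    peak_ids=sorted(near),
                )
            )
    windows.sort(key=lambda w: (w.full_window.chrom, w.full_window.start, w.side))
    return windows


def intergenic_diff(
    windows: Sequence[FlankWindow],
    rna_readsets: Sequence,
    contrast: ContrastSpec,
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    gene_size_factors: np.ndarray,
) -> pd.DataFrame:
    """Counts and log2FC for the full and adjacent windows of each gene side.

    Intergenic reads only; size factors are the gene-level factors (windows
    are too few and signal-biased for self-normalization).  Also reports
    the fraction of pooled treatment-condition adjacent-window reads on the
    strand opposite the gene.
    """
    for rs in rna_readsets:
        if rs.library_size and np.any(np.asarray(rs.strands) == "."):
            raise ValueError("stranded RNA-seq reads required (strand '.' seen)")
    gene_bodies = merge_intervals([g.interval for g in genes])
    from .landscape import _overlap_mask

    inter = [rs.subset(~_overlap_mask(rs, gene_bodies)) for rs in rna_readsets]

    def window_counts(pieces_of: str) -> CountMatrix:
        cols = []
        for rs in inter:
            col = np.zeros(len(windows), dtype=np.int64)
            for i, w in enumerate(windows):
                pieces = getattr(w, pieces_of)
                col[i] = int(count_reads_in_intervals(pieces, rs).sum())
            cols.append(col)
        counts = (
            np.column_stack(cols) if cols else np.zeros((len(windows), 0), int)
        )
        return CountMatrix(
            counts=counts,
            feature_ids=[w.uid for w in windows],
            sample_ids=[rs.sample_id for rs in rna_readsets],
            conditions=[rs.condition for rs in rna_readsets],
            size_factors=np.asarray(gene_size_factors, dtype=float),
        )

    cm_full = window_counts("full_pieces")
    cm_adj = window_counts("adjacent_pieces")

    alpha_full = estimate_dispersion(cm_full)
    alpha_adj = estimate_dispersion(cm_adj)
    res_full = wald_test(cm_full, contrast, alpha_full).set_index("id")
    res_adj = wald_test(cm_adj, contrast, alpha_adj).set_index("id")

    t_cols = cm_adj.condition_columns(contrast.treatment)
    q_adj = cm_adj.normalized()
    mean_kd_adj = q_adj[:, t_cols].mean(axis=1)

    # pooled treatment reads in the adjacent window, split by strand
    frac = np.full(len(windows), np.nan)
    n_reads = np.zeros(len(windows), dtype=np.int64)
    kd_sets = [rs for rs in inter if rs.condition == contrast.treatment]
    for i, w in enumerate(windows):
        opp = tot = 0
        for rs in kd_sets:
            for piece in w.adjacent_pieces:
                sel = (
                    (rs.chroms == piece.chrom)
                    & (rs.starts < piece.end)
                    & (rs.ends > piece.start)
                )
                tot += int(sel.sum())
                opp += int(np.sum(rs.strands[sel] != w.gene_strand))
        n_reads[i] = tot
        if tot > 0:
            frac[i] = opp / tot

    rows = []
    for i, w in enumerate(windows):
        rows.append(
            {
                "window_id": w.uid,
                "gene_id": w.gene_id,
                "side": w.side,
                "chrom": w.full_window.chrom,
                "full_start": w.full_window.start,
                "full_end": w.full_window.end,
                "masked_adjacent_bp": w.masked_length,
                "peak_ids": ",".join(w.peak_ids),
                "full_log2fc": res_full.loc[w.uid, "log2fc"],
                "full_p": res_full.loc[w.uid, "p"],
                "adj_log2fc": res_adj.loc[w.uid, "log2fc"],
                "adj_p": res_adj.loc[w.uid, "p"],
                "mean_kd_adj_count": mean_kd_adj[i],
                "adj_reads_kd": int(n_reads[i]),
                "antisense_read_fraction": frac[i],
            }
        )
    return pd.DataFrame(rows)


def orient_transcription(
    side: str, antisense_read_fraction: float, n_reads: int
) -> str:
    """Orientation class from strand purity of the window reads.

    TSS-upstream windows call 'antisense' when >= 75% of reads oppose the
    gene strand; TTS-downstream windows call 'sense-readthrough' when
    >= 75% match it; anything else (including empty windows) is ambiguous.
    """
    if n_reads == 0 or np.isnan(antisense_read_fraction):
        logger.warning("window with zero reads; orientation ambiguous")
        return "ambiguous"
    if side == "TSS-upstream" and antisense_read_fraction >= ORIENTATION_PURITY:
        return "antisense"
    if side == "TTS-downstream" and (1.0 - antisense_read_fraction) >= ORIENTATION_PURITY:
        return "sense-readthrough"
    return "ambiguous"


def call_antisense_hits(
    window_diff: pd.DataFrame,
    peak_result: pd.DataFrame,
    gene_result: pd.DataFrame,
    contrast: ContrastSpec,
    min_mean: float = 5.0,
    strict_gene_filter: bool = False,
) -> pd.DataFrame:
    """Apply the four hit thresholds and orient each hit.

    (1) adjacent-window log2FC > 0; (2) nearest-gene log2FC < 2 (strict
    mode instead requires the gene not significantly up-regulated);
    (3) peak log2FC > 1; (4) peak FDR < 0.1.  An extra guard requires a
    mean normalized treatment-window count >= min_mean.  One hit per
    (peak, gene, side), ordered deterministically.
    """
    peaks = peak_result.set_index("id")
    genes_r = gene_result.set_index("id")
    hits = []
    for row in window_diff.itertuples(index=False):
        if not row.adj_log2fc > 0:  # threshold (1)
            continue
        if row.mean_kd_adj_count < min_mean:
            continue
        if row.gene_id in genes_r.index:
            g_lfc = float(genes_r.loc[row.gene_id, "log2fc"])
            g_q = float(genes_r.loc[row.gene_id, "q"])
        else:
            g_lfc, g_q = 0.0, 1.0
        if strict_gene_filter:
            if g_lfc > 1.0 and g_q < 0.05:  # "not up-regulated"
                continue
        elif not g_lfc < 2.0:  # threshold (2)
            continue
        for pid in str(row.peak_ids).split(","):
            if not pid or pid not in peaks.index:
                continue
            p_lfc = float(peaks.loc[pid, "log2fc"])
            p_q = float(peaks.loc[pid, "q"])
            if not p_lfc > 1.0:  # threshold (3)
                continue
            if not p_q < 0.1:  # threshold (4)
                continue
            orientation = orient_transcription(
                row.side, row.antisense_read_fraction, row.adj_reads_kd
            )
            hits.append(
                {
                    "peak_id": pid,
                    "gene_id": row.gene_id,
                    "side": row.side,
                    "contrast": contrast.name,
                    "window_log2fc": row.full_log2fc,
                    "adj_log2fc": row.adj_log2fc,
                    "gene_log2fc": g_lfc,
                    "peak_log2fc": p_lfc,
                    "peak_q": p_q,
                    "mean_kd_adj_count": row.mean_kd_adj_count,
                    "antisense_read_fraction": row.antisense_read_fraction,
                    "orientation": orientation,
                }
            )
    df = pd.DataFrame(
        hits,
        columns=[
            "peak_id", "gene_id", "side", "contrast", "window_log2fc",
            "adj_log2fc", "gene_log2fc", "peak_log2fc", "peak_q",
            "mean_kd_adj_count", "antisense_read_fraction", "orientation",
        ],
    )
    return df.sort_values(["gene_id", "side", "peak_id"]).reset_index(drop=True)
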