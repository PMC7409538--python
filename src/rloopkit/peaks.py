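"""Broad enrichment peak calling versus input and consensus construction.

The caller tiles the genome into fixed bins, scores each bin's IP read
count against a Poisson expectation derived from the input (max of the
genome-wide rate and a local-window rate, scaled by library-size ratio),
converts p-values to q-values by Benjamini-Hochberg over all non-empty
bins, merges significant bins, and drops short peaks.  It is a
deterministic, fully specified stand-in for broad-mode callers used on
real DRIP data; downstream stages depend only on the resulting intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .differential import bh_fdr, count_reads_in_intervals
from .intervals import GenomeAssembly, GenomicInterval, merge_intervals
from .simulate import ReadSet


@dataclass
class PeakCall:
    interval: GenomicInterval
    sample_id: str
    summit: int
    fold_enrichment: float
    qvalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError("qvalue outside [0, 1]")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside peak interval")


@dataclass
class ConsensusPeakSet:
    """Sorted, disjoint consensus peaks with per-peak sample support."""

    peaks: list  # of GenomicInterval
    ids: list  # of str, coordinate order
    support: dict  # id -> frozenset of sample ids
    rnaseh_ratio: dict = field(default_factory=dict)  # id -> float
    hybrid: dict = field(default_factory=dict)  # id -> bool

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals_by_id(self) -> dict:
        return dict(zip(self.ids, self.peaks))

    def total_bp(self) -> int:
        return sum(p.length for p in self.peaks)


def _bin_counts(rs: ReadSet, chrom: str, nbins: int, bin_size: int) -> np.ndarray:
    mask = rs.chroms == chrom
    idx = rs.starts[mask] // bin_size
    idx = np.clip(idx, 0, nbins - 1)
    return np.bincount(idx, minlength=nbins).astype(np.int64)


def call_broad_peaks(
    ip: ReadSet,
    input_rs: ReadSet,
    assembly: GenomeAssembly,
    bin_size: int = 100,
    q_cut: float = 0.1,
    merge_gap: int = 500,
    min_length: int = 200,
    local_bg: int = 5000,
) -> list[PeakCall]:
    """Call broad peaks on one IP sample relative to the input sample."""
    if input_rs.library_size == 0:
        raise ValueError("input library is empty; cannot scale expectations")
    ratio = ip.library_size / input_rs.library_size

    total_bins = sum(
        -(-length // bin_size) for length in assembly.chrom_lengths.values()
    )
    global_rate = input_rs.library_size / total_bins  # input reads per bin

    window_bins = max(local_bg // bin_size, 1)
    per_chrom: dict[str, dict] = {}
    all_p, owners = [], []
    for chrom in assembly.chrom_names:
        length = assembly.chrom_lengths[chrom]
        nbins = -(-length // bin_size)
        k_ip = _bin_counts(ip, chrom, nbins, bin_size)
        k_in = _bin_counts(input_rs, chrom, nbins, bin_size)
        # centered moving average of the input over the local window
        kernel_half = window_bins // 2
        csum = np.concatenate(([0], np.cumsum(k_in)))
        lo = np.maximum(np.arange(nbins) - kernel_half, 0)
        hi = np.minimum(np.arange(nbins) + kernel_half + 1, nbins)
        local_rate = (csum[hi] - csum[lo]) / (hi - lo)
        lam = np.maximum(global_rate, local_rate) * ratio
        nz = np.flatnonzero(k_ip > 0)
        pvals = stats.poisson.sf(k_ip[nz] - 1, lam[nz])
        per_chrom[chrom] = {"k_ip": k_ip, "lam": lam, "nbins": nbins}
        all_p.append(pvals)
        owners.append((chrom, nz))

    if not all_p or sum(len(p) for p in all_p) == 0:
        return []
    qvals = bh_fdr(np.concatenate(all_p))
    offset = 0
    sig_bins: list[GenomicInterval] = []
    qmap: dict[tuple[str, int], float] = {}
    for chrom, nz in owners:
        n = len(nz)
        q = qvals[offset: offset + n]
        offset += n
        keep = nz[q < q_cut]
        for b, qv in zip(nz, q):
            qmap[(chrom, int(b))] = float(qv)
        length = assembly.chrom_lengths[chrom]
        for b in keep:
            sig_bins.append(
                GenomicInterval(
                    chrom, int(b) * bin_size, min((int(b) + 1) * bin_size, length)
                )
            )

    peaks: list[PeakCall] = []
    for iv in merge_intervals(sig_bins, max_gap=merge_gap):
        if iv.length < min_length:
            continue
        chrom = iv.chrom
        k_ip = per_chrom[chrom]["k_ip"]
        lam = per_chrom[chrom]["lam"]
        b0, b1 = iv.start // bin_size, -(-iv.end // bin_size)
        counts = k_ip[b0:b1]
        summit_bin = b0 + int(np.argmax(counts))
        summit = min(summit_bin * bin_size + bin_size // 2, iv.end - 1)
        ip_count = int(counts.sum())
        expect = float(lam[b0:b1].sum())
        fold = (ip_count + 1.0) / (expect + 1.0)
        qvalue = min(
            (qmap.get((chrom, b), 1.0) for b in range(b0, b1)), default=1.0
        )
        peaks.append(
            PeakCall(
                interval=iv, sample_id=ip.sample_id, summit=summit,
                fold_enrichment=fold, qvalue=qvalue,
            )
        )
    return peaks


def rnaseh_sensitivity(
    peaks: Sequence[GenomicInterval],
    ids: Sequence[str],
    ip: ReadSet,
    rnaseh: ReadSet,
    threshold: float = 0.5,
) -> tuple[dict, dict]:
    """Per-peak RNase-H / IP library-normalized signal ratio + hybrid flag.

    ratio < threshold means the signal is RNase-H sensitive, i.e. a genuine
    DNA/RNA hybrid.  Counts are guarded with a pseudocount of one read.
    """
    ip_counts = count_reads_in_intervals(peaks, ip)
    rh_counts = count_reads_in_intervals(peaks, rnaseh)
    ip_lib = max(ip.library_size, 1)
    rh_lib = max(rnaseh.library_size, 1)
    ratios, flags = {}, {}
    for pid, ipc, rhc in zip(ids, ip_counts, rh_counts):
        ratio = ((rhc + 1.0) / rh_lib) / ((ipc + 1.0) / ip_lib)
        ratios[pid] = float(ratio)
        flags[pid] = bool(ratio < threshold)
    return ratios, flags


def build_consensus(
    peak_lists: Mapping[str, Sequence[PeakCall]],
    min_support: int = 1,
) -> ConsensusPeakSet:
    """Union of per-sample peak intervals merged with gap 0.

    Support = samples whose peaks overlap the merged interval by >= 1 bp;
    merged peaks with support below min_support are removed.  Ids are
    assigned in coordinate order, so they are stable across reruns.
    """
    if not peak_lists:
        raise ValueError("need at least one sample")
    all_ivs = [pc.interval for pcs in peak_lists.values() for pc in pcs]
    merged = merge_intervals(all_ivs, max_gap=0)

    support: list[set] = [set() for _ in merged]
    for sample, pcs in peak_lists.items():
        for pc in pcs:
            for i, m in enumerate(merged):
                if (
                    m.chrom == pc.interval.chrom
                    and m.start < pc.interval.end
                    and pc.interval.start < m.end
                ):
                    support[i].add(sample)
    kept = [
        (m, frozenset(s)) for m, s in zip(merged, support) if len(s) >= min_support
    ]
    width = max(5, len(str(len(kept))))
    peaks = [m for m, _ in kept]
    ids = [f"peak_{i + 1:0{width}d}" for i in range(len(kept))]
    return ConsensusPeakSet(
        peaks=peaks, ids=ids, support={i: s for i, (_, s) in zip(ids, kept)}
    )
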