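"""Genome-landscape statistics over classified consensus peaks.

Covers peak annotation (nearest / second-nearest gene, feature category,
TSS-vs-TTS side), feature-category distributions, neighbor-distance tests,
per-chromosome gain/loss density ratios, hypergeometric overlap tests,
GC/CpG and positional nucleotide profiles, metagene coverage, and sample
QC (correlation + PCA).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import CountMatrix
from .intervals import (
    CATEGORIES,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    assign_feature,
    merge_intervals,
    nearest_genes,
    tss_tts_side,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# peak annotation
# ---------------------------------------------------------------------------

def annotate_peaks(
    consensus, genes: Sequence[GeneModel], fmap
) -> pd.DataFrame:
    """One row per consensus peak with gene context and feature category.

    Nearest/neighbor use the endpoint definition (distance to the closest
    TSS or TTS of the gene); neighbor_dist_interval additionally records
    the rank-2 gene-body gap used by the distance analyses.
    """
    rows = []
    for pid, iv in zip(consensus.ids, consensus.peaks):
        ranked_ep = nearest_genes(iv, genes, mode="endpoint")
        ranked_iv = nearest_genes(iv, genes, mode="interval")
        nearest = ranked_ep[0] if ranked_ep else (None, None)
        neighbor = ranked_ep[1] if len(ranked_ep) > 1 else (None, None)
        neighbor_iv = ranked_iv[1] if len(ranked_iv) > 1 else (None, None)
        side, side_dist = (None, None)
        if nearest[0] is not None:
            gene = next(g for g in genes if g.gene_id == nearest[0])
            side, side_dist = tss_tts_side(iv, gene)
        rows.append(
            {
                "peak_id": pid,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "nearest_gene": nearest[0],
                "nearest_dist": nearest[1],
                "neighbor_gene": neighbor[0],
                "neighbor_dist": neighbor[1],
                "neighbor_dist_interval": neighbor_iv[1],
                "feature_category": assign_feature(iv, fmap),
                "nearer_end": side,
                "end_dist": side_dist,
            }
        )
    return pd.DataFrame(rows)


def feature_distribution(categories: Sequence[str]) -> pd.Series:
    """Percentage of peaks per feature category (sums to 100)."""
    if len(categories) == 0:
        warnings.warn("empty peak subset; feature distribution undefined")
        return pd.Series(dtype=float)
    counts = pd.Series(categories).value_counts()
    pct = counts.reindex(CATEGORIES, fill_value=0).astype(float)
    return 100.0 * pct / pct.sum()


# ---------------------------------------------------------------------------
# distances and chromosome ratios
# ---------------------------------------------------------------------------

def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t statistic and p (Welch-Satterthwaite df)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def distance_tests(
    annot: pd.DataFrame, classes: Mapping[str, str]
) -> dict:
    """Welch tests of neighbor-gene distance: gain vs unchanged, loss vs
    unchanged.  Distances are the interval-mode rank-2 gaps."""
    df = annot.copy()
    df["class"] = df["peak_id"].map(classes)
    out: dict = {"samples": {}}
    samples = {}
    for cls in ("gain", "loss", "unchanged"):
        vals = df.loc[df["class"] == cls, "neighbor_dist_interval"].dropna()
        samples[cls] = vals.to_numpy(dtype=float)
        out["samples"][cls] = samples[cls]
    for cls in ("gain", "loss"):
        if len(samples[cls]) < 2 or len(samples["unchanged"]) < 2:
            warnings.warn(f"fewer than 2 peaks in class {cls} or unchanged; skipped")
            continue
        t, p = welch_t(samples[cls], samples["unchanged"])
        out[f"{cls}_vs_unchanged"] = {"t": t, "p": p}
    return out


def chromosome_density_ratio(
    annot: pd.DataFrame, classes: Mapping[str, str], assembly: GenomeAssembly
) -> pd.DataFrame:
    """Per chromosome: gain/unchanged and loss/unchanged peak-count ratios
    plus the mean neighbor distance over all consensus peaks there.

    0/0 ratios are reported as NaN (undefined)."""
    df = annot.copy()
    df["class"] = df["peak_id"].map(classes)
    rows = []
    for chrom in assembly.chrom_names:
        sub = df[df["chrom"] == chrom]
        n_gain = int((sub["class"] == "gain").sum())
        n_loss = int((sub["class"] == "loss").sum())
        n_unch = int((sub["class"] == "unchanged").sum())
        gain_ratio = n_gain / n_unch if n_unch else (np.nan if n_gain == 0 else np.inf)
        loss_ratio = n_loss / n_unch if n_unch else (np.nan if n_loss == 0 else np.inf)
        mean_dist = float(sub["neighbor_dist_interval"].dropna().mean()) if len(sub) else np.nan
        rows.append(
            {
                "chrom": chrom,
                "n_gain": n_gain,
                "n_loss": n_loss,
                "n_unchanged": n_unch,
                "gain_ratio": gain_ratio,
                "loss_ratio": loss_ratio,
                "mean_neighbor_dist": mean_dist,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap test
# ---------------------------------------------------------------------------

@dataclass
class OverlapTest:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    odds_ratio: float
    p_fisher: float


def overlap_fisher(
    set_a: set, set_b: set, universe: set, label_a: str = "A", label_b: str = "B"
) -> OverlapTest:
    """One-sided (enrichment) Fisher exact test of two peak-id sets."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - len(set_a | set_b)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return OverlapTest(
        label_a=label_a, label_b=label_b, n_a=len(set_a), n_b=len(set_b),
        n_overlap=a, n_universe=len(universe), odds_ratio=float(odds),
        p_fisher=float(p),
    )


# ---------------------------------------------------------------------------
# TSS / TTS split
# ---------------------------------------------------------------------------

def tss_tts_split(sides: Sequence[str]) -> dict:
    """Fraction of peaks nearer the TSS vs the TTS of their nearest gene."""
    sides = [s for s in sides if s in ("TSS", "TTS")]
    n = len(sides)
    if n == 0:
        return {"n": 0, "tss_fraction": np.nan, "tts_fraction": np.nan}
    n_tss = sum(1 for s in sides if s == "TSS")
    return {
        "n": n,
        "tss_fraction": n_tss / n,
        "tts_fraction": (n - n_tss) / n,
    }


# ---------------------------------------------------------------------------
# sequence composition
# ---------------------------------------------------------------------------

def gc_cpg_profile(
    peaks: Sequence[GenomicInterval],
    assembly: GenomeAssembly,
    flank: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak GC%/CpG rate and positional base frequencies around centers.

    Returns (per_peak, positional): per_peak has gc_percent (0-100) and
    cpg_rate (CG dinucleotides / (length - 1)); positional has A/C/G/T
    frequencies per offset in [-flank, flank), N bases excluded.
    """
    if assembly.sequence is None:
        raise ValueError("assembly carries no sequence")
    seqs = {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in assembly.sequence.items()}
    codes = {b: ord(b) for b in "ACGTN"}

    rows = []
    width = 2 * flank
    pos_counts = np.zeros((width, 4), dtype=np.int64)
    pos_totals = np.zeros(width, dtype=np.int64)
    for iv in peaks:
        arr = seqs[iv.chrom][iv.start: iv.end]
        acgt = np.isin(arr, [codes["A"], codes["C"], codes["G"], codes["T"]])
        denom = int(acgt.sum())
        gc = int(np.sum((arr == codes["G"]) | (arr == codes["C"])))
        cg = int(np.sum((arr[:-1] == codes["C"]) & (arr[1:] == codes["G"])))
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "gc_percent": 100.0 * gc / denom if denom else np.nan,
                "cpg_rate": cg / (len(arr) - 1) if len(arr) > 1 else np.nan,
            }
        )
        center = iv.midpoint
        lo, hi = center - flank, center + flank
        s_clip, e_clip = max(lo, 0), min(hi, len(seqs[iv.chrom]))
        window = seqs[iv.chrom][s_clip:e_clip]
        off = s_clip - lo
        for k, base in enumerate("ACGT"):
            mask = window == codes[base]
            pos_counts[off: off + len(window), k] += mask
        valid = np.isin(window, [codes[b] for b in "ACGT"])
        pos_totals[off: off + len(window)] += valid

    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = pos_counts / pos_totals[:, None]
    positional = pd.DataFrame(
        freqs, columns=list("ACGT"), index=np.arange(-flank, flank)
    )
    positional.index.name = "offset"
    return pd.DataFrame(rows), positional


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Mean reads-per-million per scaled-gene bin, per condition."""

    values: pd.DataFrame  # bins x conditions
    mode: str
    flank: int
    body_bins: int
    flank_bins: int
    control_subtracted: bool = False


def _overlap_mask(
    readset, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per read: does it overlap any of the (merged) intervals."""
    merged = merge_intervals(list(intervals), max_gap=0)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, ([], []))
        by_chrom[iv.chrom][0].append(iv.start)
        by_chrom[iv.chrom][1].append(iv.end)
    mask = np.zeros(readset.library_size, dtype=bool)
    for chrom, (starts, ends) in by_chrom.items():
        istarts = np.array(starts)
        iends = np.array(ends)
        sel = readset.chroms == chrom
        rs, re = readset.starts[sel], readset.ends[sel]
        j = np.searchsorted(iends, rs, side="right")
        ok = (j < len(istarts)) & (istarts[np.minimum(j, len(istarts) - 1)] < re)
        mask[np.flatnonzero(sel)] = ok
    return mask


def _profile_one_sample(
    readset,
    genes: Sequence[GeneModel],
    flank: int,
    body_bins: int,
    flank_bins: int,
    library_size: int | None = None,
) -> np.ndarray:
    """Mean RPM per bin over genes for one sample (reads mapped by midpoint)."""
    nbins = 2 * flank_bins + body_bins
    total = np.zeros(nbins, dtype=float)
    mids: dict[str, np.ndarray] = {}
    for chrom in np.unique(readset.chroms):
        sel = readset.chroms == chrom
        m = (readset.starts[sel] + readset.ends[sel]) // 2
        mids[str(chrom)] = np.sort(m)
    used = 0
    for g in genes:
        iv = g.interval
        if iv.length < 2 * body_bins:
            continue
        used += 1
        edges = np.concatenate(
            [
                np.linspace(iv.start - flank, iv.start, flank_bins + 1)[:-1],
                np.linspace(iv.start, iv.end, body_bins + 1)[:-1],
                np.linspace(iv.end, iv.end + flank, flank_bins + 1),
            ]
        )
        m = mids.get(iv.chrom)
        if m is None or len(m) == 0:
            continue
        idx = np.searchsorted(m, edges)
        counts = np.diff(idx).astype(float)
        if g.strand == "-":
            counts = counts[::-1]
        total += counts
    lib = readset.library_size if library_size is None else library_size
    if used == 0 or lib == 0:
        return total
    return total / used / lib * 1e6


def metagene_profile(
    readsets: Sequence,
    genes: Sequence[GeneModel],
    mode: str = "all",
    flank: int = 5000,
    body_bins: int = 50,
    flank_bins: int = 25,
    subtract: str | None = None,
) -> MetageneProfile:
    """Strand-oriented scaled-gene coverage profile per condition.

    mode 'intergenic' keeps only reads with zero gene-body overlap;
    'intronic' keeps only reads overlapping an intron.  ``subtract`` names
    a control condition whose bin-wise profile is removed from every
    condition (including itself, which then reads zero).
    """
    if mode not in ("all", "intergenic", "intronic"):
        raise ValueError(f"unknown metagene mode {mode!r}")
    bodies = [g.interval for g in genes]
    introns = [
        GenomicInterval(g.interval.chrom, s, e)
        for g in genes
        for s, e in g.introns()
    ]
    per_sample: dict[str, np.ndarray] = {}
    conditions: dict[str, list] = {}
    for rs in readsets:
        sub = rs
        if mode == "intergenic":
            sub = rs.subset(~_overlap_mask(rs, bodies))
        elif mode == "intronic":
            sub = rs.subset(_overlap_mask(rs, introns)) if introns else rs.subset(
                np.zeros(rs.library_size, dtype=bool)
            )
        # RPM normalization uses the full library size of the sample
        prof = _profile_one_sample(
            sub, genes, flank, body_bins, flank_bins,
            library_size=rs.library_size,
        )
        per_sample[rs.sample_id] = prof
        conditions.setdefault(rs.condition, []).append(rs.sample_id)

    cols = {
        cond: np.mean([per_sample[s] for s in sids], axis=0)
        for cond, sids in conditions.items()
    }
    values = pd.DataFrame(cols)
    values.index.name = "bin"
    subtracted = False
    if subtract is not None:
        if subtract not in values.columns:
            raise ValueError(f"control condition {subtract!r} not present")
        values = values.sub(values[subtract], axis=0)
        subtracted = True
    return MetageneProfile(
        values=values, mode=mode, flank=flank, body_bins=body_bins,
        flank_bins=flank_bins, control_subtracted=subtracted,
    )


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def sample_qc(
    cm: CountMatrix, n_top: int = 500
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Pearson correlations and PCA on log2(normalized + 1) counts.

    PCA uses the n_top most variable features, centered per feature.
    Returns (correlation matrix, PC coordinates, variance-explained).
    """
    if cm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if cm.n_features < 2:
        raise ValueError("need at least 2 features")
    if cm.size_factors is None:
        from .differential import size_factors

        size_factors(cm)
    y = np.log2(cm.normalized() + 1.0)
    corr = pd.DataFrame(
        np.corrcoef(y, rowvar=False), index=cm.sample_ids, columns=cm.sample_ids
    )
    variances = y.var(axis=1)
    top = np.argsort(variances)[::-1][: min(n_top, cm.n_features)]
    X = y[top].T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U * S
    var_explained = S**2 / max(np.sum(S**2), 1e-300)
    pcs = pd.DataFrame(
        coords[:, :2], index=cm.sample_ids, columns=["PC1", "PC2"]
    )
    return corr, pcs, var_explained
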