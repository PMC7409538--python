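"""Seeded synthetic-data generator with planted ground truth.

Produces a genome (GC/CpG-elevated promoters), single-transcript gene
models, DRIP IP / input / RNase-H read sets with planted enrichment peaks
carrying per-condition log2 fold changes, and stranded RNA-seq read sets
with gene expression, a nascent intronic fraction and planted intergenic
antisense loci.  Everything is generated as already-aligned BED6 intervals.

All randomness flows from one seed through named substreams, so adding a
sample or stage never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .intervals import GeneModel, GenomeAssembly, GenomicInterval, merge_intervals

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, *names: str) -> np.random.Generator:
    """Independent, reproducible generator for a named stage/sample."""
    key = zlib.crc32("/".join(names).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chroms: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 300
    gene_length_min: int = 3000
    gene_length_max: int = 20000
    min_intergenic_gap: int = 6000
    noncoding_fraction: float = 0.1
    gene_density_weights: tuple | None = None  # per-chrom gene allocation
    promoter_gc: float = 0.6
    background_gc: float = 0.4
    with_sequence: bool = True
    # DRIP
    n_peaks: int = 100
    peak_length: int = 2000
    peak_placement: dict = field(
        default_factory=lambda: {"TSS": 0.4, "TTS": 0.3, "intron": 0.2, "intergenic": 0.1}
    )
    background_rate: float = 0.01  # reads per bp per DRIP sample
    peak_enrichment: float = 8.0
    read_length: int = 75
    conditions: tuple = ("ctrl", "kd1", "kd2", "kd3")
    drip_replicates: int = 2
    n_gain_per_condition: int = 25
    n_loss_per_condition: int = 8
    gain_log2fc: float = 2.0
    loss_log2fc: float = -2.0
    gain_placement_bias: str | None = None  # e.g. "TTS": pick gains there first
    gain_chrom_bias: str | None = None  # e.g. "chr1": pick gains there first
    nb_dispersion: float = 0.05
    rnaseh_residual: float = 0.05
    # RNA-seq
    rnaseq_replicates: int = 3
    gene_expression_rate: float = 0.02  # exonic reads per bp per sample
    expression_sigma: float = 0.5
    nascent_intron_fraction: float = 0.1
    rnaseq_read_length: int = 100
    rnaseq_background_rate: float = 0.001  # reads per bp, both strands pooled
    n_up_genes: int = 10
    n_down_genes: int = 10
    gene_de_log2fc: float = 2.0
    # antisense planting
    n_antisense: int = 0
    antisense_fold: float = 4.0
    antisense_length: int = 2000
    antisense_condition: str | None = None  # default: first knockdown
    antisense_sides: tuple = ("TSS",)

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 10_000:
            raise ValueError("need >= 1 chromosome of >= 10 kb")
        for rate in (self.background_rate, self.rnaseq_background_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.peak_enrichment <= 0 or self.antisense_fold <= 0:
            raise ValueError("fold parameters must be > 0")
        if not np.isclose(sum(self.peak_placement.values()), 1.0):
            raise ValueError("peak_placement fractions must sum to 1")
        if len(self.conditions) < 2:
            raise ValueError("need a control plus at least one knockdown")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["antisense_sides"] = list(self.antisense_sides)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if "antisense_sides" in d:
            d["antisense_sides"] = tuple(d["antisense_sides"])
        if d.get("gene_density_weights") is not None:
            d["gene_density_weights"] = tuple(d["gene_density_weights"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


def demo_config(seed: int = 0) -> "SimulationConfig":
    """Default demo-scale configuration: 1 chromosome x 10 Mb, 300 genes,
    4 conditions x 2 DRIP replicates, 3 RNA replicates, 8 antisense loci
    planted upstream of TSS gain peaks."""
    return SimulationConfig(
        seed=seed,
        n_antisense=8,
        gain_placement_bias="TSS",
    )


@dataclass
class PlantedPeak:
    chrom: str
    start: int
    end: int
    placement: str  # TSS / TTS / intron / intergenic
    gene_id: str | None
    log2fc: dict  # condition -> true log2 fold change vs control

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class PlantedAntisense:
    gene_id: str
    side: str  # TSS or TTS
    strand: str  # strand the planted reads carry
    fold: float
    condition: str
    chrom: str
    start: int
    end: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class TruthTable:
    seed: int
    peaks: list  # of PlantedPeak
    antisense: list  # of PlantedAntisense
    gene_log2fc: dict  # gene_id -> {condition: log2fc}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "peaks": [dataclasses.asdict(p) for p in self.peaks],
            "antisense": [dataclasses.asdict(a) for a in self.antisense],
            "gene_log2fc": self.gene_log2fc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            peaks=[PlantedPeak(**p) for p in payload["peaks"]],
            antisense=[PlantedAntisense(**a) for a in payload["antisense"]],
            gene_log2fc=payload["gene_log2fc"],
        )


# ---------------------------------------------------------------------------
# read sets
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """One sample's aligned reads as parallel arrays (BED6-equivalent)."""

    sample_id: str
    condition: str
    replicate: int
    assay: str  # DRIP-IP / DRIP-input / DRIP-RNaseH / RNAseq
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.chroms) == len(self.ends) == len(self.strands) == n):
            raise ValueError("read arrays must have equal length")

    @property
    def library_size(self) -> int:
        return len(self.starts)

    def sorted(self) -> "ReadSet":
        order = np.lexsort((self.starts, self.chroms))
        return ReadSet(
            self.sample_id, self.condition, self.replicate, self.assay,
            self.chroms[order], self.starts[order], self.ends[order],
            self.strands[order],
        )

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(
            self.sample_id, self.condition, self.replicate, self.assay,
            self.chroms[mask], self.starts[mask], self.ends[mask],
            self.strands[mask],
        )

    def to_bed(self, path: str | Path) -> None:
        rs = self.sorted()
        df = pd.DataFrame(
            {
                "chrom": rs.chroms,
                "start": rs.starts,
                "end": rs.ends,
                "name": [f"{self.sample_id}.{i}" for i in range(len(rs.starts))],
                "score": 0,
                "strand": rs.strands,
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        sample_id: str,
        condition: str = "",
        replicate: int = 0,
        assay: str = "",
    ) -> "ReadSet":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "strand": str},
        )
        return cls(
            sample_id=sample_id, condition=condition, replicate=replicate, assay=assay,
            chroms=df["chrom"].to_numpy(dtype=object),
            starts=df["start"].to_numpy(dtype=np.int64),
            ends=df["end"].to_numpy(dtype=np.int64),
            strands=df["strand"].to_numpy(dtype=object),
        )


def _empty_arrays() -> tuple:
    return (
        np.empty(0, dtype=object), np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64), np.empty(0, dtype=object),
    )


def _make_readset(sample_id, condition, replicate, assay, parts) -> ReadSet:
    """parts: list of (chrom, starts, ends, strand_value_or_array)."""
    chroms, starts, ends, strands = [], [], [], []
    for chrom, s, e, strand in parts:
        n = len(s)
        chroms.append(np.full(n, chrom, dtype=object))
        starts.append(np.asarray(s, dtype=np.int64))
        ends.append(np.asarray(e, dtype=np.int64))
        if isinstance(strand, str):
            strands.append(np.full(n, strand, dtype=object))
        else:
            strands.append(np.asarray(strand, dtype=object))
    if chroms:
        arrays = (
            np.concatenate(chroms), np.concatenate(starts),
            np.concatenate(ends), np.concatenate(strands),
        )
    else:
        arrays = _empty_arrays()
    return ReadSet(sample_id, condition, replicate, assay, *arrays).sorted()


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _markov_promoter(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Sequence with marginal GC = gc and P(G | prev C) doubled (CpG boost)."""
    c = gc / 2.0
    g_after_c = min(gc, 1.0 - c)
    g_other = c * (1.0 - g_after_c) / (1.0 - c) if c < 1 else c
    # order A C G T; cumulative prob tables for prev==C and prev!=C
    def cum(g_prob: float) -> np.ndarray:
        rem = 1.0 - c - g_prob
        a = t = rem / 2.0
        return np.cumsum([a, c, g_prob, t])

    cum_c, cum_other = cum(g_after_c), cum(g_other)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    prev_is_c = False
    for i in range(length):
        table = cum_c if prev_is_c else cum_other
        idx = int(np.searchsorted(table, u[i], side="right"))
        idx = min(idx, 3)
        out[i] = _BASES[idx]
        prev_is_c = idx == 1
    return out


def _make_exons(
    rng: np.random.Generator, start: int, end: int
) -> tuple[tuple[tuple[int, int], ...], tuple[int, int] | None]:
    length = end - start
    n_ex = int(rng.integers(2, 8))
    while 50 * (2 * n_ex - 1) > length and n_ex > 1:
        n_ex -= 1
    n_seg = 2 * n_ex - 1
    weights = rng.dirichlet(np.ones(n_seg))
    extra = length - 50 * n_seg
    lens = 50 + np.floor(weights * extra).astype(int)
    lens[-1] += length - int(lens.sum())
    bounds = start + np.concatenate(([0], np.cumsum(lens)))
    exons = tuple(
        (int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)
    )
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    cds_s = first_s + min(100, (first_e - first_s) // 2)
    cds_e = last_e - min(100, (last_e - last_s) // 2)
    cds = (cds_s, cds_e) if cds_s < cds_e else None
    return exons, cds


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAssembly, list[GeneModel]]:
    """Place non-overlapping genes and draw sequence (GC-elevated promoters)."""
    config.validate()
    chrom_names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    lengths = {c: config.chrom_length for c in chrom_names}

    genes: list[GeneModel] = []
    gidx = 0
    if config.gene_density_weights is not None:
        w = np.asarray(config.gene_density_weights, dtype=float)
        if len(w) != config.n_chroms or np.any(w < 0) or w.sum() == 0:
            raise ValueError("gene_density_weights must be non-negative, one per chromosome")
        w = w / w.sum()
        per_chrom = [int(round(config.n_genes * wi)) for wi in w]
        per_chrom[0] += config.n_genes - sum(per_chrom)
    else:
        per_chrom = [
            config.n_genes // config.n_chroms
            + (1 if i < config.n_genes % config.n_chroms else 0)
            for i in range(config.n_chroms)
        ]
    for ci, chrom in enumerate(chrom_names):
        n = per_chrom[ci]
        if n == 0:
            continue
        rng = substream(config.seed, "genes", chrom)
        glens = rng.integers(
            config.gene_length_min, config.gene_length_max + 1, size=n
        )
        need = int(glens.sum()) + (n + 1) * config.min_intergenic_gap
        if need > lengths[chrom]:
            raise ValueError(
                f"cannot place {n} genes on {chrom}: need {need} bp but have "
                f"{lengths[chrom]}; reduce n_genes or gene lengths"
            )
        slack = lengths[chrom] - need
        extra = rng.multinomial(slack, np.ones(n + 1) / (n + 1))
        strands = rng.choice(np.array(["+", "-"]), size=n)
        noncoding = rng.random(n) < config.noncoding_fraction
        pos = 0
        for i in range(n):
            pos += config.min_intergenic_gap + int(extra[i])
            start, end = pos, pos + int(glens[i])
            pos = end
            exons, cds = _make_exons(rng, start, end)
            gidx += 1
            if noncoding[i]:
                biotype, cds = "noncoding", None
            else:
                biotype = "protein_coding"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gidx:04d}",
                    interval=GenomicInterval(chrom, start, end, str(strands[i])),
                    exons=exons,
                    biotype=biotype,
                    cds=cds,
                )
            )

    sequence = None
    if config.with_sequence:
        sequence = {}
        probs = np.array(
            [
                (1 - config.background_gc) / 2, config.background_gc / 2,
                config.background_gc / 2, (1 - config.background_gc) / 2,
            ]
        )
        for chrom in chrom_names:
            rng = substream(config.seed, "sequence", chrom)
            arr = _BASES[rng.choice(4, size=lengths[chrom], p=probs)]
            for g in genes:
                if g.interval.chrom != chrom:
                    continue
                if g.strand == "+":
                    ws, we = g.tss - 1000, g.tss + 100
                else:
                    ws, we = g.tss - 99, g.tss + 1001
                ws, we = max(0, ws), min(lengths[chrom], we)
                prng = substream(config.seed, "promoter-seq", g.gene_id)
                arr[ws:we] = _markov_promoter(prng, we - ws, config.promoter_gc)
            sequence[chrom] = arr.tobytes().decode("ascii")

    return (
        GenomeAssembly(chrom_names=chrom_names, chrom_lengths=lengths, sequence=sequence),
        genes,
    )


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _placement_counts(config: SimulationConfig) -> dict[str, int]:
    mix = config.peak_placement
    counts = {k: int(round(config.n_peaks * v)) for k, v in mix.items()}
    # fix rounding drift on the largest class
    drift = config.n_peaks - sum(counts.values())
    if drift != 0:
        top = max(counts, key=lambda k: counts[k])
        counts[top] += drift
    return counts


def plant_peaks(
    assembly: GenomeAssembly, genes: Sequence[GeneModel], config: SimulationConfig
) -> list[PlantedPeak]:
    """Choose peak intervals at TSS/TTS/intron/intergenic anchors.

    Peaks are kept >= 1 kb apart from each other so that each planted effect
    maps onto its own consensus peak.
    """
    rng = substream(config.seed, "plant-peaks")
    counts = _placement_counts(config)
    half = config.peak_length // 2
    placed: list[PlantedPeak] = []
    used_genes: set[str] = set()

    def far_enough(chrom: str, start: int, end: int) -> bool:
        for p in placed:
            if p.chrom == chrom and start - 1000 < p.end and p.start < end + 1000:
                return False
        return True

    def try_add(chrom: str, center: int, placement: str, gene_id: str | None) -> bool:
        start = center - half
        end = start + config.peak_length
        if start < 0 or end > assembly.chrom_lengths[chrom]:
            return False
        if not far_enough(chrom, start, end):
            return False
        placed.append(PlantedPeak(chrom, start, end, placement, gene_id, {}))
        return True

    gene_list = list(genes)
    for placement in ("TSS", "TTS", "intron"):
        wanted = counts.get(placement, 0)
        order = rng.permutation(len(gene_list))
        made = 0
        for idx in order:
            if made >= wanted:
                break
            g = gene_list[idx]
            if g.gene_id in used_genes:
                continue
            if placement == "TSS":
                center = g.tss
            elif placement == "TTS":
                center = g.tts
            else:
                introns = g.introns()
                wide = [iv for iv in introns if iv[1] - iv[0] >= 200]
                if not wide:
                    continue
                s, e = wide[int(rng.integers(len(wide)))]
                center = (s + e) // 2
            if try_add(g.interval.chrom, center, placement, g.gene_id):
                used_genes.add(g.gene_id)
                made += 1
        if made < wanted:
            raise ValueError(
                f"could only place {made}/{wanted} {placement} peaks; "
                "reduce n_peaks or add genes"
            )

    wanted = counts.get("intergenic", 0)
    margin = half + 2500
    gaps = []
    bodies = merge_intervals([g.interval for g in genes])
    by_chrom: dict[str, list] = {c: [] for c in assembly.chrom_names}
    for iv in bodies:
        by_chrom[iv.chrom].append(iv)
    for chrom in assembly.chrom_names:
        cursor = 0
        for iv in by_chrom[chrom]:
            if iv.start - cursor >= 2 * margin:
                gaps.append((chrom, cursor, iv.start))
            cursor = iv.end
        if assembly.chrom_lengths[chrom] - cursor >= 2 * margin:
            gaps.append((chrom, cursor, assembly.chrom_lengths[chrom]))
    made = 0
    attempts = 0
    while made < wanted and attempts < 50 * max(wanted, 1):
        attempts += 1
        chrom, gs, ge = gaps[int(rng.integers(len(gaps)))]
        center = int(rng.integers(gs + margin, ge - margin))
        if try_add(chrom, center, "intergenic", None):
            made += 1
    if made < wanted:
        raise ValueError("could not place intergenic peaks; genome too dense")

    placed.sort(key=lambda p: (p.chrom, p.start))

    # per-condition log2 fold changes (control stays 0)
    knockdowns = list(config.conditions[1:])
    n = len(placed)
    for p in placed:
        p.log2fc = {c: 0.0 for c in config.conditions}
    for cond in knockdowns:
        crng = substream(config.seed, "plant-lfc", cond)
        if config.gain_placement_bias or config.gain_chrom_bias:
            def tier(p: PlantedPeak) -> int:
                score = 0
                if config.gain_placement_bias and p.placement == config.gain_placement_bias:
                    score += 1
                if config.gain_chrom_bias and p.chrom == config.gain_chrom_bias:
                    score += 1
                return -score  # best tier first
            tiers: dict[int, list[int]] = {}
            for i, p in enumerate(placed):
                tiers.setdefault(tier(p), []).append(i)
            order = np.concatenate(
                [crng.permutation(tiers[t]) for t in sorted(tiers)]
            ).astype(int)
        else:
            order = crng.permutation(n)
        gains = order[: config.n_gain_per_condition]
        losses = order[
            config.n_gain_per_condition: config.n_gain_per_condition + config.n_loss_per_condition
        ]
        for i in gains:
            placed[int(i)].log2fc[cond] = config.gain_log2fc
        for i in losses:
            placed[int(i)].log2fc[cond] = config.loss_log2fc
    return placed


def plant_antisense(
    assembly: GenomeAssembly,
    genes: Sequence[GeneModel],
    peaks: Sequence[PlantedPeak],
    config: SimulationConfig,
) -> list[PlantedAntisense]:
    if config.n_antisense == 0:
        return []
    cond = config.antisense_condition or config.conditions[1]
    rng = substream(config.seed, "plant-antisense")
    gene_by_id = {g.gene_id: g for g in genes}
    bodies = merge_intervals([g.interval for g in genes])
    sides = list(config.antisense_sides)
    L = config.antisense_length

    def window_for(g: GeneModel, side: str) -> GenomicInterval | None:
        if side == "TSS":
            strand = "-" if g.strand == "+" else "+"
            if g.strand == "+":
                s, e = g.tss - L, g.tss
            else:
                s, e = g.tss + 1, g.tss + 1 + L
        else:  # TTS read-through: same strand, downstream of tts
            strand = g.strand
            if g.strand == "+":
                s, e = g.tts + 1, g.tts + 1 + L
            else:
                s, e = g.tts - L, g.tts
        if s < 0 or e > assembly.chrom_lengths[g.interval.chrom]:
            return None
        win = GenomicInterval(g.interval.chrom, s, e, strand)
        for b in bodies:
            if b.chrom == win.chrom and b.start < win.end and win.start < b.end:
                return None
        return win

    # candidate genes: those anchoring a planted gain peak of the target
    # condition at the requested side
    out: list[PlantedAntisense] = []
    candidates = []
    for p in peaks:
        if p.gene_id is None or p.log2fc.get(cond, 0.0) <= 0:
            continue
        if p.placement in ("TSS", "TTS"):
            candidates.append((p.placement, p.gene_id))
    order = rng.permutation(len(candidates))
    taken: set[tuple[str, str]] = set()
    for idx in order:
        if len(out) >= config.n_antisense:
            break
        placement, gene_id = candidates[int(idx)]
        g = gene_by_id[gene_id]
        for side in sides:
            if side != placement or (gene_id, side) in taken:
                continue
            win = window_for(g, side)
            if win is None:
                continue
            out.append(
                PlantedAntisense(
                    gene_id=gene_id, side=side, strand=win.strand,
                    fold=config.antisense_fold, condition=cond,
                    chrom=win.chrom, start=win.start, end=win.end,
                )
            )
            taken.add((gene_id, side))
    if len(out) < config.n_antisense:
        raise ValueError(
            f"only {len(out)} antisense loci could be planted "
            f"({config.n_antisense} requested); increase gain peaks at "
            "gene ends or intergenic space"
        )
    out.sort(key=lambda a: (a.chrom, a.start))
    return out


def plant_gene_de(
    genes: Sequence[GeneModel],
    antisense: Sequence[PlantedAntisense],
    config: SimulationConfig,
) -> dict[str, dict[str, float]]:
    excluded = {a.gene_id for a in antisense}
    eligible = [g.gene_id for g in genes if g.gene_id not in excluded]
    truth: dict[str, dict[str, float]] = {}
    for cond in config.conditions[1:]:
        rng = substream(config.seed, "plant-gene-de", cond)
        order = rng.permutation(len(eligible))
        ups = order[: config.n_up_genes]
        downs = order[config.n_up_genes: config.n_up_genes + config.n_down_genes]
        for i in ups:
            truth.setdefault(eligible[int(i)], {})[cond] = config.gene_de_log2fc
        for i in downs:
            truth.setdefault(eligible[int(i)], {})[cond] = -config.gene_de_log2fc
    return truth


def build_truth(
    assembly: GenomeAssembly, genes: Sequence[GeneModel], config: SimulationConfig
) -> TruthTable:
    peaks = plant_peaks(assembly, genes, config)
    antisense = plant_antisense(assembly, genes, peaks, config)
    gene_lfc = plant_gene_de(genes, antisense, config)
    return TruthTable(seed=config.seed, peaks=peaks, antisense=antisense, gene_log2fc=gene_lfc)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _uniform_reads(
    rng: np.random.Generator, n: int, lo: int, hi: int, read_len: int, chrom_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """n read start positions uniform in [lo, hi); ends clipped to chrom."""
    if hi <= lo or n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = rng.integers(lo, hi, size=n)
    ends = np.minimum(starts + read_len, chrom_len)
    return starts.astype(np.int64), ends.astype(np.int64)


def _gamma_multiplier(rng: np.random.Generator, alpha: float) -> float:
    if alpha <= 0:
        return 1.0
    return float(rng.gamma(shape=1.0 / alpha, scale=alpha))


def _background_parts(
    rng: np.random.Generator,
    assembly: GenomeAssembly,
    rate: float,
    read_len: int,
    strand: str | None,
) -> list:
    parts = []
    for chrom in assembly.chrom_names:
        L = assembly.chrom_lengths[chrom]
        n = int(rng.poisson(rate * L))
        s, e = _uniform_reads(rng, n, 0, max(L - read_len, 1), read_len, L)
        if strand is None:
            strands = rng.choice(np.array(["+", "-"], dtype=object), size=n)
            parts.append((chrom, s, e, strands))
        else:
            parts.append((chrom, s, e, strand))
    return parts


def simulate_drip_reads(
    assembly: GenomeAssembly,
    genes: Sequence[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
) -> list[ReadSet]:
    """IP per condition x replicate, one pooled input, one RNase-H control.

    Read rate inside a planted peak is background * enrichment * 2^log2fc
    (background everywhere plus a signal component on top); signal counts
    carry a per-(peak, sample) gamma multiplier with variance nb_dispersion.
    The RNase-H sample retains rnaseh_residual of the control-level signal.
    """
    config.validate()
    rl = config.read_length
    bg = config.background_rate
    out: list[ReadSet] = []

    def signal_parts(rng, lfc_of_peak) -> list:
        parts = []
        for p in truth.peaks:
            lfc = lfc_of_peak(p)
            sig_rate = bg * max(config.peak_enrichment * 2.0 ** lfc - 1.0, 0.0)
            if sig_rate <= 0:
                continue
            g = _gamma_multiplier(rng, config.nb_dispersion)
            span = p.end - p.start - rl
            n = int(rng.poisson(sig_rate * (p.end - p.start) * g))
            s, e = _uniform_reads(
                rng, n, p.start, p.start + max(span, 1), rl,
                assembly.chrom_lengths[p.chrom],
            )
            parts.append((p.chrom, s, e, "."))
        return parts

    for cond in config.conditions:
        for rep in range(1, config.drip_replicates + 1):
            sid = f"drip_{cond}_rep{rep}"
            rng = substream(config.seed, "drip", sid)
            parts = _background_parts(rng, assembly, bg, rl, ".")
            parts += signal_parts(rng, lambda p: p.log2fc.get(cond, 0.0))
            out.append(_make_readset(sid, cond, rep, "DRIP-IP", parts))

    rng = substream(config.seed, "drip", "input")
    parts = _background_parts(rng, assembly, bg, rl, ".")
    out.append(_make_readset("drip_input", "input", 1, "DRIP-input", parts))

    rng = substream(config.seed, "drip", "rnaseh")
    parts = _background_parts(rng, assembly, bg, rl, ".")
    rho = config.rnaseh_residual
    for p in truth.peaks:
        sig_rate = bg * max(config.peak_enrichment - 1.0, 0.0) * rho
        if sig_rate <= 0:
            continue
        n = int(rng.poisson(sig_rate * (p.end - p.start)))
        s, e = _uniform_reads(
            rng, n, p.start, p.start + max(p.end - p.start - rl, 1), rl,
            assembly.chrom_lengths[p.chrom],
        )
        parts.append((p.chrom, s, e, "."))
    out.append(_make_readset("drip_rnaseh", "rnaseh", 1, "DRIP-RNaseH", parts))
    return out


def simulate_rnaseq_reads(
    assembly: GenomeAssembly,
    genes: Sequence[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
) -> list[ReadSet]:
    """Stranded RNA-seq with exonic + nascent intronic + background reads
    and planted antisense loci (fold * local background in the planted
    condition, 1x background otherwise)."""
    config.validate()
    bodies = merge_intervals([g.interval for g in genes])
    for a in truth.antisense:
        for b in bodies:
            if b.chrom == a.chrom and b.start < a.end and a.start < b.end:
                raise ValueError(
                    f"antisense locus for {a.gene_id} overlaps a gene body"
                )

    rl = config.rnaseq_read_length
    expr_rng = substream(config.seed, "rnaseq", "expression")
    sigma = config.expression_sigma
    expr = {
        g.gene_id: config.gene_expression_rate
        * float(expr_rng.lognormal(-sigma**2 / 2.0, sigma))
        for g in genes
    }

    out: list[ReadSet] = []
    for cond in config.conditions:
        for rep in range(1, config.rnaseq_replicates + 1):
            sid = f"rna_{cond}_rep{rep}"
            rng = substream(config.seed, "rnaseq", sid)
            parts = _background_parts(
                rng, assembly, config.rnaseq_background_rate, rl, None
            )
            for g in genes:
                lfc = truth.gene_log2fc.get(g.gene_id, {}).get(cond, 0.0)
                rate = expr[g.gene_id] * 2.0 ** lfc
                if rate <= 0:
                    continue
                gmult = _gamma_multiplier(rng, config.nb_dispersion)
                chrom_len = assembly.chrom_lengths[g.interval.chrom]
                # exonic reads: uniform over the exon union
                ex_lens = np.array([e - s for s, e in g.exons], dtype=np.int64)
                cum = np.concatenate(([0], np.cumsum(ex_lens)))
                n_ex = int(rng.poisson(rate * gmult * int(ex_lens.sum())))
                if n_ex > 0:
                    offs = rng.integers(0, int(ex_lens.sum()), size=n_ex)
                    which = np.searchsorted(cum, offs, side="right") - 1
                    starts = np.array(
                        [g.exons[w][0] for w in which], dtype=np.int64
                    ) + (offs - cum[which])
                    ends = np.minimum(starts + rl, chrom_len)
                    parts.append((g.interval.chrom, starts, ends, g.strand))
                introns = g.introns()
                if introns and config.nascent_intron_fraction > 0:
                    in_lens = np.array([e - s for s, e in introns], dtype=np.int64)
                    icum = np.concatenate(([0], np.cumsum(in_lens)))
                    n_in = int(
                        rng.poisson(
                            rate * gmult * config.nascent_intron_fraction
                            * int(in_lens.sum())
                        )
                    )
                    if n_in > 0:
                        offs = rng.integers(0, int(in_lens.sum()), size=n_in)
                        which = np.searchsorted(icum, offs, side="right") - 1
                        starts = np.array(
                            [introns[w][0] for w in which], dtype=np.int64
                        ) + (offs - icum[which])
                        ends = np.minimum(starts + rl, chrom_len)
                        parts.append((g.interval.chrom, starts, ends, g.strand))
            for a in truth.antisense:
                rate = config.rnaseq_background_rate
                if cond == a.condition:
                    rate *= a.fold
                n = int(rng.poisson(rate * (a.end - a.start)))
                s, e = _uniform_reads(
                    rng, n, a.start, max(a.end - rl, a.start + 1), rl,
                    assembly.chrom_lengths[a.chrom],
                )
                parts.append((a.chrom, s, e, a.strand))
            out.append(_make_readset(sid, cond, rep, "RNAseq", parts))
    return out


# ---------------------------------------------------------------------------
# orchestration + serialization
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    assembly: GenomeAssembly
    genes: list
    truth: TruthTable
    drip_readsets: list
    rna_readsets: list


def simulate_all(config: SimulationConfig) -> SimulationResult:
    assembly, genes = simulate_genome(config)
    truth = build_truth(assembly, genes, config)
    drip = simulate_drip_reads(assembly, genes, truth, config)
    rna = simulate_rnaseq_reads(assembly, genes, truth, config)
    return SimulationResult(config, assembly, genes, truth, drip, rna)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict:
    """Write FASTA, GTF, BED12, chrom sizes, per-sample BED6, truth and
    config JSON under one directory, plus a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "reads").mkdir(exist_ok=True)

    files: dict[str, str] = {}
    if result.assembly.sequence is not None:
        rio.write_fasta(result.assembly, outdir / "genome.fa")
        files["genome_fasta"] = "genome.fa"
    rio.write_chrom_sizes(result.assembly, outdir / "chrom.sizes")
    files["chrom_sizes"] = "chrom.sizes"
    rio.write_gtf(result.genes, outdir / "genes.gtf")
    files["genes_gtf"] = "genes.gtf"
    rio.write_bed12(result.genes, outdir / "genes.bed12")
    files["genes_bed12"] = "genes.bed12"
    result.truth.to_json(outdir / "truth.json")
    files["truth"] = "truth.json"
    with open(outdir / "config.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=1, sort_keys=True)
    files["config"] = "config.json"

    samples = []
    for rs in result.drip_readsets + result.rna_readsets:
        rel = f"reads/{rs.sample_id}.bed"
        rs.to_bed(outdir / rel)
        samples.append(
            {
                "sample_id": rs.sample_id,
                "condition": rs.condition,
                "replicate": rs.replicate,
                "assay": rs.assay,
                "path": rel,
                "library_size": rs.library_size,
            }
        )

    manifest = {
        "seed": result.config.seed,
        "files": files,
        "samples": samples,
        "checksums": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_simulation(simdir: str | Path) -> SimulationResult:
    simdir = Path(simdir)
    with open(simdir / "manifest.json") as fh:
        manifest = json.load(fh)
    with open(simdir / "config.json") as fh:
        config = SimulationConfig.from_dict(json.load(fh))
    if (simdir / "genome.fa").exists():
        assembly = rio.read_fasta(simdir / "genome.fa")
    else:
        assembly = rio.read_chrom_sizes(simdir / "chrom.sizes")
    genes = rio.read_gtf(simdir / "genes.gtf")
    truth = TruthTable.from_json(simdir / "truth.json")
    drip, rna = [], []
    for s in manifest["samples"]:
        rs = ReadSet.from_bed(
            simdir / s["path"], s["sample_id"], s["condition"],
            s["replicate"], s["assay"],
        )
        (rna if s["assay"] == "RNAseq" else drip).append(rs)
    return SimulationResult(config, assembly, genes, truth, drip, rna)
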