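"""Shared fixtures: tiny deterministic genomes, gene sets and read sets."""

from __future__ import annotations

import numpy as np
import pytest

from rloopkit.intervals import GeneModel, GenomeAssembly, GenomicInterval
from rloopkit.simulate import ReadSet


def make_readset(
    reads,
    sample_id="s1",
    condition="ctrl",
    replicate=1,
    assay="DRIP-IP",
):
    """reads: iterable of (chrom, start, end[, strand]) tuples."""
    reads = list(reads)
    chroms = np.array([r[0] for r in reads], dtype=object)
    starts = np.array([r[1] for r in reads], dtype=np.int64)
    ends = np.array([r[2] for r in reads], dtype=np.int64)
    strands = np.array(
        [r[3] if len(r) > 3 else "." for r in reads], dtype=object
    )
    return ReadSet(
        sample_id=sample_id, condition=condition, replicate=replicate,
        assay=assay, chroms=chroms, starts=starts, ends=ends, strands=strands,
    )


def random_genes(rng, assembly, n, min_len=500, max_len=3000, gap=200):
    """Non-overlapping random gene models across the assembly."""
    genes = []
    gid = 0
    for chrom in assembly.chrom_names:
        L = assembly.chrom_lengths[chrom]
        pos = int(rng.integers(0, gap + 1))
        while gid < n and pos + min_len < L - gap:
            length = int(rng.integers(min_len, max_len + 1))
            if pos + length > L:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            third = length // 3
            exons = ((pos, pos + third), (pos + 2 * third, pos + length))
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:03d}",
                    interval=GenomicInterval(chrom, pos, pos + length, strand),
                    exons=exons,
                    cds=(pos + third // 2, pos + length - third // 2),
                )
            )
            pos += length + gap + int(rng.integers(0, 2000))
    return genes


@pytest.fixture
def toy_assembly():
    return GenomeAssembly(
        chrom_names=("chr1", "chr2"),
        chrom_lengths={"chr1": 100_000, "chr2": 50_000},
    )


@pytest.fixture
def toy_genes(toy_assembly):
    rng = np.random.default_rng(42)
    return random_genes(rng, toy_assembly, 20)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
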