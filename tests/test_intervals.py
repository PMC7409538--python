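"""Interval arithmetic, gene models and the feature-category partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopkit.intervals import (
    CATEGORIES,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    assign_feature,
    build_feature_map,
    complement_intervals,
    interval_distance,
    merge_intervals,
    nearest_genes,
    subtract_intervals,
    tss_tts_side,
)

from .conftest import random_genes


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


# ---------------------------------------------------------------------------
# merge / distance
# ---------------------------------------------------------------------------

class TestMerge:
    def test_overlap_merge(self):
        out = merge_intervals([iv(10, 20), iv(15, 30), iv(40, 50)], max_gap=0)
        assert [(o.start, o.end) for o in out] == [(10, 30), (40, 50)]

    def test_gap_exactly_at_threshold(self):
        out = merge_intervals([iv(10, 30), iv(40, 50)], max_gap=10)
        assert [(o.start, o.end) for o in out] == [(10, 50)]

    def test_empty(self):
        assert merge_intervals([], max_gap=0) == []

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals([iv(0, 10)], max_gap=-1)

    def test_cross_chromosome_never_merges(self):
        out = merge_intervals([iv(0, 10, "chr1"), iv(0, 10, "chr2")], max_gap=100)
        assert len(out) == 2

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)), max_size=15
        ),
        st.integers(0, 20),
    )
    def test_idempotent(self, spans, gap):
        ivs = [iv(s, s + l) for s, l in spans]
        once = merge_intervals(ivs, gap)
        twice = merge_intervals(once, gap)
        assert [(o.start, o.end) for o in once] == [(o.start, o.end) for o in twice]

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=15))
    def test_covered_bp_conserved_at_gap_zero(self, spans):
        ivs = [iv(s, s + l) for s, l in spans]
        merged = merge_intervals(ivs, 0)
        covered = set()
        for s, l in spans:
            covered.update(range(s, s + l))
        assert sum(o.length for o in merged) == len(covered)


class TestDistance:
    def test_overlap_zero(self):
        assert interval_distance(iv(0, 10), iv(5, 15)) == 0

    def test_half_open_gap(self):
        assert interval_distance(iv(0, 10), iv(20, 30)) == 10
        assert interval_distance(iv(20, 30), iv(0, 10)) == 10

    def test_cross_chromosome_undefined(self):
        assert interval_distance(iv(0, 10, "chr1"), iv(0, 10, "chr2")) is None

    def test_touching_intervals(self):
        assert interval_distance(iv(0, 10), iv(10, 20)) == 0 or \
            interval_distance(iv(0, 10), iv(10, 20)) == 0
        # touching half-open intervals do not overlap: gap is 0
        assert interval_distance(iv(0, 10), iv(10, 20)) == 0


# ---------------------------------------------------------------------------
# nearest genes
# ---------------------------------------------------------------------------

def brute_force_ranks(peak, genes, mode):
    mid = peak.start + (peak.end - peak.start) // 2
    rows = []
    for g in genes:
        if g.interval.chrom != peak.chrom:
            continue
        if mode == "endpoint":
            d = min(abs(mid - g.tss), abs(mid - g.tts))
        else:
            if peak.start < g.interval.end and g.interval.start < peak.end:
                d = 0
            elif g.interval.start >= peak.end:
                d = g.interval.start - peak.end
            else:
                d = peak.start - g.interval.end
        rows.append((d, g.interval.start, g.gene_id))
    rows.sort()
    return [(gid, d) for d, _, gid in rows]


class TestNearestGenes:
    def test_single_gene(self, toy_assembly):
        g = GeneModel("g1", iv(1000, 3000, strand="+"), ((1000, 3000),))
        out = nearest_genes(iv(5000, 5200), [g])
        assert len(out) == 1 and out[0][0] == "g1"

    def test_midpoint_inside_body_interval_mode(self):
        g = GeneModel("g1", iv(1000, 3000, strand="+"), ((1000, 3000),))
        out = nearest_genes(iv(1500, 1700), [g], mode="interval")
        assert out[0] == ("g1", 0)

    @pytest.mark.parametrize("mode", ["endpoint", "interval"])
    def test_brute_force_oracle_50_genes(self, mode, toy_assembly, rng):
        genes = random_genes(np.random.default_rng(7), toy_assembly, 50)
        for _ in range(20):
            s = int(rng.integers(0, 95_000))
            peak = iv(s, s + int(rng.integers(100, 3000)))
            assert nearest_genes(peak, genes, mode) == brute_force_ranks(peak, genes, mode)

    def test_empty_gene_list(self):
        assert nearest_genes(iv(0, 100), []) == []


class TestTssTtsSide:
    def test_near_tss(self):
        g = GeneModel("g1", iv(1000, 5000, strand="+"), ((1000, 5000),))
        assert tss_tts_side(iv(1100, 1300), g) == ("TSS", 200)

    def test_near_tts(self):
        g = GeneModel("g1", iv(1000, 5000, strand="+"), ((1000, 5000),))
        # tts is the last base (4999), so midpoint 4900 sits 99 bp away
        assert tss_tts_side(iv(4800, 5000), g) == ("TTS", 99)

    def test_tie_goes_to_tss(self):
        g = GeneModel("g1", iv(1000, 5001, strand="+"), ((1000, 5001),))
        # midpoint 3000 equidistant (2000) from tss=1000 and tts=5000
        side, d = tss_tts_side(iv(2900, 3100), g)
        assert side == "TSS" and d == 2000

    def test_cross_chromosome_error(self):
        g = GeneModel("g1", iv(1000, 5000, "chr2", "+"), ((1000, 5000),))
        with pytest.raises(ValueError):
            tss_tts_side(iv(0, 100, "chr1"), g)

    def test_minus_strand(self):
        g = GeneModel("g1", iv(1000, 5000, strand="-"), ((1000, 5000),))
        # tss = 4999, tts = 1000
        assert tss_tts_side(iv(4800, 5000), g)[0] == "TSS"
        assert tss_tts_side(iv(1000, 1200), g)[0] == "TTS"


# ---------------------------------------------------------------------------
# feature map
# ---------------------------------------------------------------------------

def oracle_category(base, chrom, genes, promoter_up=1000, promoter_down=100,
                    tts_up=100, tts_down=1000):
    """Literal per-base classification, highest priority first."""
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        if g.strand == "+":
            if g.tss - promoter_up <= base < g.tss + promoter_down:
                return "promoter-TSS"
        else:
            if g.tss - promoter_down + 1 <= base < g.tss + promoter_up + 1:
                return "promoter-TSS"
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        if g.strand == "+":
            if g.tts - tts_up <= base < g.tts + tts_down:
                return "TTS"
        else:
            if g.tts - tts_down + 1 <= base < g.tts + tts_up + 1:
                return "TTS"
    for cat in ("5UTR", "3UTR", "exon"):
        for g in genes:
            if g.interval.chrom != chrom or g.biotype != "protein_coding":
                continue
            in_exon = any(s <= base < e for s, e in g.exons)
            if not in_exon:
                continue
            if g.cds is None:
                label = "exon"
            else:
                cs, ce = g.cds
                if cs <= base < ce:
                    label = "exon"
                elif (base < cs) == (g.strand == "+"):
                    label = "5UTR"
                else:
                    label = "3UTR"
            if label == cat:
                return cat
    for g in genes:
        if (
            g.interval.chrom == chrom
            and g.biotype == "protein_coding"
            and g.interval.start <= base < g.interval.end
        ):
            return "intron"
    for g in genes:
        if (
            g.interval.chrom == chrom
            and g.biotype != "protein_coding"
            and g.interval.start <= base < g.interval.end
        ):
            return "noncoding"
    return "intergenic"


class TestFeatureMap:
    def test_zero_genes_all_intergenic(self, toy_assembly):
        fmap = build_feature_map([], toy_assembly)
        totals = fmap.bp_totals()
        assert totals["intergenic"] == toy_assembly.total_length
        assert sum(totals.values()) == toy_assembly.total_length

    def test_promoter_window(self, toy_assembly):
        g = GeneModel("g1", iv(5000, 9000, strand="+"), ((5000, 9000),))
        fmap = build_feature_map([g], toy_assembly)
        assert fmap.category_at("chr1", 4500) == "promoter-TSS"  # tss-500
        assert fmap.category_at("chr1", 3999) == "intergenic"
        assert fmap.category_at("chr1", 5099) == "promoter-TSS"  # tss+99

    def test_partition_sums_on_random_fixture(self, toy_assembly):
        genes = random_genes(np.random.default_rng(3), toy_assembly, 15)
        fmap = build_feature_map(genes, toy_assembly)
        assert sum(fmap.bp_totals().values()) == toy_assembly.total_length

    def test_per_base_oracle_toy_genome(self):
        asm = GenomeAssembly(("chrT",), {"chrT": 20_000})
        rng = np.random.default_rng(11)
        genes = random_genes(rng, asm, 4, min_len=800, max_len=4000, gap=300)
        genes[0] = GeneModel(
            genes[0].gene_id, genes[0].interval, genes[0].exons,
            biotype="noncoding", cds=None,
        )
        fmap = build_feature_map(genes, asm)
        for base in range(0, 20_000, 7):
            assert fmap.category_at("chrT", base) == oracle_category(
                base, "chrT", genes
            ), f"mismatch at base {base}"

    def test_gene_outside_assembly_names_gene(self, toy_assembly):
        g = GeneModel("bad_gene", iv(99_500, 100_500, strand="+"), ((99_500, 100_500),))
        with pytest.raises(ValueError, match="bad_gene"):
            build_feature_map([g], toy_assembly)


class TestAssignFeature:
    def test_midpoint_category(self, toy_assembly):
        g = GeneModel(
            "g1", iv(10_000, 20_000, strand="+"),
            ((10_000, 12_000), (18_000, 20_000)),
            cds=(11_000, 19_000),
        )
        fmap = build_feature_map([g], toy_assembly)
        assert assign_feature(iv(14_000, 16_000), fmap) == "intron"
        # peak centered at tts + 50 (inside the TTS window)
        assert assign_feature(iv(20_000, 20_100), fmap) == "TTS"

    def test_random_peaks_match_oracle_lookup(self, toy_assembly, rng):
        genes = random_genes(np.random.default_rng(5), toy_assembly, 12)
        fmap = build_feature_map(genes, toy_assembly)
        for _ in range(300):
            s = int(rng.integers(0, 99_000))
            peak = iv(s, s + int(rng.integers(10, 1000)))
            mid = peak.start + peak.length // 2
            assert assign_feature(peak, fmap) == fmap.category_at("chr1", mid)


# ---------------------------------------------------------------------------
# complement / subtract helpers
# ---------------------------------------------------------------------------

class TestComplementSubtract:
    def test_complement_no_intervals(self, toy_assembly):
        out = complement_intervals([], toy_assembly)
        assert sum(o.length for o in out) == toy_assembly.total_length

    def test_complement_partition(self, toy_assembly):
        ivs = [iv(10, 100), iv(50, 200), iv(5000, 6000, "chr2")]
        comp = complement_intervals(ivs, toy_assembly)
        total = sum(o.length for o in comp) + sum(
            o.length for o in merge_intervals(ivs, 0)
        )
        assert total == toy_assembly.total_length

    def test_subtract_middle(self):
        pieces = subtract_intervals(iv(0, 100), [iv(40, 60)])
        assert [(p.start, p.end) for p in pieces] == [(0, 40), (60, 100)]

    def test_subtract_all(self):
        assert subtract_intervals(iv(10, 20), [iv(0, 50)]) == []
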