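"""Feature distributions, Welch/Fisher tests, GC/CpG, metagene, QC."""

import math

import numpy as np
import pandas as pd
import pytest

from rloopkit.differential import CountMatrix, size_factors
from rloopkit.intervals import (
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    build_feature_map,
)
from rloopkit.landscape import (
    annotate_peaks,
    chromosome_density_ratio,
    distance_tests,
    feature_distribution,
    gc_cpg_profile,
    metagene_profile,
    overlap_fisher,
    sample_qc,
    tss_tts_split,
    welch_t,
)
from rloopkit.peaks import ConsensusPeakSet

from .conftest import make_readset, random_genes


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def consensus_from(intervals):
    ids = [f"peak_{i+1:05d}" for i in range(len(intervals))]
    return ConsensusPeakSet(
        peaks=list(intervals), ids=ids,
        support={i: frozenset({"s"}) for i in ids},
    )


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

class TestFeatureDistribution:
    def test_all_intronic(self):
        d = feature_distribution(["intron"] * 7)
        assert d["intron"] == 100.0
        assert d.sum() == pytest.approx(100.0, abs=1e-9)

    def test_even_split(self):
        d = feature_distribution(["promoter-TSS", "promoter-TSS", "TTS", "TTS"])
        assert d["promoter-TSS"] == 50.0 and d["TTS"] == 50.0

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            d = feature_distribution([])
        assert len(d) == 0

    def test_always_sums_to_100(self, rng):
        from rloopkit.intervals import CATEGORIES

        for _ in range(20):
            cats = rng.choice(CATEGORIES, size=int(rng.integers(1, 50)))
            assert feature_distribution(list(cats)).sum() == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy import stats

    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_formula_fixed_vectors(self):
        a = [27.5, 21.0, 19.0, 23.6, 17.0]
        b = [27.1, 22.0, 20.8, 23.4, 23.4]
        t, p = welch_t(a, b)
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0, rel=1e-12)
        assert p == pytest.approx(p0, rel=1e-12)

    def test_separated_samples_significant(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(5, 1, 40)
        _, p = welch_t(a, b)
        assert p < 1e-10


# ---------------------------------------------------------------------------
# Fisher overlap
# ---------------------------------------------------------------------------

def hypergeom_oracle(n_overlap, n_a, n_b, n_universe):
    """Exact upper-tail P(X >= n_overlap) by enumeration with math.comb."""
    total = 0
    denom = math.comb(n_universe, n_b)
    for k in range(n_overlap, min(n_a, n_b) + 1):
        total += math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k)
    return total / denom


class TestOverlapFisher:
    def test_exact_small_case(self):
        universe = set(range(10))
        a = set(range(5))
        b = {0, 1, 2, 3}
        ot = overlap_fisher(a, b, universe)
        assert ot.p_fisher == pytest.approx(1 / 42, rel=1e-10)

    def test_full_overlap_p_one(self):
        u = set(range(8))
        ot = overlap_fisher(u, u, u)
        assert ot.p_fisher == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            overlap_fisher({1, 99}, {1}, {1, 2, 3})

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(50):
            n_u = int(rng.integers(5, 200))
            n_a = int(rng.integers(1, n_u + 1))
            n_b = int(rng.integers(1, n_u + 1))
            ids = list(range(n_u))
            a = set(rng.choice(ids, size=n_a, replace=False).tolist())
            b = set(rng.choice(ids, size=n_b, replace=False).tolist())
            ot = overlap_fisher(a, b, set(ids))
            expect = hypergeom_oracle(ot.n_overlap, n_a, n_b, n_u)
            assert ot.p_fisher == pytest.approx(expect, rel=1e-10)

    def test_monotone_in_overlap(self):
        universe = set(range(50))
        ps = []
        for k in range(1, 11):
            a = set(range(10))
            b = set(range(k)) | set(range(30, 40 - k))
            ot = overlap_fisher(a, b, universe)
            ps.append(ot.p_fisher)
        assert all(x >= y - 1e-15 for x, y in zip(ps[:-1], ps[1:]))


# ---------------------------------------------------------------------------
# annotation, chromosome ratios, TSS/TTS split
# ---------------------------------------------------------------------------

class TestAnnotation:
    def test_neighbor_differs_from_nearest(self, toy_assembly, toy_genes):
        fmap = build_feature_map(toy_genes, toy_assembly)
        cps = consensus_from([iv(1000, 1500), iv(30_000, 30_400)])
        annot = annotate_peaks(cps, toy_genes, fmap)
        assert (annot["nearest_gene"] != annot["neighbor_gene"]).all()
        assert (annot["nearest_dist"] <= annot["neighbor_dist"]).all()

    def test_chromosome_ratio_zero_and_undefined(self, toy_assembly, toy_genes):
        fmap = build_feature_map(toy_genes, toy_assembly)
        cps = consensus_from([iv(1000, 1500), iv(2000, 2400), iv(100, 400, "chr2")])
        annot = annotate_peaks(cps, toy_genes, fmap)
        classes = {
            cps.ids[0]: "unchanged", cps.ids[1]: "unchanged", cps.ids[2]: "gain",
        }
        df = chromosome_density_ratio(annot, classes, toy_assembly).set_index("chrom")
        assert df.loc["chr1", "gain_ratio"] == 0.0
        # chr2 has a gain but zero unchanged -> undefined (inf sentinel)
        assert np.isinf(df.loc["chr2", "gain_ratio"])

    def test_split_all_tss(self):
        s = tss_tts_split(["TSS", "TSS", "TSS"])
        assert s["tss_fraction"] == 1.0

    def test_split_mixed(self):
        s = tss_tts_split(["TSS", "TTS", "TTS", "TTS"])
        assert s["tts_fraction"] == 0.75
        assert s["n"] == 4

    def test_distance_tests_constructed_difference(self, toy_assembly, toy_genes):
        fmap = build_feature_map(toy_genes, toy_assembly)
        # gains right at gene starts, unchanged far away in gaps
        near = [iv(g.interval.start, g.interval.start + 200) for g in toy_genes[:6]]
        far = [iv(95_000 + i * 500, 95_200 + i * 500) for i in range(6)]
        cps = consensus_from(near + far)
        annot = annotate_peaks(cps, toy_genes, fmap)
        classes = {}
        for pid in cps.ids[:6]:
            classes[pid] = "gain"
        for pid in cps.ids[6:]:
            classes[pid] = "unchanged"
        out = distance_tests(annot, classes)
        assert out["gain_vs_unchanged"]["p"] < 0.01
        assert out["gain_vs_unchanged"]["t"] < 0


# ---------------------------------------------------------------------------
# GC / CpG
# ---------------------------------------------------------------------------

class TestGcCpg:
    def make_asm(self, seq):
        return GenomeAssembly(("chr1",), {"chr1": len(seq)}, {"chr1": seq})

    def test_all_gc(self):
        asm = self.make_asm("GCGC" * 10)
        per_peak, _ = gc_cpg_profile([iv(0, 4)], asm, flank=2)
        assert per_peak["gc_percent"].iloc[0] == 100.0

    def test_acgt_example(self):
        asm = self.make_asm("ACGT" * 10)
        per_peak, _ = gc_cpg_profile([iv(0, 4)], asm, flank=2)
        assert per_peak["gc_percent"].iloc[0] == 50.0
        assert per_peak["cpg_rate"].iloc[0] == pytest.approx(1 / 3)

    def test_missing_sequence_errors(self, toy_assembly):
        with pytest.raises(ValueError):
            gc_cpg_profile([iv(0, 10)], toy_assembly)

    def test_positional_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        asm = self.make_asm(seq)
        _, positional = gc_cpg_profile([iv(4000, 4400), iv(6000, 6500)], asm, flank=500)
        sums = positional.sum(axis=1)
        assert np.allclose(sums, 1.0)


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

class TestMetagene:
    def make_gene(self, start, end, strand="+"):
        return GeneModel("g1", GenomicInterval("chr1", start, end, strand),
                         ((start, end),))

    def test_uniform_coverage_flat(self):
        rng = np.random.default_rng(0)
        genes = [self.make_gene(20_000, 40_000)]
        reads = [
            ("chr1", int(s), int(s) + 75)
            for s in rng.integers(0, 99_900, size=30_000)
        ]
        rs = make_readset(reads, condition="c")
        prof = metagene_profile([rs], genes).values["c"].to_numpy()
        body = prof[25:75]
        # uniform: each body bin (400 bp) ~ 120 reads -> RPM ~ 4000
        assert body.std() / body.mean() < 0.3
        assert abs(body.mean() - 4000) / 4000 < 0.2

    def test_reads_at_tts_edge(self):
        genes = [self.make_gene(20_000, 40_000)]
        reads = [("chr1", 39_900, 39_975)] * 100
        rs = make_readset(reads, condition="c")
        prof = metagene_profile([rs], genes).values["c"].to_numpy()
        assert np.argmax(prof) == 74  # last body bin

    def test_minus_strand_orientation(self):
        genes = [self.make_gene(20_000, 40_000, strand="-")]
        reads = [("chr1", 39_900, 39_975)] * 100  # at genomic end = gene 5' end
        rs = make_readset(reads, condition="c")
        prof = metagene_profile([rs], genes).values["c"].to_numpy()
        assert np.argmax(prof) == 25  # first body bin (TSS side)

    def test_subtract_self_is_zero(self):
        rng = np.random.default_rng(1)
        genes = [self.make_gene(20_000, 40_000)]
        reads = [
            ("chr1", int(s), int(s) + 75) for s in rng.integers(0, 99_900, 5000)
        ]
        rs = make_readset(reads, condition="c")
        prof = metagene_profile([rs], genes, subtract="c")
        assert np.allclose(prof.values["c"], 0.0)
        assert prof.control_subtracted

    def test_read_order_invariance(self):
        genes = [self.make_gene(20_000, 40_000)]
        rng = np.random.default_rng(2)
        reads = [
            ("chr1", int(s), int(s) + 75) for s in rng.integers(0, 99_900, 2000)
        ]
        p1 = metagene_profile([make_readset(reads, condition="c")], genes)
        p2 = metagene_profile([make_readset(reads[::-1], condition="c")], genes)
        assert np.allclose(p1.values["c"], p2.values["c"])


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

class TestSampleQC:
    def test_duplicated_sample_correlation_one(self, rng):
        counts = rng.poisson(40, size=(100, 2))
        counts[:, 1] = counts[:, 0]
        cm = CountMatrix(counts, [f"f{i}" for i in range(100)], ["a", "b"],
                         ["c", "c"])
        corr, _, _ = sample_qc(cm)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_correlation_matches_direct_formula(self):
        counts = np.array([[3, 10, 2, 8], [7, 1, 9, 4], [5, 5, 5, 6]])
        cm = CountMatrix(counts, ["f1", "f2", "f3"], list("wxyz"),
                         ["c"] * 4)
        cm.size_factors = np.ones(4)
        corr, _, _ = sample_qc(cm)
        y = np.log2(counts + 1.0)
        expect = np.corrcoef(y, rowvar=False)
        assert np.allclose(corr.to_numpy(), expect)

    def test_pc12_dominate_variance(self, rng):
        base = rng.poisson(100, size=(300, 1))
        counts = np.tile(base, (1, 6)).astype(float)
        counts[:100, :3] *= 3  # condition effect 1
        counts[100:200, 3:] *= 2  # condition effect 2
        cm = CountMatrix(counts.astype(int), [f"f{i}" for i in range(300)],
                         list("abcdef"), ["x"] * 3 + ["y"] * 3)
        _, pcs, var_exp = sample_qc(cm)
        assert var_exp[0] + var_exp[1] >= max(var_exp[2:]) * 2

    def test_too_few_samples_rejected(self):
        cm = CountMatrix(np.ones((5, 1), int), list("abcde"), ["s"], ["c"])
        with pytest.raises(ValueError):
            sample_qc(cm)
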