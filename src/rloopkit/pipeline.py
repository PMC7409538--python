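"""End-to-end orchestration: simulation -> peaks -> differential ->
landscape annotation -> RNA-seq differential -> antisense detection.

Every analysis table is written as TSV, headline numbers are collected in
``summary.json``, and a checksum manifest makes runs auditable.  The same
entry points back the CLI and real-data mode (user-supplied FASTA/GTF/BED).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .antisense import call_antisense_hits, intergenic_diff, make_flank_windows
from .differential import (
    ContrastSpec,
    classify,
    count_reads,
    estimate_dispersion,
    size_factors,
    wald_test,
)
from .intervals import build_feature_map, GenomicInterval
from .landscape import (
    annotate_peaks,
    chromosome_density_ratio,
    distance_tests,
    feature_distribution,
    gc_cpg_profile,
    metagene_profile,
    overlap_fisher,
    sample_qc,
    tss_tts_split,
)
from .peaks import build_consensus, call_broad_peaks, rnaseh_sensitivity
from .simulate import (
    ReadSet,
    SimulationConfig,
    TruthTable,
    _sha256,
    load_simulation,
    simulate_all,
    write_simulation,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters plus pointers to the input data."""

    simdir: str | None = None
    fasta: str | None = None
    chrom_sizes: str | None = None
    genes: str | None = None  # .gtf or .bed12, chosen by extension
    samples: list = field(default_factory=list)
    control_condition: str | None = None
    min_support: int = 1
    filter_rnaseh: bool = False
    rnaseh_threshold: float = 0.5
    peak_bin: int = 100
    peak_qcut: float = 0.1
    peak_merge_gap: int = 500
    peak_min_length: int = 200
    peak_local_bg: int = 5000
    drip_lfc: float = 1.0
    drip_fdr: float = 0.1
    rna_lfc: float = 1.0
    rna_fdr: float = 0.05
    antisense_full: int = 5000
    antisense_adjacent: int = 2000
    antisense_min_mean: float = 5.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineInputs:
    assembly: object
    genes: list
    drip_readsets: list
    rna_readsets: list
    truth: TruthTable | None = None


def load_inputs(config: RunConfig) -> PipelineInputs:
    if config.simdir:
        sim = load_simulation(config.simdir)
        return PipelineInputs(
            assembly=sim.assembly, genes=sim.genes,
            drip_readsets=sim.drip_readsets, rna_readsets=sim.rna_readsets,
            truth=sim.truth,
        )
    if config.fasta:
        assembly = rio.read_fasta(config.fasta)
    elif config.chrom_sizes:
        assembly = rio.read_chrom_sizes(config.chrom_sizes)
    else:
        raise ValueError("need simdir, fasta, or chrom_sizes")
    if not config.genes:
        raise ValueError("need a genes file (GTF or BED12)")
    if str(config.genes).endswith((".gtf", ".gff")):
        genes = rio.read_gtf(config.genes)
    else:
        genes = rio.read_bed12(config.genes)
    drip, rna = [], []
    for s in config.samples:
        rs = ReadSet.from_bed(
            s["path"], s["sample_id"], s.get("condition", ""),
            int(s.get("replicate", 1)), s["assay"],
        )
        (rna if s["assay"] == "RNAseq" else drip).append(rs)
    return PipelineInputs(assembly=assembly, genes=genes, drip_readsets=drip, rna_readsets=rna)


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def cmd_simulate(sim_config: SimulationConfig, outdir: str | Path) -> dict:
    result = simulate_all(sim_config)
    return write_simulation(result, outdir)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _pool_readsets(readsets, sample_id: str) -> ReadSet:
    return ReadSet(
        sample_id=sample_id, condition="pooled", replicate=0,
        assay=readsets[0].assay,
        chroms=np.concatenate([r.chroms for r in readsets]),
        starts=np.concatenate([r.starts for r in readsets]),
        ends=np.concatenate([r.ends for r in readsets]),
        strands=np.concatenate([r.strands for r in readsets]),
    ).sorted()


def cmd_run(config: RunConfig, outdir: str | Path, skip_existing: bool = False) -> dict:
    outdir = Path(outdir)
    if skip_existing and (outdir / "summary.json").exists():
        logger.info("summary.json present; skipping (skip-existing mode)")
        with open(outdir / "summary.json") as fh:
            return json.load(fh)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t_stage = time.perf_counter

    def tick(name: str, t0: float) -> None:
        timings[name] = round(t_stage() - t0, 3)

    t0 = t_stage()
    inputs = load_inputs(config)
    assembly, genes = inputs.assembly, inputs.genes
    ips = [r for r in inputs.drip_readsets if r.assay == "DRIP-IP"]
    input_rs_list = [r for r in inputs.drip_readsets if r.assay == "DRIP-input"]
    rnaseh_list = [r for r in inputs.drip_readsets if r.assay == "DRIP-RNaseH"]
    if not ips or not input_rs_list:
        raise ValueError("need DRIP-IP samples and a DRIP-input sample")
    input_rs = (
        input_rs_list[0] if len(input_rs_list) == 1
        else _pool_readsets(input_rs_list, "drip_input_pooled")
    )
    conditions = list(dict.fromkeys(r.condition for r in ips))
    control = config.control_condition or conditions[0]
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not among IP samples")
    knockdowns = [c for c in conditions if c != control]
    tick("load", t0)

    # --- peak calling ------------------------------------------------------
    t0 = t_stage()
    peak_lists = {}
    with open(outdir / "peak_calls.bed", "w") as fh:
        for rs in ips:
            calls = call_broad_peaks(
                rs, input_rs, assembly,
                bin_size=config.peak_bin, q_cut=config.peak_qcut,
                merge_gap=config.peak_merge_gap,
                min_length=config.peak_min_length,
                local_bg=config.peak_local_bg,
            )
            peak_lists[rs.sample_id] = calls
            for pc in calls:
                fh.write(
                    f"{pc.interval.chrom}\t{pc.interval.start}\t{pc.interval.end}"
                    f"\t{pc.sample_id}\t{pc.fold_enrichment:.4g}\t.\t{pc.qvalue:.4g}\n"
                )
    consensus = build_consensus(peak_lists, min_support=config.min_support)
    if rnaseh_list:
        pooled_ip = _pool_readsets(ips, "drip_ip_pooled")
        ratios, flags = rnaseh_sensitivity(
            consensus.peaks, consensus.ids, pooled_ip, rnaseh_list[0],
            threshold=config.rnaseh_threshold,
        )
        consensus.rnaseh_ratio, consensus.hybrid = ratios, flags
        if config.filter_rnaseh:
            keep = [i for i, pid in enumerate(consensus.ids) if flags[pid]]
            consensus.peaks = [consensus.peaks[i] for i in keep]
            kept_ids = [consensus.ids[i] for i in keep]
            consensus.support = {pid: consensus.support[pid] for pid in kept_ids}
            consensus.ids = kept_ids
    with open(outdir / "consensus_peaks.bed", "w") as fh:
        for pid, iv in zip(consensus.ids, consensus.peaks):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pid}"
                f"\t{len(consensus.support[pid])}\t."
                f"\t{consensus.rnaseh_ratio.get(pid, float('nan')):.4g}\n"
            )
    tick("peaks", t0)

    # --- DRIP differential -------------------------------------------------
    t0 = t_stage()
    cm = count_reads(consensus.peaks, ips, mode="any-overlap",
                     feature_ids=consensus.ids)
    size_factors(cm)
    cm.to_tsv(outdir / "drip_counts.tsv")
    alpha = estimate_dispersion(cm)
    drip_results: dict[str, pd.DataFrame] = {}
    for kd in knockdowns:
        contrast = ContrastSpec(
            treatment=kd, control=control,
            lfc_threshold=config.drip_lfc, fdr_threshold=config.drip_fdr,
        )
        res = classify(wald_test(cm, contrast, alpha), contrast)
        drip_results[kd] = res
        _write_tsv(res, outdir / f"drip_differential_{contrast.name}.tsv")
    tick("drip_differential", t0)

    # --- annotation + landscape -------------------------------------------
    t0 = t_stage()
    fmap = build_feature_map(genes, assembly)
    annot = annotate_peaks(consensus, genes, fmap)
    for kd, res in drip_results.items():
        annot[f"class_{kd}"] = annot["peak_id"].map(
            dict(zip(res["id"], res["class"]))
        )
    _write_tsv(annot, outdir / "peak_annotation.tsv")

    class_maps = {
        kd: dict(zip(res["id"], res["class"])) for kd, res in drip_results.items()
    }
    gain_sets = {
        kd: {pid for pid, c in cmap.items() if c == "gain"}
        for kd, cmap in class_maps.items()
    }
    loss_sets = {
        kd: {pid for pid, c in cmap.items() if c == "loss"}
        for kd, cmap in class_maps.items()
    }
    unchanged_all = {
        pid for pid in consensus.ids
        if all(cmap.get(pid) == "unchanged" for cmap in class_maps.values())
    }

    cat_by_peak = dict(zip(annot["peak_id"], annot["feature_category"]))
    side_by_peak = dict(zip(annot["peak_id"], annot["nearer_end"]))
    fd_rows = []
    subsets = {"unchanged_all": unchanged_all}
    for kd in knockdowns:
        subsets[f"gain_{kd}"] = gain_sets[kd]
        subsets[f"loss_{kd}"] = loss_sets[kd]
    for label, ids in subsets.items():
        if not ids:
            continue
        dist = feature_distribution([cat_by_peak[p] for p in sorted(ids)])
        for cat, pct in dist.items():
            fd_rows.append({"subset": label, "category": cat, "percent": pct})
    feature_dist_df = pd.DataFrame(fd_rows)
    _write_tsv(feature_dist_df, outdir / "feature_distribution.tsv")

    dist_test_rows = []
    for kd in knockdowns:
        tests = distance_tests(annot, class_maps[kd])
        for cmp_name in ("gain_vs_unchanged", "loss_vs_unchanged"):
            if cmp_name in tests:
                dist_test_rows.append(
                    {
                        "contrast": kd, "comparison": cmp_name,
                        "t": tests[cmp_name]["t"], "p": tests[cmp_name]["p"],
                    }
                )
    _write_tsv(pd.DataFrame(dist_test_rows), outdir / "distance_tests.tsv")

    chrom_rows = []
    for kd in knockdowns:
        df = chromosome_density_ratio(annot, class_maps[kd], assembly)
        df.insert(0, "contrast", kd)
        chrom_rows.append(df)
    _write_tsv(pd.concat(chrom_rows, ignore_index=True), outdir / "chromosome_ratios.tsv")

    universe = set(consensus.ids)
    fisher_rows = []
    for cls, sets in (("gain", gain_sets), ("loss", loss_sets)):
        for a, b in combinations(knockdowns, 2):
            ot = overlap_fisher(sets[a], sets[b], universe, a, b)
            fisher_rows.append(
                {
                    "class": cls, "set_a": a, "set_b": b,
                    "n_a": ot.n_a, "n_b": ot.n_b, "n_overlap": ot.n_overlap,
                    "n_universe": ot.n_universe, "odds_ratio": ot.odds_ratio,
                    "p_fisher": ot.p_fisher,
                }
            )
    overlap_df = pd.DataFrame(fisher_rows)
    _write_tsv(overlap_df, outdir / "overlap_fisher.tsv")

    split_rows = []
    split_subsets: dict[str, set] = {"consensus_all": universe}
    for kd in knockdowns:
        split_subsets[f"gain_{kd}"] = gain_sets[kd]
    for kd in knockdowns:
        others = [o for o in knockdowns if o != kd]
        only = gain_sets[kd] - set().union(*(gain_sets[o] for o in others)) \
            if others else gain_sets[kd]
        split_subsets[f"gain_{kd}_only"] = only
    for a, b in combinations(knockdowns, 2):
        split_subsets[f"gain_{a}&{b}"] = gain_sets[a] & gain_sets[b]
    if len(knockdowns) >= 3:
        split_subsets["gain_all_kd"] = set.intersection(
            *(gain_sets[kd] for kd in knockdowns)
        )
    for label, ids in split_subsets.items():
        split = tss_tts_split([side_by_peak[p] for p in sorted(ids)])
        split_rows.append({"subset": label, **split})
    tss_split_df = pd.DataFrame(split_rows)
    _write_tsv(tss_split_df, outdir / "tss_tts_split.tsv")

    if assembly.sequence is not None:
        per_peak, positional = gc_cpg_profile(consensus.peaks, assembly)
        per_peak.insert(0, "peak_id", consensus.ids)
        _write_tsv(per_peak, outdir / "gc_cpg_per_peak.tsv")
        positional.reset_index().to_csv(
            outdir / "nucleotide_positional.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

    for mode in ("all", "intergenic", "intronic"):
        prof = metagene_profile(ips, genes, mode=mode)
        prof.values.reset_index().to_csv(
            outdir / f"metagene_{mode}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        prof_sub = metagene_profile(ips, genes, mode=mode, subtract=control)
        prof_sub.values.reset_index().to_csv(
            outdir / f"metagene_{mode}_minus_{control}.tsv", sep="\t",
            index=False, float_format="%.6g",
        )

    corr, pcs, var_exp = sample_qc(cm)
    corr.reset_index(names="sample_id").to_csv(
        outdir / "drip_sample_correlation.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    pcs.reset_index(names="sample_id").to_csv(
        outdir / "drip_sample_pca.tsv", sep="\t", index=False, float_format="%.6g"
    )
    tick("landscape", t0)

    # --- RNA-seq differential ---------------------------------------------
    t0 = t_stage()
    rna_results: dict[str, pd.DataFrame] = {}
    gene_sf = None
    rna_cm = None
    if inputs.rna_readsets:
        rna_cm = count_reads(genes, inputs.rna_readsets, mode="strand-aware")
        gene_sf = size_factors(rna_cm)
        rna_cm.to_tsv(outdir / "rna_counts.tsv")
        rna_alpha = estimate_dispersion(rna_cm)
        for kd in knockdowns:
            contrast = ContrastSpec(
                treatment=kd, control=control,
                lfc_threshold=config.rna_lfc, fdr_threshold=config.rna_fdr,
            )
            res = classify(wald_test(rna_cm, contrast, rna_alpha), contrast)
            rna_results[kd] = res
            _write_tsv(res, outdir / f"rna_differential_{contrast.name}.tsv")
        rcorr, rpcs, _ = sample_qc(rna_cm)
        rcorr.reset_index(names="sample_id").to_csv(
            outdir / "rna_sample_correlation.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        rpcs.reset_index(names="sample_id").to_csv(
            outdir / "rna_sample_pca.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
    tick("rna_differential", t0)

    # --- antisense ---------------------------------------------------------
    t0 = t_stage()
    antisense_counts: dict[str, int] = {}
    all_hits = []
    if inputs.rna_readsets:
        for kd in knockdowns:
            contrast = ContrastSpec(treatment=kd, control=control)
            windows = make_flank_windows(
                annot, sorted(gain_sets[kd]), genes, assembly,
                full=config.antisense_full, adjacent=config.antisense_adjacent,
            )
            if not windows:
                antisense_counts[kd] = 0
                continue
            wdiff = intergenic_diff(
                windows, inputs.rna_readsets, contrast, genes, assembly, gene_sf
            )
            hits = call_antisense_hits(
                wdiff, drip_results[kd], rna_results[kd], contrast,
                min_mean=config.antisense_min_mean,
            )
            antisense_counts[kd] = len(hits)
            all_hits.append(hits)
            _write_tsv(wdiff, outdir / f"antisense_windows_{contrast.name}.tsv")
        non_empty = [h for h in all_hits if len(h)]
        hits_df = (
            pd.concat(non_empty, ignore_index=True)
            if non_empty
            else (all_hits[0] if all_hits else pd.DataFrame())
        )
        _write_tsv(hits_df, outdir / "antisense_hits.tsv")
    tick("antisense", t0)

    # --- summary -----------------------------------------------------------
    bp_by_peak = {pid: iv.length for pid, iv in zip(consensus.ids, consensus.peaks)}
    summary = {
        "control_condition": control,
        "conditions": conditions,
        "consensus_peak_count": len(consensus),
        "consensus_bp": consensus.total_bp(),
        "genome_fraction": consensus.total_bp() / assembly.total_length,
        "rnaseh_hybrid_fraction": (
            float(np.mean([consensus.hybrid[p] for p in consensus.ids]))
            if consensus.hybrid else None
        ),
        "contrasts": {
            kd: {
                "gain_count": len(gain_sets[kd]),
                "loss_count": len(loss_sets[kd]),
                "gain_bp": sum(bp_by_peak[p] for p in gain_sets[kd]),
                "loss_bp": sum(bp_by_peak[p] for p in loss_sets[kd]),
            }
            for kd in knockdowns
        },
        "overlaps": fisher_rows,
        "feature_distribution": fd_rows,
        "tss_tts_split": split_rows,
        "antisense_hits": antisense_counts,
        "rna_de_counts": {
            kd: {
                "up": int((res["class"] == "gain").sum()),
                "down": int((res["class"] == "loss").sum()),
            }
            for kd, res in rna_results.items()
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    if config.simdir and Path(config.simdir, "truth.json").exists():
        shutil.copy(Path(config.simdir, "truth.json"), outdir / "truth.json")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "timings_s": timings,
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# truth-vs-called comparison and report
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def peak_recovery(
    planted, called_intervals, min_reciprocal: float = 0.5
) -> tuple[int, int]:
    """(#planted recovered, #called matching a planted peak)."""
    recovered = 0
    matched_called = set()
    for p in planted:
        for i, iv in enumerate(called_intervals):
            if reciprocal_overlap(p.interval, iv) >= min_reciprocal:
                recovered += 1
                matched_called.add(i)
                break
    return recovered, len(matched_called)


def truth_confusion(results_dir: Path) -> list[str]:
    """Confusion summaries comparing calls with the planted truth."""
    truth = TruthTable.from_json(results_dir / "truth.json")
    annot = pd.read_csv(results_dir / "peak_annotation.tsv", sep="\t")
    lines = ["", "== Truth vs called (planted simulation) =="]
    peak_iv = {
        r.peak_id: GenomicInterval(r.chrom, r.start, r.end)
        for r in annot.itertuples(index=False)
    }
    class_cols = [c for c in annot.columns if c.startswith("class_")]
    for col in class_cols:
        kd = col[len("class_"):]
        called_gain = {
            r.peak_id for r in annot.itertuples(index=False) if getattr(r, col) == "gain"
        }
        planted_gain = [p for p in truth.peaks if p.log2fc.get(kd, 0) > 0]
        tp = 0
        for p in planted_gain:
            if any(
                reciprocal_overlap(p.interval, peak_iv[pid]) > 0
                for pid in called_gain
            ):
                tp += 1
        lines.append(
            f"{kd}: planted gains {len(planted_gain)}, recovered as gain {tp}, "
            f"called gains {len(called_gain)}"
        )
    hits_path = results_dir / "antisense_hits.tsv"
    if hits_path.exists() and truth.antisense:
        try:
            hits = pd.read_csv(hits_path, sep="\t")
        except pd.errors.EmptyDataError:
            hits = pd.DataFrame(columns=["gene_id", "side"])
        hit_keys = set(zip(hits.get("gene_id", []), hits.get("side", [])))
        side_label = {"TSS": "TSS-upstream", "TTS": "TTS-downstream"}
        found = sum(
            1 for a in truth.antisense if (a.gene_id, side_label[a.side]) in hit_keys
        )
        lines.append(
            f"antisense: planted {len(truth.antisense)}, detected {found}, "
            f"total hits {len(hits)}"
        )
    return lines


def cmd_report(results_dir: str | Path) -> str:
    """Render a plain-text report from the emitted tables."""
    results_dir = Path(results_dir)
    summary_path = results_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {results_dir}")
    with open(summary_path) as fh:
        summary = json.load(fh)

    lines = ["== R-loop pipeline report =="]
    lines.append(
        f"Consensus peaks: {summary['consensus_peak_count']} covering "
        f"{summary['consensus_bp']} bp "
        f"({100 * summary['genome_fraction']:.2f}% of the genome)"
    )
    if summary.get("rnaseh_hybrid_fraction") is not None:
        lines.append(
            f"RNase-H sensitive (hybrid) fraction: "
            f"{100 * summary['rnaseh_hybrid_fraction']:.1f}%"
        )
    lines.append("")
    lines.append("-- Gains / losses per knockdown --")
    for kd, d in summary["contrasts"].items():
        lines.append(
            f"{kd}: {d['gain_count']} gains ({d['gain_bp']} bp), "
            f"{d['loss_count']} losses ({d['loss_bp']} bp)"
        )
    if summary["overlaps"]:
        lines.append("")
        lines.append("-- Pairwise overlaps (Fisher) --")
        for row in summary["overlaps"]:
            lines.append(
                f"{row['class']} {row['set_a']} x {row['set_b']}: "
                f"overlap {row['n_overlap']} (|A|={row['n_a']}, |B|={row['n_b']}), "
                f"p={row['p_fisher']:.3g}"
            )
    fd = pd.DataFrame(summary["feature_distribution"])
    if len(fd):
        lines.append("")
        lines.append("-- Feature-category distribution (%) --")
        pivot = fd.pivot(index="category", columns="subset", values="percent")
        lines.append(pivot.round(1).to_string())
    ts = pd.DataFrame(summary["tss_tts_split"])
    if len(ts):
        lines.append("")
        lines.append("-- TSS/TTS proximity split --")
        lines.append(ts.round(3).to_string(index=False))
    if summary.get("antisense_hits"):
        lines.append("")
        lines.append("-- Antisense hits --")
        for kd, n in summary["antisense_hits"].items():
            lines.append(f"{kd}: {n} hits")
    if (results_dir / "truth.json").exists():
        lines.extend(truth_confusion(results_dir))
    report = "\n".join(lines) + "\n"
    with open(results_dir / "report.txt", "w") as fh:
        fh.write(report)
    return report
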