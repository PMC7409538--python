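# rloopkit

Genome-wide R-loop (DRIP-seq) analysis pipeline with a seeded,
planted-truth simulator. The package covers:

- **`intervals`** — 0-based half-open coordinate model, interval arithmetic
  (merge, distance, nearest/second-nearest gene ranking), single-transcript
  gene models, and a per-base feature-category partition of the genome
  (promoter-TSS / TTS / 5'UTR / 3'UTR / exon / intron / noncoding /
  intergenic).
- **`simulate`** — synthetic genome (GC/CpG-elevated promoters),
  non-overlapping gene models, DRIP IP / input / RNase-H read sets with
  planted enrichment peaks carrying per-condition log2 fold changes, and
  stranded RNA-seq with gene expression, a nascent intronic fraction and
  planted intergenic antisense loci. Ground truth is serialized alongside
  the data.
- **`peaks`** — deterministic Poisson local-background broad peak caller
  versus input (binned, BH-corrected, merged), RNase-H sensitivity
  flagging, and consensus-peak construction across samples.
- **`differential`** — read counting (interval / exonic / strand-aware),
  median-of-ratios size factors, trend-shrunk negative-binomial dispersion
  estimation, Wald tests, Benjamini-Hochberg FDR, and gain/loss/unchanged
  classification (|log2FC| > 1, FDR < 0.1 for DRIP; FDR < 0.05 for RNA).
- **`landscape`** — peak annotation (nearest/neighbor genes, feature
  category, TSS-vs-TTS side), feature-category distributions, Welch
  distance tests, per-chromosome gain/loss density ratios, hypergeometric
  overlap tests, GC%/CpG and positional nucleotide profiles, metagene
  coverage (all / intergenic / intronic reads, optional control
  subtraction), and sample QC (Pearson correlation + PCA).
- **`antisense`** — intergenic masking, 5-kb/2-kb flank windows beside the
  TSS/TTS of genes anchoring gain peaks, window-level differential
  testing, the four-threshold antisense hit caller, and strand-purity
  orientation calls (antisense vs sense read-through).
- **`pipeline` / `cli`** — end-to-end orchestration with TSV/BED/JSON
  outputs, a checksum manifest, and a plain-text report including
  truth-vs-called confusion tables on simulated data.

## Quick start (synthetic demo)

```sh
# generate a 10 Mb, 300-gene demo dataset with planted peaks + antisense loci
rloopkit simulate --out demo_sim --seed 1

# run the full analysis (peaks -> differential -> landscape -> antisense)
rloopkit run --simdir demo_sim --out demo_results

# render a report (includes truth-vs-called confusion tables)
rloopkit report demo_results
```

`simulate` accepts a YAML/JSON config overriding any `SimulationConfig`
field; `run` accepts a YAML/JSON `RunConfig` (`--config`) for real-data
mode, pointing at a FASTA (or chrom-sizes TSV), a GTF/BED12 gene file
(the longest transcript per gene is used), and per-sample BED6 read
files tagged with condition/replicate/assay. Exit codes: 0 ok, 1 user
error, 2 internal error.

Key result files in the output directory: `consensus_peaks.bed`,
`drip_differential_<kd>_vs_<ctl>.tsv`, `peak_annotation.tsv`,
`feature_distribution.tsv`, `distance_tests.tsv`,
`chromosome_ratios.tsv`, `overlap_fisher.tsv`, `tss_tts_split.tsv`,
`gc_cpg_per_peak.tsv`, `metagene_*.tsv`, `rna_differential_*.tsv`,
`antisense_windows_*.tsv`, `antisense_hits.tsv`, `summary.json`,
`manifest.json`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: brute-force oracle
equivalence for the statistical primitives, feature-map conservation,
planted-peak recovery (sensitivity/precision), differential calibration
and power, antisense parameter recovery, qualitative landscape patterns,
and end-to-end byte-reproducibility.

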