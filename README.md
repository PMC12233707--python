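# tdrprof

Profiling of tRNA-derived small RNAs (tDRs) from small-RNA sequencing:
from adapter-ligated reads to fragment-level classification (5'-halves,
G-1/G1 start isoforms), proportional distributions, negative-binomial
differential abundance across timepoints, and PCA / heatmap / volcano
summaries. A built-in synthetic-data generator produces complete
libraries with ground truth, so every stage is testable end to end.

The package is written for small-RNA biologists studying stress- or
differentiation-induced tRNA cleavage — the motivating design is a
monocyte-to-macrophage differentiation time course (0/6/24 h, three
replicates) in which the 5'-half of tRNA-His-GUG dominates its family,
is strongly downregulated at the late timepoint, and shifts from its
G-1-starting isoform to the canonical G1 isoform.

## The model in brief

Fragments live in mature-tRNA coordinates: body positions `1..L`, CCA
at `L+1..L+3`, and the post-transcriptional His guanosine at `-1`
(there is no position 0). A fragment is a (family, start, end) triple,
named like `G-1-G34` or `G1-G34`. Classification follows angiogenin
anatomy: 5'-halves run from the 5' end (start <= 1) into the anticodon
loop window `[anticodon_start - 2, anticodon_start + 5]`; 3'-halves
from the loop to the (CCA-tolerant) 3' terminus; shorter anchored
species are 5'/3'-tRFs; the rest is internal.

Mapping is exact and hierarchical (tRNA, then rRNA, then unmapped),
with multi-family hits weighted 1/k. Differential abundance uses
median-of-ratios size factors s_j, a method-of-moments NB dispersion
α̂ = (s² − m̄)/m̄² pooled within groups, group means μ_g of normalized
counts (pseudocount 0.5), and the Wald statistic

    W = log2(μ_B/μ_A) / se,   se² = Σ_g (1/μ_g + α̂) / (n_g ln²2),

with a two-sided t reference (n_A + n_B − 2 df) and Benjamini-Hochberg
adjustment. See `docs/methods.md` for every convention and its
rationale.

## Worked example

Simulate a study and run the full pipeline on it:

```bash
tdrprof simulate --seed 1 --outdir sim
tdrprof init-config --out run.yaml
# edit run.yaml: fastq_dir: sim/fastq, design_table: sim/design.tsv,
#                refdir: sim/ref, outdir: out,
#                adapter_3p: TGGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG
tdrprof all --config run.yaml
```

which prints

```
simulated 382743 reads across 9 samples in sim
wrote 35 outputs to out
```

and leaves, under `out/`: `mapping_summary.tsv` (per-sample tRNA /
rRNA / unmapped read totals), `fragments.tsv` (one row per named,
classified fragment with per-sample weighted counts),
`five_half_fraction.tsv` and `first_base_split.tsv`, `count_matrix.tsv`
and `size_factors.tsv`, `de_6h_vs_0h.tsv` / `de_24h_vs_0h.tsv`,
`pca.tsv`, `heatmap_His-GUG.tsv`, `volcano_24h_vs_0h.tsv`,
`family_trends.tsv`, and a `manifest.json` of content hashes
(re-running the same config reproduces them byte-for-byte).

On this simulation (seed 1) the headline biology reads out in
`de_24h_vs_0h.tsv` as

```
fragment          log2fc      padj
His-GUG:G-1-G34   -2.64       0.10
```

— a ~6-fold drop of the G-1-starting His half at 24 h (programmed
truth: -3.22; at n = 3 with a noisy unshrunk dispersion the adjusted p
is weak even for a large fold change, which is why the methods note
recommends fold-change ranking at this sample size). The His-GUG
5'-half fraction stays above 81% at every timepoint, and the G-1 share
of half reads falls from ~68% (0 h) to ~31% (24 h), matching the
programmed 70% -> 30% shift within counting noise.

In Python the same stages are plain functions:

```python
from tdrprof import SimConfig, simulate_library, PipelineConfig, run_all

cfg = SimConfig(seed=1)
truth = simulate_library(cfg, "sim")
run_all(PipelineConfig(fastq_dir="sim/fastq", design_table="sim/design.tsv",
                       refdir="sim/ref", outdir="out",
                       adapter_3p=cfg.adapter_3p))
```

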