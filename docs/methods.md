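# Methods

`tdrprof` quantifies tRNA-derived small RNAs (tDRs) from single-end,
3'-adapter-ligated small-RNA sequencing libraries and tests their
differential abundance across timepoints of a stimulus (the motivating
design is PMA-driven THP-1 monocyte-to-macrophage differentiation,
sampled at 0, 6 and 24 h with three biological replicates each). This
note records the model, the conventions, and the choices made where the
design was genuinely open.

## Coordinate convention and the reference model

All fragments are named in mature-tRNA coordinates. Body position 1 is
the first nucleotide of the mature body; the 3'-CCA (added
post-transcriptionally and present on all mature tRNAs) occupies
positions `body_len+1 .. body_len+3`. tRNA-His carries one extra
guanosine added post-transcriptionally upstream of position 1; it is
labelled **-1**, and label 0 does not exist internally. Fragment length
is always the number of labelled positions covered, computed through
the label-offset bijection — never by label subtraction, which would be
off by one across the -1/+1 gap (the G-1..G34 half is 35 nt, not 36).
Some figure conventions alias the -1 G as "position 0"; writers accept
a `minus1_as_zero` display flag for that, but the internal label is
always -1.

Input references are intron-free tRNA bodies plus a metadata table
(family, anticodon start). CCA is appended at load time
(`assume_cca_present` skips this for references that already carry it);
the -1 G is prepended for His families. Isodecoders whose mature
sequences are identical are merged into one record; isodecoders of the
same family with *different* mature sequences are rejected with an
instruction to disambiguate, because the pipeline quantifies at family
level. Bodies longer than 120 nt are rejected — they indicate
unspliced or genomic input, which is out of scope. All sequences are
normalised to the DNA alphabet (U -> T), matching the read alphabet.

## Read preparation

The library geometry is a 5' adapter upstream of the sequencing primer
(never read) and a 3' adapter ligated downstream of the insert, so only
3' trimming is needed. With 55-bp and 63-bp adapters and the 20-50-nt
insert window, amplified cDNA products span 138-168 bp
(`expected_cdna_bounds`). Trimming is exact-match: the leftmost full
adapter occurrence, else the longest adapter prefix (at least
`min_overlap = 7` nt) terminating the read. There is no quality
trimming and no mismatch tolerance: the entire analysis path is
exact-match, which keeps it deterministic and makes every downstream
stage testable against a brute-force oracle. Inserts containing N are
discarded (they could never exact-match) and counted separately. Read
conservation (`n_input = kept + no_adapter + with_N + length_fail`)
holds exactly per file and is logged per stage.

## Hierarchical mapping

Collapsed inserts are searched, exactly, in this priority order: all
mature tRNA sequences, then mature rRNA (a sink with no coordinates
kept), then unmapped. The order is total — an insert present in both a
tRNA and an rRNA is a tRNA read. Multi-mapping policy: hits are
collapsed to distinct (family, start); when one family retains several
starts the count goes to the 5'-most start (logged when triggered), and
each surviving family receives weight 1/k, so per-insert weights always
sum to 1 and total tRNA read mass is conserved to numerical precision.

## Fragment classes

Angiogenin produces halves by cleaving in the anticodon loop. The loop
window is `[anticodon_start - 2, anticodon_start + 5]` in body
coordinates — 8 nt covering the canonical loop. Classes, applied in
fixed precedence so they partition all (start, end) keys:

- **5'-half**: start <= 1 (admitting the His -1 isoform) and end inside
  the loop window;
- **3'-half**: end within 3 nt of the mature 3' terminus (CCA-trimming
  heterogeneity tolerance) and start inside the window;
- **5'-tRF**: start <= 1, end before the window;
- **3'-tRF**: 3'-anchored, start after the window;
- **internal**: everything else (including near-full-length species).

Proportions (the 5'-half fraction of a family, and the G-1 vs G1 first
base split of its 5'-half reads) are read-count weighted, not species
weighted, and are reported NA (not 0) for empty denominators.

## Differential abundance

A deliberately simple estimator in the DESeq2 family, aimed at
simulation calibration rather than parity with any package:

- **Size factors**: median-of-ratios over fragments positive in all
  samples, rescaled to geometric mean 1; total-count fallback (with a
  warning) when no such fragment exists.
- **Dispersion**: per-fragment method-of-moments on normalised counts,
  `alpha = clamp((s^2 - m) / m^2, 1e-8, 10)`. The Wald test uses the
  pooled within-group residual variant (df = n_A + n_B - 2); per-group
  estimates at n = 3 are too unstable.
- **Test**: group means with pseudocount 0.5 (finite log2FC for zero
  groups), `log2FC = log2(mu_B / mu_A)`, delta-method
  `se^2 = sum_g (1/mu_g + alpha) / (n_g ln^2 2)`, statistic
  `W = log2FC / se`. The p-value is two-sided from a **t distribution
  with n_A + n_B - 2 df**: with a 4-df variance estimate a normal
  reference is visibly anticonservative (measured ~12% raw p < 0.05
  under the null at alpha = 0.1), while the t reference lands at ~5%,
  inside the intended 3-8% band. No shrinkage, no Cook's filtering, no
  independent filtering, no trended dispersion.
- **Multiple testing**: Benjamini-Hochberg step-up (scipy), NAs passed
  through. Significance labels use `padj < 0.05` and `|log2FC| >= 1`,
  both configurable; fractional multi-map counts are rounded
  half-to-even before modelling.

pydeseq2 serves as a non-gating cross-check: per-fragment log2FC on a
simulated matrix is compared and written out as a report in the test
suite.

## Profiles

Variance stabilisation is `log2(count / size_factor + 1)` — monotone,
simple, and exactly equivariant to normalisation (the formula is a
declared choice; heatmap z-scores are computed on this scale and the
output metadata says so). PCA centres features and projects samples,
with a deterministic sign convention (largest-magnitude loading
positive). PCA uses tRNA-mapped fragments only. Heatmaps are row-wise
z-scores of the top-20 fragments per family (total-count ranking, ties
lexicographic), row-ordered by average-linkage hierarchical clustering
on Euclidean distance; constant rows are emitted as zeros and placed
last. Volcano tables group fragments as HisGUG / LysCUU / other.

## The synthetic-data generator

The generator defines the study conditions the tests and calibration
run under: 3 timepoints x 3 replicates; 20-50-nt inserts drawn from
mature coordinates of a toy reference (His-GUG with the -1 G, Lys-CUU,
Glu-CUC, four further families with random 72-76-nt bodies, one 120-nt
rRNA decoy); counts are negative binomial with per-fragment dispersion
alpha = 0.1 (typical of small-RNA-seq replicates) and multiplicative
per-sample depth jitter uniform on [0.8, 1.2]; reads are insert +
63-nt 3' adapter truncated to 75 nt, error-free, constant Q40.

The default fragment roster (~45k reads/sample in expectation) encodes
the qualitative biology the pipeline must recover: the His-GUG 5'-half
dominates its family (>80% of family reads at every timepoint, dipping
at 24 h), is jointly downregulated ~2 log2 units at 24 h, and shifts
from the G-1-starting isoform toward the canonical G1 isoform
(first-base split 0.70 -> 0.50 -> 0.30 across 0/6/24 h); Lys-CUU
fragments are heterogeneous without a consistent direction; Glu-CUC and
other families carry mixed up/down effects that give the timepoints
separable multivariate profiles.

The generator audits itself by brute-force substring search: every
configured insert must occur exactly once in the tRNA space (so mapping
is unique and the round trip is exact), decoys must not occur in the
tRNAs, and every read must survive the adapter trim round trip;
generation retries with derived seeds until the audit passes. Because
reads are error-free and matching is exact, pipeline fragment counts
equal the simulated truth **exactly** — the round-trip test tolerates
zero mismatch.

What the generator does not emulate: sequencing errors and quality
variation, 2',3'-cyclic-phosphate ligation chemistry (all simulated
fragments are declared ligatable, standing in for the T4 PNK
end-repair), isodecoder sequence diversity within a family,
modification-induced misincorporation, and genome-scale mapping
ambiguity. Passing tests therefore demonstrate the correctness of the
analysis logic under its stated assumptions, not robustness to
real-library noise.

## Calibration measurements and problem sizes

- **Null calibration**: 2,000 unregulated NB fragments (alpha = 0.1,
  means lognormal around 200), n = 3 vs 3; raw p < 0.05 expected for
  3-8% of fragments.
- **Spike recovery**: 50 fragments at mean 500 with true log2FC = -2;
  mean estimate within +/-0.3.
- **Size-factor recovery**: 200-fragment unregulated roster per seed
  (a power analysis shows the 19-fragment default roster cannot
  resolve +/-20% depth jitter at alpha = 0.1: the median-of-ratios
  standard error ~0.09 rivals the jitter spread), 20 seeds; mean
  Spearman between estimated factors and true depth factors >= 0.9.
- **Proportion recovery**: Poisson fragments (alpha = 0) totalling
  ~10,000 family reads, so conditional class splits are exactly
  binomial; estimates must fall in the exact binomial 99% interval.
- **PCA structure**: 10 seeded default simulations; mean
  within-timepoint PC1-PC2 distance below mean between-timepoint
  distance in at least 9.

## Degenerate inputs and numerical conventions

Zero-count families yield NA proportions; all-zero fragments are
excluded from dispersion and testing (NA rows) and from size-factor
medians; constant heatmap rows become zero vectors placed last;
p-values are clipped into (0, 1]; collapsed outputs sort by descending
count then sequence, and all exports have deterministic row order, so
re-running a fixed configuration reproduces byte-identical outputs
(verified by content hash in the run manifest).

## Known limitations

Exact matching undercounts fragments from modified or edited tRNAs;
family-level quantification cannot separate isodecoders; the dispersion
estimator is unshrunk and noisy at n = 3 (fold-change ranking is more
reliable than individual p-values); the 8-nt loop window is a fixed
geometric convention, not a per-tRNA structural call; and 5'/3'
classification assumes single-cleavage products of mature tRNAs
(pre-tRNA leaders/trailers are out of scope).
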