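# Methods

`secrc` implements a complete desk-scale pipeline for identifying
super-enhancers (SEs) from H3K27ac ChIP-seq peak calls and inferring the
core regulatory circuitry (CRC) of SE-driven transcription factors, across
multiple tumor types. This note documents the model, its parameters, the
numerical choices, and what the synthetic data can and cannot show.

## Enhancer definition and signal

Enhancers are significant H3K27ac peaks (p < `p_threshold`, default 1e-9,
strict inequality on the MACS2 −log10 p column) whose midpoint lies
strictly more than `min_tss_distance` (default 2,500 bp) from every
annotated TSS. Distance is anchored at the peak midpoint, for symmetry
with the signal window, which is the midpoint ±5 kb (clamped at the
chromosome start; only there may a window be shorter than 10 kb).

The enhancer signal is the mean, over `bin_size` (default 100 bp) bins of
the window, of the number of aligned fragments overlapping each bin, scaled
to fragments per million (FPM). A fragment overlapping k bins counts once
in each; no length weighting. Two consequences are used as invariants:
the signal is unchanged by uniform duplication of all fragments, and it is
a continuous quantity even for sparse tracks. Counting *fragments* per bin
(rather than peak calls) is the only reading under which a per-bin average
behaves as a signal; the alternative would be almost surely 0/1 per bin.

For sample-similarity analysis the genome is tiled into `corr_bin_size`
(default 2 kb) bins; per-sample FPM bin counts are compared by Pearson
correlation without transformation (a `log1p` option exists but is off by
default). Rows with zero variance are an error, named by sample.

## Super-enhancer calling

Enhancers of one sample within `stitch_distance` (default 12.5 kb,
boundary inclusive — "within") of each other are merged transitively into
stitched enhancers; the stitched signal is the **sum** of constituent
signals (the cumulative-signal convention of rank-based SE callers; the
alternative mean convention compresses the dynamic range and is not used).

Stitched entities are sorted by signal; with ranks and signals both scaled
to [0, 1], the SE/TE threshold is the point where the tangent slope of the
ascending curve reaches 1. For a convex increasing curve this is exactly
`argmin(y − x)`, which is what the implementation computes — it is
noise-robust, unlike finite differences, which are kept only as a test
oracle. Entities with signal strictly greater than the cutoff entity's
signal are super-enhancers; ties at the cutoff signal are typical. Labels
are invariant under positive rescaling of all signals. All signals equal
is a degenerate curve and an error.

## Cross-tumor merging and classification

Per tumor type, SE intervals from different cell lines are unioned when
they share at least one base (transitively; bookended intervals do not
merge), and merged entities seen in fewer than `min_cell_lines` (default 2)
distinct cell lines are dropped. Each merged SE is assigned to the gene
with the TSS nearest its center (unbounded distance, same chromosome,
ties to the lexicographically smaller symbol, for determinism).

A gene's frequency is the number of distinct tumor types (not cell lines)
in which it has a merged SE; with eight types, frequency > 6 is
"conservative", exactly 1 "specific", otherwise "intermediate". TFs are
classified identically from per-type motif-enrichment calls at thresholds
> 4 / == 1. Optional expression summaries report per-gene, per-type mean
FPKM; genes absent from the matrix are listed as missing, never zeroed.

## NFRs, motif scanning, enrichment

Nucleosome-free regions are taken from a provided BED and intersected with
the constituent peaks of called SEs (the faithful path). A self-contained
valley caller is also provided: inside a constituent, a maximal run of
≥ 50 bp with coverage below 0.25× the constituent's peak coverage, flanked
on both sides by positions reaching 0.5× peak.

PWMs are read from JASPAR-style PFM text with a +1 pseudocount per cell
(avoids −∞ log-odds) and uniform background. Scanning scores each window
as Σ log2(p/background) on both strands; a hit requires at least
`motif_threshold` (default 0.8) of the motif's maximum attainable score.
Windows containing N never match. The degenerate uniform PWM (max score
0) matches every N-free window by construction; this is documented rather
than special-cased. Enrichment of SE NFRs versus non-SE NFRs is a
hypergeometric upper tail on per-sequence hit indicators; being discrete,
its null is slightly conservative (empirically P(p ≤ 0.05) ≈ 0.034–0.042
at the calibration design used in the tests).

## CRC construction

Nodes are TFs that (i) have a PWM in the library and (ii) are the assigned
target gene of a merged SE in the tumor type. Edge u → v exists iff u's
motif hits any NFR of v's SE; u is autoregulated iff u → u. Candidate
circuitries are maximal sets of autoregulated TFs with all ordered pairs
present (equivalently, maximal cliques of the mutual-regulation undirected
graph, enumerated with Bron–Kerbosch via networkx). A TF's score is the
fraction of enumerated cliques (size ≥ `min_clique_size`, default 2)
containing it; a clique's score is the mean of member scores. This
frequency-based score is a design choice: the upstream literature names a
"highest score" without a formula.

## Synthetic study conditions

Defaults model 8 tumor types × 3 cell lines on one 5 Mb chromosome.
Loci occupy 65 kb slots: 5 shared SEs (all types), 3 TF-gene SEs carrying
the planted TFA/TFB/TFC motif triad in their NFRs (all types), 2
type-specific SEs per type, and 20 typical enhancers. An SE is a cluster
of 4 constituent peaks spaced 3 kb apart at 8× the typical fragment rate
(`constituent_signal_fold`); each locus's target gene TSS sits 11 kb from
the last constituent midpoint (outside the 2.5 kb filter, nearest by a
wide margin). Decoy promoter-proximal peaks (1 kb from each TSS) are
planted in every sample to exercise the TSS filter, and low-significance
peaks (−log10 p = 5) to exercise the significance filter. Two decoy PWMs
assigned to shared genes are present in the library but never planted, so
CRC inference must reject them as non-autoregulated.

Each sample draws 50,000 fragments of fixed 200 bp: 10% uniform
background, the rest multinomially allocated across active enhancer units
proportional to rate, with centers Normal(midpoint, 500 bp). These sizes
keep a full 24-sample run under ~15 s while leaving the SE/TE signal
contrast (~30×) and the within- vs between-type correlation structure
clearly resolvable. Motif planting uses consensus insertion (10-mers,
mutually distinct on both strands), guaranteeing hits at any threshold
≤ 1. All randomness derives from one `numpy` SeedSequence, so outputs are
byte-deterministic per seed.

What the generator does **not** emulate: read-level noise (duplicates, GC
and mappability bias), multiple chromosomes, irregular peak shapes,
partially overlapping SE boundaries between cell lines, and biological
between-sample variation beyond multinomial sampling. Passing the planted
recovery checks therefore demonstrates correctness of the interval
arithmetic, ranking geometry, classification logic, and network inference
— not calling performance on real ChIP-seq.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open throughout; GTF converted on read.
- BED peaks without a p-value column carry a +∞ sentinel ("pre-filtered").
- Zero-length intervals, unknown strands, unequal PFM rows, fragments
  beyond chromosome ends, zero-depth tracks, and zero-variance correlation
  rows are errors, not silent fixes.
- Pipeline outputs are plain TSV/BED with '#' headers, floats at %.6g;
  manifests carry no timestamps, so reruns are byte-identical.

## Problem sizes used in the checks

Oracle-equivalence checks use 100 seeded random instances per operation
(n ≤ 200 intervals; digraphs of ≤ 10 nodes against exhaustive subset
enumeration); the tangent check uses 10,001 points of y = x³ against the
analytic slope-1 point 1/√3; null calibration uses 2,000 replicates of
250 + 250 random 80-mers; planted recovery uses the full default synthetic
conditions above.
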