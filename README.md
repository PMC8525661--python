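# secrc

Super-enhancer calling and core-regulatory-circuitry analysis for
multi-tumor H3K27ac ChIP-seq studies.

Super-enhancers (SEs) are clusters of active enhancers with exceptionally
high aggregate H3K27ac signal that drive cell-identity and oncogene
expression. A handful of SE-driven transcription factors (TFs) that bind
their own and each other's SEs — an autoregulated, fully interconnected
*core regulatory circuitry* (CRC) — often sits at the top of a tumor's
transcriptional program. `secrc` implements the full downstream analysis
for such a study, starting from per-sample peak calls and fragment tracks
(everything after read alignment and peak calling):

1. **Enhancer definition** — significant peaks (p < 10⁻⁹) farther than
   2.5 kb from any TSS, expanded to midpoint ±5 kb; signal = mean per-100 bp-bin
   fragments-per-million.
2. **Sample similarity** — Pearson correlation of depth-normalized 2 kb
   genome-bin counts (same-type samples cluster together).
3. **SE calling** — ROSE-style stitching of enhancers within 12.5 kb and
   the hockey-stick rank curve: with ranks and signals scaled to [0, 1],
   the slope-1 tangent point (argmin of y − x) splits SEs from typical
   enhancers.
4. **Cross-tumor analysis** — SEs unioned across cell lines per tumor
   type (kept if seen in ≥ 2 lines), assigned to nearest-TSS target genes;
   genes with SEs in > 6 of 8 tumor types are *conservative*, in exactly 1
   *specific* (TFs likewise at > 4 / = 1).
5. **CRC inference** — PWM log-odds scanning of nucleosome-free regions
   (NFRs) on SE constituents, hypergeometric motif enrichment, and
   enumeration of maximal cliques of autoregulated, mutually regulating
   TFs, scored by clique-membership frequency.

A synthetic-data generator plants SEs, decoy promoter peaks, NFRs, and a
known 3-TF clique on a toy genome so that every stage is testable without
any download; see `docs/methods.md` for the model details.

## Worked example

Generate a synthetic 8-tumor-type study (24 samples) and run every stage:

```sh
secrc synth --seed 7 --out demo/
# -> wrote synthetic inputs for 24 samples to demo/
#    (80 planted SE/tumor pairs, clique TFA+TFB+TFC)

cat > config.yaml <<EOF
peaks_dir: demo/peaks
fragments_dir: demo/fragments
tss: demo/tss.bed
genome: demo/genome.fa
nfr: demo/nfr.bed
pwm: demo/motifs.pfm
samples: demo/samples.tsv
chrom_sizes: demo/chrom.sizes
out_dir: demo_run
seed: 7
EOF
secrc all --config config.yaml
```

This takes about ten seconds and writes `enhancers.bed`,
`correlation.tsv`, `ses.bed`, `hockey.tsv`, `merged_ses.bed`,
`gene_freq.tsv`, `tf_freq.tsv`, `enrichment.tsv`, `crc_edges.tsv`,
`cliques.tsv` and `manifest.json` under `demo_run/`. The merged SE table
recovers all 80 planted SEs, e.g.:

```
chrom  start   end     tumor_type  cell_line_count  cell_lines
chr1   55000   74000   bladder     3                bladder_cl1,bladder_cl2,bladder_cl3
chr1   120000  139000  bladder     3                bladder_cl1,bladder_cl2,bladder_cl3
```

`gene_freq.tsv` classifies the shared-SE genes as conservative (SEs in
all 8 tumor types) and the single-type genes as specific:

```
gene_symbol  frequency  category      tumor_types
CONS1        8          conservative  bladder,breast,colorectal,...
SPEC_BLADDER_1  1       specific      bladder
```

and `cliques.tsv` reports the planted autoregulated triad as the
top-scored clique in every tumor type:

```
tumor_type  clique_rank  members      size  clique_score
bladder     1            TFA,TFB,TFC  3     1
```

Each stage is also available as its own subcommand (`secrc enhancers`,
`secrc rose`, `secrc merge`, `secrc genes`, `secrc crc`, ...), and the
same functionality is importable (`secrc.stitch`, `secrc.rank_and_cutoff`,
`secrc.build_crc`, ...).

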