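"""Synthetic toy-genome generator with planted ground truth.

Emulates the statistical structure of a multi-tumor H3K27ac ChIP-seq study
on a single small chromosome: clusters of high-signal enhancer peaks
(planted super-enhancers, shared across tumor types or specific to one),
isolated typical enhancers, decoy promoter-proximal peaks that the TSS
filter must remove, nucleosome-free regions inside SE constituents, and a
fully interconnected autoregulated 3-TF motif clique planted into the NFRs
of three TF-gene SEs.  Every pipeline input format (FASTA, narrowPeak,
BED, PFM, chrom.sizes, sample sheet) is written, together with a JSON
ground-truth record.

What it does not emulate: read-level noise (duplicates, GC bias, mappability),
multiple chromosomes, and inter-sample batch effects beyond Poisson-level
fragment sampling.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .core_io import GenomicInterval

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "truth_compare", "TUMOR_TYPE_NAMES"]

TUMOR_TYPE_NAMES = [
    "gastric",
    "renal",
    "esophageal",
    "colorectal",
    "bladder",
    "breast",
    "lung",
    "liver",
]

CHROM = "chr1"
SLOT_WIDTH = 65_000
SLOT_MARGIN = 50_000
CONSTITUENT_SPACING = 3_000
PEAK_HALF_WIDTH = 500
NFR_HALF_WIDTH = 60
ENHANCER_FLANK = 5_000
FRAGMENT_LENGTH = 200
FRAGMENT_SD = 500.0
BACKGROUND_FRACTION = 0.10

# Planted motif consensus sequences (10-mers, mutually distinct on both
# strands).  The triad TFA/TFB/TFC forms the planted clique; the two decoy
# motifs are assigned to shared-SE genes and are never planted, so the
# corresponding TFs must come out non-autoregulated.
TRIAD_CONSENSI = {"TFA": "ACGGATTACC", "TFB": "TGACGTCAAG", "TFC": "CATGGCACTT"}
DECOY_CONSENSI = {"CONS1": "AGGTCATTGC", "CONS2": "CCATATGGTC"}
MOTIF_COUNT_HIGH = 18  # consensus base count per PFM column
MOTIF_COUNT_LOW = 1


@dataclass
class SyntheticConfig:
    n_tumor_types: int = 8
    cell_lines_per_type: int = 3
    genome_length: int = 5_000_000
    n_shared_ses: int = 5
    n_specific_ses_per_type: int = 2
    n_typical: int = 20
    fragments_per_sample: int = 50_000
    se_constituents: int = 4
    constituent_signal_fold: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_tumor_types,
            self.cell_lines_per_type,
            self.genome_length,
            self.n_shared_ses,
            self.n_typical,
            self.fragments_per_sample,
            self.se_constituents,
        ]
        if any(c <= 0 for c in counts) or self.n_specific_ses_per_type < 0:
            raise ValueError("all synthetic counts must be positive")
        if self.constituent_signal_fold <= 1:
            raise ValueError("constituent_signal_fold must exceed 1")

    @property
    def tumor_types(self) -> List[str]:
        names = list(TUMOR_TYPE_NAMES)
        while len(names) < self.n_tumor_types:
            names.append(f"type{len(names) + 1}")
        return names[: self.n_tumor_types]

    @property
    def sample_ids(self) -> List[str]:
        return [
            f"{t}_cl{j + 1}"
            for t in self.tumor_types
            for j in range(self.cell_lines_per_type)
        ]


@dataclass
class SyntheticTruth:
    planted_ses: List[Tuple[str, GenomicInterval, str]]
    planted_typical: List[GenomicInterval]
    planted_clique: Set[str]
    motif_placements: List[Tuple[str, GenomicInterval]]
    seed: int

    def conservative_genes(self, conservative_gt: int = 6) -> Set[str]:
        counts: Dict[str, Set[str]] = {}
        for tumor, _iv, gene in self.planted_ses:
            counts.setdefault(gene, set()).add(tumor)
        return {g for g, tumors in counts.items() if len(tumors) > conservative_gt}

    def specific_genes(self) -> Set[str]:
        counts: Dict[str, Set[str]] = {}
        for tumor, _iv, gene in self.planted_ses:
            counts.setdefault(gene, set()).add(tumor)
        return {g for g, tumors in counts.items() if len(tumors) == 1}

    def ses_of_tumor(self, tumor: str) -> List[GenomicInterval]:
        return [iv for t, iv, _g in self.planted_ses if t == tumor]


@dataclass
class _SELocus:
    kind: str  # shared | tf | specific
    gene: str
    tumor: Optional[str]  # None = all tumor types
    constituent_mids: List[int]
    tss: int

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            CHROM,
            self.constituent_mids[0] - ENHANCER_FLANK,
            self.constituent_mids[-1] + ENHANCER_FLANK,
        )

    def peaks(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(CHROM, m - PEAK_HALF_WIDTH, m + PEAK_HALF_WIDTH)
            for m in self.constituent_mids
        ]

    def nfrs(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(CHROM, m - NFR_HALF_WIDTH, m + NFR_HALF_WIDTH)
            for m in self.constituent_mids
        ]


def _layout(config: SyntheticConfig) -> Tuple[List[_SELocus], List[int], List[int]]:
    """Place loci in fixed-width slots: shared SEs, 3 TF SEs, per-type
    specific SEs, then typical enhancers.  Returns (SE loci, typical peak
    midpoints, low-significance decoy peak midpoints)."""
    tumors = config.tumor_types
    n_slots = (
        config.n_shared_ses
        + 3
        + config.n_tumor_types * config.n_specific_ses_per_type
        + config.n_typical
    )
    required = 2 * SLOT_MARGIN + n_slots * SLOT_WIDTH
    if required > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too small for {n_slots} loci "
            f"(need at least {required})"
        )
    loci: List[_SELocus] = []
    typical_mids: List[int] = []
    lowsig_mids: List[int] = []
    slot = 0

    def se_slot(kind: str, gene: str, tumor: Optional[str]) -> None:
        nonlocal slot
        base = SLOT_MARGIN + slot * SLOT_WIDTH
        mids = [base + 10_000 + k * CONSTITUENT_SPACING for k in range(config.se_constituents)]
        tss = mids[-1] + ENHANCER_FLANK + 6_000
        loci.append(_SELocus(kind=kind, gene=gene, tumor=tumor, constituent_mids=mids, tss=tss))
        slot += 1

    for i in range(config.n_shared_ses):
        se_slot("shared", f"CONS{i + 1}", None)
    for tf in sorted(TRIAD_CONSENSI):
        se_slot("tf", tf, None)
    for tumor in tumors:
        for k in range(config.n_specific_ses_per_type):
            se_slot("specific", f"SPEC_{tumor.upper()}_{k + 1}", tumor)
    for _ in range(config.n_typical):
        base = SLOT_MARGIN + slot * SLOT_WIDTH
        typical_mids.append(base + 10_000)
        lowsig_mids.append(base + 30_000)
        slot += 1
    return loci, typical_mids, lowsig_mids


def _write_fasta(path: Path, seq: np.ndarray, width: int = 80) -> None:
    raw = seq.tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(raw), width):
            fh.write(raw[i : i + width] + "\n")


def _write_pfm(path: Path) -> None:
    with open(path, "w") as fh:
        for tf, consensus in {**TRIAD_CONSENSI, **DECOY_CONSENSI}.items():
            fh.write(f">M_{tf} {tf}\n")
            for base in "ACGT":
                counts = [
                    str(MOTIF_COUNT_HIGH if c == base else MOTIF_COUNT_LOW) for c in consensus
                ]
                fh.write(base + " [ " + " ".join(counts) + " ]\n")


def generate(config: SyntheticConfig, outdir: Union[str, Path]) -> SyntheticTruth:
    """Write a full synthetic input set under ``outdir`` and return the
    ground truth.  Byte-deterministic for a fixed config (incl. seed)."""
    outdir = Path(outdir)
    loci, typical_mids, lowsig_mids = _layout(config)  # raises before any file I/O
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / "fragments").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.sample_ids))
    genome_rng = np.random.default_rng(children[0])
    L = config.genome_length

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = bases[genome_rng.integers(0, 4, L)].copy()

    # Plant the triad consensi into every NFR of each TF-gene SE.
    motif_placements: List[Tuple[str, GenomicInterval]] = []
    for locus in loci:
        if locus.kind != "tf":
            continue
        for nfr in locus.nfrs():
            offset = nfr.start + 10
            for tf in sorted(TRIAD_CONSENSI):
                consensus = TRIAD_CONSENSI[tf]
                enc = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
                genome[offset : offset + len(enc)] = enc
                motif_placements.append(
                    (f"M_{tf}", GenomicInterval(CHROM, offset, offset + len(enc)))
                )
                offset += len(enc)

    _write_fasta(outdir / "genome.fa", genome)
    with open(outdir / "chrom.sizes", "w") as fh:
        fh.write(f"{CHROM}\t{L}\n")

    with open(outdir / "tss.bed", "w") as fh:
        for locus in loci:
            fh.write(f"{CHROM}\t{locus.tss}\t{locus.tss + 1000}\t{locus.gene}\t0\t+\n")

    nfr_intervals: List[GenomicInterval] = []
    for locus in loci:
        nfr_intervals.extend(locus.nfrs())
    for mid in typical_mids:
        nfr_intervals.append(GenomicInterval(CHROM, mid - NFR_HALF_WIDTH, mid + NFR_HALF_WIDTH))
    nfr_intervals.sort()
    with open(outdir / "nfr.bed", "w") as fh:
        for iv in nfr_intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    _write_pfm(outdir / "motifs.pfm")

    tumors = config.tumor_types
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\ttumor_type\n")
        for sid in config.sample_ids:
            fh.write(f"{sid}\t{sid.rsplit('_cl', 1)[0]}\n")

    fold = config.constituent_signal_fold
    for sidx, sid in enumerate(config.sample_ids):
        tumor = sid.rsplit("_cl", 1)[0]
        rng = np.random.default_rng(children[1 + sidx])

        active_mids: List[int] = []
        weights: List[float] = []
        peak_lines: List[Tuple[int, int, float]] = []  # start, end, -log10 p
        for locus in loci:
            present = locus.tumor is None or locus.tumor == tumor
            if present:
                for m in locus.constituent_mids:
                    active_mids.append(m)
                    weights.append(fold)
                    peak_lines.append((m - PEAK_HALF_WIDTH, m + PEAK_HALF_WIDTH, 50.0))
            # Promoter-proximal decoy peaks are present in every sample
            # (active promoters are ubiquitous); the TSS filter must drop them.
            decoy_mid = locus.tss + 1000
            peak_lines.append((decoy_mid - PEAK_HALF_WIDTH, decoy_mid + PEAK_HALF_WIDTH, 30.0))
        for mid in typical_mids:
            active_mids.append(mid)
            weights.append(1.0)
            peak_lines.append((mid - PEAK_HALF_WIDTH, mid + PEAK_HALF_WIDTH, 50.0))
        for mid in lowsig_mids:
            peak_lines.append((mid - PEAK_HALF_WIDTH, mid + PEAK_HALF_WIDTH, 5.0))

        n_bg = int(round(BACKGROUND_FRACTION * config.fragments_per_sample))
        n_signal = config.fragments_per_sample - n_bg
        w = np.asarray(weights)
        counts = rng.multinomial(n_signal, w / w.sum())
        starts_parts = [rng.integers(0, L - FRAGMENT_LENGTH, n_bg)]
        for mid, count in zip(active_mids, counts):
            centers = rng.normal(mid, FRAGMENT_SD, count).round().astype(np.int64)
            centers = np.clip(centers, FRAGMENT_LENGTH // 2, L - FRAGMENT_LENGTH)
            starts_parts.append(centers - FRAGMENT_LENGTH // 2)
        starts = np.sort(np.concatenate(starts_parts))
        with open(outdir / "fragments" / f"{sid}.bed", "w") as fh:
            fh.writelines(
                f"{CHROM}\t{s}\t{s + FRAGMENT_LENGTH}\n" for s in starts.tolist()
            )

        peak_lines.sort()
        with open(outdir / "peaks" / f"{sid}.narrowPeak", "w") as fh:
            for i, (start, end, nlp) in enumerate(peak_lines):
                fh.write(
                    f"{CHROM}\t{start}\t{end}\tpeak_{sid}_{i}\t0\t.\t"
                    f"{nlp * 2:.1f}\t{nlp:.1f}\t{nlp:.1f}\t{(end - start) // 2}\n"
                )

    planted_ses: List[Tuple[str, GenomicInterval, str]] = []
    for locus in loci:
        for tumor in tumors:
            if locus.tumor is None or locus.tumor == tumor:
                planted_ses.append((tumor, locus.span, locus.gene))
    planted_typical = [
        GenomicInterval(CHROM, m - ENHANCER_FLANK, m + ENHANCER_FLANK) for m in typical_mids
    ]
    truth = SyntheticTruth(
        planted_ses=planted_ses,
        planted_typical=planted_typical,
        planted_clique=set(TRIAD_CONSENSI),
        motif_placements=motif_placements,
        seed=config.seed,
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "planted_clique": sorted(truth.planted_clique),
                "planted_ses": [
                    [t, iv.chrom, iv.start, iv.end, g] for t, iv, g in truth.planted_ses
                ],
                "planted_typical": [
                    [iv.chrom, iv.start, iv.end] for iv in truth.planted_typical
                ],
                "motif_placements": [
                    [m, iv.chrom, iv.start, iv.end] for m, iv in truth.motif_placements
                ],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return truth


def _reciprocal_match(a: GenomicInterval, b: GenomicInterval, fraction: float) -> bool:
    ov = a.overlap_length(b)
    return ov >= fraction * a.length() and ov >= fraction * b.length()


def truth_compare(
    truth: SyntheticTruth,
    se_calls: Optional[Sequence] = None,
    gene_categories: Optional[Mapping[str, str]] = None,
    top_cliques: Optional[Iterable[Set[str]]] = None,
    overlap_fraction: float = 0.5,
    conservative_gt: int = 6,
) -> pd.DataFrame:
    """Per-layer precision/recall of pipeline output against planted truth.

    ``se_calls`` are (tumor_type, interval) pairs or objects with those
    attributes; a call matches a planted SE of the same tumor type at
    reciprocal overlap >= ``overlap_fraction``.  Gene layers compare the
    predicted conservative/specific gene sets with the planted ones;
    ``top_cliques`` (one TF set per tumor type) are compared as sets.
    Precision is NaN (not a crash) when nothing was called.
    """
    rows = []

    def add(layer: str, n_matched_calls: int, n_calls: int, n_matched_truth: int, n_truth: int):
        rows.append(
            {
                "layer": layer,
                "precision": (n_matched_calls / n_calls) if n_calls else float("nan"),
                "recall": (n_matched_truth / n_truth) if n_truth else float("nan"),
                "n_called": n_calls,
                "n_truth": n_truth,
            }
        )

    if se_calls is not None:
        calls: List[Tuple[str, GenomicInterval]] = []
        for item in se_calls:
            if isinstance(item, tuple):
                calls.append(item)
            else:
                calls.append((item.tumor_type, item.interval))
        truth_by_tumor: Dict[str, List[GenomicInterval]] = {}
        for tumor, iv, _g in truth.planted_ses:
            truth_by_tumor.setdefault(tumor, []).append(iv)
        matched_calls = sum(
            any(
                _reciprocal_match(iv, tiv, overlap_fraction)
                for tiv in truth_by_tumor.get(tumor, [])
            )
            for tumor, iv in calls
        )
        matched_truth = sum(
            any(
                _reciprocal_match(civ, tiv, overlap_fraction)
                for ct, civ in calls
                if ct == tumor
            )
            for tumor, tivs in truth_by_tumor.items()
            for tiv in tivs
        )
        add("se", matched_calls, len(calls), matched_truth, len(truth.planted_ses))

    if gene_categories is not None:
        for layer, truth_set in (
            ("gene_conservative", truth.conservative_genes(conservative_gt)),
            ("gene_specific", truth.specific_genes()),
        ):
            pred = {g for g, c in gene_categories.items() if c == layer.split("_", 1)[1]}
            add(layer, len(pred & truth_set), len(pred), len(pred & truth_set), len(truth_set))

    if top_cliques is not None:
        cliques = [set(c) for c in top_cliques]
        n_pred = sum(len(c) for c in cliques)
        n_hit = sum(len(c & truth.planted_clique) for c in cliques)
        n_truth_total = len(truth.planted_clique) * max(len(cliques), 1)
        add("clique", n_hit, n_pred, n_hit, n_truth_total if cliques else len(truth.planted_clique))

    return pd.DataFrame(rows)
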