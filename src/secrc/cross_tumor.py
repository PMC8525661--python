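"""Cross-sample SE merging, gene assignment, and conservative/specific
classification across tumor types.

Super-enhancer calls from the cell lines of one tumor type are unioned when
they share at least one base; merged entities seen in fewer than a minimum
number of cell lines (default 2) are dropped.  Each merged SE is assigned to
the gene with the nearest TSS.  A gene's frequency is the number of distinct
tumor types in which it has at least one merged SE; with eight tumor types,
frequency > 6 is "conservative" and frequency == 1 "specific".  TFs are
classified the same way at thresholds > 4 / == 1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, TSSRecord

__all__ = [
    "MergedSE",
    "GeneFrequency",
    "TFFrequency",
    "merge_ses",
    "assign_genes",
    "gene_frequency_table",
    "tf_frequency_table",
    "expression_summary",
]


@dataclass
class MergedSE:
    interval: GenomicInterval
    tumor_type: str
    cell_lines: Set[str]

    @property
    def cell_line_count(self) -> int:
        return len(self.cell_lines)

    @property
    def key(self) -> str:
        return f"{self.tumor_type}:{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass(frozen=True)
class GeneFrequency:
    gene_symbol: str
    tumor_types_with_se: frozenset
    frequency: int
    category: str


@dataclass(frozen=True)
class TFFrequency:
    tf_name: str
    tumor_types_enriched: frozenset
    frequency: int
    category: str


def merge_ses(
    per_sample_ses: Mapping[str, Sequence[GenomicInterval]],
    tumor_of: Mapping[str, str],
    min_cell_lines: int = 2,
) -> List[MergedSE]:
    """Union overlapping SE intervals across the cell lines of each tumor
    type (transitive, >= 1 shared base) and keep entities supported by at
    least ``min_cell_lines`` distinct cell lines."""
    for sample_id in per_sample_ses:
        if sample_id not in tumor_of:
            raise ValueError(f"sample {sample_id} has no tumor-type assignment")
    by_tumor: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
    for sample_id, intervals in per_sample_ses.items():
        tumor = tumor_of[sample_id]
        for iv in intervals:
            by_tumor.setdefault(tumor, []).append((iv, sample_id))

    merged: List[MergedSE] = []
    for tumor in sorted(by_tumor):
        entries = sorted(by_tumor[tumor], key=lambda t: (t[0].chrom, t[0].start, t[0].end))
        cur_iv: Optional[GenomicInterval] = None
        cur_samples: Set[str] = set()
        cur_end = 0
        for iv, sample_id in entries:
            if cur_iv is not None and iv.chrom == cur_iv.chrom and iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
                cur_samples.add(sample_id)
            else:
                if cur_iv is not None:
                    merged.append(
                        MergedSE(
                            GenomicInterval(cur_iv.chrom, cur_iv.start, cur_end),
                            tumor,
                            cur_samples,
                        )
                    )
                cur_iv, cur_end, cur_samples = iv, iv.end, {sample_id}
        if cur_iv is not None:
            merged.append(
                MergedSE(GenomicInterval(cur_iv.chrom, cur_iv.start, cur_end), tumor, cur_samples)
            )
    return [m for m in merged if m.cell_line_count >= min_cell_lines]


def assign_genes(
    merged_ses: Sequence[MergedSE],
    tss: Sequence[TSSRecord],
) -> Dict[str, str]:
    """Map each merged SE (by ``key``) to the gene whose TSS is nearest to
    the SE center; ties go to the lexicographically smaller gene symbol.

    Distance is unbounded but confined to the SE's chromosome; SEs on
    chromosomes without any TSS are left unassigned.
    """
    if not tss:
        raise ValueError("TSS list is empty")
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append((rec.tss_position, rec.gene_symbol))
    positions: Dict[str, np.ndarray] = {}
    symbols: Dict[str, List[str]] = {}
    for chrom, entries in by_chrom.items():
        entries.sort()
        positions[chrom] = np.array([p for p, _ in entries], dtype=np.int64)
        symbols[chrom] = [s for _, s in entries]

    out: Dict[str, str] = {}
    for se in merged_ses:
        chrom = se.interval.chrom
        if chrom not in positions:
            continue
        pos, syms = positions[chrom], symbols[chrom]
        center = se.interval.midpoint
        dists = np.abs(pos - center)
        best = int(dists.min())
        candidates = [syms[i] for i in np.flatnonzero(dists == best)]
        out[se.key] = min(candidates)
    return out


def _categorize(frequency: int, conservative_gt: int) -> str:
    if frequency > conservative_gt:
        return "conservative"
    if frequency == 1:
        return "specific"
    return "intermediate"


def gene_frequency_table(
    genes_by_tumor: Mapping[str, Iterable[str]],
    conservative_gt: int = 6,
) -> List[GeneFrequency]:
    """Count, per gene, the distinct tumor types with at least one SE
    assigned to it, and classify conservative (> ``conservative_gt``) vs
    specific (== 1) vs intermediate."""
    types_by_gene: Dict[str, Set[str]] = {}
    for tumor, genes in genes_by_tumor.items():
        for gene in genes:
            types_by_gene.setdefault(gene, set()).add(tumor)
    return [
        GeneFrequency(
            gene_symbol=gene,
            tumor_types_with_se=frozenset(types),
            frequency=len(types),
            category=_categorize(len(types), conservative_gt),
        )
        for gene, types in sorted(types_by_gene.items())
    ]


def tf_frequency_table(
    enriched_tfs_by_tumor: Mapping[str, Iterable[str]],
    conservative_gt: int = 4,
) -> List[TFFrequency]:
    """Classify TFs by the number of tumor types in which their motif is
    enriched on SE nucleosome-free regions (> ``conservative_gt`` types =
    conservative, exactly 1 = specific)."""
    types_by_tf: Dict[str, Set[str]] = {}
    for tumor, tfs in enriched_tfs_by_tumor.items():
        for tf in tfs:
            types_by_tf.setdefault(tf, set()).add(tumor)
    return [
        TFFrequency(
            tf_name=tf,
            tumor_types_enriched=frozenset(types),
            frequency=len(types),
            category=_categorize(len(types), conservative_gt),
        )
        for tf, types in sorted(types_by_tf.items())
    ]


def expression_summary(
    expression: pd.DataFrame,
    sample_to_tumor: Mapping[str, str],
    genes: Sequence[str],
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-gene, per-tumor-type mean expression (FPKM-like units).

    Returns (means table restricted to genes found in the matrix, list of
    requested genes missing from the matrix).  Missing genes are reported,
    never imputed as zero.
    """
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    unmapped = [s for s in expression.columns if s not in sample_to_tumor]
    if unmapped:
        raise ValueError(f"samples without tumor-type mapping: {unmapped}")
    missing = [g for g in genes if g not in expression.index]
    present = [g for g in genes if g in expression.index]
    groups = pd.Series({s: sample_to_tumor[s] for s in expression.columns})
    means = expression.loc[present].T.groupby(groups).mean().T
    means.index.name = "gene_symbol"
    return means, missing
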