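"""Domain types and readers/writers for the standard formats the pipeline touches.

Every coordinate in the package is 0-based, half-open (BED convention).
GTF input, which is 1-based inclusive, is converted on read and never leaks
its convention past this module.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "GenomicInterval",
    "Peak",
    "TSSRecord",
    "SampleTrack",
    "PWM",
    "ParseError",
    "ValidationError",
    "read_peaks",
    "filter_significant",
    "read_tss",
    "read_pwms",
    "write_bed",
    "read_chrom_sizes",
]


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A significant-peak call (e.g. MACS2 narrowPeak line).

    ``neg_log10_p`` of +inf marks peaks read from formats without a p-value
    column, which are treated as already filtered for significance.
    """

    interval: GenomicInterval
    name: str = "."
    neg_log10_p: float = math.inf
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.neg_log10_p < 0:
            raise ValidationError(f"negative -log10(p) for peak {self.name}")


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    gene_symbol: str
    chrom: str
    tss_position: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"strand must be '+' or '-', got {self.strand!r} for {self.gene_id}"
            )
        if self.tss_position < 0:
            raise ValidationError(f"negative TSS position for {self.gene_id}")


@dataclass
class SampleTrack:
    """One sample's aligned-fragment set, with total depth for per-million scaling."""

    sample_id: str
    tumor_type: str
    fragments: list  # list[GenomicInterval], sorted by (chrom, start)
    total_fragments: int = 0

    def __post_init__(self) -> None:
        if self.total_fragments == 0:
            self.total_fragments = len(self.fragments)
        if self.total_fragments != len(self.fragments):
            raise ValidationError(
                f"total_fragments != len(fragments) for sample {self.sample_id}"
            )
        key = [(f.chrom, f.start) for f in self.fragments]
        if key != sorted(key):
            raise ValidationError(f"fragments not sorted for sample {self.sample_id}")


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with a background distribution.

    ``matrix`` is L x 4 (positions x bases); rows sum to 1 after
    normalization with a pseudocount.
    """

    motif_id: str
    tf_name: str
    matrix: "object"  # numpy array, L x 4
    background: "object" = None  # length-4 probability vector

    def __post_init__(self) -> None:
        import numpy as np

        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"PWM {self.motif_id}: matrix must be L x 4")
        if (self.matrix < 0).any():
            raise ValidationError(f"PWM {self.motif_id}: negative entries")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValidationError(f"PWM {self.motif_id}: background does not sum to 1")
        rowsums = self.matrix.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > 1e-9:
            raise ValidationError(f"PWM {self.motif_id}: rows do not sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def _split_fields(line: str) -> list:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_peaks(path: Union[str, Path], format: str = "narrowPeak") -> list:
    """Read peak calls from narrowPeak or BED.

    narrowPeak column 8 (0-based 7) holds -log10(p); column 10 (0-based 9)
    the summit offset (-1 meaning absent).  Plain BED carries no p-value and
    yields ``neg_log10_p = +inf``.  Output is sorted by (chrom, start).
    """
    fmt = format.lower()
    if fmt not in ("narrowpeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_fields(line)
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            name = f[3] if len(f) > 3 and f[3] else "."
            if fmt == "narrowpeak":
                if len(f) < 10:
                    raise ParseError(
                        f"{path}: line {lineno}: narrowPeak needs 10 columns, got {len(f)}"
                    )
                try:
                    neg_log10_p = float(f[7])
                    summit = int(f[9])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
                summit_offset = None if summit < 0 else summit
            else:
                neg_log10_p = math.inf
                summit_offset = None
            try:
                interval = GenomicInterval(chrom, start, end)
                peaks.append(
                    Peak(interval, name=name, neg_log10_p=neg_log10_p, summit_offset=summit_offset)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def filter_significant(peaks: Sequence[Peak], p_threshold: float = 1e-9) -> list:
    """Keep peaks with p < p_threshold, i.e. neg_log10_p strictly above
    -log10(p_threshold).  Order is preserved; idempotent."""
    if not (0 < p_threshold < 1) and p_threshold != 1.0:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    cutoff = -math.log10(p_threshold)
    return [p for p in peaks if p.neg_log10_p > cutoff]


def read_tss(path: Union[str, Path], format: str = "bed6") -> list:
    """Read TSS records from BED6 or a gene/transcript-level GTF.

    BED6: the TSS is the strand-aware first base of the interval
    ('+': start; '-': end - 1).  GTF 1-based inclusive coordinates are
    converted to the same convention.
    """
    fmt = format.lower()
    if fmt not in ("bed6", "gtf"):
        raise ValueError(f"unknown TSS format {format!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split_fields(line)
            try:
                if fmt == "bed6":
                    if len(f) < 6:
                        raise ParseError("BED6 needs 6 columns")
                    chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
                    gene_id = gene_symbol = name
                else:
                    if len(f) < 9:
                        raise ParseError("GTF needs 9 columns")
                    feature = f[2]
                    if feature not in ("gene", "transcript"):
                        continue
                    chrom, start1, end1, strand = f[0], int(f[3]), int(f[4]), f[6]
                    start, end = start1 - 1, end1  # to 0-based half-open
                    attrs = {}
                    for part in f[8].split(";"):
                        part = part.strip()
                        if not part:
                            continue
                        k, _, v = part.partition(" ")
                        attrs[k] = v.strip().strip('"')
                    gene_id = attrs.get("gene_id", ".")
                    gene_symbol = attrs.get("gene_name", gene_id)
            except ParseError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            tss = start if strand == "+" else end - 1
            try:
                records.append(TSSRecord(gene_id, gene_symbol, chrom, tss, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return records


def read_pwms(path: Union[str, Path], pseudocount: float = 1.0) -> list:
    """Read a JASPAR-style PFM file into probability PWMs.

    Each record is a ``>ID NAME`` header followed by four rows (A, C, G, T)
    of equal length.  Counts are normalized per position as
    (c + pseudocount) / (sum + 4 * pseudocount); background is uniform.
    """
    import numpy as np

    pwms = []
    header = None
    rows: list = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        if len(rows) != 4:
            raise ParseError(
                f"{path}: motif {header[0]} (line {header_line}): expected 4 base rows, got {len(rows)}"
            )
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ParseError(
                f"{path}: motif {header[0]} (line {header_line}): unequal row lengths"
            )
        counts = np.array(rows, dtype=float).T  # L x 4
        probs = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
        )
        pwms.append(PWM(motif_id=header[0], tf_name=header[1], matrix=probs))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                motif_id = parts[0]
                tf_name = parts[1].strip() if len(parts) > 1 else motif_id
                header = (motif_id, tf_name)
                header_line = lineno
                rows = []
            else:
                cleaned = line.replace("[", " ").replace("]", " ")
                fields = cleaned.split()
                if fields and fields[0].upper() in "ACGT" and len(fields[0]) == 1:
                    fields = fields[1:]
                try:
                    rows.append([float(x) for x in fields])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
    flush()
    return pwms


def write_bed(items: Iterable, path: Union[str, Path], header: Optional[str] = None) -> None:
    """Write intervals (or peak-like objects carrying ``.interval``) as BED.

    Plain ``GenomicInterval`` items become BED3; ``Peak`` items become
    BED4 + extra columns so they survive a round-trip through
    ``read_peaks(format='bed')`` with coordinates and names intact.
    Header comment lines are prefixed with '#'.
    """
    with open(path, "w") as fh:
        if header:
            for hline in header.splitlines():
                fh.write(f"# {hline}\n")
        for item in items:
            if isinstance(item, GenomicInterval):
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")
            elif isinstance(item, Peak):
                iv = item.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.name}\n")
            else:
                iv = item.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: Union[str, Path]) -> dict:
    """Read a UCSC two-column chrom.sizes file."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_fields(line)
            try:
                sizes[f[0]] = int(f[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return sizes
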