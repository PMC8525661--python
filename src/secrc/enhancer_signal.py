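"""Enhancer definition and H3K27ac signal quantification.

Enhancers are significant H3K27ac peaks lying more than a minimum distance
(default 2.5 kb) from every annotated TSS; each retained peak is expanded to
a fixed +/- 5 kb window around the peak midpoint, clamped at the chromosome
start.  The enhancer signal is the mean, over 100 bp bins of the window, of
the depth-normalized (fragments-per-million) count of aligned fragments
overlapping each bin.  For the genome-wide sample-similarity analysis the
genome is tiled into 2 kb bins and a Pearson correlation matrix is computed
over the per-sample normalized bin counts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core_io import GenomicInterval, Peak, SampleTrack, TSSRecord, ValidationError

__all__ = [
    "Enhancer",
    "BinMatrix",
    "define_enhancers",
    "quantify_enhancer_signal",
    "genome_bin_matrix",
    "sample_correlation",
]

ENHANCER_FLANK = 5_000  # bp added on each side of the peak midpoint


@dataclass(frozen=True)
class Enhancer:
    """A TSS-distal peak expanded to its signal-quantification window."""

    interval: GenomicInterval
    source_peak: Peak
    signal: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValidationError("enhancer signal must be non-negative")


@dataclass
class BinMatrix:
    """Samples x genome-bins matrix of depth-normalized fragment counts."""

    bin_size: int
    chrom_sizes: Dict[str, int]
    sample_ids: List[str]
    values: np.ndarray  # samples x total bins, fragments per million

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def chrom_offsets(self) -> Dict[str, int]:
        offsets, total = {}, 0
        for chrom in sorted(self.chrom_sizes):
            offsets[chrom] = total
            total += math.ceil(self.chrom_sizes[chrom] / self.bin_size)
        return offsets


def define_enhancers(
    peaks: Sequence[Peak],
    tss: Sequence[TSSRecord],
    min_tss_distance: int = 2_500,
) -> List[Enhancer]:
    """Keep peaks whose midpoint lies strictly more than ``min_tss_distance``
    from every TSS, and expand each to [mid - 5kb, mid + 5kb) clamped at 0.

    Peaks on chromosomes without any annotated TSS are kept (their distance
    to the annotation is unbounded).
    """
    if not tss:
        raise ValueError("TSS list is empty: TSS distance is undefined")
    tss_by_chrom: Dict[str, np.ndarray] = {}
    for rec in tss:
        tss_by_chrom.setdefault(rec.chrom, []).append(rec.tss_position)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    out: List[Enhancer] = []
    for peak in peaks:
        mid = peak.interval.midpoint
        positions = tss_by_chrom.get(peak.interval.chrom)
        if positions is not None:
            i = int(np.searchsorted(positions, mid))
            dist = math.inf
            if i < len(positions):
                dist = min(dist, abs(int(positions[i]) - mid))
            if i > 0:
                dist = min(dist, abs(int(positions[i - 1]) - mid))
            if dist <= min_tss_distance:
                continue
        start = max(0, mid - ENHANCER_FLANK)
        out.append(
            Enhancer(
                interval=GenomicInterval(peak.interval.chrom, start, mid + ENHANCER_FLANK),
                source_peak=peak,
            )
        )
    return out


def _track_arrays(track: SampleTrack) -> Dict[str, tuple]:
    """Per-chromosome (starts, ends, max_length) arrays for fast overlap lookups."""
    by_chrom: Dict[str, tuple] = {}
    chroms: Dict[str, list] = {}
    for frag in track.fragments:
        chroms.setdefault(frag.chrom, []).append((frag.start, frag.end))
    for chrom, pairs in chroms.items():
        arr = np.asarray(pairs, dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
        by_chrom[chrom] = (starts, ends, int((ends - starts).max()))
    return by_chrom


def _bin_counts(
    starts: np.ndarray, ends: np.ndarray, origin: int, n_bins: int, bin_size: int
) -> np.ndarray:
    """Count, for each of ``n_bins`` bins starting at ``origin``, the fragments
    overlapping it by at least one base.  A fragment spanning k bins counts
    once in each."""
    counts = np.zeros(n_bins, dtype=np.int64)
    if len(starts) == 0:
        return counts
    b0 = np.maximum((starts - origin) // bin_size, 0)
    b1 = np.minimum((ends - 1 - origin) // bin_size, n_bins - 1)
    valid = b0 <= b1
    b0, b1 = b0[valid], b1[valid]
    if len(b0) == 0:
        return counts
    span = int((b1 - b0).max()) + 1
    for k in range(span):
        idx = b0 + k
        mask = idx <= b1
        np.add.at(counts, idx[mask], 1)
    return counts


def quantify_enhancer_signal(
    enhancers: Sequence[Enhancer],
    track: SampleTrack,
    bin_size: int = 100,
) -> List[Enhancer]:
    """Mean per-bin fragment count over the enhancer window, in fragments
    per million.  Invariant under uniform duplication of all fragments."""
    if track.total_fragments == 0:
        raise ValueError(f"sample {track.sample_id} has zero fragments")
    per_million = 1e6 / track.total_fragments
    arrays = _track_arrays(track)
    out: List[Enhancer] = []
    for enh in enhancers:
        iv = enh.interval
        n_bins = math.ceil(iv.length() / bin_size)
        data = arrays.get(iv.chrom)
        if data is None:
            signal = 0.0
        else:
            starts, ends, max_len = data
            hi = int(np.searchsorted(starts, iv.end))
            lo = int(np.searchsorted(starts, iv.start - max_len))
            sel = slice(lo, hi)
            s, e = starts[sel], ends[sel]
            keep = e > iv.start
            counts = _bin_counts(s[keep], e[keep], iv.start, n_bins, bin_size)
            signal = float(counts.mean()) * per_million
        out.append(replace(enh, signal=signal, sample_id=track.sample_id))
    return out


def genome_bin_matrix(
    tracks: Sequence[SampleTrack],
    chrom_sizes: Dict[str, int],
    bin_size: int = 2_000,
) -> BinMatrix:
    """Tile the genome into fixed bins and count, per sample, the fragments
    overlapping each bin, normalized to fragments per million."""
    offsets, total = {}, 0
    for chrom in sorted(chrom_sizes):
        offsets[chrom] = total
        total += math.ceil(chrom_sizes[chrom] / bin_size)
    values = np.zeros((len(tracks), total), dtype=float)
    for si, track in enumerate(tracks):
        if track.total_fragments == 0:
            raise ValueError(f"sample {track.sample_id} has zero fragments")
        for chrom, (starts, ends, _max_len) in _track_arrays(track).items():
            if chrom not in chrom_sizes:
                raise ValidationError(
                    f"sample {track.sample_id}: fragments on {chrom} absent from chrom sizes"
                )
            size = chrom_sizes[chrom]
            if int(ends.max()) > size:
                raise ValidationError(
                    f"sample {track.sample_id}: fragment beyond {chrom} length {size}"
                )
            n_bins = math.ceil(size / bin_size)
            counts = _bin_counts(starts, ends, 0, n_bins, bin_size)
            values[si, offsets[chrom] : offsets[chrom] + n_bins] += counts
        values[si] *= 1e6 / track.total_fragments
    return BinMatrix(
        bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes),
        sample_ids=[t.sample_id for t in tracks],
        values=values,
    )


def sample_correlation(matrix: BinMatrix, log1p: bool = False) -> np.ndarray:
    """Pearson correlation between sample rows of the bin matrix.

    ``log1p`` applies log(1 + x) before correlating; off by default.
    """
    values = matrix.values
    if values.shape[0] < 2:
        raise ValueError("correlation needs at least two samples")
    if log1p:
        values = np.log1p(values)
    variances = values.var(axis=1)
    for sid, var in zip(matrix.sample_ids, variances):
        if var == 0:
            raise ValueError(f"sample {sid} has zero variance across bins")
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return corr
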