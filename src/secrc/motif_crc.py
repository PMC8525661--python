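"""Motif scanning on nucleosome-free regions and core-regulatory-circuitry
(CRC) inference.

Nucleosome-free regions (NFRs) are coverage valleys inside SE constituent
peaks where transcription factors contact DNA.  Known motifs (PWMs) are
scanned over NFR sequences with a log2-odds score against a background base
distribution; a hit is a window scoring at least a fraction (default 0.8)
of the motif's maximum attainable score, on either strand.  Motif
enrichment of SE NFRs against background NFRs uses a hypergeometric upper
tail on per-sequence hit indicators.

The CRC graph has one node per SE-regulated TF; an edge u -> v means u's
motif occurs in an NFR of v's SE.  TFs with a self-edge are autoregulated;
fully interconnected sets of autoregulated TFs (maximal cliques under
mutual regulation) form candidate circuitries.  A TF's score is the
fraction of enumerated cliques containing it, and a clique's score the mean
of its members' scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .core_io import GenomicInterval, PWM

__all__ = [
    "NFR",
    "MotifHit",
    "EnrichmentResult",
    "CRCGraph",
    "CliqueScore",
    "find_nfrs",
    "find_valley_nfrs",
    "scan_motif",
    "sequences_with_hit",
    "enrichment_test",
    "build_crc",
    "enumerate_cliques",
]

logger = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"
# A=0 C=1 G=2 T=3, anything else (incl. N) = 4
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class NFR:
    """A nucleosome-free interval with its DNA sequence."""

    interval: GenomicInterval
    sequence: str
    parent_se: Optional[str] = None  # key of the owning (merged or stitched) SE

    def __post_init__(self) -> None:
        if len(self.sequence) != self.interval.length():
            raise ValueError(
                f"NFR sequence length {len(self.sequence)} != interval length "
                f"{self.interval.length()}"
            )


@dataclass(frozen=True)
class MotifHit:
    pwm_id: str
    offset: int
    strand: str
    log_odds: float
    nfr: Optional[NFR] = None


@dataclass(frozen=True)
class EnrichmentResult:
    pwm_id: str
    tf_name: str
    n_target_hits: int
    n_target: int
    n_background_hits: int
    n_background: int
    p_value: float


@dataclass
class CRCGraph:
    nodes: Set[str]
    edges: Set[Tuple[str, str]]  # directed (u, v): u's motif in v's SE NFRs

    @property
    def autoregulated(self) -> Set[str]:
        return {u for u in self.nodes if (u, u) in self.edges}

    def mutual_graph(self) -> nx.Graph:
        """Undirected graph over autoregulated nodes with an edge where both
        directions of regulation are present."""
        g = nx.Graph()
        auto = self.autoregulated
        g.add_nodes_from(auto)
        for u in auto:
            for v in auto:
                if u < v and (u, v) in self.edges and (v, u) in self.edges:
                    g.add_edge(u, v)
        return g


@dataclass(frozen=True)
class CliqueScore:
    clique: frozenset
    tf_scores: Mapping[str, float]
    clique_score: float


def _log_odds_matrix(pwm: PWM) -> np.ndarray:
    """L x 5 log2-odds matrix; the 5th column (ambiguous base) is a large
    negative sentinel so windows containing N never reach any threshold."""
    with np.errstate(divide="ignore"):
        lo = np.log2(pwm.matrix / pwm.background[None, :])
    lo = np.where(np.isneginf(lo), -1e9, lo)
    return np.hstack([lo, np.full((lo.shape[0], 1), -1e9)])


def _window_scores(encoded: np.ndarray, lo_ext: np.ndarray) -> np.ndarray:
    """Scores of every length-L window of a (n_seq x seq_len) encoded batch."""
    L = lo_ext.shape[0]
    n, m = encoded.shape
    w = m - L + 1
    scores = np.zeros((n, w))
    for j in range(L):
        scores += lo_ext[j][encoded[:, j : j + w]]
    return scores


def _n_free_windows(encoded: np.ndarray, L: int) -> np.ndarray:
    """Boolean mask of windows containing no ambiguous base."""
    is_n = (encoded == 4).astype(np.int64)
    cs = np.cumsum(np.pad(is_n, ((0, 0), (1, 0))), axis=1)
    return (cs[:, L:] - cs[:, :-L]) == 0


def scan_motif(
    pwm: PWM,
    sequence: str,
    threshold_fraction: float = 0.8,
    nfr: Optional[NFR] = None,
) -> List[MotifHit]:
    """Scan both strands of ``sequence`` for ``pwm`` occurrences.

    A hit is reported where the log2-odds score is at least
    ``threshold_fraction`` times the motif's maximum attainable score.
    Windows containing N never match.  The offset of a '-' hit is the
    0-based position, on the given sequence, where the motif's reverse
    complement begins.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    L = len(pwm)
    if L > len(sequence):
        return []
    lo_ext = _log_odds_matrix(pwm)
    max_score = float(lo_ext[:, :4].max(axis=1).sum())
    threshold = threshold_fraction * max_score
    encoded = _encode(sequence)[None, :]
    ok = _n_free_windows(encoded, L)[0]
    hits: List[MotifHit] = []
    fwd = _window_scores(encoded, lo_ext)[0]
    # '-' strand: score the reverse complement of each window, i.e. scan with
    # the reverse-complemented matrix.
    rc_ext = np.hstack([lo_ext[::-1, [3, 2, 1, 0]], lo_ext[::-1, 4:5]])
    rev = _window_scores(encoded, rc_ext)[0]
    for strand, scores in (("+", fwd), ("-", rev)):
        for off in np.flatnonzero(ok & (scores >= threshold)):
            hits.append(
                MotifHit(
                    pwm_id=pwm.motif_id,
                    offset=int(off),
                    strand=strand,
                    log_odds=float(scores[off]),
                    nfr=nfr,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def sequences_with_hit(
    sequences: Sequence[str],
    pwm: PWM,
    threshold_fraction: float = 0.8,
) -> np.ndarray:
    """Vectorized per-sequence boolean: does each sequence carry >= 1 hit?

    Ragged inputs are padded with N, which can never be part of a match, so
    padding does not create or destroy hits.
    """
    if not sequences:
        return np.zeros(0, dtype=bool)
    L = len(pwm)
    m = max(max(len(s) for s in sequences), L)
    padded = [s + "N" * (m - len(s)) for s in sequences]
    encoded = np.stack([_encode(s) for s in padded])
    lo_ext = _log_odds_matrix(pwm)
    max_score = float(lo_ext[:, :4].max(axis=1).sum())
    threshold = threshold_fraction * max_score
    ok = _n_free_windows(encoded, L)
    rc_ext = np.hstack([lo_ext[::-1, [3, 2, 1, 0]], lo_ext[::-1, 4:5]])
    hit = (ok & (_window_scores(encoded, lo_ext) >= threshold)).any(axis=1)
    hit |= (ok & (_window_scores(encoded, rc_ext) >= threshold)).any(axis=1)
    return hit


def enrichment_test(
    target_nfrs: Sequence[NFR],
    background_nfrs: Sequence[NFR],
    pwm: PWM,
    threshold_fraction: float = 0.8,
) -> EnrichmentResult:
    """Hypergeometric upper-tail test of motif presence in target vs
    background NFR sequences.

    With N = n_target + n_background sequences of which K carry >= 1 hit,
    the p-value is P(X >= n_target_hits) for X hypergeometric(N, K,
    n_target).
    """
    if not target_nfrs:
        raise ValueError("empty target NFR list")
    if not background_nfrs:
        raise ValueError("empty background NFR list")
    t_hit = int(sequences_with_hit([n.sequence for n in target_nfrs], pwm, threshold_fraction).sum())
    b_hit = int(
        sequences_with_hit([n.sequence for n in background_nfrs], pwm, threshold_fraction).sum()
    )
    n_t, n_b = len(target_nfrs), len(background_nfrs)
    p = float(hypergeom.sf(t_hit - 1, n_t + n_b, t_hit + b_hit, n_t))
    return EnrichmentResult(
        pwm_id=pwm.motif_id,
        tf_name=pwm.tf_name,
        n_target_hits=t_hit,
        n_target=n_t,
        n_background_hits=b_hit,
        n_background=n_b,
        p_value=min(p, 1.0),
    )


def find_nfrs(
    constituents: Sequence[GenomicInterval],
    provided_nfrs: Sequence[GenomicInterval],
    genome: Mapping[str, object],
    parent_se: Optional[str] = None,
) -> List[NFR]:
    """Intersect externally provided NFR intervals with SE constituent
    peaks (>= 1 shared base) and attach sequences from the genome."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in provided_nfrs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[NFR] = []
    for cons in constituents:
        for nfr_iv in by_chrom.get(cons.chrom, []):
            ov_start = max(cons.start, nfr_iv.start)
            ov_end = min(cons.end, nfr_iv.end)
            if ov_end <= ov_start:
                continue
            if cons.chrom not in genome:
                raise KeyError(f"genome has no sequence for {cons.chrom}")
            seq = str(genome[cons.chrom][ov_start:ov_end]).upper()
            out.append(
                NFR(
                    interval=GenomicInterval(cons.chrom, ov_start, ov_end),
                    sequence=seq,
                    parent_se=parent_se,
                )
            )
    out.sort(key=lambda n: (n.interval.chrom, n.interval.start, n.interval.end))
    return out


def find_valley_nfrs(
    constituent: GenomicInterval,
    coverage: np.ndarray,
    genome: Optional[Mapping[str, object]] = None,
    min_length: int = 50,
    low_fraction: float = 0.25,
    flank_fraction: float = 0.5,
    parent_se: Optional[str] = None,
) -> List[NFR]:
    """Call coverage valleys inside one constituent peak as NFRs.

    A valley is a maximal run of >= ``min_length`` positions where coverage
    is below ``low_fraction`` of the constituent's peak coverage, with some
    position reaching ``flank_fraction`` of the peak on both sides.
    """
    cov = np.asarray(coverage, dtype=float)
    if len(cov) != constituent.length():
        raise ValueError("coverage length must match the constituent interval")
    peak = cov.max()
    if peak <= 0:
        return []
    low = cov < low_fraction * peak
    high = cov >= flank_fraction * peak
    out: List[NFR] = []
    i = 0
    n = len(cov)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        if j - i >= min_length and high[:i].any() and high[j:].any():
            start = constituent.start + i
            end = constituent.start + j
            if genome is not None:
                if constituent.chrom not in genome:
                    raise KeyError(f"genome has no sequence for {constituent.chrom}")
                seq = str(genome[constituent.chrom][start:end]).upper()
            else:
                seq = "N" * (end - start)
            out.append(
                NFR(
                    interval=GenomicInterval(constituent.chrom, start, end),
                    sequence=seq,
                    parent_se=parent_se,
                )
            )
        i = j
    return out


def build_crc(
    tf_to_se: Mapping[str, str],
    nfrs_by_se: Mapping[str, Sequence[NFR]],
    pwms_by_tf: Mapping[str, PWM],
    threshold_fraction: float = 0.8,
) -> CRCGraph:
    """Directed TF regulation graph: u -> v iff u's motif hits any NFR of
    v's SE.  TFs lacking a PWM are dropped with a warning; TFs lacking an
    assigned SE cannot be nodes by construction."""
    nodes = set()
    for tf in tf_to_se:
        if tf in pwms_by_tf:
            nodes.add(tf)
        else:
            logger.warning("TF %s has no PWM in the motif library; excluded from CRC", tf)
    edges: Set[Tuple[str, str]] = set()
    hit_cache: Dict[Tuple[str, str], bool] = {}
    for u in nodes:
        pwm = pwms_by_tf[u]
        for v in nodes:
            se_key = tf_to_se[v]
            cache_key = (u, se_key)
            if cache_key not in hit_cache:
                seqs = [n.sequence for n in nfrs_by_se.get(se_key, [])]
                hit_cache[cache_key] = bool(
                    sequences_with_hit(seqs, pwm, threshold_fraction).any()
                )
            if hit_cache[cache_key]:
                edges.add((u, v))
    return CRCGraph(nodes=nodes, edges=edges)


def enumerate_cliques(graph: CRCGraph, min_size: int = 2) -> List[CliqueScore]:
    """Maximal fully interconnected sets of autoregulated TFs, scored.

    A clique is a maximal set of autoregulated nodes with every ordered
    pair (both directions) present in the edge set.  tf_score(t) is the
    fraction of enumerated cliques containing t; a clique's score is the
    mean of its members' tf_scores.  Sorted by score descending, ties by
    the sorted member list.
    """
    g = graph.mutual_graph()
    cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= min_size]
    if not cliques:
        return []
    counts: Dict[str, int] = {}
    for c in cliques:
        for t in c:
            counts[t] = counts.get(t, 0) + 1
    tf_scores = {t: counts[t] / len(cliques) for t in counts}
    scored = [
        CliqueScore(
            clique=c,
            tf_scores={t: tf_scores[t] for t in sorted(c)},
            clique_score=float(np.mean([tf_scores[t] for t in c])),
        )
        for c in cliques
    ]
    scored.sort(key=lambda cs: (-cs.clique_score, tuple(sorted(cs.clique))))
    return scored
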