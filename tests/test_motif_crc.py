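from itertools import combinations
from math import comb

import numpy as np
import pytest

from secrc.core_io import GenomicInterval, PWM
from secrc.motif_crc import (
    NFR,
    CRCGraph,
    build_crc,
    enrichment_test,
    enumerate_cliques,
    find_nfrs,
    find_valley_nfrs,
    reverse_complement,
    scan_motif,
)


def one_hot_pwm(consensus, motif_id="M1", tf_name="TF1"):
    matrix = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus):
        matrix[i, "ACGT".index(base)] = 1.0
    return PWM(motif_id=motif_id, tf_name=tf_name, matrix=matrix)


def nfr_from_seq(seq, start=0, chrom="chr1"):
    return NFR(interval=GenomicInterval(chrom, start, start + len(seq)), sequence=seq)


class TestScanMotif:
    def test_exact_match_forward(self):
        hits = scan_motif(one_hot_pwm("ACGG"), "TTACGGTT", threshold_fraction=1.0)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]

    def test_reverse_strand_hit_at_revcomp_site(self):
        # CCGT is the reverse complement of ACGG
        hits = scan_motif(one_hot_pwm("ACGG"), "TTCCGTTT", threshold_fraction=1.0)
        assert [(h.offset, h.strand) for h in hits] == [(2, "-")]

    def test_ambiguous_bases_never_match(self):
        assert scan_motif(one_hot_pwm("ACGG"), "NNNN") == []
        assert scan_motif(one_hot_pwm("ACGG"), "ACGN", threshold_fraction=0.5) == []

    def test_uniform_pwm_degenerate_hits_everywhere(self):
        pwm = PWM(motif_id="U", tf_name="U", matrix=np.full((3, 4), 0.25))
        hits = scan_motif(pwm, "ACGTAC", threshold_fraction=1.0)
        # max attainable score is 0, so every N-free window on both strands hits
        assert sorted({h.offset for h in hits}) == [0, 1, 2, 3]
        assert len(hits) == 8

    def test_pwm_longer_than_sequence_is_empty_not_error(self):
        assert scan_motif(one_hot_pwm("ACGTACGT"), "ACG") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_complement_mirror_property(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 60))
        counts = rng.integers(0, 20, (6, 4)) + 1
        pwm = PWM("M", "M", counts / counts.sum(axis=1, keepdims=True))
        fwd = scan_motif(pwm, seq, threshold_fraction=0.75)
        rev = scan_motif(pwm, reverse_complement(seq), threshold_fraction=0.75)
        mirrored = sorted(
            (len(seq) - len(pwm) - h.offset, {"+": "-", "-": "+"}[h.strand], round(h.log_odds, 9))
            for h in rev
        )
        assert mirrored == sorted((h.offset, h.strand, round(h.log_odds, 9)) for h in fwd)


class TestEnrichmentTest:
    def test_exact_hypergeometric_tail(self):
        targets = [nfr_from_seq("TTACGGTT", start=10 * i) for i in range(10)]
        background = [nfr_from_seq("TTTTTTTT", start=10_000 + 10 * i) for i in range(100)]
        res = enrichment_test(targets, background, one_hot_pwm("ACGG"), threshold_fraction=1.0)
        assert res.n_target_hits == 10 and res.n_background_hits == 0
        assert res.p_value == pytest.approx(1 / comb(110, 10), rel=1e-9)

    def test_no_enrichment_when_identical(self):
        seqs = [nfr_from_seq("TTACGGTT", start=10 * i) for i in range(20)]
        other = [nfr_from_seq("TTACGGTT", start=1_000 + 10 * i) for i in range(20)]
        res = enrichment_test(seqs, other, one_hot_pwm("ACGG"), threshold_fraction=1.0)
        assert res.p_value >= 0.5

    def test_zero_target_hits_gives_p_one(self):
        targets = [nfr_from_seq("TTTTTTTT", start=10 * i) for i in range(5)]
        background = [nfr_from_seq("TTACGGTT", start=1_000 + 10 * i) for i in range(5)]
        res = enrichment_test(targets, background, one_hot_pwm("ACGG"), threshold_fraction=1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            enrichment_test([nfr_from_seq("ACGT")], [], one_hot_pwm("ACGG"))


class TestFindNFRs:
    def test_provided_mode_intersects_constituents(self):
        genome = {"chr1": "A" * 1_000}
        nfrs = find_nfrs(
            [GenomicInterval("chr1", 100, 200)],
            [GenomicInterval("chr1", 120, 180), GenomicInterval("chr1", 500, 600)],
            genome,
        )
        assert [(n.interval.start, n.interval.end) for n in nfrs] == [(120, 180)]
        assert nfrs[0].sequence == "A" * 60

    def test_partial_overlap_is_clipped(self):
        genome = {"chr1": "ACGT" * 100}
        (n,) = find_nfrs(
            [GenomicInterval("chr1", 100, 200)], [GenomicInterval("chr1", 180, 260)], genome
        )
        assert (n.interval.start, n.interval.end) == (180, 200)

    def test_missing_chromosome_is_an_error(self):
        with pytest.raises(KeyError, match="chr9"):
            find_nfrs(
                [GenomicInterval("chr9", 0, 10)], [GenomicInterval("chr9", 0, 10)], {"chr1": "A" * 100}
            )

    def test_flat_coverage_has_no_valley(self):
        cons = GenomicInterval("chr1", 0, 400)
        assert find_valley_nfrs(cons, np.full(400, 5.0)) == []

    def test_twin_peak_profile_yields_one_valley(self):
        cov = np.concatenate([np.full(150, 10.0), np.full(100, 1.0), np.full(150, 10.0)])
        cons = GenomicInterval("chr1", 1_000, 1_400)
        (n,) = find_valley_nfrs(cons, cov)
        assert (n.interval.start, n.interval.end) == (1_150, 1_250)

    def test_valley_without_flanks_rejected(self):
        # low run at the edge has no high flank on the left
        cov = np.concatenate([np.full(100, 1.0), np.full(300, 10.0)])
        cons = GenomicInterval("chr1", 0, 400)
        assert find_valley_nfrs(cons, cov) == []

    def test_short_valley_rejected(self):
        cov = np.concatenate([np.full(180, 10.0), np.full(40, 1.0), np.full(180, 10.0)])
        assert find_valley_nfrs(GenomicInterval("chr1", 0, 400), cov) == []


def exhaustive_clique_oracle(nodes, edges, min_size=2):
    auto = [n for n in nodes if (n, n) in edges]
    valid = []
    for r in range(1, len(auto) + 1):
        for subset in combinations(auto, r):
            if all(
                (u, v) in edges and (v, u) in edges
                for u, v in combinations(subset, 2)
            ):
                valid.append(frozenset(subset))
    maximal = [s for s in valid if not any(s < t for t in valid)]
    return sorted(tuple(sorted(s)) for s in maximal if len(s) >= min_size)


class TestBuildCRC:
    genome = {"TFA": "ACGGATCAGT", "TFB": "CCTGACTGAA", "TFC": "GGATCCTTAA"}

    @staticmethod
    def nfrs_for(sequences):
        return {
            key: [nfr_from_seq(seq, start=1_000 * i)]
            for i, (key, seq) in enumerate(sequences.items())
        }

    def test_planted_triad_is_complete_and_autoregulated(self):
        motifs = {"TFA": "ACGGAT", "TFB": "CCTGAC", "TFC": "GGATCC"}
        pwms = {tf: one_hot_pwm(m, motif_id=tf, tf_name=tf) for tf, m in motifs.items()}
        planted = "".join(motifs.values())
        nfrs = self.nfrs_for({k: planted for k in motifs})
        graph = build_crc({tf: tf for tf in motifs}, nfrs, pwms, threshold_fraction=1.0)
        assert graph.autoregulated == set(motifs)
        assert len(graph.edges) == 9

    def test_tf_with_absent_motif_has_no_edges(self):
        pwms = {
            "HIT": one_hot_pwm("ACGGAT", tf_name="HIT"),
            "MISS": one_hot_pwm("TTTTTT", tf_name="MISS"),
        }
        nfrs = self.nfrs_for({"HIT": "ACGGATACGGAT", "MISS": "ACGGATCCCCCC"})
        graph = build_crc({"HIT": "HIT", "MISS": "MISS"}, nfrs, pwms, threshold_fraction=1.0)
        assert all(u != "MISS" for u, _v in graph.edges)
        assert "MISS" not in graph.autoregulated

    def test_outgoing_only_tf_is_excluded_from_cliques(self):
        # OUT's motif sits in SELF's NFR but not in its own
        pwms = {
            "SELF": one_hot_pwm("ACGGAT", tf_name="SELF"),
            "OUT": one_hot_pwm("CCTGAC", tf_name="OUT"),
        }
        nfrs = self.nfrs_for({"SELF": "ACGGATCCTGAC", "OUT": "ACGGATAAAAAA"})
        graph = build_crc({"SELF": "SELF", "OUT": "OUT"}, nfrs, pwms, threshold_fraction=1.0)
        assert ("OUT", "SELF") in graph.edges
        assert graph.autoregulated == {"SELF"}
        assert enumerate_cliques(graph, min_size=2) == []

    def test_tf_without_pwm_is_dropped_with_warning(self, caplog):
        pwms = {"TFA": one_hot_pwm("ACGGAT", tf_name="TFA")}
        nfrs = self.nfrs_for({"TFA": "ACGGAT", "GHOST": "ACGGAT"})
        with caplog.at_level("WARNING"):
            graph = build_crc({"TFA": "TFA", "GHOST": "GHOST"}, nfrs, pwms)
        assert graph.nodes == {"TFA"}
        assert "GHOST" in caplog.text

    def test_lowering_threshold_never_removes_edges(self):
        rng = np.random.default_rng(17)
        motifs = {f"T{i}": "".join(rng.choice(list("ACGT"), 6)) for i in range(4)}
        pwms = {}
        for tf in motifs:
            counts = rng.integers(1, 15, (6, 4))
            pwms[tf] = PWM(tf, tf, counts / counts.sum(axis=1, keepdims=True))
        nfrs = self.nfrs_for(
            {tf: "".join(rng.choice(list("ACGT"), 80)) for tf in motifs}
        )
        tf_to_se = {tf: tf for tf in motifs}
        strict = build_crc(tf_to_se, nfrs, pwms, threshold_fraction=0.9)
        loose = build_crc(tf_to_se, nfrs, pwms, threshold_fraction=0.6)
        assert strict.edges <= loose.edges


class TestEnumerateCliques:
    def test_complete_triad_scores_one(self):
        nodes = {"A", "B", "C"}
        edges = {(u, v) for u in nodes for v in nodes}
        (cs,) = enumerate_cliques(CRCGraph(nodes=nodes, edges=edges))
        assert cs.clique == frozenset(nodes)
        assert cs.clique_score == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in cs.tf_scores.values())

    def test_no_edges_gives_empty_list(self):
        assert enumerate_cliques(CRCGraph(nodes={"A", "B"}, edges=set())) == []

    def test_scores_are_clique_membership_fractions(self):
        # two overlapping triangles sharing node S
        nodes = {"S", "A", "B", "X", "Y"}
        pairs = [("S", "A"), ("S", "B"), ("A", "B"), ("S", "X"), ("S", "Y"), ("X", "Y")]
        edges = {(n, n) for n in nodes}
        for u, v in pairs:
            edges |= {(u, v), (v, u)}
        cliques = enumerate_cliques(CRCGraph(nodes=nodes, edges=edges))
        assert len(cliques) == 2
        for cs in cliques:
            assert cs.tf_scores["S"] == pytest.approx(1.0)
            assert cs.clique_score == pytest.approx((1.0 + 0.5 + 0.5) / 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_subset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        nodes = {f"N{i}" for i in range(n)}
        edges = {
            (u, v) for u in nodes for v in nodes if rng.random() < 0.45 or u == v and rng.random() < 0.8
        }
        graph = CRCGraph(nodes=nodes, edges=edges)
        got = sorted(tuple(sorted(cs.clique)) for cs in enumerate_cliques(graph, min_size=2))
        assert got == exhaustive_clique_oracle(nodes, edges, min_size=2)
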