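import numpy as np
import pandas as pd
import pytest

from secrc.core_io import GenomicInterval, TSSRecord
from secrc.cross_tumor import (
    MergedSE,
    assign_genes,
    expression_summary,
    gene_frequency_table,
    merge_ses,
    tf_frequency_table,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def tss(pos, gene, chrom="chr1"):
    return TSSRecord(gene, gene, chrom, pos, "+")


def brute_force_union(intervals):
    """Transitive union of strictly overlapping intervals (>= 1 shared base)."""
    items = [[c, s, e] for c, s, e in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(x) for x in items)


class TestMergeSES:
    tumor_of = {"A": "tum1", "B": "tum1", "C": "tum1", "X": "tum2"}

    def test_overlap_union_across_two_lines(self):
        merged = merge_ses({"A": [iv(100, 200)], "B": [iv(150, 300)]}, self.tumor_of)
        assert len(merged) == 1
        m = merged[0]
        assert (m.interval.start, m.interval.end) == (100, 300)
        assert m.cell_line_count == 2 and m.cell_lines == {"A", "B"}

    def test_single_line_se_dropped_at_default(self):
        assert merge_ses({"A": [iv(100, 200)], "B": []}, self.tumor_of) == []

    def test_chain_across_three_lines(self):
        merged = merge_ses(
            {"A": [iv(0, 100)], "B": [iv(50, 200)], "C": [iv(150, 400)]}, self.tumor_of
        )
        assert len(merged) == 1
        assert merged[0].cell_line_count == 3
        assert (merged[0].interval.start, merged[0].interval.end) == (0, 400)

    def test_touching_intervals_do_not_merge(self):
        # bookended intervals share no base
        merged = merge_ses({"A": [iv(0, 100)], "B": [iv(100, 200)]}, self.tumor_of)
        assert merged == []  # two singleton entities, both below min_cell_lines

    def test_tumor_types_kept_separate(self):
        merged = merge_ses(
            {"A": [iv(0, 100)], "X": [iv(0, 100)]}, self.tumor_of, min_cell_lines=1
        )
        assert sorted(m.tumor_type for m in merged) == ["tum1", "tum2"]

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="tumor-type"):
            merge_ses({"Z": [iv(0, 100)]}, self.tumor_of)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_interval_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        per_sample = {
            s: [
                iv(int(p), int(p) + int(l), chrom=f"chr{c}")
                for p, l, c in zip(
                    rng.integers(0, 5_000, 12), rng.integers(1, 600, 12), rng.integers(1, 3, 12)
                )
            ]
            for s in ("A", "B", "C")
        }
        merged = merge_ses(per_sample, self.tumor_of, min_cell_lines=1)
        got = sorted((m.interval.chrom, m.interval.start, m.interval.end) for m in merged)
        pooled = [
            (i.chrom, i.start, i.end) for lst in per_sample.values() for i in lst
        ]
        assert got == brute_force_union(pooled)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_bedtools_merge(self, seed, tmp_path):
        """Cross-check the >= 1 shared base union against bedtools
        (`merge -d -1`, which excludes bookended intervals)."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        rng = np.random.default_rng(seed)
        intervals = sorted(
            (int(p), int(p) + int(l))
            for p, l in zip(rng.integers(0, 20_000, 60), rng.integers(1, 900, 60))
        )
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"chr1\t{s}\t{e}\n" for s, e in intervals))
        out = subprocess.run(
            ["bedtools", "merge", "-d", "-1", "-i", str(bed)],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = [
            ("chr1", int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.strip().splitlines())
        ]
        merged = merge_ses(
            {"A": [iv(s, e) for s, e in intervals]}, self.tumor_of, min_cell_lines=1
        )
        got = [(m.interval.chrom, m.interval.start, m.interval.end) for m in merged]
        assert got == expected

    def test_raising_min_cell_lines_never_adds_entities(self):
        rng = np.random.default_rng(5)
        per_sample = {
            s: [iv(int(p), int(p) + 300) for p in rng.integers(0, 10_000, 15)]
            for s in ("A", "B", "C")
        }
        counts = [
            len(merge_ses(per_sample, self.tumor_of, min_cell_lines=k)) for k in (1, 2, 3)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAssignGenes:
    def make_merged(self, start, end, tumor="tum1"):
        return MergedSE(iv(start, end), tumor, {"A", "B"})

    def test_nearest_tss_wins(self):
        se = self.make_merged(9_500, 10_500)  # center 10,000
        genes = assign_genes([se], [tss(9_000, "GENE1"), tss(12_000, "GENE2")])
        assert genes[se.key] == "GENE1"

    def test_equidistant_tie_breaks_lexicographically(self):
        se = self.make_merged(9_500, 10_500)
        genes = assign_genes([se], [tss(9_000, "GENE-B"), tss(11_000, "GENE-A")])
        assert genes[se.key] == "GENE-A"

    def test_tss_inside_se_is_distance_zero(self):
        se = self.make_merged(9_500, 10_500)
        genes = assign_genes([se], [tss(10_000, "INSIDE"), tss(10_100, "NEAR")])
        assert genes[se.key] == "INSIDE"

    def test_se_on_tss_free_chromosome_unassigned(self):
        se = MergedSE(iv(0, 100, chrom="chrX"), "tum1", {"A", "B"})
        assert assign_genes([se], [tss(10, "G")]) == {}


class TestFrequencyTables:
    def test_gene_categories(self):
        table = gene_frequency_table(
            {
                f"t{i}": (["CONSERVED"] if i < 7 else [])
                + (["LONER"] if i == 0 else [])
                + (["MIDDLING"] if i < 4 else [])
                for i in range(8)
            }
        )
        by_name = {g.gene_symbol: g for g in table}
        assert by_name["CONSERVED"].frequency == 7
        assert by_name["CONSERVED"].category == "conservative"
        assert by_name["LONER"].category == "specific"
        assert by_name["MIDDLING"].frequency == 4
        assert by_name["MIDDLING"].category == "intermediate"

    def test_gene_categories_partition(self):
        rng = np.random.default_rng(7)
        genes_by_tumor = {
            f"t{i}": {f"G{g}" for g in rng.integers(0, 40, 20)} for i in range(8)
        }
        table = gene_frequency_table(genes_by_tumor)
        assert all(g.category in {"conservative", "specific", "intermediate"} for g in table)
        all_genes = set().union(*genes_by_tumor.values())
        assert {g.gene_symbol for g in table} == all_genes

    def test_tf_categories(self):
        table = tf_frequency_table(
            {f"t{i}": (["KLF-like"] if i < 5 else []) + (["POU-like"] if i == 2 else []) + (["SO"] if i < 3 else []) for i in range(8)}
        )
        by_name = {t.tf_name: t for t in table}
        assert by_name["KLF-like"].category == "conservative"  # 5 > 4
        assert by_name["POU-like"].category == "specific"
        assert by_name["SO"].category == "intermediate"


class TestExpressionSummary:
    def test_per_tumor_means(self):
        expr = pd.DataFrame(
            {"s1": [2.0, 1.0], "s2": [4.0, 1.0], "s3": [10.0, 7.0]},
            index=["G1", "G2"],
        )
        mapping = {"s1": "tumA", "s2": "tumA", "s3": "tumB"}
        means, missing = expression_summary(expr, mapping, ["G1", "G2", "GHOST"])
        assert means.loc["G1", "tumA"] == pytest.approx(3.0)
        assert means.loc["G1", "tumB"] == pytest.approx(10.0)  # single-sample type
        assert missing == ["GHOST"]

    def test_constant_matrix_all_means_equal(self):
        expr = pd.DataFrame(5.0, index=["G1", "G2"], columns=["s1", "s2"])
        means, _ = expression_summary(expr, {"s1": "a", "s2": "b"}, ["G1", "G2"])
        assert (means.to_numpy() == 5.0).all()

    def test_unmapped_sample_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["G1"])
        with pytest.raises(ValueError, match="mapping"):
            expression_summary(expr, {}, ["G1"])
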