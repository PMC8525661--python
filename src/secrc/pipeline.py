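"""End-to-end orchestration: configuration, staged execution, provenance.

Stages run in a fixed order (enhancers -> correlate -> rose -> merge ->
genes -> crc -> expression) on a directory of standard-format inputs.
Outputs are plain TSV/BED tables with '#' header comments under one run
directory, plus a JSON manifest recording parameters, input hashes and
output row counts.  Reruns with identical inputs and configuration are
byte-identical; nothing time- or host-dependent is written.
"""
from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    GenomicInterval,
    SampleTrack,
    filter_significant,
    read_chrom_sizes,
    read_peaks,
    read_pwms,
    read_tss,
)
from .enhancer_signal import (
    define_enhancers,
    genome_bin_matrix,
    quantify_enhancer_signal,
    sample_correlation,
)
from .rose import hockey_plot_data, rank_and_cutoff, stitch
from .cross_tumor import (
    assign_genes,
    expression_summary,
    gene_frequency_table,
    merge_ses,
    tf_frequency_table,
)
from .motif_crc import NFR, build_crc, enrichment_test, enumerate_cliques, find_nfrs

logger = logging.getLogger(__name__)

STAGES = ["enhancers", "correlate", "rose", "merge", "genes", "crc", "expression"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # paths
    peaks_dir: str = ""
    fragments_dir: str = ""
    tss: str = ""
    genome: str = ""
    nfr: str = ""
    pwm: str = ""
    samples: str = ""
    chrom_sizes: str = ""
    expression: str = ""  # optional
    out_dir: str = "secrc_run"
    # parameters
    p_threshold: float = 1e-9
    min_tss_distance: int = 2_500
    bin_size: int = 100
    corr_bin_size: int = 2_000
    stitch_distance: int = 12_500
    min_cell_lines: int = 2
    gene_conservative_gt: int = 6
    tf_conservative_gt: int = 4
    motif_threshold: float = 0.8
    enrichment_alpha: float = 0.05
    min_clique_size: int = 2
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        checks = {
            "p_threshold": (0 < self.p_threshold <= 1, "(0, 1]"),
            "min_tss_distance": (self.min_tss_distance > 0, "> 0"),
            "bin_size": (self.bin_size > 0, "> 0"),
            "corr_bin_size": (self.corr_bin_size > 0, "> 0"),
            "stitch_distance": (self.stitch_distance > 0, "> 0"),
            "min_cell_lines": (self.min_cell_lines >= 1, ">= 1"),
            "gene_conservative_gt": (self.gene_conservative_gt >= 1, ">= 1"),
            "tf_conservative_gt": (self.tf_conservative_gt >= 1, ">= 1"),
            "motif_threshold": (0 < self.motif_threshold <= 1, "(0, 1]"),
            "enrichment_alpha": (0 < self.enrichment_alpha < 1, "(0, 1)"),
            "min_clique_size": (self.min_clique_size >= 2, ">= 2"),
        }
        for key, (ok, allowed) in checks.items():
            if not ok:
                raise ValueError(
                    f"parameter {key}={getattr(self, key)!r} out of range (allowed: {allowed})"
                )
        return self


def validate_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys (with a suggestion) and
    filling defaults; an empty file yields the default configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValueError(f"{path}: unknown config key {key!r}{suffix}")
    config = PipelineConfig(**raw).validate()
    logger.info("resolved configuration: %s", asdict(config))
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _row_count(path: Path) -> int:
    """Data rows in a written table (excludes '#' comments and the single
    column-header line)."""
    with open(path) as fh:
        n = sum(1 for line in fh if line.strip() and not line.startswith("#"))
    return max(n - 1, 0)


def _write_table(df: pd.DataFrame, path: Path, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# secrc {__version__}\n# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


class PipelineRunner:
    """Executes pipeline stages in order, holding intermediates in memory."""

    def __init__(self, config: PipelineConfig):
        self.config = config.validate()
        self.out_dir = Path(config.out_dir)
        self.manifest: Dict = {
            "secrc_version": __version__,
            "parameters": {
                k: v
                for k, v in asdict(config).items()
                if not isinstance(v, str) or k == "out_dir"
            },
            "inputs": {},
            "stages": {},
        }
        # intermediates
        self.sample_to_tumor: Dict[str, str] = {}
        self.tss = []
        self.enhancers_by_sample: Dict[str, list] = {}
        self.tracks: Dict[str, SampleTrack] = {}
        self.stitched_by_sample: Dict[str, list] = {}
        self.merged: list = []
        self.assignments: Dict[str, str] = {}
        self.gene_freq = []
        self.cliques_by_tumor: Dict[str, list] = {}
        self.enriched_by_tumor: Dict[str, Set[str]] = {}

    # -- helpers ----------------------------------------------------------
    def _require(self, stage: str, *paths: str) -> None:
        for p in paths:
            if not p:
                raise PipelineError(stage, "required input path not configured")
            if not Path(p).exists():
                raise PipelineError(stage, f"missing input file: {p}")
            self.manifest["inputs"][str(p)] = _sha256(Path(p))

    def _record(self, stage: str, *outputs: Path) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {p.name: _row_count(p) for p in outputs}
        }

    def _sample_files(self, stage: str) -> Dict[str, Tuple[Path, Path]]:
        peaks_dir = Path(self.config.peaks_dir)
        frags_dir = Path(self.config.fragments_dir)
        out = {}
        for sid in sorted(self.sample_to_tumor):
            candidates = [peaks_dir / f"{sid}.narrowPeak", peaks_dir / f"{sid}.bed"]
            peak_file = next((c for c in candidates if c.exists()), None)
            frag_file = frags_dir / f"{sid}.bed"
            if peak_file is None:
                raise PipelineError(stage, f"no peak file for sample {sid} in {peaks_dir}")
            if not frag_file.exists():
                raise PipelineError(stage, f"no fragment file for sample {sid}: {frag_file}")
            out[sid] = (peak_file, frag_file)
        return out

    # -- stages -----------------------------------------------------------
    def stage_enhancers(self) -> None:
        cfg = self.config
        self._require("enhancers", cfg.tss, cfg.samples)
        sheet = pd.read_csv(cfg.samples, sep="\t")
        self.sample_to_tumor = dict(zip(sheet["sample_id"], sheet["tumor_type"]))
        self.tss = read_tss(cfg.tss, format="gtf" if cfg.tss.endswith(".gtf") else "bed6")
        rows = []
        for sid, (peak_file, frag_file) in self._sample_files("enhancers").items():
            self.manifest["inputs"][str(peak_file)] = _sha256(peak_file)
            self.manifest["inputs"][str(frag_file)] = _sha256(frag_file)
            fmt = "narrowPeak" if peak_file.suffix == ".narrowPeak" else "bed"
            peaks = filter_significant(read_peaks(peak_file, format=fmt), cfg.p_threshold)
            candidates = define_enhancers(peaks, self.tss, cfg.min_tss_distance)
            fragments = [p.interval for p in read_peaks(frag_file, format="bed")]
            track = SampleTrack(
                sample_id=sid,
                tumor_type=self.sample_to_tumor[sid],
                fragments=fragments,
            )
            self.tracks[sid] = track
            enhancers = quantify_enhancer_signal(candidates, track, cfg.bin_size)
            self.enhancers_by_sample[sid] = enhancers
            rows.extend(
                {
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "sample_id": sid,
                    "signal": e.signal,
                }
                for e in enhancers
            )
        out = self.out_dir / "enhancers.bed"
        _write_table(
            pd.DataFrame(rows),
            out,
            "enhancer windows (+/-5 kb around TSS-distal peak midpoints); "
            "signal = mean per-bin fragments per million",
        )
        self._record("enhancers", out)

    def stage_correlate(self) -> None:
        cfg = self.config
        self._require("correlate", cfg.chrom_sizes)
        sizes = read_chrom_sizes(cfg.chrom_sizes)
        tracks = [self.tracks[sid] for sid in sorted(self.tracks)]
        matrix = genome_bin_matrix(tracks, sizes, cfg.corr_bin_size)
        corr = sample_correlation(matrix)
        df = pd.DataFrame(corr, index=matrix.sample_ids, columns=matrix.sample_ids)
        out = self.out_dir / "correlation.tsv"
        with open(out, "w") as fh:
            fh.write(
                f"# secrc {__version__}\n# Pearson correlation of {cfg.corr_bin_size} bp "
                "genome-bin fragments-per-million between samples\n"
            )
            df.to_csv(fh, sep="\t", float_format="%.6g", index_label="sample_id")
        self._record("correlate", out)

    def stage_rose(self) -> None:
        cfg = self.config
        se_rows, hockey_frames = [], []
        for sid in sorted(self.enhancers_by_sample):
            stitched = stitch(self.enhancers_by_sample[sid], cfg.stitch_distance)
            rank_and_cutoff(stitched)
            self.stitched_by_sample[sid] = stitched
            plot = hockey_plot_data(stitched)
            plot.insert(0, "sample_id", sid)
            hockey_frames.append(plot)
            se_rows.extend(
                {
                    "chrom": s.interval.chrom,
                    "start": s.interval.start,
                    "end": s.interval.end,
                    "sample_id": sid,
                    "signal": s.signal,
                    "rank": s.rank,
                    "is_super": s.is_super,
                    "n_constituents": len(s.constituents),
                }
                for s in stitched
            )
        ses_out = self.out_dir / "ses.bed"
        _write_table(
            pd.DataFrame(se_rows),
            ses_out,
            "stitched enhancers; signal = sum of constituent signals; "
            "is_super from the slope-1 tangent cutoff on the scaled rank curve",
        )
        hockey_out = self.out_dir / "hockey.tsv"
        _write_table(
            pd.concat(hockey_frames, ignore_index=True), hockey_out, "ranked signal curves"
        )
        self._record("rose", ses_out, hockey_out)

    def stage_merge(self) -> None:
        cfg = self.config
        per_sample = {
            sid: [s.interval for s in stitched if s.is_super]
            for sid, stitched in self.stitched_by_sample.items()
        }
        self.merged = merge_ses(per_sample, self.sample_to_tumor, cfg.min_cell_lines)
        out = self.out_dir / "merged_ses.bed"
        _write_table(
            pd.DataFrame(
                {
                    "chrom": m.interval.chrom,
                    "start": m.interval.start,
                    "end": m.interval.end,
                    "tumor_type": m.tumor_type,
                    "cell_line_count": m.cell_line_count,
                    "cell_lines": ",".join(sorted(m.cell_lines)),
                }
                for m in self.merged
            ),
            out,
            f"SEs unioned across cell lines per tumor type; kept if seen in "
            f">= {cfg.min_cell_lines} cell lines",
        )
        self._record("merge", out)

    def stage_genes(self) -> None:
        cfg = self.config
        self.assignments = assign_genes(self.merged, self.tss)
        genes_by_tumor: Dict[str, Set[str]] = {}
        for m in self.merged:
            gene = self.assignments.get(m.key)
            if gene is not None:
                genes_by_tumor.setdefault(m.tumor_type, set()).add(gene)
        self.gene_freq = gene_frequency_table(genes_by_tumor, cfg.gene_conservative_gt)
        out = self.out_dir / "gene_freq.tsv"
        _write_table(
            pd.DataFrame(
                {
                    "gene_symbol": g.gene_symbol,
                    "frequency": g.frequency,
                    "category": g.category,
                    "tumor_types": ",".join(sorted(g.tumor_types_with_se)),
                }
                for g in self.gene_freq
            ),
            out,
            f"tumor-type frequency of SE target genes; conservative if > "
            f"{cfg.gene_conservative_gt}, specific if == 1",
        )
        self._record("genes", out)

    def stage_crc(self) -> None:
        cfg = self.config
        self._require("crc", cfg.genome, cfg.nfr, cfg.pwm)
        from pyfaidx import Fasta

        genome = Fasta(cfg.genome)
        nfr_intervals = [p.interval for p in read_peaks(cfg.nfr, format="bed")]
        pwms = read_pwms(cfg.pwm)
        pwms_by_tf = {p.tf_name: p for p in pwms}

        tumors = sorted({m.tumor_type for m in self.merged})
        edge_rows, clique_rows, enrich_rows, tf_rows = [], [], [], []
        for tumor in tumors:
            tumor_ses = [m for m in self.merged if m.tumor_type == tumor]
            # constituent peaks of super entities in this tumor's cell lines
            constituents: List[GenomicInterval] = []
            for sid, stitched in self.stitched_by_sample.items():
                if self.sample_to_tumor[sid] != tumor:
                    continue
                for s in stitched:
                    if s.is_super:
                        constituents.extend(e.source_peak.interval for e in s.constituents)
            constituents = sorted(set(constituents))
            se_nfrs = find_nfrs(constituents, nfr_intervals, genome)
            # deduplicate identical intersections from replicate cell lines
            seen = set()
            unique_nfrs = []
            for n in se_nfrs:
                key = (n.interval.chrom, n.interval.start, n.interval.end)
                if key not in seen:
                    seen.add(key)
                    unique_nfrs.append(n)
            se_nfrs = unique_nfrs

            nfrs_by_se: Dict[str, List[NFR]] = {m.key: [] for m in tumor_ses}
            for n in se_nfrs:
                for m in tumor_ses:
                    if n.interval.overlaps(m.interval):
                        n.parent_se = m.key
                        nfrs_by_se[m.key].append(n)
                        break
            se_nfrs = [n for n in se_nfrs if n.parent_se is not None]

            # background: provided NFRs not on any SE of this tumor
            background = []
            for iv in nfr_intervals:
                if not any(iv.overlaps(m.interval) for m in tumor_ses):
                    seq = str(genome[iv.chrom][iv.start : iv.end]).upper()
                    background.append(NFR(interval=iv, sequence=seq))

            enriched: Set[str] = set()
            if se_nfrs and background:
                for pwm in pwms:
                    res = enrichment_test(se_nfrs, background, pwm, cfg.motif_threshold)
                    enrich_rows.append(
                        {
                            "tumor_type": tumor,
                            "pwm_id": res.pwm_id,
                            "tf_name": res.tf_name,
                            "n_target_hits": res.n_target_hits,
                            "n_target": res.n_target,
                            "n_background_hits": res.n_background_hits,
                            "n_background": res.n_background,
                            "p_value": res.p_value,
                        }
                    )
                    if res.p_value < cfg.enrichment_alpha:
                        enriched.add(res.tf_name)
            else:
                logger.warning("tumor %s: no SE NFRs or no background NFRs", tumor)
            self.enriched_by_tumor[tumor] = enriched

            tf_to_se = {}
            for m in tumor_ses:
                gene = self.assignments.get(m.key)
                if gene in pwms_by_tf:
                    tf_to_se[gene] = m.key
            graph = build_crc(tf_to_se, nfrs_by_se, pwms_by_tf, cfg.motif_threshold)
            for u, v in sorted(graph.edges):
                edge_rows.append(
                    {
                        "tumor_type": tumor,
                        "source_tf": u,
                        "target_tf": v,
                        "autoregulation": u == v,
                    }
                )
            cliques = enumerate_cliques(graph, cfg.min_clique_size)
            self.cliques_by_tumor[tumor] = cliques
            for rank, cs in enumerate(cliques, start=1):
                clique_rows.append(
                    {
                        "tumor_type": tumor,
                        "clique_rank": rank,
                        "members": ",".join(sorted(cs.clique)),
                        "size": len(cs.clique),
                        "clique_score": cs.clique_score,
                    }
                )

        tf_freq = tf_frequency_table(self.enriched_by_tumor, cfg.tf_conservative_gt)
        tf_rows = [
            {
                "tf_name": t.tf_name,
                "frequency": t.frequency,
                "category": t.category,
                "tumor_types": ",".join(sorted(t.tumor_types_enriched)),
            }
            for t in tf_freq
        ]
        outs = []
        for name, rows, note in (
            ("crc_edges.tsv", edge_rows, "directed TF->TF edges: source motif hits target SE NFRs"),
            ("cliques.tsv", clique_rows, "maximal fully interconnected autoregulated TF sets"),
            ("enrichment.tsv", enrich_rows, "hypergeometric motif enrichment, SE NFRs vs non-SE NFRs"),
            ("tf_freq.tsv", tf_rows, f"tumor-type frequency of enriched TFs; conservative if > {cfg.tf_conservative_gt}"),
        ):
            out = self.out_dir / name
            _write_table(pd.DataFrame(rows), out, note)
            outs.append(out)
        self._record("crc", *outs)

    def stage_expression(self) -> None:
        cfg = self.config
        if not cfg.expression:
            return
        self._require("expression", cfg.expression)
        expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)
        genes = [g.gene_symbol for g in self.gene_freq]
        means, missing = expression_summary(expr, self.sample_to_tumor, genes)
        out = self.out_dir / "expression_summary.tsv"
        with open(out, "w") as fh:
            fh.write(
                f"# secrc {__version__}\n# mean expression per tumor type for SE target genes\n"
            )
            if missing:
                fh.write(f"# missing genes: {','.join(missing)}\n")
            means.to_csv(fh, sep="\t", float_format="%.6g")
        self._record("expression", out)

    # -- driver -----------------------------------------------------------
    def run(self, until: str = "expression") -> Dict:
        if until not in STAGES:
            raise ValueError(f"unknown stage {until!r}; stages are {STAGES}")
        self.out_dir.mkdir(parents=True, exist_ok=True)
        for stage in STAGES[: STAGES.index(until) + 1]:
            t0 = time.perf_counter()
            try:
                getattr(self, f"stage_{stage}")()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            logger.info("stage %-10s done in %.2fs", stage, time.perf_counter() - t0)
        manifest_path = self.out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return self.manifest


def run_all(config: PipelineConfig, until: str = "expression") -> Dict:
    """Run the pipeline end to end; returns the provenance manifest."""
    return PipelineRunner(config).run(until=until)
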