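import numpy as np
import pytest

from secrc.core_io import GenomicInterval, Peak
from secrc.enhancer_signal import Enhancer


def make_enhancer(start: int, end: int, signal: float = 0.0, chrom: str = "chr1") -> Enhancer:
    iv = GenomicInterval(chrom, start, end)
    return Enhancer(interval=iv, source_peak=Peak(iv), signal=signal)


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """A reduced synthetic input set: 3 tumor types x 2 cell lines on a
    1.3 Mb chromosome.  Session-scoped; tests must not mutate the files."""
    from secrc.synthetic import SyntheticConfig, generate

    config = SyntheticConfig(
        n_tumor_types=3,
        cell_lines_per_type=2,
        genome_length=1_300_000,
        n_shared_ses=2,
        n_specific_ses_per_type=1,
        n_typical=5,
        fragments_per_sample=20_000,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("small_synth")
    truth = generate(config, outdir)
    return config, truth, outdir


def pipeline_config_for(synth_dir, out_dir, seed=0, **overrides):
    from secrc.pipeline import PipelineConfig

    defaults = dict(
        peaks_dir=str(synth_dir / "peaks"),
        fragments_dir=str(synth_dir / "fragments"),
        tss=str(synth_dir / "tss.bed"),
        genome=str(synth_dir / "genome.fa"),
        nfr=str(synth_dir / "nfr.bed"),
        pwm=str(synth_dir / "motifs.pfm"),
        samples=str(synth_dir / "samples.tsv"),
        chrom_sizes=str(synth_dir / "chrom.sizes"),
        out_dir=str(out_dir),
        seed=seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def small_run(small_synth, tmp_path_factory):
    """Full pipeline run on the small synthetic set."""
    from secrc.pipeline import PipelineRunner

    _config, truth, synth_dir = small_synth
    out_dir = tmp_path_factory.mktemp("small_run")
    runner = PipelineRunner(pipeline_config_for(synth_dir, out_dir, seed=11))
    manifest = runner.run()
    return runner, manifest, truth
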