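"""Shared fixtures: one study-scale synthetic library run per session."""

from types import SimpleNamespace

import pytest

from srnatlas.pipeline import RunConfig, run_all
from srnatlas.synthetic import build_genome, default_manifest, simulate_reads

STUDY_SEED = 1
STUDY_N = 200_000


def make_run(tmpdir, seed: int, n_reads: int) -> SimpleNamespace:
    """Build references, simulate a library and run the full pipeline."""
    man = default_manifest(seed)
    paths = build_genome(man, tmpdir)
    _, truth = simulate_reads(man, n_reads, out_fastq=tmpdir / "reads.fastq")
    cfg = RunConfig(
        fastq=str(tmpdir / "reads.fastq"),
        mirna_fasta=str(paths["matures"]),
        genome_fasta=str(paths["genome"]),
        annotation_gff=str(paths["gff"]),
        trna_bed=str(paths["trna_bed"]),
        foreign_mature_fasta=str(paths["foreign"]),
        outdir=str(tmpdir / "run"),
        seed=seed,
    )
    result = run_all(cfg)
    return SimpleNamespace(
        manifest=man, paths=paths, truth=truth, config=cfg, result=result, dir=tmpdir
    )


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """A full study-scale run (200k reads) shared across test modules."""
    return make_run(tmp_path_factory.mktemp("study"), STUDY_SEED, STUDY_N)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A cheaper 40k-read run for structural checks."""
    return make_run(tmp_path_factory.mktemp("small"), STUDY_SEED + 100, 40_000)
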