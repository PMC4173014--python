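"""Shared fixtures: default config and cached end-to-end simulation runs."""

import dataclasses

import numpy as np
import pytest

from relign.io_formats import Config, ReadRecord, load_reference, read_target_regions
from relign.realignment import realign
from relign.simulator import TruthVariant, simulate_dataset


@pytest.fixture()
def config():
    return Config()


def make_read(
    name: str,
    seq: str,
    qual: int = 36,
    quals=None,
    chrom="chr1",
    pos=0,
    cigar=None,
    flags=0,
    mapq=60,
) -> ReadRecord:
    """Convenience constructor for hand-built reads."""
    if quals is None:
        quals = np.full(len(seq), qual, dtype=np.uint8)
    if cigar is None and not (flags & 0x4):
        cigar = [("M", len(seq))]
    return ReadRecord(
        name=name,
        seq=seq,
        quals=np.asarray(quals, dtype=np.uint8),
        chrom=None if flags & 0x4 else chrom,
        pos=-1 if flags & 0x4 else pos,
        cigar=cigar or [],
        mapq=mapq,
        flags=flags,
    )


@dataclasses.dataclass
class PipelineRun:
    sim: object
    out_bam: str
    manifest: dict
    config: Config


def run_pipeline(tmp_dir, variants, ref_length=8000, depth=50, read_length=100,
                 seed=11, error_rate=0.005, config=None) -> PipelineRun:
    sim = simulate_dataset(
        str(tmp_dir),
        ref_length=ref_length,
        variants=variants,
        depth=depth,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )
    cfg = config or Config()
    out_bam = str(tmp_dir / "out.bam")
    reference = load_reference(sim.fasta_path)
    manifest = realign(
        sim.bam_path,
        reference,
        read_target_regions(sim.targets_path),
        cfg,
        out_bam,
    )
    return PipelineRun(sim=sim, out_bam=out_bam, manifest=manifest, config=cfg)


@pytest.fixture(scope="session")
def del50_run(tmp_path_factory):
    """8 kb reference with one homozygous 50 bp deletion, realigned."""
    tmp = tmp_path_factory.mktemp("del50")
    return run_pipeline(tmp, [TruthVariant("DEL", "chr1", 4000, 50)])


@pytest.fixture(scope="session")
def ins25_run(tmp_path_factory):
    """8 kb reference with one homozygous 25 bp insertion, realigned."""
    tmp = tmp_path_factory.mktemp("ins25")
    return run_pipeline(tmp, [TruthVariant("INS", "chr1", 4000, 25)])
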