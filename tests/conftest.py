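"""Shared fixtures: a small synthetic genome with planted JunD-style motifs,
peak calls, alignments and a tiled grid, all generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from seqcover import (
    ChromSizes,
    extend_and_merge,
    read_regions,
    tile,
)
from seqcover import synthetic

GENOME_SEED = 7
CHROM_LENGTHS = {"chr1": 30000, "chr2": 20000, "chr3": 15000}
N_PLANTS = 6


@pytest.fixture(scope="session")
def genome():
    return synthetic.make_genome(GENOME_SEED, CHROM_LENGTHS, n_plants=N_PLANTS)


@pytest.fixture(scope="session")
def data_dir(tmp_path_factory, genome):
    """Directory with genome.fa, chrom.sizes, peaks.narrowPeak, reads.sam."""
    d = tmp_path_factory.mktemp("data")
    genome.write(d / "genome.fa")
    with open(d / "genome.chrom.sizes", "w") as fh:
        for c in genome.sizes:
            fh.write(f"{c}\t{genome.sizes[c]}\n")
    (d / "peaks.narrowPeak").write_text(
        synthetic.make_peaks(genome.plants, 100, genome.sizes)
    )
    return d


@pytest.fixture(scope="session")
def peaks(data_dir, genome):
    return read_regions(data_dir / "peaks.narrowPeak", "narrowpeak", genome.sizes)


@pytest.fixture(scope="session")
def roi(peaks):
    """Union of peaks extended by 1 kb, the ROI-construction recipe."""
    return extend_and_merge(peaks, 1000)


@pytest.fixture(scope="session")
def grid(roi):
    """200-bp windows with a 150-bp flank (500-bp fetch windows)."""
    return tile(roi, 200, 200, flank=150)


@pytest.fixture(scope="session")
def sam_reads(data_dir, genome, roi):
    """SAM file over the ROI plus the 5'-end oracle list."""
    sam_text, five_primes = synthetic.make_alignments(
        genome, roi, depth=25, read_len=36, seed=GENOME_SEED + 1
    )
    path = data_dir / "reads.sam"
    path.write_text(sam_text)
    return path, five_primes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
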