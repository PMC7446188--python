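import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_read, make_simulated_fixture, write_bam, write_fasta  # noqa: E402


@pytest.fixture
def small_bam(tmp_path):
    """Five hand-placed reads on two chromosomes, mixed CIGARs and flags."""
    reads = [
        make_read("r1", 0, 10, "10M", "ACGTACGTAC"),
        make_read("r2", 0, 10, "10M", "ACGTACGTAC", flag=16),  # reverse
        make_read("r3", 0, 15, "5M5N5M", "ACGTAACGTA"),
        make_read("r4", 0, 50, "10M", "ACGTACGTAC", mapq=5),  # low mapq
        make_read("r5", 1, 0, "10M", "GGGGGGGGGG"),
    ]
    path = write_bam(
        str(tmp_path / "small.bam"), [("chr1", 100), ("chr2", 50)], reads
    )
    return path


@pytest.fixture
def small_fasta(tmp_path):
    seqs = {"chr1": "acgT" * 25, "chr2": "ACGTN" * 10}
    return write_fasta(str(tmp_path / "ref.fa"), seqs)


@pytest.fixture
def sim_fixture(tmp_path):
    """Moderate simulated dataset: 2 chromosomes, planted sites."""
    return make_simulated_fixture(
        str(tmp_path / "sim"),
        seed=11,
        chrom_lengths=(("chr1", 6000), ("chr2", 4000)),
        depth=20.0,
        n_sites=12,
        read_length=80,
    )
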