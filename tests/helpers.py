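"""Independent oracles and BAM-building helpers shared by the test suite.

The oracles deliberately re-implement behaviour with naive algorithms
(per-position re-fetching, brute-force scans, manual CIGAR walks) so they
stay independent of the code paths they verify.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from redikit.alignment_io import (
    GenomicInterval,
    fetch_overlapping,
    read_passes_filters,
)
from redikit.pileup_engine import PileupConfig, PositionPileup, TraversalStats

_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}


def parse_cigar(cigar: str) -> List[Tuple[int, int]]:
    """'2M3I5M' -> [(0, 2), (1, 3), (0, 5)]"""
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((_OP_CODE[ch], int(num)))
            num = ""
    return out


def make_read(
    name: str,
    tid: int,
    start: int,
    cigar: str,
    seq: str,
    quals: Optional[Sequence[int]] = None,
    mapq: int = 60,
    flag: int = 0,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment()
    a.query_name = name
    a.reference_id = tid
    a.reference_start = start
    a.cigartuples = parse_cigar(cigar)
    a.query_sequence = seq
    a.query_qualities = list(quals) if quals is not None else [38] * len(seq)
    a.mapping_quality = mapq
    a.flag = flag
    return a


def write_bam(
    path: str,
    chrom_lengths: Sequence[Tuple[str, int]],
    reads: Sequence[pysam.AlignedSegment],
    index: bool = True,
) -> str:
    """Write reads (sorted here by coordinate) to an indexed BAM."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths],
        }
    )
    ordered = sorted(reads, key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for a in ordered:
            bam.write(a)
    if index:
        pysam.index(path)
    return path


def write_fasta(path: str, sequences: Dict[str, str]) -> str:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)
    return path


def reference_positions_of(read) -> Dict[int, Tuple[str, int]]:
    """Manual CIGAR walk: genomic position -> (base, quality).

    Independent of redikit's base_at / tally implementations.
    """
    out: Dict[int, Tuple[str, int]] = {}
    qpos = 0
    gpos = read.start
    for op, n in read.cigar:
        if op in "M=X":
            for k in range(n):
                out[gpos + k] = (read.seq[qpos + k], int(read.quals[qpos + k]))
            qpos += n
            gpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            gpos += n
    return out


def naive_traverse(
    handle,
    interval: GenomicInterval,
    config: PileupConfig,
    stats: Optional[TraversalStats] = None,
) -> List[PositionPileup]:
    """Per-position re-fetching oracle: loads each read once per position."""
    pileups: List[PositionPileup] = []
    for pos in range(interval.start, interval.end):
        counts = [0, 0, 0, 0]
        qual_sum = 0
        fwd = rev = 0
        window = GenomicInterval(interval.chrom, pos, pos + 1)
        for read in fetch_overlapping(handle, window):
            if not read_passes_filters(read, config.read_filters):
                continue
            if stats is not None:
                stats.record_load(read)
            hit = reference_positions_of(read).get(pos)
            if hit is None:
                continue
            base, qual = hit
            if qual < config.min_base_quality or base not in "ACGT":
                continue
            counts["ACGT".index(base)] += 1
            qual_sum += qual
            if read.is_reverse:
                rev += 1
            else:
                fwd += 1
        if sum(counts) > 0:
            pileups.append(
                PositionPileup(
                    chrom=interval.chrom,
                    pos=pos,
                    counts=tuple(counts),
                    qual_sum=qual_sum,
                    forward=fwd,
                    reverse=rev,
                )
            )
    return pileups


def brute_force_overlaps(
    handle, interval: GenomicInterval
) -> List[Tuple[str, int, int]]:
    """All stored reads intersecting the interval, by whole-chromosome scan."""
    length = handle.chromosome_length(interval.chrom)
    hits = []
    for read in fetch_overlapping(handle, GenomicInterval(interval.chrom, 0, length)):
        if read.start < interval.end and read.reference_end > interval.start:
            hits.append((read.query_name, read.start, read.reference_end))
    return hits


def pileup_key(p: PositionPileup) -> tuple:
    return (p.chrom, p.pos, p.counts, p.qual_sum, p.forward, p.reverse)


def file_text(path) -> str:
    with open(path) as fh:
        return fh.read()


def make_simulated_fixture(
    tmpdir,
    seed: int,
    chrom_lengths=(("chr1", 3000),),
    depth: float = 8.0,
    n_sites: int = 5,
    read_length: int = 60,
    error_rate: float = 0.0,
    frac_spliced: float = 0.1,
    frac_indel: float = 0.1,
    low_quality_fraction: float = 0.0,
    freq_range=(0.2, 1.0),
    hotspots=(),
):
    """Reference + truth + BAM triple under ``tmpdir``, deterministic per seed."""
    from redikit.synthetic_data import (
        CoverageProfile,
        generate_reference,
        plant_sites,
        simulate_alignments,
    )

    os.makedirs(tmpdir, exist_ok=True)
    fasta = generate_reference(
        list(chrom_lengths), seed=seed, out_fasta=os.path.join(tmpdir, "ref.fa")
    )
    truth = plant_sites(
        fasta, n_sites, freq_range=freq_range, seed=seed + 1, margin=read_length
    )
    bam = simulate_alignments(
        fasta,
        truth,
        CoverageProfile(baseline=depth, hotspots=tuple(hotspots)),
        read_length=read_length,
        error_rate=error_rate,
        frac_spliced=frac_spliced,
        frac_indel=frac_indel,
        low_quality_fraction=low_quality_fraction,
        seed=seed + 2,
        out_bam=os.path.join(tmpdir, "reads.bam"),
    )
    return fasta, truth, bam
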