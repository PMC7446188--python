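"""Synthetic references, planted editing sites and simulated alignments.

Everything is generated deterministically from an integer seed so that any
fixture can be rebuilt at test time with no external data. Edited sites are
planted per-read with an independent Bernoulli draw at the site's target
frequency: an A on the plus strand reads as G, a T on the minus strand
reads as C (bases stored genome-forward, as in BAM).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .alignment_io import GenomicInterval
from .errors import InsufficientSitesError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthSite:
    chrom: str
    pos: int  # 0-based
    ref: str  # A on plus, T on minus
    strand: str  # "+" or "-"
    frequency: float

    @property
    def edited_base(self) -> str:
        """Base observed genome-forward in an edited read."""
        return "G" if self.strand == "+" else "C"


@dataclass
class TruthTable:
    sites: List[TruthSite] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def by_chrom(self) -> Dict[str, List[TruthSite]]:
        out: Dict[str, List[TruthSite]] = {}
        for s in self.sites:
            out.setdefault(s.chrom, []).append(s)
        for sites in out.values():
            sites.sort(key=lambda s: s.pos)
        return out

    def to_tsv(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\tstrand\tfrequency\n")
            for s in self.sites:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.strand}\t{s.frequency:.6f}\n")

    @classmethod
    def from_tsv(cls, path: Union[str, os.PathLike]) -> "TruthTable":
        sites = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                chrom, pos, ref, strand, freq = line.rstrip("\n").split("\t")
                sites.append(TruthSite(chrom, int(pos), ref, strand, float(freq)))
        return cls(sites)


@dataclass(frozen=True)
class CoverageProfile:
    """Baseline expected depth plus multiplicative hotspots."""

    baseline: float = 30.0
    hotspots: Tuple[Tuple[GenomicInterval, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        for _, fold in self.hotspots:
            if fold < 1:
                raise ValueError("hotspot fold-increase must be >= 1")


def expected_depth(profile: CoverageProfile, chrom: str, pos: int) -> float:
    """Baseline times the product of folds of hotspots containing pos."""
    depth = profile.baseline
    for iv, fold in profile.hotspots:
        if iv.chrom == chrom and iv.start <= pos < iv.end:
            depth *= fold
    return depth


def generate_reference(
    chrom_lengths: Sequence[Tuple[str, int]],
    gc_fraction: float = 0.5,
    seed: int = 0,
    out_fasta: Union[str, os.PathLike] = "reference.fa",
) -> str:
    """Write a random multi-chromosome FASTA (+ .fai index)."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    out_fasta = str(out_fasta)
    with open(out_fasta, "w") as fh:
        for chrom, length in chrom_lengths:
            seq = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
            fh.write(f">{chrom}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60].tobytes().decode("ascii") + "\n")
    pysam.faidx(out_fasta)
    return out_fasta


def _load_sequences(fasta: Union[str, os.PathLike]) -> Dict[str, str]:
    with pysam.FastaFile(str(fasta)) as fa:
        return {c: fa.fetch(c).upper() for c in fa.references}


def plant_sites(
    reference: Union[str, os.PathLike],
    n_sites: int,
    freq_range: Tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
    margin: int = 0,
) -> TruthTable:
    """Draw editable positions (A plus / T minus) without replacement.

    ``margin`` keeps sites away from chromosome ends, where uniformly
    placed reads cannot reach the nominal depth.
    """
    seqs = _load_sequences(reference)
    rng = np.random.default_rng(seed)
    candidates: List[Tuple[str, int, str]] = []
    for chrom, seq in seqs.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        hi = len(arr) - margin
        for pos in np.flatnonzero(arr == ord("A")):
            if margin <= pos < hi:
                candidates.append((chrom, int(pos), "A"))
        for pos in np.flatnonzero(arr == ord("T")):
            if margin <= pos < hi:
                candidates.append((chrom, int(pos), "T"))
    if len(candidates) < n_sites:
        raise InsufficientSitesError(
            f"only {len(candidates)} eligible A/T positions for {n_sites} sites"
        )
    chosen = rng.choice(len(candidates), size=n_sites, replace=False)
    lo, hi = freq_range
    sites = []
    for i in sorted(int(c) for c in chosen):
        chrom, pos, ref = candidates[i]
        strand = "+" if ref == "A" else "-"
        sites.append(
            TruthSite(chrom, pos, ref, strand, float(rng.uniform(lo, hi)))
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return TruthTable(sites)


def _segments(
    profile: CoverageProfile, chrom: str, length: int
) -> List[Tuple[int, int, float]]:
    """Constant-expected-depth segments of one chromosome."""
    cuts = {0, length}
    for iv, _ in profile.hotspots:
        if iv.chrom == chrom:
            cuts.add(max(0, iv.start))
            cuts.add(min(length, iv.end))
    edges = sorted(cuts)
    return [
        (lo, hi, expected_depth(profile, chrom, lo))
        for lo, hi in zip(edges, edges[1:])
    ]


def _build_read(
    name: str,
    tid: int,
    chrom_seq: str,
    start: int,
    read_length: int,
    cigar: List[Tuple[int, int]],
    rng: np.random.Generator,
    site_lookup: Dict[int, TruthSite],
    error_rate: float,
    base_quality: int,
    low_quality_fraction: int,
    is_reverse: bool,
) -> pysam.AlignedSegment:
    """Assemble one alignment; applies edits, then errors, then qualities."""
    seq_parts: List[str] = []
    qpos_of_ref: Dict[int, int] = {}
    qpos = 0
    gpos = start
    for op, n in cigar:
        if op == 0:  # M
            seq_parts.append(chrom_seq[gpos : gpos + n])
            for k in range(n):
                qpos_of_ref[gpos + k] = qpos + k
            qpos += n
            gpos += n
        elif op == 1:  # I
            seq_parts.append(
                rng.choice(_BASES, size=n).tobytes().decode("ascii")
            )
            qpos += n
        elif op in (2, 3):  # D / N
            gpos += n

    seq = np.frombuffer("".join(seq_parts).encode("ascii"), dtype=np.uint8).copy()

    for rpos, qp in qpos_of_ref.items():
        site = site_lookup.get(rpos)
        if site is not None and rng.random() < site.frequency:
            seq[qp] = ord(site.edited_base)

    if error_rate > 0:
        err = np.flatnonzero(rng.random(len(seq)) < error_rate)
        for qp in err:
            current = seq[qp]
            choices = _BASES[_BASES != current]
            seq[qp] = rng.choice(choices)

    quals = np.full(len(seq), base_quality, dtype=np.uint8)
    if low_quality_fraction > 0:
        low = rng.random(len(seq)) < low_quality_fraction
        quals[low] = 15

    a = pysam.AlignedSegment()
    a.query_name = name
    a.reference_id = tid
    a.reference_start = start
    a.mapping_quality = 60
    a.cigartuples = cigar
    a.query_sequence = seq.tobytes().decode("ascii")
    a.query_qualities = quals.tolist()
    a.flag = 16 if is_reverse else 0
    return a


def simulate_alignments(
    reference: Union[str, os.PathLike],
    truth: Optional[TruthTable] = None,
    profile: Optional[CoverageProfile] = None,
    read_length: int = 100,
    error_rate: float = 0.0,
    frac_spliced: float = 0.0,
    frac_indel: float = 0.0,
    low_quality_fraction: float = 0.0,
    forward_fraction: float = 0.5,
    base_quality: int = 38,
    seed: int = 0,
    out_bam: Union[str, os.PathLike] = "reads.bam",
) -> str:
    """Simulate a coordinate-sorted, indexed BAM over ``reference``.

    Read starts are drawn uniformly within constant-depth segments of the
    coverage profile so per-position expected depth follows the profile;
    requested fractions of reads carry an N-gap (splice) or a 2-bp indel.
    """
    truth = truth or TruthTable()
    profile = profile or CoverageProfile()
    rng = np.random.default_rng(seed)
    seqs = _load_sequences(reference)
    chromosomes = list(seqs.items())
    if read_length > min(len(s) for _, s in chromosomes):
        raise ValueError("read_length exceeds shortest chromosome")

    truth_by_chrom = truth.by_chrom()
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in chromosomes],
        }
    )
    out_bam = str(out_bam)
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for tid, (chrom, seq) in enumerate(chromosomes):
            length = len(seq)
            site_lookup = {s.pos: s for s in truth_by_chrom.get(chrom, [])}
            starts: List[int] = []
            for lo, hi, depth in _segments(profile, chrom, length):
                if depth <= 0:
                    continue
                wlo = max(0, lo - read_length + 1)
                whi = min(hi - 1, length - read_length)
                if whi < wlo:
                    continue
                window = whi - wlo + 1
                n = int(round(depth * window / read_length))
                if n > 0:
                    starts.extend(rng.integers(wlo, whi + 1, size=n).tolist())
            starts.sort()
            reads = []
            for i, start in enumerate(starts):
                kind = rng.random()
                cigar: List[Tuple[int, int]]
                if kind < frac_spliced and start + read_length + 250 < length:
                    a_len = int(rng.integers(20, read_length - 19))
                    gap = int(rng.integers(50, 251))
                    cigar = [(0, a_len), (3, gap), (0, read_length - a_len)]
                elif kind < frac_spliced + frac_indel:
                    a_len = int(rng.integers(10, read_length - 12))
                    if rng.random() < 0.5:
                        cigar = [(0, a_len), (1, 2), (0, read_length - a_len - 2)]
                    elif start + read_length + 2 < length:
                        cigar = [(0, a_len), (2, 2), (0, read_length - a_len)]
                    else:
                        cigar = [(0, read_length)]
                else:
                    cigar = [(0, read_length)]
                reads.append(
                    _build_read(
                        name=f"sim_{chrom}_{i}",
                        tid=tid,
                        chrom_seq=seq,
                        start=start,
                        read_length=read_length,
                        cigar=cigar,
                        rng=rng,
                        site_lookup=site_lookup,
                        error_rate=error_rate,
                        base_quality=base_quality,
                        low_quality_fraction=low_quality_fraction,
                        is_reverse=rng.random() >= forward_fraction,
                    )
                )
            for a in reads:
                bam.write(a)
    pysam.index(out_bam)
    return out_bam
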